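"""Hypomethylated-region (HMR) segmentation of a single methylome.

A two-state first-order hidden Markov model runs over the ordered CpG
sequence of each chromosome.  Emissions are beta-binomial on the observed
(methylated, total) read counts, which absorbs the overdispersion of
methylation levels around each state's mean that a plain binomial would
mistake for state switching, especially at low coverage.  Parameters
(start distribution, transition matrix and per-state beta-binomial
(a, b)) are fitted by Baum-Welch EM; the state with the lower emission
mean a/(a+b) is labelled *hypomethylated*.  CpGs are assigned by
posterior decoding (posterior > 0.5), maximal hypomethylated runs become
HMRs, runs are split across CpG deserts (consecutive CpGs further apart
than ``max_intra_gap_bp``) and runs with fewer than ``min_cpgs`` CpGs are
discarded.  HMR intervals span the first CpG to the last CpG + 2 so the
closing dinucleotide is covered (half-open coordinates).

Viterbi decoding is available as an option; posterior decoding is the
default because it gives more stable boundaries for short regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .intervals import GenomicInterval
from .io import MethylomeTable

logger = logging.getLogger(__name__)

__all__ = ["HMR", "SegmentationSummary", "BetaBinomialHMM", "segment_hmrs",
           "summarize_segmentation", "classify_blocks"]


@dataclass(frozen=True)
class HMR:
    """One hypomethylated region called in one sample."""

    interval: GenomicInterval
    n_cpg: int
    mean_level: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_level <= 1.0:
            raise ValueError("mean_level must lie in [0, 1]")


@dataclass(frozen=True)
class SegmentationSummary:
    """Per-sample segmentation summary (region count, genome coverage, sizes)."""

    n_hmrs: int
    coverage_bp: int
    coverage_pct: float
    mean_size_geometric: float


def _betaln(x, y):
    return gammaln(x) + gammaln(y) - gammaln(x + y)


class BetaBinomialHMM:
    """Two-state HMM with beta-binomial emissions, fitted by Baum-Welch.

    Parameters
    ----------
    tol:
        EM stops when the absolute log-likelihood improvement drops below
        this value.
    max_iter:
        Hard cap on EM iterations.
    init_means, init_strength:
        Initial per-state emission means and beta "sample size"
        a + b; state order is (hypomethylated-candidate, methylated).
    """

    N_STATES = 2
    _LOG_BOUNDS = (-7.0, 12.0)

    def __init__(self, tol: float = 1e-4, max_iter: int = 200,
                 init_means=(0.1, 0.8), init_strength: float = 10.0):
        self.tol = tol
        self.max_iter = max_iter
        self.init_means = tuple(init_means)
        self.init_strength = init_strength
        self.converged_ = False
        self.loglik_history_: list[float] = []

    # -- emission helpers ---------------------------------------------------
    @property
    def state_means_(self) -> np.ndarray:
        return self.ab_[:, 0] / self.ab_.sum(axis=1)

    def _emission_logprob_unique(self, k, n) -> np.ndarray:
        """(n_unique, 2) log beta-binomial pmf, binomial coefficient included."""
        out = np.empty((len(k), self.N_STATES))
        lchoose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        for s in range(self.N_STATES):
            a, b = self.ab_[s]
            out[:, s] = lchoose + _betaln(k + a, n - k + b) - _betaln(a, b)
        return out

    # -- core EM ------------------------------------------------------------
    def fit(self, meth, total, lengths, rng: np.random.Generator | None = None):
        """Fit by EM on one or more concatenated sequences.

        ``lengths`` gives the per-sequence (per-chromosome) lengths of the
        concatenated ``meth``/``total`` arrays.  On EM degeneracy the fit
        restarts once from a perturbed initialisation drawn from ``rng``.
        """
        meth = np.asarray(meth, dtype=np.int64)
        total = np.asarray(total, dtype=np.int64)
        rng = rng or np.random.default_rng(0)
        try:
            self._fit_once(meth, total, lengths, jitter=None)
        except FloatingPointError:
            self.converged_ = False
        if not self.converged_ and len(self.loglik_history_) < 2:
            logger.warning("EM failed to improve; restarting from perturbed init")
            self._fit_once(meth, total, lengths, jitter=rng)
            if len(self.loglik_history_) < 2:
                raise RuntimeError("EM degenerate after restart")
        return self

    def _fit_once(self, meth, total, lengths, jitter) -> None:
        means = np.array(self.init_means, dtype=float)
        if jitter is not None:
            means = np.clip(means + jitter.uniform(-0.05, 0.05, size=2), 0.01, 0.99)
        s = self.init_strength
        self.ab_ = np.column_stack([means * s, (1.0 - means) * s])
        self.startprob_ = np.full(self.N_STATES, 0.5)
        self.transmat_ = np.array([[0.99, 0.01], [0.01, 0.99]])
        self.loglik_history_ = []
        self.converged_ = False

        pairs = np.stack([meth, total], axis=1)
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        ku, nu = uniq[:, 0].astype(float), uniq[:, 1].astype(float)

        bounds = [tuple(self._LOG_BOUNDS)] * 2
        prev = -np.inf
        for _ in range(self.max_iter):
            logB = self._emission_logprob_unique(ku, nu)[inverse]
            loglik, gamma, xi_sum, start_acc = _forward_backward_multi(
                logB, self.transmat_, self.startprob_, lengths)
            self.loglik_history_.append(loglik)
            if loglik - prev < self.tol and np.isfinite(prev):
                self.converged_ = True
                break
            prev = loglik
            # M-step: closed forms for start/transition, numeric for emissions
            self.startprob_ = np.clip(start_acc / start_acc.sum(), 1e-10, None)
            self.startprob_ /= self.startprob_.sum()
            tm = np.clip(xi_sum, 1e-10, None)
            self.transmat_ = tm / tm.sum(axis=1, keepdims=True)
            for st in range(self.N_STATES):
                w = np.bincount(inverse, weights=gamma[:, st], minlength=len(ku))
                if w.sum() < 1e-6:
                    continue  # state starved of responsibility; keep params
                theta0 = np.log(self.ab_[st])

                def nll_grad(theta, w=w):
                    a, b = np.exp(theta)
                    ll = w @ (_betaln(ku + a, nu - ku + b) - _betaln(a, b))
                    da = w @ (digamma(ku + a) - digamma(nu + a + b)
                              - digamma(a) + digamma(a + b))
                    db = w @ (digamma(nu - ku + b) - digamma(nu + a + b)
                              - digamma(b) + digamma(a + b))
                    return -ll, -np.array([da * a, db * b])

                res = minimize(nll_grad, theta0, jac=True, method="L-BFGS-B",
                               bounds=bounds, options={"maxiter": 60})
                if np.all(np.isfinite(res.x)):
                    self.ab_[st] = np.exp(res.x)

    # -- decoding -----------------------------------------------------------
    def posterior(self, meth, total, lengths) -> np.ndarray:
        pairs = np.stack([np.asarray(meth, dtype=np.int64),
                          np.asarray(total, dtype=np.int64)], axis=1)
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        logB = self._emission_logprob_unique(
            uniq[:, 0].astype(float), uniq[:, 1].astype(float))[inverse]
        _, gamma, _, _ = _forward_backward_multi(
            logB, self.transmat_, self.startprob_, lengths)
        return gamma

    def viterbi(self, meth, total, lengths) -> np.ndarray:
        pairs = np.stack([np.asarray(meth, dtype=np.int64),
                          np.asarray(total, dtype=np.int64)], axis=1)
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        logB = self._emission_logprob_unique(
            uniq[:, 0].astype(float), uniq[:, 1].astype(float))[inverse]
        logA = np.log(self.transmat_)
        logpi = np.log(self.startprob_)
        states = np.empty(len(logB), dtype=np.int64)
        off = 0
        for ln in lengths:
            states[off:off + ln] = _viterbi_one(logB[off:off + ln], logA, logpi)
            off += ln
        return states


def _fb_kernel(B, A, pi):
    # Scaled forward-backward with explicit loops; numba-jitted when
    # numba is importable (identical arithmetic either way).
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * A[j, k]
            alpha[t, k] = acc * B[t, k]
            s += alpha[t, k]
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s
    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        ct = c[t + 1]
        for j in range(K):
            w_j = B[t + 1, j] * beta[t + 1, j] / ct
            for i in range(K):
                xi_sum[i, j] += alpha[t, i] * A[i, j] * w_j
        for i in range(K):
            acc = 0.0
            for j in range(K):
                acc += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / ct
    gamma = alpha * beta
    for t in range(T):
        s = 0.0
        for k in range(K):
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s
    logc = 0.0
    for t in range(T):
        logc += np.log(c[t])
    return logc, gamma, xi_sum


try:  # optional acceleration; the numpy path is the reference semantics
    from numba import njit as _njit

    _fb_kernel = _njit(cache=False)(_fb_kernel)  # type: ignore[assignment]
except ImportError:  # pragma: no cover - numba present in supported envs
    pass


def _forward_backward_one(B, A, pi):
    """Scaled forward-backward on one sequence; B is the (T, K) linear-domain
    emission matrix already rescaled rowwise.  Returns (sum log c, gamma,
    xi_sum, gamma[0])."""
    logc, gamma, xi_sum = _fb_kernel(B, A, pi)
    return logc, gamma, xi_sum, gamma[0].copy()


def _forward_backward_one_numpy(B, A, pi):
    """Pure-numpy reference used in tests to cross-check the kernel."""
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    alpha[0] = pi * B[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        w = B[t + 1] * beta[t + 1]
        beta[t] = (A @ w) / c[t + 1]
        xi_sum += np.outer(alpha[t], w / c[t + 1]) * A
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return float(np.log(c).sum()), gamma, xi_sum, gamma[0]


def _forward_backward_multi(logB, A, pi, lengths):
    if sum(lengths) != len(logB):
        raise ValueError("lengths do not sum to the number of observations")
    m = logB.max(axis=1, keepdims=True)
    B = np.exp(logB - m)
    np.clip(B, 1e-300, None, out=B)
    loglik = float(m.sum())
    gamma = np.empty_like(B)
    xi_sum = np.zeros((B.shape[1], B.shape[1]))
    start_acc = np.zeros(B.shape[1])
    off = 0
    for ln in lengths:
        ll, g, xs, g0 = _forward_backward_one(B[off:off + ln], A, pi)
        loglik += ll
        gamma[off:off + ln] = g
        xi_sum += xs
        start_acc += g0
        off += ln
    return loglik, gamma, xi_sum, start_acc


def _viterbi_one(logB, logA, logpi):
    T, K = logB.shape
    delta = logpi + logB[0]
    back = np.empty((T, K), dtype=np.int64)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + logB[t]
    states = np.empty(T, dtype=np.int64)
    states[T - 1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        states[t] = back[t + 1, states[t + 1]]
    return states


def _runs(mask: np.ndarray):
    """Yield (start_idx, end_idx) of maximal True runs (end exclusive)."""
    if not mask.any():
        return
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    yield from zip(starts, ends)


def segment_hmrs(sample: MethylomeTable, min_cpgs: int = 10,
                 max_intra_gap_bp: int = 5000, seed: int = 0,
                 decoding: str = "posterior",
                 model: BetaBinomialHMM | None = None) -> list[HMR]:
    """Segment one methylome into HMRs.

    The HMM is fitted jointly across chromosomes (each chromosome is one
    sequence).  If the two fitted states collapse onto one emission mean
    the sample is effectively single-state: everything is called
    hypomethylated if that mean is < 0.5, nothing otherwise.
    """
    if decoding not in ("posterior", "viterbi"):
        raise ValueError("decoding must be 'posterior' or 'viterbi'")
    per_chrom = list(sample.per_chrom())
    if not per_chrom:
        return []
    lengths = [len(p[1]) for p in per_chrom]
    meth = np.concatenate([p[2] for p in per_chrom])
    total = np.concatenate([p[3] for p in per_chrom])

    hmm = model or BetaBinomialHMM()
    hmm.fit(meth, total, lengths, rng=np.random.default_rng(seed))
    means = hmm.state_means_
    if abs(means[0] - means[1]) < 1e-3:
        hypo_mask = np.full(len(meth), bool(means.mean() < 0.5))
        logger.warning("HMM states collapsed (mean %.3f); single-state decoding",
                       means.mean())
    else:
        hypo_state = int(np.argmin(means))
        if decoding == "posterior":
            hypo_mask = hmm.posterior(meth, total, lengths)[:, hypo_state] > 0.5
        else:
            hypo_mask = hmm.viterbi(meth, total, lengths) == hypo_state

    hmrs: list[HMR] = []
    off = 0
    for (chrom, pos, m, t), ln in zip(per_chrom, lengths):
        mask = hypo_mask[off:off + ln]
        off += ln
        for i0, i1 in _runs(mask):
            # split the run across CpG deserts
            gaps = np.diff(pos[i0:i1])
            cut_points = np.flatnonzero(gaps > max_intra_gap_bp) + 1 + i0
            pieces = np.split(np.arange(i0, i1), cut_points - i0)
            for piece in pieces:
                if len(piece) < min_cpgs:
                    continue
                j0, j1 = int(piece[0]), int(piece[-1])
                levels = m[j0:j1 + 1] / t[j0:j1 + 1]
                hmrs.append(HMR(
                    interval=GenomicInterval(chrom, int(pos[j0]), int(pos[j1]) + 2),
                    n_cpg=len(piece),
                    mean_level=float(levels.mean()),
                    sample_id=sample.sample_id,
                ))
    return hmrs


def summarize_segmentation(hmrs: list[HMR], genome_bp: int) -> SegmentationSummary:
    """Count/coverage/size summary of a (non-overlapping) HMR set."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    if not hmrs:
        return SegmentationSummary(0, 0, 0.0, 0.0)
    sizes = np.array([len(h.interval) for h in hmrs], dtype=float)
    cov = int(sizes.sum())
    return SegmentationSummary(
        n_hmrs=len(hmrs),
        coverage_bp=cov,
        coverage_pct=100.0 * cov / genome_bp,
        mean_size_geometric=float(np.exp(np.log(sizes).mean())),
    )


def classify_blocks(hmrs: list[HMR], size_cut_bp: int = 1500,
                    level_band=(0.3, 0.7)) -> list[str]:
    """Label each HMR ``"block"`` (PMD-like: long and intermediately
    methylated) or ``"focal"``. Returned in input order."""
    lo, hi = level_band
    return ["block" if (len(h.interval) > size_cut_bp and lo <= h.mean_level <= hi)
            else "focal" for h in hmrs]
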