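"""Dispersal frequency versus wing length: HMM, logistic threshold, contrasts.

The per-My dispersal-event series (from biogeographic stochastic mapping) is
binarized at its mean into frequent/infrequent regimes.  A two-state hidden
Markov model with Gaussian wing-length (WL) emissions is fit by Baum-Welch —
hidden state = dispersal regime, emission = the bin's mean WL — initialized
from the observed regimes, which also label the states (the state associated
with frequent dispersal).  Simulating many (regime, WL) sequences from the
fitted model and pooling them, a logistic regression of regime on WL yields
the WL threshold (-b0/b1, the P=0.5 crossing) above which dispersal is
notably more frequent; kernel densities of WL per regime are estimated for
both raw and simulated data.  Welch's t and an exact small-sample
Mann-Whitney test compare wing-shape groups.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["binarize", "HmmModel", "fit_hmm", "simulate_and_regress",
           "ThresholdResult", "group_contrast"]


def binarize(events) -> np.ndarray:
    """1 where the count strictly exceeds the series mean, else 0."""
    e = np.asarray(events, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 bins")
    return (e > e.mean()).astype(int)


# ----------------------------------------------------------------------- HMM

@dataclass
class HmmModel:
    """Two-regime Gaussian-emission HMM ({infrequent: 0, frequent: 1})."""

    transition: np.ndarray          # 2x2, rows sum to 1
    means: np.ndarray               # per-regime WL mean, mm
    sds: np.ndarray                 # per-regime WL sd, mm (> 0)
    startprob: np.ndarray
    loglik_path: list[float] = field(default_factory=list)
    variance_floored: bool = False

    def __post_init__(self):
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("emission SDs must be positive")

    # ------------------------------------------------------------- inference
    def _emission_probs(self, obs: np.ndarray) -> np.ndarray:
        return np.column_stack([stats.norm.pdf(obs, self.means[k], self.sds[k])
                                for k in range(2)])

    def forward_loglik(self, obs) -> float:
        """Scaled forward-algorithm log-likelihood of a WL sequence."""
        obs = np.asarray(obs, dtype=float)
        B = self._emission_probs(obs)
        alpha = self.startprob * B[0]
        ll = 0.0
        c = alpha.sum()
        ll += np.log(c)
        alpha /= c
        for t in range(1, obs.size):
            alpha = (alpha @ self.transition) * B[t]
            c = alpha.sum()
            ll += np.log(c)
            alpha /= c
        return float(ll)

    def simulate(self, n_steps: int, rng: np.random.Generator):
        """One (regimes, WL) sequence drawn from the model."""
        z = np.empty(n_steps, dtype=int)
        x = np.empty(n_steps)
        z[0] = rng.choice(2, p=self.startprob)
        for t in range(n_steps):
            if t > 0:
                z[t] = rng.choice(2, p=self.transition[z[t - 1]])
            x[t] = rng.normal(self.means[z[t]], self.sds[z[t]])
        return z, x


def fit_hmm(regimes, wl, seed: int | None = None, max_iter: int = 200,
            tol: float = 1e-8, var_floor: float = 1e-6) -> HmmModel:
    """Baum-Welch fit of the two-regime Gaussian WL emission model.

    The observed (binarized) regimes initialize the transition matrix and the
    emission parameters and label the hidden states afterwards, so state 1 is
    the frequent-dispersal regime.  The EM log-likelihood is asserted to be
    non-decreasing at every iteration; a degenerate emission variance is
    floored with a warning.
    """
    z = np.asarray(regimes, dtype=int)
    x = np.asarray(wl, dtype=float)
    if x.size != z.size or x.size < 10:
        raise ValueError("need aligned sequences of length >= 10")
    # initialization from the observed regimes
    A = np.full((2, 2), 0.1)
    for a, b in zip(z, z[1:]):
        A[a, b] += 1.0
    A /= A.sum(axis=1, keepdims=True)
    means = np.array([x[z == k].mean() if (z == k).any() else x.mean()
                      for k in range(2)])
    if np.isclose(means[0], means[1]):
        means = means + np.array([-0.5, 0.5]) * max(x.std(), 1e-3)
    sds = np.array([max(x[z == k].std(), 0.1 * x.std(), 1e-3)
                    if (z == k).sum() > 1 else max(x.std(), 1e-3)
                    for k in range(2)])
    pi = np.array([0.5, 0.5])
    floored = False
    prev_ll = -np.inf
    ll_path: list[float] = []
    for _ in range(max_iter):
        B = np.column_stack([stats.norm.pdf(x, means[k], sds[k])
                             for k in range(2)])
        B = np.clip(B, 1e-300, None)
        n = x.size
        alpha = np.empty((n, 2))
        scale = np.empty(n)
        alpha[0] = pi * B[0]
        scale[0] = alpha[0].sum()
        alpha[0] /= scale[0]
        for t in range(1, n):
            alpha[t] = (alpha[t - 1] @ A) * B[t]
            scale[t] = alpha[t].sum()
            alpha[t] /= scale[t]
        beta = np.empty((n, 2))
        beta[-1] = 1.0
        for t in range(n - 2, -1, -1):
            beta[t] = (A @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
        ll = float(np.log(scale).sum())
        assert ll >= prev_ll - 1e-6, "EM log-likelihood decreased"
        ll_path.append(ll)
        if ll - prev_ll < tol:
            prev_ll = ll
            break
        prev_ll = ll
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        xi = np.zeros((2, 2))
        for t in range(n - 1):
            m = (alpha[t][:, None] * A) * (B[t + 1] * beta[t + 1])[None, :]
            xi += m / m.sum()
        A = xi / xi.sum(axis=1, keepdims=True)
        pi = gamma[0]
        for k in range(2):
            wk = gamma[:, k]
            means[k] = float(wk @ x / wk.sum())
            var = float(wk @ (x - means[k]) ** 2 / wk.sum())
            if var < var_floor:
                var = var_floor
                floored = True
            sds[k] = np.sqrt(var)
    if floored:
        warnings.warn("degenerate emission variance floored")
    # label states: hidden state most associated with observed frequent regime
    B = np.column_stack([stats.norm.pdf(x, means[k], sds[k]) for k in range(2)])
    post = B / B.sum(axis=1, keepdims=True)
    assoc = np.array([float((post[:, k] * z).sum()) / max(post[:, k].sum(), 1e-12)
                      for k in range(2)])
    if assoc[0] > assoc[1]:  # swap so state 1 = frequent
        A = A[::-1][:, ::-1]
        means, sds, pi = means[::-1].copy(), sds[::-1].copy(), pi[::-1].copy()
    return HmmModel(transition=A, means=means, sds=sds, startprob=pi,
                    loglik_path=ll_path, variance_floored=floored)


# -------------------------------------------------------- logistic + threshold

@dataclass
class ThresholdResult:
    wl_threshold: float
    beta0: float
    beta1: float
    separation: bool
    kde_raw: dict
    kde_simulated: dict
    n_simulations: int


def _logistic_irls(X, y, max_iter=100, tol=1e-10):
    """Plain IRLS logistic fit with a perfect-separation detector."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        if W.max() < 1e-10:
            break
        z = eta + (y - p) / np.clip(W, 1e-10, None)
        WX = X * W[:, None]
        new = np.linalg.solve(X.T @ WX, X.T @ (W * z))
        if np.linalg.norm(new - beta) < tol:
            beta = new
            break
        beta = new
        if np.abs(beta).max() > 1e4:  # diverging: separation
            raise np.linalg.LinAlgError("separation")
    return beta


def _kde(values, bw_method="silverman"):
    if np.std(values) == 0:
        grid = np.linspace(values.min() - 1.0, values.max() + 1.0, 256)
        return {"grid": grid, "density": np.zeros_like(grid)}
    k = stats.gaussian_kde(values, bw_method=bw_method)
    # margin wide enough that the density integrates to ~1 on the grid
    margin = 6.0 * float(k.factor) * float(np.std(values)) + 0.5
    grid = np.linspace(values.min() - margin, values.max() + margin, 512)
    return {"grid": grid, "density": k(grid)}


def simulate_and_regress(model: HmmModel, raw_regimes=None, raw_wl=None,
                         n_iter: int = 10_000, seq_len: int | None = None,
                         seed: int | None = None) -> ThresholdResult:
    """Pooled logistic regression of regime on WL over ``n_iter`` simulations.

    Sequences are simulated from the fitted HMM, pooled, and regime is
    regressed on WL; the threshold is the P = 0.5 crossing -b0/b1.  Perfect
    separation is flagged and the threshold taken as the midpoint of the
    separating gap.  Kernel densities (Silverman bandwidth) of WL per regime
    are estimated for the raw and the simulated data.
    """
    rng = np.random.default_rng(seed)
    if seq_len is None:
        seq_len = len(raw_wl) if raw_wl is not None else 100
    # all sequences simulated in parallel, stepping over time
    Z = np.empty((n_iter, seq_len), dtype=int)
    Z[:, 0] = rng.uniform(size=n_iter) < model.startprob[1]
    p_stay1 = model.transition[:, 1]
    for t in range(1, seq_len):
        Z[:, t] = rng.uniform(size=n_iter) < p_stay1[Z[:, t - 1]]
    z = Z.ravel()
    x = rng.normal(model.means[z], model.sds[z])
    separation = False
    if z.min() == z.max():
        raise ValueError("simulated regimes are constant; cannot regress")
    hi0, lo1 = x[z == 0].max(), x[z == 1].min()
    if lo1 > hi0:  # perfectly separated in WL
        separation = True
        thr = 0.5 * (hi0 + lo1)
        b0, b1 = np.nan, np.nan
    else:
        X = np.column_stack([np.ones_like(x), x])
        try:
            beta = _logistic_irls(X, z.astype(float))
            b0, b1 = float(beta[0]), float(beta[1])
            thr = -b0 / b1 if b1 != 0 else np.nan
        except np.linalg.LinAlgError:
            separation = True
            thr = 0.5 * (hi0 + lo1)
            b0, b1 = np.nan, np.nan
    kde_sim = {k: _kde(x[z == k]) for k in (0, 1)}
    kde_raw = {}
    if raw_wl is not None and raw_regimes is not None:
        rw = np.asarray(raw_wl, dtype=float)
        rz = np.asarray(raw_regimes, dtype=int)
        for k in (0, 1):
            if (rz == k).sum() >= 2:
                kde_raw[k] = _kde(rw[rz == k])
    return ThresholdResult(wl_threshold=float(thr), beta0=b0, beta1=b1,
                           separation=separation, kde_raw=kde_raw,
                           kde_simulated=kde_sim, n_simulations=n_iter)


# ------------------------------------------------------------ group contrasts

def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumeration (small samples)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = a.size
    obs = float(ranks[:n1].sum())
    idx = range(pooled.size)
    mu = n1 * (pooled.size + 1) / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(idx, n1):
        w = float(ranks[list(comb)].sum())
        total += 1
        if abs(w - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


def group_contrast(values_a, values_b) -> dict:
    """Welch's t and Mann-Whitney rank-sum statistics for two groups.

    The rank-sum null is exact (full enumeration) when both groups have at
    most 10 observations combined <= 20; otherwise the normal approximation
    with tie correction is used.  Two groups with zero variance and equal
    means give p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one observation")
    out: dict = {"mean_a": float(a.mean()), "mean_b": float(b.mean()),
                 "n_a": int(a.size), "n_b": int(b.size)}
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        out.update(welch_t=0.0, welch_p=1.0, u_stat=float(a.size * b.size / 2),
                   ranksum_p=1.0, exact=True)
        return out
    if a.size >= 2 and b.size >= 2:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out.update(welch_t=float(t), welch_p=float(p))
    else:
        out.update(welch_t=np.nan, welch_p=np.nan)
    u = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    if a.size <= 10 and b.size <= 10:
        out.update(u_stat=float(u.statistic), ranksum_p=_exact_rank_sum_p(a, b),
                   exact=True)
    else:
        out.update(u_stat=float(u.statistic), ranksum_p=float(u.pvalue),
                   exact=False)
    return out
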