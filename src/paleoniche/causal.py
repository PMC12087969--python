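"""Convergent cross-mapping (CCM) and plain correlation tests.

CCM infers causality between coupled dynamical systems: if x forces y, the
time-delay embedding (shadow manifold) of y contains information about x, so
cross-mapping from y's manifold predicts x with a skill that *converges*
(increases) as the library of manifold points grows.  Prediction uses simplex
projection: the E+1 nearest library neighbours of each target point with
exponential distance weights.  Significance comes from phase-randomized
surrogates of the putative cause, which preserve the power spectrum but
destroy the coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["CCMConfig", "CCMResult", "ccm", "correlate",
           "choose_embedding", "phase_surrogate"]


@dataclass
class CCMConfig:
    E: int = 2                  # embedding dimension
    tau: int = 1                # embedding lag
    library_sizes: list[int] | None = None
    n_samples: int = 20         # random libraries per size
    n_surrogates: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.E < 2:
            raise ValueError("E must be at least 2")
        if self.tau < 1:
            raise ValueError("tau must be at least 1")


@dataclass
class CCMResult:
    library_sizes: np.ndarray
    skill_curve: np.ndarray     # mean rho per library size
    skill_final: float
    p_value: float
    convergent: bool
    direction: str
    extras: dict = field(default_factory=dict)


def _embed(y: np.ndarray, E: int, tau: int) -> np.ndarray:
    n = y.size - (E - 1) * tau
    if n < 2:
        raise ValueError("series too short for this embedding")
    return np.column_stack([y[(E - 1 - k) * tau:(E - 1 - k) * tau + n]
                            for k in range(E)])


def _cross_map_skill(M: np.ndarray, x: np.ndarray, lib_idx: np.ndarray,
                     D: np.ndarray, E: int) -> float:
    """Simplex-projection estimate of x from manifold M using library lib_idx."""
    preds = np.empty(M.shape[0])
    for t in range(M.shape[0]):
        cand = lib_idx[lib_idx != t]
        d = D[t, cand]
        order = np.argsort(d, kind="stable")[:E + 1]
        nn = cand[order]
        dn = d[order]
        dmin = max(dn[0], 1e-12)
        w = np.exp(-dn / dmin)
        w /= w.sum()
        preds[t] = w @ x[nn]
    if np.std(preds) == 0 or np.std(x) == 0:
        return 0.0
    return float(np.corrcoef(preds, x)[0, 1])


def phase_surrogate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized surrogate preserving the power spectrum."""
    n = x.size
    X = np.fft.rfft(x)
    phases = rng.uniform(0, 2 * np.pi, X.size)
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0
    return np.fft.irfft(np.abs(X) * np.exp(1j * phases), n)


def ccm(x_series, y_series, cfg: CCMConfig | None = None) -> CCMResult:
    """Test the direction "x causes y" by cross-mapping x from y's manifold.

    Skill is the Pearson correlation between the cross-mapped and observed
    cause.  The result is convergent when skill increases from the smallest
    to the largest library and the final skill exceeds the surrogate null's
    99th percentile; the p-value is the surrogate exceedance probability.
    """
    cfg = cfg or CCMConfig()
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant series: cross-map skill undefined")
    offset = (cfg.E - 1) * cfg.tau
    if x.size < offset + cfg.E + 2:
        raise ValueError("series too short for this embedding")
    rng = np.random.default_rng(cfg.seed)
    M = _embed(y, cfg.E, cfg.tau)
    xa = x[offset:]
    n = M.shape[0]
    D = np.sqrt(((M[:, None, :] - M[None, :, :]) ** 2).sum(axis=2))
    if cfg.library_sizes is None:
        lo = cfg.E + 2
        sizes = np.unique(np.linspace(lo, n, 8).astype(int))
    else:
        sizes = np.array([s for s in cfg.library_sizes if s <= n], dtype=int)
        if sizes.size == 0:
            raise ValueError("all library sizes exceed the manifold size")
    curve = np.empty(sizes.size)
    for si, L in enumerate(sizes):
        reps = []
        for _ in range(cfg.n_samples if L < n else 1):
            lib = rng.choice(n, size=L, replace=False)
            reps.append(_cross_map_skill(M, xa, lib, D, cfg.E))
        curve[si] = float(np.mean(reps))
    full_lib = np.arange(n)
    skill_final = _cross_map_skill(M, xa, full_lib, D, cfg.E)
    null = np.empty(cfg.n_surrogates)
    for k in range(cfg.n_surrogates):
        xs = phase_surrogate(x, rng)[offset:]
        null[k] = _cross_map_skill(M, xs, full_lib, D, cfg.E)
    p = float((1 + (null >= skill_final).sum()) / (cfg.n_surrogates + 1))
    # convergence demands a non-trivial skill increase (0.05), not any slope:
    # on uncoupled noise the curve's sign is a coin flip
    convergent = bool(curve[-1] - curve[0] > 0.05 and
                      skill_final > np.percentile(null, 99))
    return CCMResult(library_sizes=sizes, skill_curve=curve,
                     skill_final=skill_final, p_value=p, convergent=convergent,
                     direction="x->y",
                     extras={"E": cfg.E, "tau": cfg.tau,
                             "null_q99": float(np.percentile(null, 99))})


def choose_embedding(y_series, max_E: int = 6, max_tau: int = 10) -> tuple[int, int]:
    """Heuristic (E, tau): first 1/e autocorrelation crossing; FNN-style E.

    Both choices are returned so callers can log them.
    """
    y = np.asarray(y_series, dtype=float)
    yc = y - y.mean()
    denom = float(yc @ yc)
    tau = 1
    for lag in range(1, min(max_tau, y.size // 3) + 1):
        r = float(yc[:-lag] @ yc[lag:]) / denom
        if r < 1.0 / np.e:
            tau = lag
            break
    best_e = 2
    for E in range(2, max_E + 1):
        try:
            M1 = _embed(y, E, tau)
            M2 = _embed(y, E + 1, tau)
        except ValueError:
            break
        m = min(M1.shape[0], M2.shape[0])
        M1 = M1[-m:]
        M2 = M2[-m:]
        false = 0
        for t in range(m):
            d = np.sqrt(((M1 - M1[t]) ** 2).sum(axis=1))
            d[t] = np.inf
            nn = int(np.argmin(d))
            d2 = np.sqrt(((M2[t] - M2[nn]) ** 2).sum())
            if d[nn] > 0 and d2 / d[nn] > 10:
                false += 1
        best_e = E
        if false / m < 0.1:
            break
    return best_e, tau


def correlate(series_a, series_b, method: str = "pearson") -> dict:
    """Pearson or Spearman correlation with a two-sided p-value.

    Spearman uses average ranks for ties (scipy's default).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size or a.size < 4:
        raise ValueError("need at least 4 paired points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant input: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return {"r": float(r), "p": float(p), "method": method, "n": int(a.size)}
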