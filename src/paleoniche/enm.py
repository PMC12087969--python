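"""Ecological niche modeling: screening, thinning, linear-feature MaxEnt.

The suitability model is the maximum-entropy Gibbs distribution over
background cells with linear features only: cell density
q(x) = exp(w . z(x)) / Z with features z scaled to [0, 1] by background
min/max, fit by maximizing the L1-regularized log likelihood of the presence
feature means.  At the optimum the KKT conditions bound each feature's model
expectation within beta_f of its presence mean, with
beta_f = reg_multiplier * sd_f / sqrt(n_presences) (reg_multiplier 1.5 by
default).  Output is the complementary log-log transform
P = 1 - exp(-exp(H) * q) (H the entropy of q over the background), with a
raw-density switch.  Projections are classed suitable (P > 0.5), less
suitable (0.3 < P <= 0.5) and unsuitable (P <= 0.3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from .rasters import ClimateSlice

__all__ = [
    "screen_variables", "thin_records", "LinearMaxEnt", "fit_maxent_linear",
    "SuitabilityMap", "project", "evaluate", "EnmEvaluation",
]


# ------------------------------------------------------------------ screening

def screen_variables(records: pd.DataFrame, threshold: float = 0.8) -> dict:
    """Correlation grouping plus PCA-contribution selection.

    Variables whose pairwise |Pearson r| reaches ``threshold`` are grouped
    (connected components); within each group the variable contributing most
    to the principal components (variance-weighted squared loadings) is
    retained.  Constant variables are excluded with a warning.  Returns the
    retained names plus the full correlation and contribution tables.
    """
    if len(records) < 3 or records.shape[1] < 2:
        raise ValueError("need at least 3 records and 2 variables")
    X = records.astype(float)
    sd = X.std(ddof=0)
    constant = list(sd.index[sd == 0])
    if constant:
        warnings.warn(f"constant variables excluded: {constant}")
        X = X.drop(columns=constant)
    corr = X.corr()
    g = nx.Graph()
    g.add_nodes_from(X.columns)
    for i, a in enumerate(X.columns):
        for b in X.columns[i + 1:]:
            if abs(corr.loc[a, b]) >= threshold:
                g.add_edge(a, b)
    Z = (X - X.mean()) / X.std(ddof=0)
    pca = PCA()
    pca.fit(Z.to_numpy())
    # contribution over the leading components covering >= 80% of variance
    # (weighting over ALL components is identically 1/p for a correlation PCA)
    evr = pca.explained_variance_ratio_
    m = int(np.searchsorted(np.cumsum(evr), 0.80)) + 1
    contrib = pd.Series(
        (pca.components_[:m] ** 2 * evr[:m, None]).sum(axis=0) / evr[:m].sum(),
        index=X.columns, name="pc_contribution")
    selected = []
    for comp in nx.connected_components(g):
        best = max(comp, key=lambda v: contrib[v])
        selected.append(best)
    selected = [v for v in X.columns if v in set(selected)]  # stable order
    return {"selected": selected, "correlation": corr,
            "contributions": contrib, "excluded_constant": constant,
            "groups": [sorted(c) for c in nx.connected_components(g)],
            "threshold": threshold}


# ------------------------------------------------------------------- thinning

_EARTH_R_KM = 6371.0088


def great_circle_km(lon1, lat1, lon2, lat2) -> float:
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dl = np.deg2rad(lon2 - lon1)
    h = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * _EARTH_R_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def thin_records(records: pd.DataFrame, radius_km: float) -> pd.DataFrame:
    """Greedy spatial thinning: first record kept wins (deterministic).

    No two retained records lie within ``radius_km`` great-circle distance.
    """
    if radius_km < 0:
        raise ValueError("radius must be nonnegative")
    if radius_km == 0 or len(records) == 0:
        return records.copy()
    kept: list[int] = []
    lons = records["lon"].to_numpy()
    lats = records["lat"].to_numpy()
    for i in range(len(records)):
        ok = True
        for k in kept:
            if great_circle_km(lons[i], lats[i], lons[k], lats[k]) < radius_km:
                ok = False
                break
        if ok:
            kept.append(i)
    return records.iloc[kept].copy()


# -------------------------------------------------------------------- MaxEnt

class LinearMaxEnt:
    """Linear-feature maximum-entropy niche model (sklearn-style).

    Parameters
    ----------
    reg_multiplier : float
        L1 regularization multiplier (1.5 default).
    output_transform : {"cloglog", "raw"}
        Output scale of :meth:`predict`.
    """

    def __init__(self, reg_multiplier: float = 1.5,
                 output_transform: str = "cloglog"):
        if reg_multiplier <= 0:
            raise ValueError("reg_multiplier must be positive")
        if output_transform not in ("cloglog", "raw"):
            raise ValueError("output_transform must be 'cloglog' or 'raw'")
        self.reg_multiplier = reg_multiplier
        self.output_transform = output_transform

    # ------------------------------------------------------------------ fit
    def fit(self, presences, background, variable_names=None) -> "LinearMaxEnt":
        P = self._as_array(presences, variable_names, fit=True)
        B = self._as_array(background, variable_names)
        if P.shape[0] < 2:
            raise ValueError("need at least 2 presences")
        lo = B.min(axis=0)
        hi = B.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        self.feature_bounds_ = (lo, hi)
        Zp = (P - lo) / span
        Zb = (B - lo) / span
        pbar = Zp.mean(axis=0)
        sd = Zp.std(axis=0, ddof=0)
        beta = self.reg_multiplier * (sd + 1e-3) / np.sqrt(P.shape[0])
        m = Zb.shape[1]

        def obj(uv):
            w = uv[:m] - uv[m:]
            eta = Zb @ w
            lse = logsumexp(eta)
            q = np.exp(eta - lse)
            val = lse - w @ pbar + beta @ (uv[:m] + uv[m:])
            Ez = q @ Zb
            g = Ez - pbar
            return val, np.concatenate([g + beta, -g + beta])

        res = minimize(obj, np.zeros(2 * m), jac=True, method="L-BFGS-B",
                       bounds=[(0, None)] * 2 * m,
                       options={"maxiter": 5000, "ftol": 1e-18, "gtol": 1e-13,
                                "maxls": 60})
        if not res.success and np.linalg.norm(res.jac) > 1e-3:
            raise RuntimeError(
                f"MaxEnt did not converge (grad norm {np.linalg.norm(res.jac):.2e})")
        w = res.x[:m] - res.x[m:]
        # Newton polish on the active set: L-BFGS-B stops around 1e-7; a few
        # steps on the smooth restricted objective reach machine precision
        free = np.abs(w) > 1e-10
        if free.any():
            sign = np.sign(w)
            for _ in range(30):
                eta = Zb @ w
                q = np.exp(eta - logsumexp(eta))
                Ez = q @ Zb
                g = (Ez - pbar + sign * beta)[free]
                if np.max(np.abs(g)) < 1e-14:
                    break
                Zc = Zb[:, free] - Ez[free]
                H = (Zc * q[:, None]).T @ Zc
                try:
                    step = np.linalg.solve(H + 1e-12 * np.eye(H.shape[0]), g)
                except np.linalg.LinAlgError:
                    break
                wn = w.copy()
                wn[free] -= step
                if np.any(np.sign(wn[free]) * sign[free] < 0):
                    break  # active set would change; keep the L-BFGS-B point
                w = wn
        self.weights_ = w
        self.beta_ = beta
        self.presence_means_ = pbar
        eta = Zb @ self.weights_
        self._logZ = float(logsumexp(eta))
        q = np.exp(eta - self._logZ)
        self.entropy_ = float(-(q * np.log(np.clip(q, 1e-300, None))).sum())
        self.background_density_ = q
        return self

    def _as_array(self, X, names, fit=False):
        if isinstance(X, pd.DataFrame):
            if fit:
                self.selected_variables_ = (list(names) if names
                                            else list(X.columns))
            cols = getattr(self, "selected_variables_", None) or list(X.columns)
            return X[cols].to_numpy(dtype=float)
        if fit:
            self.selected_variables_ = list(names) if names else None
        return np.asarray(X, dtype=float)

    # -------------------------------------------------------------- predict
    def raw_density(self, X) -> np.ndarray:
        Xa = self._as_array(X, None)
        lo, hi = self.feature_bounds_
        span = np.where(hi > lo, hi - lo, 1.0)
        Z = (Xa - lo) / span
        return np.exp(Z @ self.weights_ - self._logZ)

    def predict(self, X) -> np.ndarray:
        q = self.raw_density(X)
        if self.output_transform == "raw":
            return q
        return 1.0 - np.exp(-np.exp(self.entropy_) * q)

    def model_feature_expectations(self, background) -> np.ndarray:
        B = self._as_array(background, None)
        lo, hi = self.feature_bounds_
        span = np.where(hi > lo, hi - lo, 1.0)
        Z = (B - lo) / span
        eta = Z @ self.weights_
        q = np.exp(eta - logsumexp(eta))
        return q @ Z

    def kkt_gaps(self, background) -> np.ndarray:
        """|E_model[f] - presence mean f| per feature (must be <= beta_f)."""
        return np.abs(self.model_feature_expectations(background)
                      - self.presence_means_)

    def get_params(self, deep=True):
        return {"reg_multiplier": self.reg_multiplier,
                "output_transform": self.output_transform}

    def set_params(self, **p):
        for k, v in p.items():
            setattr(self, k, v)
        return self


def fit_maxent_linear(presences, background, reg_multiplier: float = 1.5,
                      variable_names=None,
                      output_transform: str = "cloglog") -> LinearMaxEnt:
    return LinearMaxEnt(reg_multiplier, output_transform).fit(
        presences, background, variable_names)


# ----------------------------------------------------------------- projection

CLASS_NAMES = ("unsuitable", "less_suitable", "suitable")


@dataclass
class SuitabilityMap:
    P: np.ndarray                  # probabilities in [0, 1]
    classes: np.ndarray            # strings per cell
    age_ma: float | None = None
    meta: dict = field(default_factory=dict)

    def class_fractions(self) -> dict:
        tot = self.classes.size
        return {c: float((self.classes == c).sum()) / tot for c in CLASS_NAMES}


def classify(P: np.ndarray) -> np.ndarray:
    """Three-class map: suitable P > 0.5; less suitable 0.3 < P <= 0.5."""
    return np.select([P > 0.5, P > 0.3], ["suitable", "less_suitable"],
                     default="unsuitable")


def project(model, slc: ClimateSlice, variables=None) -> SuitabilityMap:
    """Project one model (or a replicate list, averaged cell-wise) on a slice."""
    models = model if isinstance(model, (list, tuple)) else [model]
    names = variables or models[0].selected_variables_
    if names is None:
        raise ValueError("variable names required to project onto a slice")
    missing = [v for v in names if v not in slc.variables]
    if missing:
        raise ValueError(f"slice is missing variables: {missing}")
    X = slc.table(names)
    P = np.mean([m.predict(X) for m in models], axis=0)
    grid = P.reshape(slc.shape)
    return SuitabilityMap(P=grid, classes=classify(grid), age_ma=slc.age_ma,
                          meta={"variables": list(names),
                                "n_replicates": len(models)})


# ----------------------------------------------------------------- evaluation

@dataclass
class EnmEvaluation:
    auc_train: float
    auc_test: float
    test_fraction: float
    n_replicates: int
    per_replicate: pd.DataFrame | None = None


def evaluate(presences, background, test_fraction: float = 0.2,
             n_replicates: int = 10, seed: int | None = None,
             reg_multiplier: float = 1.5, variable_names=None) -> EnmEvaluation:
    """Replicate-averaged AUC with random presence train/test splits.

    Per replicate the model is refit on the training presences; AUC scores
    presences against the background.  The replicate means are reported.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    P = presences[variable_names] if (isinstance(presences, pd.DataFrame)
                                      and variable_names) else presences
    Pa = P.to_numpy(dtype=float) if isinstance(P, pd.DataFrame) else np.asarray(P, float)
    names = variable_names or (list(P.columns) if isinstance(P, pd.DataFrame) else None)
    B = background[names].to_numpy(dtype=float) if (
        isinstance(background, pd.DataFrame) and names) else np.asarray(
        background, dtype=float)
    n = Pa.shape[0]
    n_test = int(round(n * test_fraction))
    if n_test < 1 or n - n_test < 2:
        raise ValueError("too few presences to split")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        m = LinearMaxEnt(reg_multiplier).fit(Pa[train_idx], B)
        s_bg = m.predict(B)
        auc_tr = roc_auc_score(
            np.r_[np.ones(train_idx.size), np.zeros(B.shape[0])],
            np.r_[m.predict(Pa[train_idx]), s_bg])
        auc_te = roc_auc_score(
            np.r_[np.ones(test_idx.size), np.zeros(B.shape[0])],
            np.r_[m.predict(Pa[test_idx]), s_bg])
        rows.append(dict(replicate=rep, auc_train=auc_tr, auc_test=auc_te))
    tab = pd.DataFrame(rows)
    return EnmEvaluation(auc_train=float(tab["auc_train"].mean()),
                         auc_test=float(tab["auc_test"].mean()),
                         test_fraction=test_fraction,
                         n_replicates=n_replicates, per_replicate=tab)
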