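"""Outlying Mean Index (OMI): niche position and breadth, binned through time.

OMI ordination weights environment axes by species usage.  Sites are weighted
by total abundance; environment variables are centred and standardized with
those weights.  A species' niche position (NP, marginality) is the squared
distance of its abundance-weighted environmental centroid from the overall
(weighted) mean; its niche breadth (NB, tolerance) is the abundance-weighted
variance of the sites it uses around that centroid.  Canonical weights are
the leading eigenvectors of the species-weighted marginality cross-product.

Two aggregation schemes are provided: a five-interval geochronological scheme
and a finer scheme of 10-My bins except for two 20-My bins across 105-65 Ma
(16 bins for a ~170-Ma root), with records assigned half-open [older,
younger) and presence records counted per grid cell as abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OmiResult", "omi", "BinScheme", "bin_scheme",
           "five_interval_scheme", "np_nb_through_time"]


@dataclass
class OmiResult:
    NP: pd.Series                 # per-species marginality (squared distance)
    NB: pd.Series                 # per-species tolerance (weighted variance)
    canonical_weights: pd.DataFrame   # variables x axes
    species_scores: pd.DataFrame
    site_scores: pd.DataFrame
    total_marginality: float      # species-weighted sum of NP (= trace of M)
    eigenvalues: np.ndarray


def omi(site_env: pd.DataFrame, abundance: pd.DataFrame) -> OmiResult:
    """OMI analysis of a sites-by-variables table and a species-by-sites table.

    Species with zero total abundance are excluded with a warning.
    """
    E = site_env.astype(float)
    A = abundance.astype(float)
    if (A.to_numpy() < 0).any():
        raise ValueError("abundance must be nonnegative")
    if list(A.columns) != list(E.index):
        A = A[E.index]
    tot = A.sum(axis=1)
    dead = list(tot.index[tot <= 0])
    if dead:
        warnings.warn(f"species with zero abundance excluded: {dead}")
        A = A.drop(index=dead)
        tot = tot.drop(index=dead)
    w_site = A.sum(axis=0)
    w_site = w_site / w_site.sum()
    mu = E.mul(w_site, axis=0).sum(axis=0)
    var = (E.sub(mu, axis=1) ** 2).mul(w_site, axis=0).sum(axis=0)
    sd = np.sqrt(var)
    if (sd == 0).any():
        zero = list(sd.index[sd == 0])
        warnings.warn(f"constant variables dropped: {zero}")
        E = E.drop(columns=zero)
        mu, sd = mu.drop(zero), sd.drop(zero)
    Z = E.sub(mu, axis=1).div(sd, axis=1)
    U = A.div(A.sum(axis=1), axis=0)  # per-species site profiles
    centroids = U.to_numpy() @ Z.to_numpy()  # species x variables
    np_vals = (centroids ** 2).sum(axis=1)
    nb_vals = np.empty(len(A))
    Zm = Z.to_numpy()
    for k in range(len(A)):
        d2 = ((Zm - centroids[k]) ** 2).sum(axis=1)
        nb_vals[k] = float(U.to_numpy()[k] @ d2)
    w_sp = (tot / tot.sum()).to_numpy()
    M = (centroids * w_sp[:, None]).T @ centroids
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    axes = [f"OMI{k + 1}" for k in range(evecs.shape[1])]
    return OmiResult(
        NP=pd.Series(np_vals, index=A.index, name="NP"),
        NB=pd.Series(nb_vals, index=A.index, name="NB"),
        canonical_weights=pd.DataFrame(evecs, index=Z.columns, columns=axes),
        species_scores=pd.DataFrame(centroids @ evecs, index=A.index, columns=axes),
        site_scores=pd.DataFrame(Zm @ evecs, index=E.index, columns=axes),
        total_marginality=float(w_sp @ np_vals),
        eigenvalues=evals)


# ------------------------------------------------------------------- binning

@dataclass
class BinScheme:
    """Time bins with strictly decreasing edges; bins half-open [older, younger)."""

    edges: list[float]
    labels: list[str] | None = None

    def __post_init__(self):
        e = list(self.edges)
        if any(a <= b for a, b in zip(e, e[1:])):
            raise ValueError("edges must strictly decrease")
        if self.labels is None:
            self.labels = [f"{e[i]:g}-{e[i + 1]:g}" for i in range(len(e) - 1)]

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, age) -> np.ndarray:
        """Bin index per age; the youngest bin is closed at its younger edge."""
        age = np.atleast_1d(np.asarray(age, dtype=float))
        out = np.full(age.shape, -1, dtype=int)
        for b in range(self.n_bins):
            older, younger = self.edges[b], self.edges[b + 1]
            m = (age <= older) & (age > younger) if b < self.n_bins - 1 else \
                (age <= older) & (age >= younger)
            out[m] = b
        return out if out.size > 1 else out


def bin_scheme(root_age: float) -> BinScheme:
    """10-My bins except two 20-My bins spanning 105-65 Ma.

    For a 170-Ma root this yields 16 bins (short 110-105 and 5-0 closers).
    """
    if root_age <= 65:
        raise ValueError("root_age must exceed 65 Ma")
    ladder = []
    cur = root_age
    while cur - 10 > 105:
        cur -= 10
        ladder.append(float(cur))
    ladder += [105.0, 85.0, 65.0, 55.0, 45.0, 35.0, 25.0, 15.0, 5.0]
    edges = [float(root_age)] + [e for e in ladder
                                 if e < root_age - 1e-9] + [0.0]
    return BinScheme(edges=edges)


def five_interval_scheme(root_age: float = 170.0,
                         inner_edges=(145.0, 100.0, 66.0, 23.0)) -> BinScheme:
    """Five coarse geochronological intervals (period-boundary defaults)."""
    edges = [float(root_age)] + [e for e in inner_edges if e < root_age] + [0.0]
    return BinScheme(edges=edges)


def np_nb_through_time(records: pd.DataFrame, scheme: BinScheme,
                       variables, min_records: int = 2) -> pd.DataFrame:
    """Per-bin OMI summaries: NP centroid and NB spread.

    ``records`` needs columns taxon, lon, lat, age_ma plus the environment
    variables; presence records are counted per grid cell (site) as abundance.
    Bins with fewer than ``min_records`` records are reported undefined, not
    fabricated.
    """
    bins = scheme.assign(records["age_ma"].to_numpy())
    rows = []
    for b in range(scheme.n_bins):
        sub = records.iloc[np.flatnonzero(bins == b)]
        if len(sub) < min_records or sub["taxon"].nunique() < 1:
            rows.append(dict(label=scheme.labels[b], bin_older=scheme.edges[b],
                             bin_younger=scheme.edges[b + 1], n_records=len(sub),
                             np_mean=np.nan, nb_mean=np.nan, undefined=True))
            continue
        site_key = sub["lon"].round(6).astype(str) + "_" + sub["lat"].round(6).astype(str)
        sub = sub.assign(_site=site_key.to_numpy())
        env = sub.groupby("_site")[list(variables)].mean()
        ab = sub.groupby(["taxon", "_site"]).size().unstack(fill_value=0)
        ab = ab[env.index]
        if env.shape[0] < 2:
            rows.append(dict(label=scheme.labels[b], bin_older=scheme.edges[b],
                             bin_younger=scheme.edges[b + 1], n_records=len(sub),
                             np_mean=np.nan, nb_mean=np.nan, undefined=True))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = omi(env, ab)
        rows.append(dict(label=scheme.labels[b], bin_older=scheme.edges[b],
                         bin_younger=scheme.edges[b + 1], n_records=len(sub),
                         np_mean=float(res.NP.mean()), nb_mean=float(res.NB.mean()),
                         undefined=False))
    return pd.DataFrame(rows)
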