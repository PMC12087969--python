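"""Synthetic study systems for the full niche-dynamics / dispersal pipeline.

Everything downstream consumes is generated here with the statistical
structure the analyses assume: a fossilized-birth-death (FBD) tree with
non-contemporaneous tips, Brownian niche and wing-length traits (wing length
with a directional trend and an optional wing-shape shift), a 2-state Mk
wing-shape character, latitudinally structured climate grids with a secular
cooling trend, presence records sampled where a planted suitability is high,
an epoch-structured realm adjacency history, geographic ranges simulated with
a planted wing-length -> dispersal-rate coupling, and per-record atmospheric
variables.  Planted parameters are retained so downstream stages can be
tested for recovery.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .rasters import ClimateSlice, write_ascii_grid
from .trees import TimeTree
from . import biogeo
from .biogeo import RealmHistory, Epoch, BiogeoModel

__all__ = [
    "VARIABLES", "SimConfig", "Scenario",
    "simulate_fbd_tree", "simulate_bm_trait", "simulate_mk_states",
    "simulate_climate_history", "simulate_occurrences",
    "simulate_realm_history", "simulate_atmospheric_records",
    "make_scenario", "write_scenario", "realm_of_cells",
]

#: the eleven environmental variables carried by every occurrence record
VARIABLES = ["MAT", "TS", "MAP", "WMP", "DMP", "PS", "EQ", "CI", "WMT", "CMT", "EL"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic scenario.

    Defaults emulate a ~50-genus clade (25 extant + 25 fossil tips) rooted
    near 170 Ma with a modest net diversification rate, a secular cooling of
    0.05 degC/My, eight realms, and a positive wing-length -> dispersal
    coupling (log-odds per mm).
    """

    seed: int = 0
    n_extant: int = 25
    n_fossil: int = 25
    birth_rate: float = 0.025          # per My
    death_rate: float = 0.010          # per My
    fossil_sampling_rate: float = 0.01  # per My per lineage
    root_age: float = 170.0            # Ma
    bm_sigma2: float = 0.05            # trait variance per My
    cooling_slope: float = 0.05        # degC per My (warmer in deep time)
    n_realms: int = 8
    coupling_beta: float = 1.0         # log dispersal-rate units per mm WL
    # generator knobs beyond the headline parameters
    wl_root: float = 4.0               # root wing length, mm
    wl_trend: float = 0.025            # mm per My directional trend
    wl_sigma2: float = 0.02            # mm^2 per My
    wl_shape_shift: float = 2.0        # mm added on falcate-wing lineages
    mk_rate: float = 0.004             # wing-shape Mk transition rate per My
    niche_opt_root: float = 16.0       # root MAT optimum, degC
    niche_width: float = 6.0           # suitability kernel width, degC
    records_per_tip: int = 4
    nlat: int = 18
    nlon: int = 36
    climate_noise_sd: float = 0.6
    dispersal_d: float = 0.015         # baseline per-My dispersal rate
    dispersal_e: float = 0.004

    def __post_init__(self):
        for f in ("birth_rate", "death_rate", "fossil_sampling_rate",
                  "bm_sigma2", "wl_sigma2"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")
        if self.root_age <= 0:
            raise ValueError("root_age must be positive")
        if not 1 <= self.n_realms <= 8:
            raise ValueError("n_realms must be in 1..8")


# ------------------------------------------------------------------- FBD tree

def simulate_fbd_tree(cfg: SimConfig, max_attempts: int = 1000,
                      rng: np.random.Generator | None = None) -> TimeTree:
    """Simulate a dated tree under a fossilized-birth-death-style scheme.

    A complete birth-death tree is grown forward from the root (two initial
    lineages at ``root_age``); fossil tips are constant-rate Poisson samples
    along the complete tree's branches, grafted as short pendant tips so the
    tree stays strictly binary with positive branch lengths.  The process is
    conditioned by bounded retry on at least ``n_extant`` survivors, then
    pruned to exactly ``n_extant`` randomly chosen extant tips plus the
    fossil samples.  When ``n_fossil`` is set, fossil times are the Poisson
    process conditioned on its count (uniform over total branch length).

    The returned tree carries ``tree.info`` with the realized complete-tree
    branch length and the fossil count, for Monte-Carlo checks.
    """
    if cfg.birth_rate <= cfg.death_rate and cfg.death_rate > 0:
        raise ValueError("birth_rate must exceed death_rate")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    b, d = cfg.birth_rate, cfg.death_rate
    cap = max(4000, 20 * cfg.n_extant)

    for attempt in range(1, max_attempts + 1):
        ages = [cfg.root_age]
        parent = [-1]
        is_tip_extinct: dict[int, bool] = {}
        alive = [0, 0]  # lineages extend from these nodes
        t = cfg.root_age
        ok = True
        while alive:
            n = len(alive)
            if n > cap:
                ok = False
                break
            rate = n * (b + d)
            if rate <= 0:
                break
            t -= rng.exponential(1.0 / rate)
            if t <= 0:
                break
            k = int(rng.integers(n))
            src = alive[k]
            nid = len(ages)
            ages.append(t)
            parent.append(src)
            if rng.uniform() < b / (b + d):
                alive[k] = nid
                alive.append(nid)
            else:
                is_tip_extinct[nid] = True
                alive.pop(k)
        if not ok:
            continue
        extant_nodes = []
        for src in alive:
            nid = len(ages)
            ages.append(0.0)
            parent.append(src)
            extant_nodes.append(nid)
        if len(extant_nodes) < cfg.n_extant:
            continue

        ages_arr = np.array(ages)
        parent_arr = np.array(parent)
        nn = len(ages)
        blen = np.zeros(nn)
        for i in range(1, nn):
            blen[i] = ages_arr[parent_arr[i]] - ages_arr[i]
        total_len = float(blen.sum())

        # fossil sampling on the complete tree
        if cfg.fossil_sampling_rate == 0:
            n_f = 0
        elif cfg.n_fossil is not None:
            n_f = int(cfg.n_fossil)
        else:
            n_f = int(rng.poisson(cfg.fossil_sampling_rate * total_len))
        fossils_by_branch: dict[int, list[float]] = {}
        if n_f > 0 and total_len > 0:
            cum = np.cumsum(blen)
            for _ in range(n_f):
                u = rng.uniform(0, total_len)
                br = int(np.searchsorted(cum, u))
                offset = u - (cum[br] - blen[br])
                t_f = ages_arr[parent_arr[br]] - offset
                fossils_by_branch.setdefault(br, []).append(float(t_f))

        # rebuild with grafted fossil pendants (eps keeps branches positive)
        eps = 1e-6
        parent2 = list(parent_arr)
        ages2 = list(ages_arr)
        labels2: list[str | None] = [None] * nn
        fossil_tip_ids = []
        for br, times in fossils_by_branch.items():
            top = parent_arr[br]
            for t_f in sorted(times, reverse=True):
                att = len(ages2)
                ages2.append(t_f)
                parent2.append(top)
                labels2.append(None)
                ftip = len(ages2)
                ages2.append(max(t_f - eps, eps))
                parent2.append(att)
                labels2.append(f"f{len(fossil_tip_ids)}")
                fossil_tip_ids.append(ftip)
                top = att
            parent2[br] = top

        for k, nid in enumerate(extant_nodes):
            labels2[nid] = f"t{k}"

        blen2 = [0.0] + [max(ages2[parent2[i]] - ages2[i], eps)
                         for i in range(1, len(ages2))]
        full = TimeTree(parent2, blen2, labels2, root_age=cfg.root_age)

        keep_extant = sorted(rng.choice(extant_nodes, size=cfg.n_extant,
                                        replace=False).tolist())
        keep = list(keep_extant) + fossil_tip_ids
        tree = full.prune_to_tips(keep)
        tree.info = {"complete_tree_length": total_len,
                     "n_fossil": n_f, "attempts": attempt}
        return tree
    raise RuntimeError(f"FBD simulation failed to reach {cfg.n_extant} extant "
                       f"tips in {max_attempts} attempts")


# ---------------------------------------------------------------- trait models

def simulate_bm_trait(tree: TimeTree, sigma2: float, root_value: float,
                      seed: int | None = None, trend: float = 0.0,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Brownian trait values at every node (ground truth for recovery tests).

    Increments along a branch of length t are Normal(trend*t, sigma2*t).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    rng = np.random.default_rng(seed) if rng is None else rng
    vals = np.zeros(tree.n_nodes)
    for i in tree.preorder:
        if i == tree.root:
            vals[i] = root_value
        else:
            t = tree.blen[i]
            vals[i] = vals[tree.parent[i]] + trend * t + \
                rng.normal(0.0, np.sqrt(sigma2 * t))
    return vals


def simulate_mk_states(tree: TimeTree, rate: float, k_states: int = 2,
                       seed: int | None = None, root_state: int = 0,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Symmetric Mk character simulated forward along the tree (per node)."""
    rng = np.random.default_rng(seed) if rng is None else rng
    states = np.zeros(tree.n_nodes, dtype=int)
    for i in tree.preorder:
        if i == tree.root:
            states[i] = root_state
            continue
        s = states[tree.parent[i]]
        t = tree.blen[i]
        # jump chain: total leave rate (k-1)*rate
        tau = 0.0
        while True:
            tau += rng.exponential(1.0 / ((k_states - 1) * rate)) if rate > 0 \
                else np.inf
            if tau >= t:
                break
            others = [x for x in range(k_states) if x != s]
            s = others[int(rng.integers(k_states - 1))]
        states[i] = s
    return states


# -------------------------------------------------------------------- climate

def _smooth_noise(rng, nlat, nlon, sd, sigma=2.0):
    if sd <= 0:
        return np.zeros((nlat, nlon))
    f = gaussian_filter(rng.normal(size=(nlat, nlon)), sigma=sigma,
                        mode=("nearest", "wrap"))
    f /= max(f.std(), 1e-12)
    return sd * f


def simulate_climate_history(n_slices: int, cooling_slope: float,
                             seed: int | None = None, nlat: int = 18,
                             nlon: int = 36, noise_sd: float = 0.6,
                             present_mean: float = 14.0,
                             age_step: float = 10.0,
                             rng: np.random.Generator | None = None
                             ) -> list[ClimateSlice]:
    """Gridded climate slices, oldest first, with a secular cooling trend.

    Each slice's area-weighted global mean annual temperature equals
    ``present_mean + cooling_slope * age`` exactly when ``noise_sd`` is 0;
    every slice carries a latitudinal gradient (equator warmer than poles)
    and spatially autocorrelated precipitation fields.  Elevation is a single
    smooth field shared by all slices.
    """
    if n_slices < 1:
        raise ValueError("need at least one slice")
    rng = np.random.default_rng(seed) if rng is None else rng
    lats = np.linspace(90 - 90 / nlat, -90 + 90 / nlat, nlat)
    lons = np.linspace(-180 + 180 / nlon, 180 - 180 / nlon, nlon)
    w = np.cos(np.deg2rad(lats))
    w2d = np.repeat(w[:, None], nlon, axis=1)
    w2d = w2d / w2d.sum()
    latg = np.repeat(np.abs(lats)[:, None], nlon, axis=1)
    grad = 28.0 * np.cos(np.deg2rad(np.repeat(lats[:, None], nlon, axis=1)))
    grad -= (grad * w2d).sum()
    elevation = np.clip(1200.0 + _smooth_noise(rng, nlat, nlon, 900.0, 3.0),
                        0.0, 4000.0)
    ci_field = 25.0 + _smooth_noise(rng, nlat, nlon, 8.0, 3.0)

    slices = []
    for i in range(n_slices):
        age = (n_slices - 1 - i) * age_step
        target = present_mean + cooling_slope * age
        noise = _smooth_noise(rng, nlat, nlon, noise_sd)
        noise -= (noise * w2d).sum()
        mat = target + grad + noise
        ts = 2.0 + 0.45 * latg + _smooth_noise(rng, nlat, nlon, 0.5 * noise_sd)
        mapr = np.clip(250.0 + 2200.0 * np.exp(-(latg / 28.0) ** 2)
                       + _smooth_noise(rng, nlat, nlon, 130.0 * noise_sd), 0, None)
        wmp = np.clip(0.22 * mapr + _smooth_noise(rng, nlat, nlon, 20 * noise_sd), 0, None)
        dmp = np.clip(0.03 * mapr + _smooth_noise(rng, nlat, nlon, 4 * noise_sd), 0, None)
        ps = np.clip(20.0 + 0.9 * latg + _smooth_noise(rng, nlat, nlon, 3 * noise_sd), 0, None)
        eq = 100.0 - 1.1 * latg + _smooth_noise(rng, nlat, nlon, 2 * noise_sd)
        variables = {
            "MAT": mat, "TS": ts, "MAP": mapr, "WMP": wmp, "DMP": dmp,
            "PS": ps, "EQ": eq, "CI": ci_field, "WMT": mat + 0.5 * ts,
            "CMT": mat - 0.5 * ts, "EL": elevation,
        }
        slices.append(ClimateSlice(age_ma=float(age), lats=lats.copy(),
                                   lons=lons.copy(), variables=variables))
    return slices


# ---------------------------------------------------------------- occurrences

def gaussian_suitability(optimum: float, width: float):
    """Suitability kernel over MAT: exp(-(MAT - optimum)^2 / (2 width^2))."""
    def rule(slc: ClimateSlice) -> np.ndarray:
        m = slc.variables["MAT"]
        return np.exp(-0.5 * ((m - optimum) / width) ** 2)
    return rule


def simulate_occurrences(tree: TimeTree, climate: list[ClimateSlice],
                         suitability_rule=None, records_per_tip: int = 4,
                         seed: int | None = None, tip_optima=None,
                         width: float = 6.0,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Presence records sampled with probability proportional to suitability.

    Each tip contributes ``records_per_tip`` records drawn from the climate
    slice nearest its age; the record's 11-variable environment vector is read
    exactly from the chosen cell.  ``suitability_rule(slice)`` may be given
    explicitly; otherwise a Gaussian kernel centred on the tip's niche optimum
    (``tip_optima``, per node) is used.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    slice_ages = np.array([s.age_ma for s in climate])
    rows = []
    for t_i in tree.tips:
        age = float(tree.age[t_i])
        if age < slice_ages.min() - 1e-9 or age > slice_ages.max() + 1e-9:
            raise ValueError("tip age outside the span of the climate slices")
        slc = climate[int(np.argmin(np.abs(slice_ages - age)))]
        if suitability_rule is not None:
            wts = np.asarray(suitability_rule(slc), dtype=float)
        else:
            opt = float(tip_optima[t_i]) if tip_optima is not None else 16.0
            wts = gaussian_suitability(opt, width)(slc)
        tot = wts.sum()
        if tot <= 0:
            raise ValueError("suitability is zero everywhere: no region to sample")
        p = (wts / tot).ravel()
        cells = rng.choice(p.size, size=records_per_tip, p=p)
        nlat = len(slc.lats)
        nlon = len(slc.lons)
        for c in cells:
            i, j = divmod(int(c), nlon)
            row = dict(taxon=tree.labels[t_i],
                       status="extant" if age <= 1e-6 else "fossil",
                       lon=float(slc.lons[j]), lat=float(slc.lats[i]),
                       paleo_lon=float(slc.lons[j]), paleo_lat=float(slc.lats[i]),
                       age_ma=age)
            for v in VARIABLES:
                row[v] = float(slc.variables[v][i, j])
            rows.append(row)
    return pd.DataFrame(rows)


# -------------------------------------------------------------- realm history

def simulate_realm_history(n_realms: int, root_age: float, n_epochs: int = 4,
                           seed: int | None = None,
                           rng: np.random.Generator | None = None
                           ) -> RealmHistory:
    """Epoch-structured adjacency history with barrier-class multipliers.

    Each epoch assigns every realm pair one of the three barrier classes
    (0.75 adjacent, 0.5 one barrier, 1e-6 isolated).  A random spanning chain
    of adjacent pairs connects a core of the realms so dispersal is always
    possible somewhere, but up to two realms per epoch are left outside the
    guaranteed chain and can be fully isolated — emulating drifting plates
    and making the habitable-but-inaccessible class attainable.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    realms = biogeo.REALMS[:n_realms]
    cuts = np.linspace(root_age, 0.0, n_epochs + 1)
    classes = [0.75, 0.5, 1e-6]
    probs = [0.45, 0.35, 0.20]
    epochs = []
    for k in range(n_epochs):
        m = np.ones((n_realms, n_realms))
        for a in range(n_realms):
            for b_ in range(a + 1, n_realms):
                v = classes[rng.choice(3, p=probs)]
                m[a, b_] = m[b_, a] = v
        order = rng.permutation(n_realms)
        core = order[:min(n_realms, max(3, n_realms - 2))]
        for a, b_ in zip(core, core[1:]):
            m[a, b_] = m[b_, a] = 0.75
        epochs.append(Epoch(float(cuts[k]), float(cuts[k + 1]), m))
    return RealmHistory(realms, epochs)


def realm_of_cells(nlat: int, nlon: int, n_realms: int) -> np.ndarray:
    """Longitude-band realm membership for every grid cell."""
    bands = np.minimum((np.arange(nlon) * n_realms) // nlon, n_realms - 1)
    return np.repeat(bands[None, :], nlat, axis=0)


# ----------------------------------------------------------------- atmosphere

def simulate_atmospheric_records(occurrences: pd.DataFrame,
                                 seed: int | None = None,
                                 rng: np.random.Generator | None = None
                                 ) -> pd.DataFrame:
    """Per-record atmospheric variables (P, Pv, T, v in SI units).

    Pressure follows the barometric decay with the record's elevation,
    vapour pressure is a random relative humidity times the Magnus saturation
    pressure, and wind speed is lognormal around ~3 m/s.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    tc = occurrences["MAT"].to_numpy()
    el = occurrences["EL"].to_numpy()
    T = tc + 273.15
    P = 101325.0 * np.exp(-el / 8400.0) * \
        np.exp(rng.normal(0.0, 0.004, size=len(occurrences)))
    es = 610.94 * np.exp(17.625 * tc / (tc + 243.04))
    rh = rng.uniform(0.3, 0.9, size=len(occurrences))
    Pv = np.minimum(rh * es, 0.95 * P)
    v = rng.lognormal(mean=1.0, sigma=0.35, size=len(occurrences))
    return pd.DataFrame({"taxon": occurrences["taxon"], "P": P, "Pv": Pv,
                         "T": T, "v": v})


# ------------------------------------------------------------------- scenario

@dataclass
class Scenario:
    cfg: SimConfig
    tree: TimeTree
    traits: dict = field(default_factory=dict)       # name -> per-node array
    wing_shape: np.ndarray | None = None             # per-node 0=oval 1=falcate
    occurrences: pd.DataFrame | None = None
    climate: list = field(default_factory=list)
    realm_history: RealmHistory | None = None
    tip_ranges: dict = field(default_factory=dict)   # label -> bitmask range
    atmo: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.occurrences is not None and len(self.occurrences):
            tipset = set(self.tree.tip_labels)
            bad = set(self.occurrences["taxon"]) - tipset
            if bad:
                raise ValueError(f"occurrence taxa not on the tree: {sorted(bad)}")


def make_scenario(cfg: SimConfig) -> Scenario:
    """Generate one complete, internally consistent synthetic study system."""
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_fbd_tree(cfg, rng=rng)
    niche = simulate_bm_trait(tree, cfg.bm_sigma2, cfg.niche_opt_root, rng=rng)
    shape = simulate_mk_states(tree, cfg.mk_rate, 2, rng=rng)
    wl = simulate_bm_trait(tree, cfg.wl_sigma2, cfg.wl_root, trend=cfg.wl_trend,
                           rng=rng) + cfg.wl_shape_shift * shape
    n_slices = int(np.ceil(cfg.root_age / 10.0)) + 1
    climate = simulate_climate_history(n_slices, cfg.cooling_slope, rng=rng,
                                       nlat=cfg.nlat, nlon=cfg.nlon,
                                       noise_sd=cfg.climate_noise_sd)
    occ = simulate_occurrences(tree, climate, records_per_tip=cfg.records_per_tip,
                               tip_optima=niche, width=cfg.niche_width, rng=rng)
    history = simulate_realm_history(cfg.n_realms, cfg.root_age, rng=rng)

    # planted wing-length -> dispersal coupling: the per-My dispersal rate is
    # scaled by exp(beta * (expected mean WL at that age - reference))
    wl_ref = cfg.wl_root + cfg.wl_trend * cfg.root_age / 2.0

    def modifier(age: float) -> float:
        wl_mean = cfg.wl_root + cfg.wl_trend * (cfg.root_age - age)
        return float(np.exp(cfg.coupling_beta * (wl_mean - wl_ref)))

    model = BiogeoModel(d=cfg.dispersal_d, e=cfg.dispersal_e, scheme="DEC",
                        max_range_size=2)
    sim = biogeo.simulate_ranges(tree, model, history, rng_or_seed(rng),
                                 rate_modifier=modifier)
    atmo = simulate_atmospheric_records(occ, rng=rng)
    return Scenario(cfg=cfg, tree=tree,
                    traits={"niche_MAT_optimum": niche, "WL": wl},
                    wing_shape=shape, occurrences=occ, climate=climate,
                    realm_history=history, tip_ranges=sim["tip_ranges"],
                    atmo=atmo,
                    truth={"niche": niche, "wl": wl, "shape": shape,
                           "range_events": sim["events"],
                           "node_ranges": sim["node_states"],
                           "wl_modifier_ref": wl_ref})


def rng_or_seed(rng: np.random.Generator) -> int:
    """Deterministic child seed drawn from a generator (stays below 2^31)."""
    return int(rng.integers(0, 2**31 - 1))


# ---------------------------------------------------------------- persistence

def load_scenario(indir: str) -> dict:
    """Read back the serialized pieces of a scenario directory.

    Returns a dict with tree, occurrences, traits, atmo, tip_ranges,
    realm_history, climate (list of ClimateSlice) and cfg.
    """
    import glob as _glob
    import re as _re

    from .rasters import read_ascii_grid

    with open(os.path.join(indir, "tree.nwk")) as fh:
        tree = TimeTree.from_newick(fh.read())
    occ = pd.read_csv(os.path.join(indir, "occurrences.csv"))
    traits = pd.read_csv(os.path.join(indir, "traits.csv"))
    atmo = pd.read_csv(os.path.join(indir, "atmosphere.csv"))
    with open(os.path.join(indir, "realm_history.yaml")) as fh:
        hist_raw = yaml.safe_load(fh)
    history = RealmHistory(hist_raw["realms"],
                           [Epoch(e["start"], e["end"], np.array(e["multipliers"]))
                            for e in hist_raw["epochs"]])
    ranges_df = pd.read_csv(os.path.join(indir, "tip_ranges.csv"))
    tip_ranges = {r["taxon"]: biogeo.range_from_string(r["range"], history.realms)
                  for _, r in ranges_df.iterrows()}
    with open(os.path.join(indir, "config.yaml")) as fh:
        cfg = SimConfig(**yaml.safe_load(fh))
    by_age: dict[float, dict] = {}
    for path in sorted(_glob.glob(os.path.join(indir, "climate", "*.asc"))):
        m = _re.match(r"(.+)_(\d+)Ma\.asc$", os.path.basename(path))
        if not m:
            continue
        var, age = m.group(1), float(m.group(2))
        grid, _ = read_ascii_grid(path)
        by_age.setdefault(age, {})[var] = grid
    slices = []
    for age in sorted(by_age, reverse=True):
        grids = by_age[age]
        nlat, nlon = next(iter(grids.values())).shape
        lats = np.linspace(90 - 90 / nlat, -90 + 90 / nlat, nlat)
        lons = np.linspace(-180 + 180 / nlon, 180 - 180 / nlon, nlon)
        slices.append(ClimateSlice(age_ma=age, lats=lats, lons=lons,
                                   variables=grids))
    return {"tree": tree, "occurrences": occ, "traits": traits, "atmo": atmo,
            "tip_ranges": tip_ranges, "realm_history": history,
            "climate": slices, "cfg": cfg}


def write_scenario(sc: Scenario, outdir: str) -> None:
    """Serialize a scenario: Newick tree, CSV tables, ASCII grids, YAML config."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(sc.tree.to_newick() + "\n")
    sc.occurrences.to_csv(os.path.join(outdir, "occurrences.csv"), index=False)
    tips = sc.tree.tips
    tdf = pd.DataFrame({"taxon": [sc.tree.labels[i] for i in tips]})
    for name, arr in sc.traits.items():
        tdf[name] = arr[tips]
    tdf["wing_shape"] = np.where(sc.wing_shape[tips] == 1, "falcate", "oval")
    tdf.to_csv(os.path.join(outdir, "traits.csv"), index=False)
    sc.atmo.to_csv(os.path.join(outdir, "atmosphere.csv"), index=False)
    pd.DataFrame({
        "taxon": list(sc.tip_ranges),
        "range": [biogeo.range_to_string(r, sc.realm_history.realms)
                  for r in sc.tip_ranges.values()],
    }).to_csv(os.path.join(outdir, "tip_ranges.csv"), index=False)
    grid_dir = os.path.join(outdir, "climate")
    os.makedirs(grid_dir, exist_ok=True)
    for slc in sc.climate:
        cell = 180.0 / len(slc.lats)
        for v, g in slc.variables.items():
            write_ascii_grid(os.path.join(grid_dir, f"{v}_{int(slc.age_ma)}Ma.asc"),
                             g, xll=-180.0, yll=-90.0, cellsize=cell)
    hist = {"realms": sc.realm_history.realms,
            "epochs": [{"start": e.start, "end": e.end,
                        "multipliers": e.multipliers.tolist()}
                       for e in sc.realm_history.epochs]}
    with open(os.path.join(outdir, "realm_history.yaml"), "w") as fh:
        yaml.safe_dump(hist, fh)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(sc.cfg), fh)
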