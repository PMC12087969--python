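"""End-to-end orchestration of the synthetic niche-dynamics pipeline.

Stages run in dependency order on one scenario:

    synthgen -> enm / omi / comparative -> causal / biogeo
             -> dispersal / habitability / atmosphere

Every stage draws its randomness from a seed derived deterministically from
the pipeline seed, every paper-stated setting (regularization multiplier 1.5,
20% random test split, 10 niche-model replicates, 200 stochastic maps,
10,000 HMM simulations, 10-My bins) is a config default rather than a
constant, and the manifest records parameters, seeds and per-stage checksums
so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import (atmosphere, biogeo, causal, dispersal_wing, enm, habitability,
               niche_omi, phylo, synthgen)
from .niche_omi import BinScheme

__all__ = ["PipelineConfig", "PipelineError", "run"]

STAGES = ["synthgen", "enm", "omi", "comparative", "causal", "biogeo",
          "dispersal", "atmosphere", "habitability"]

DEPENDS = {
    "enm": ["synthgen"], "omi": ["synthgen"], "comparative": ["synthgen"],
    "causal": ["synthgen", "comparative"],
    "biogeo": ["synthgen"],
    "dispersal": ["synthgen", "biogeo", "comparative"],
    "atmosphere": ["synthgen"],
    "habitability": ["synthgen", "comparative", "biogeo"],
}


class PipelineError(RuntimeError):
    """A stage failed or a required upstream stage was disabled."""


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: dict = field(default_factory=dict)        # SimConfig overrides
    stages: dict = field(default_factory=dict)     # stage -> bool toggles
    reg_multiplier: float = 1.5
    test_fraction: float = 0.2
    n_enm_replicates: int = 10
    correlation_threshold: float = 0.8
    thin_radius_km: float = 6.0
    n_bsm: int = 200
    biogeo_schemes: tuple = ("DEC", "DIVALIKE", "BAYAREALIKE")
    biogeo_with_j: bool = True
    hmm_iterations: int = 10_000
    n_signal_permutations: int = 1_000
    ccm_E: int = 2
    ccm_tau: int = 1
    ccm_surrogates: int = 100

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def _checksum(obj) -> str:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return round(float(o), 10)
        if isinstance(o, np.ndarray):
            return np.round(o.astype(float), 10).tolist()
        if isinstance(o, pd.DataFrame):
            return o.round(10).to_csv()
        if isinstance(o, pd.Series):
            return o.round(10).to_dict()
        return str(o)
    payload = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run(config: PipelineConfig) -> dict:
    """Run the configured stages on one synthetic scenario.

    Returns ``{"results": {stage: ...}, "manifest": {...}}``; a stage failure
    raises :class:`PipelineError` naming the stage, with the partial results
    attached to the exception.
    """
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {s: int(c.generate_state(1)[0] % (2**31 - 1))
                   for s, c in zip(STAGES, ss.spawn(len(STAGES)))}
    results: dict = {}
    manifest: dict = {"seed": config.seed, "stage_seeds": stage_seeds,
                      "parameters": {k: v for k, v in asdict(config).items()
                                     if k not in ("sim", "stages")},
                      "stages": {}}

    def require(stage: str):
        for dep in DEPENDS.get(stage, []):
            if dep not in results:
                raise PipelineError(
                    f"stage {stage!r} requires {dep!r}, which is disabled or "
                    f"did not run")

    def record(stage: str, out, summary) -> None:
        results[stage] = out
        manifest["stages"][stage] = {"status": "ok",
                                     "checksum": _checksum(summary)}

    def guard(stage: str, fn):
        if not config.enabled(stage):
            manifest["stages"][stage] = {"status": "disabled"}
            return
        require(stage)
        t0 = time.perf_counter()
        try:
            fn()
        except PipelineError:
            raise
        except Exception as exc:
            err = PipelineError(f"stage {stage!r} failed: {exc}")
            err.partial_results = results
            raise err from exc
        manifest["stages"][stage]["seconds"] = round(time.perf_counter() - t0, 3)

    # ------------------------------------------------------------- synthgen
    def _synthgen():
        cfg = synthgen.SimConfig(seed=stage_seeds["synthgen"], **config.sim)
        sc = synthgen.make_scenario(cfg)
        record("synthgen", sc,
               {"newick": sc.tree.to_newick(), "n_occ": len(sc.occurrences)})
    guard("synthgen", _synthgen)
    if "synthgen" not in results:
        manifest["complete"] = False
        return {"results": results, "manifest": manifest}
    sc = results["synthgen"]

    # ------------------------------------------------------------------ enm
    def _enm():
        occ = sc.occurrences
        screened = enm.screen_variables(occ[synthgen.VARIABLES],
                                        config.correlation_threshold)
        thinned = enm.thin_records(occ, config.thin_radius_km)
        names = screened["selected"]
        background = sc.climate[-1].table(names)
        ev = enm.evaluate(thinned[names], background,
                          test_fraction=config.test_fraction,
                          n_replicates=config.n_enm_replicates,
                          seed=stage_seeds["enm"],
                          reg_multiplier=config.reg_multiplier,
                          variable_names=names)
        model = enm.fit_maxent_linear(thinned[names], background,
                                      config.reg_multiplier,
                                      variable_names=names)
        maps = {s.age_ma: enm.project(model, s, names) for s in
                (sc.climate[0], sc.climate[-1])}
        out = {"screened": screened, "thinned_n": len(thinned),
               "model": model, "evaluation": ev, "maps": maps}
        record("enm", out, {"selected": names, "auc_train": ev.auc_train,
                            "auc_test": ev.auc_test,
                            "weights": model.weights_})
    guard("enm", _enm)

    # ------------------------------------------------------------------ omi
    def _omi():
        root_age = float(sc.tree.age[sc.tree.root])
        fine = niche_omi.bin_scheme(max(root_age, 66.0))
        coarse = niche_omi.five_interval_scheme(max(root_age, 66.0))
        occ = sc.occurrences
        out = {
            "fine": niche_omi.np_nb_through_time(occ, fine, synthgen.VARIABLES),
            "coarse": niche_omi.np_nb_through_time(occ, coarse, synthgen.VARIABLES),
            "schemes": {"fine": fine, "coarse": coarse},
        }
        record("omi", out, {"fine": out["fine"], "coarse": out["coarse"]})
    guard("omi", _omi)

    # ------------------------------------------------------------ comparative
    def _comparative():
        tree = sc.tree
        tips = tree.tips
        niche_tip = sc.truth["niche"][tips]
        wl_tip = sc.truth["wl"][tips]
        sig = phylo.phylo_signal(tree, niche_tip,
                                 n_perm=config.n_signal_permutations,
                                 seed=stage_seeds["comparative"])
        asr_niche = phylo.asr_bm(tree, niche_tip)
        asr_wl = phylo.asr_bm(tree, wl_tip)
        shape_tip = sc.truth["shape"][tips]
        asr_shape = phylo.asr_mk(tree, shape_tip, 2)
        root_age = float(tree.age[tree.root])
        tenmy = BinScheme(list(np.arange(np.ceil(root_age / 10) * 10, -1, -10.0)))
        onemy = BinScheme(list(np.arange(np.ceil(root_age), -1, -1.0)))
        wl_bins = phylo.branch_bin_means(tree, asr_wl, wl_tip, onemy)
        niche_thresholds = phylo.niche_thresholds_by_bin(tree, asr_niche,
                                                         niche_tip, tenmy)
        ages, counts = phylo.ltt(tree)
        rates = phylo.rate_through_time_proxy(tree, niche_tip, tenmy,
                                              seed=stage_seeds["comparative"])
        pg = phylo.pgls(tree, wl_tip, shape_tip.astype(float))
        models = phylo.fit_evo_models(tree, niche_tip)
        out = {"signal": sig, "asr_niche": asr_niche, "asr_wl": asr_wl,
               "asr_shape": asr_shape, "wl_per_my": wl_bins,
               "niche_thresholds": niche_thresholds,
               "ltt": (ages, counts), "rates": rates, "pgls": pg,
               "evo_models": models, "schemes": {"tenmy": tenmy, "onemy": onemy}}
        record("comparative", out,
               {"lambda": sig.lambda_hat, "K": sig.K,
                "asr": asr_niche.node_values, "ltt": counts.tolist(),
                "best_model": models["AICc"].idxmin()})
    guard("comparative", _comparative)

    # ---------------------------------------------------------------- causal
    def _causal():
        comp = results["comparative"]
        gmat = np.array([s.global_mean("MAT") for s in sc.climate])
        slice_ages = np.array([s.age_ma for s in sc.climate])
        ages, counts = comp["ltt"]

        def ltt_at_age(a):
            # count after the most recent event not younger than age a
            idx = np.flatnonzero(ages >= a)
            return int(counts[idx[-1]]) if idx.size else 1

        ltt_at = np.array([ltt_at_age(a) for a in slice_ages])
        corr = causal.correlate(gmat, np.log(ltt_at), method="pearson")
        cfg = causal.CCMConfig(E=config.ccm_E, tau=config.ccm_tau,
                               n_surrogates=config.ccm_surrogates,
                               seed=stage_seeds["causal"])
        ccm_res = causal.ccm(gmat, np.log(ltt_at.astype(float)), cfg)
        out = {"gmat": gmat, "ltt_series": ltt_at,
               "gmat_ltt_correlation": corr, "ccm_gmat_to_ltt": ccm_res}
        record("causal", out, {"r": corr["r"], "p": corr["p"],
                               "ccm_skill": ccm_res.skill_final})
    guard("causal", _causal)

    # ---------------------------------------------------------------- biogeo
    def _biogeo():
        fit_tab = biogeo.fit(sc.tree, sc.tip_ranges, sc.realm_history,
                             schemes=config.biogeo_schemes,
                             with_j=config.biogeo_with_j)
        best = fit_tab.index[0]
        row = fit_tab.iloc[0]
        model = biogeo.BiogeoModel(d=row["d"], e=row["e"], j=row["j"],
                                   scheme=best.replace("+j", ""))
        maps = biogeo.bsm(sc.tree, sc.tip_ranges, model, sc.realm_history,
                          n_maps=config.n_bsm, seed=stage_seeds["biogeo"])
        out = {"fit": fit_tab, "best_model": model, "bsm": maps}
        record("biogeo", out, {"fit": fit_tab,
                               "per_my": maps["per_my"],
                               "pairs": maps["realm_pair_percent"]})
    guard("biogeo", _biogeo)

    # ------------------------------------------------------------- dispersal
    def _dispersal():
        comp = results["comparative"]
        bg = results["biogeo"]
        per_my = bg["bsm"]["per_my"]
        wl_bins = comp["wl_per_my"]
        # align: per_my is young->old ascending by bin_younger; wl_bins old->young
        wl_sorted = wl_bins.sort_values("bin_younger")
        k = min(len(per_my), len(wl_sorted))
        events = per_my["mean_dispersal_events"].to_numpy()[:k]
        wl = wl_sorted["mean"].to_numpy()[:k]
        ok = ~np.isnan(wl)
        series = pd.DataFrame({"bin_younger": per_my["bin_younger"].to_numpy()[:k],
                               "dispersal_events": events, "mean_wl": wl})[ok]
        rho = causal.correlate(series["dispersal_events"],
                               series["mean_wl"], method="spearman")
        regimes = dispersal_wing.binarize(series["dispersal_events"])
        hmm = dispersal_wing.fit_hmm(regimes, series["mean_wl"].to_numpy())
        thr = dispersal_wing.simulate_and_regress(
            hmm, raw_regimes=regimes, raw_wl=series["mean_wl"].to_numpy(),
            n_iter=config.hmm_iterations, seed=stage_seeds["dispersal"])
        shape_tip = sc.truth["shape"][sc.tree.tips]
        wl_tip = sc.truth["wl"][sc.tree.tips]
        contrast = dispersal_wing.group_contrast(wl_tip[shape_tip == 1],
                                                 wl_tip[shape_tip == 0]) \
            if 0 < shape_tip.sum() < shape_tip.size else None
        out = {"series": series, "spearman": rho, "hmm": hmm,
               "threshold": thr, "shape_contrast": contrast}
        record("dispersal", out,
               {"rho": rho["r"], "p": rho["p"],
                "threshold": thr.wl_threshold,
                "transition": hmm.transition})
    guard("dispersal", _dispersal)

    # ------------------------------------------------------------ atmosphere
    def _atmosphere():
        rec = atmosphere.derive_records(sc.atmo)
        sets = atmosphere.field_condition_sets(rec)
        out = {"records": rec, "field_conditions": sets}
        record("atmosphere", out, {"steady": sets["steady"],
                                   "summary": sets["summary"]})
    guard("atmosphere", _atmosphere)

    # ---------------------------------------------------------- habitability
    def _habitability():
        comp = results["comparative"]
        thr_tab = comp["niche_thresholds"]
        realm_grid = synthgen.realm_of_cells(sc.cfg.nlat, sc.cfg.nlon,
                                             sc.cfg.n_realms)
        bg = results["biogeo"]
        node_ranges = sc.truth["node_ranges"]
        maps = []
        slice_by_age = {s.age_ma: s for s in sc.climate}
        for _, row in thr_tab.iterrows():
            if row["empty"]:
                continue
            mid = 0.5 * (row["bin_older"] + row["bin_younger"])
            age = min(slice_by_age, key=lambda a: abs(a - mid))
            slc = slice_by_age[age]
            mask = habitability.project_thresholds(
                {"MAT": (row["vmin"], row["vmax"])}, slc, ["MAT"])
            # realms occupied by branches alive in this bin (simulated truth)
            occ_realms = set()
            tr = sc.tree
            for nd, state in node_ranges.items():
                if row["bin_younger"] <= tr.age[nd] <= row["bin_older"]:
                    occ_realms |= {i for i in range(8) if state >> i & 1}
            if not occ_realms:
                occ_realms = {i for i in range(8)
                              if node_ranges[tr.root] >> i & 1}
            hm = habitability.partition_accessibility(
                mask, occ_realms, sc.realm_history, mid, realm_grid)
            maps.append(hm)
        out = {"maps": maps,
               "area_fractions": [m.area_fractions() for m in maps]}
        record("habitability", out, {"fractions": out["area_fractions"]})
    guard("habitability", _habitability)

    manifest["complete"] = all(
        v.get("status") == "ok" for s, v in manifest["stages"].items()
        if config.enabled(s))
    return {"results": results, "manifest": manifest}
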