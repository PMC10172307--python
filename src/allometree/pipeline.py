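"""End-to-end orchestration: load -> prune -> trajectories -> HOS tests ->
allometric space -> disparity -> convergence -> evolutionary models.

Every stage writes its artifact (CSV/JSON) into the output directory and
the run ends with a machine-readable ``summary.json`` embedding the
configuration, seeds and package version, so a run is reproducible and
resumable from its written artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .convergence import angle_state_convergence, c_significance
from .disparity import disparity_permutation_test, residual_disparity
from .evomodels import fit_all_models
from .io import SpeciesMeta, SpecimenTable, load_dataset, prune_by_sample_size
from .shape import (ShapeData, fit_all_trajectories, coefficients_frame,
                    to_shape_ratios, trajectory_display_scores)
from .sma import common_slope_lr_test, composite_shape_score, \
    elevation_wald_test, pairwise_hos
from .space import broken_stick_axes, build_space, significant_axes
from .tree import Phylo

log = logging.getLogger("allometree")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline settings; defaults follow the analysis conventions the
    package documents (minimum series size 15, alpha 0.05, 10,000
    permutations, 300 convergence simulations, 10 stochastic maps, at most
    4 retained PCs)."""

    specimen_csv: str = ""
    meta_csv: str = ""
    tree_newick: str = ""
    outdir: str = "allometree_out"
    min_specimens: int = 15
    alpha: float = 0.05
    permutations: int = 10000
    convergence_sims: int = 300
    n_maps: int = 10
    pc_cap: int = 4
    seed: int = 0
    run_species_pairwise: bool = True
    fit_models: bool = True
    exclude_single_partition_diets: bool = True

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def hash(self) -> str:
        """Digest of the analysis-relevant settings (output location
        excluded, so reruns into different directories hash identically)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _stage_seeds(master: int, names: list[str]) -> dict:
    ss = np.random.SeedSequence(master)
    kids = ss.spawn(len(names))
    return {n: int(k.generate_state(1)[0] % (2 ** 31))
            for n, k in zip(names, kids)}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _pooled_hos(shape: ShapeData, units: np.ndarray, alpha: float) -> dict:
    """One pooled slope LR + elevation Wald test across all unit groups."""
    labels = sorted(np.unique(units))
    mask = np.ones(len(units), bool)
    score = composite_shape_score(shape, mask)
    groups = [(shape.x[units == u], score[units == u]) for u in labels]
    groups = [(x, y) for x, y in groups if len(x) >= 3]
    out = {"groups": labels, "n": [int((units == u).sum()) for u in labels]}
    slope = common_slope_lr_test(groups)
    out["slope_LR"] = slope.statistic
    out["slope_df"] = slope.df
    out["slope_p"] = slope.p
    out["common_slope"] = slope.common_slope
    try:
        elev = elevation_wald_test(groups, slope.common_slope)
        out["elevation_W"] = elev.statistic
        out["elevation_df"] = elev.df
        out["elevation_p"] = elev.p
    except ValueError as exc:
        out["elevation_error"] = str(exc)
    return out


def run_pipeline(
    config: PipelineConfig,
    table: SpecimenTable | None = None,
    meta: SpeciesMeta | None = None,
    tree: Phylo | None = None,
) -> dict:
    """Run the full analysis; returns the summary dict (also written to
    ``summary.json``). Input objects may be passed directly (e.g. from the
    synthetic generator) instead of paths."""
    t_start = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["disparity", "convergence", "models"])
    summary: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "stage_seeds": seeds,
    }

    if table is None or meta is None or tree is None:
        log.info("stage load: %s", config.specimen_csv)
        table, meta, tree = load_dataset(
            config.specimen_csv, config.meta_csv, config.tree_newick)
    summary["n_species_input"] = len(table.species)
    summary["n_specimens_input"] = table.n_specimens

    # -- prune ------------------------------------------------------------
    pruned = prune_by_sample_size(table, config.min_specimens)
    summary["n_species_retained"] = len(pruned.species)
    summary["n_specimens_retained"] = pruned.n_specimens
    summary["species_dropped"] = list(pruned.dropped_species)
    log.info("stage prune: %d -> %d species", len(table.species),
             len(pruned.species))

    # -- shape ratios & trajectories --------------------------------------
    shape_full = to_shape_ratios(table)
    shape = to_shape_ratios(pruned)
    coeffs = fit_all_trajectories(shape)
    coefficients_frame(coeffs).to_csv(out / "coefficients.csv", index=False)
    trajectory_display_scores(shape).to_csv(
        out / "trajectory_scores.csv", index=False)

    part_of = meta.lookup("partition")
    diet_of = meta.lookup("diet")
    order_of = meta.lookup("order")
    sp_full = shape_full.species
    units_part = np.array([part_of[s] for s in sp_full])
    units_diet = np.array([diet_of[s] for s in sp_full])
    units_order = np.array([order_of[s] for s in sp_full])
    units_pxd = np.array([f"{a}|{b}" for a, b in zip(units_part, units_diet)])

    # -- HOS tests ---------------------------------------------------------
    log.info("stage HOS")
    hos: dict = {}
    for name, units in (("partition", units_part), ("order", units_order),
                        ("diet", units_diet)):
        hos[name] = _pooled_hos(shape_full, units, config.alpha)
    pairwise_tables = {}
    fams = {"order": units_order, "diet": units_diet,
            "partition_diet": units_pxd}
    if config.run_species_pairwise:
        fams["species"] = shape_full.species
    for fam, units in fams.items():
        tab = pairwise_hos(shape_full, units, alpha=config.alpha)
        tab.to_csv(out / f"hos_pairwise_{fam}.csv", index=False)
        pairwise_tables[fam] = tab
        if not tab.empty:
            sl = tab[tab["test"] == "slope"]
            el = tab[tab["test"] == "elevation"]
            hos[f"pairwise_{fam}"] = {
                "n_slope_comparisons": int(len(sl)),
                "n_slope_significant": int(sl["significant"].sum()),
                "n_elevation_comparisons": int(len(el)),
                "n_elevation_significant": int(el["significant"].sum()),
            }
    summary["hos"] = hos

    # -- allometric space --------------------------------------------------
    space = build_space(coeffs)
    space.scores_frame().to_csv(out / "space_scores.csv", index=False)
    space.loadings_frame().to_csv(out / "space_loadings.csv", index=False)
    pd.DataFrame({"axis": [f"PC{i+1}" for i in range(len(space.var_fraction))],
                  "eigenvalue": space.eigenvalues,
                  "var_fraction": space.var_fraction}).to_csv(
        out / "space_variance.csv", index=False)
    k_star = significant_axes(space, config.pc_cap)
    summary["space"] = {
        "var_fraction": space.var_fraction.tolist(),
        "pc1_pct": 100 * float(space.var_fraction[0]),
        "pc2_pct": 100 * float(space.var_fraction[1]),
        "broken_stick_k": broken_stick_axes(space),
        "k_used": k_star,
        "var_pct_retained": 100 * float(space.var_fraction[:k_star].sum()),
    }
    log.info("stage space: PC1 %.1f%%, k*=%d", summary["space"]["pc1_pct"], k_star)

    # -- disparity ---------------------------------------------------------
    sp_list = space.species
    B = np.array([c.b for c in coeffs])
    disp: dict = {}
    for name, lut in (("partition", part_of), ("order", order_of),
                      ("diet", diet_of)):
        groups = np.array([lut[s] for s in sp_list])
        res = disparity_permutation_test(B, groups, config.permutations,
                                         seeds["disparity"])
        res.pairwise_p.to_csv(out / f"disparity_p_{name}.csv")
        disp[name] = {"PV": {k: float(v) for k, v in res.pv.items()},
                      "pairwise_p": res.pairwise_p.to_dict()}
    groups_pxd = np.array([f"{part_of[s]}|{diet_of[s]}" for s in sp_list])
    disp["partition_diet"] = {
        "PV": {k: float(v)
               for k, v in disparity_permutation_test(
                   B, groups_pxd, max(100, config.permutations // 10),
                   seeds["disparity"]).pv.items()}}
    # allometry-corrected residual disparity per diet
    mask = np.ones(len(shape_full.x), bool)
    comp = composite_shape_score(shape_full, mask)
    try:
        cs = common_slope_lr_test(
            [(shape_full.x[units_diet == d], comp[units_diet == d])
             for d in sorted(np.unique(units_diet))])
        disp["residual_by_diet"] = {
            k: float(v) for k, v in residual_disparity(
                shape_full.x, comp, units_diet, cs.common_slope).items()}
    except ValueError as exc:
        disp["residual_by_diet"] = {"error": str(exc)}
    summary["disparity"] = disp

    # -- convergence --------------------------------------------------------
    log.info("stage convergence")
    tree_species = sorted(set(sp_list) & set(tree.labels))
    subtree = tree.retain_tips(tree_species) if set(tree.labels) - set(
        tree_species) else tree
    score_of = dict(zip(space.species, space.scores))
    Z = np.array([score_of[s][:k_star] for s in subtree.labels])
    conv: dict = {}
    diets_present = sorted({diet_of[s] for s in subtree.labels})
    for d in diets_present:
        members = [s for s in subtree.labels if diet_of[s] == d]
        parts = {part_of[s] for s in members}
        entry: dict = {"n_species": len(members),
                       "partitions_present": sorted(parts)}
        if len(parts) < 2:
            entry["skipped"] = "absent from one partition"
            if config.exclude_single_partition_diets:
                conv[d] = entry
                continue
        if len(members) >= 2:
            # convergence question is between the two partitions: enumerate
            # cross-partition pairs only (all pairs when one partition)
            pairs = [(a, b) for i, a in enumerate(members)
                     for b in members[i + 1:]
                     if part_of[a] != part_of[b]] or None
            res = c_significance(subtree, Z, members,
                                 n_sims=config.convergence_sims,
                                 seed=seeds["convergence"], pairs=pairs)
            entry["C"] = {k: float(v) for k, v in res.C.items()}
            entry["p"] = {k: float(v) for k, v in res.p.items()}
            res.pairs.to_csv(out / f"convergence_pairs_{d}.csv", index=False)
        per_part = {pt: sum(1 for s in members if part_of[s] == pt)
                    for pt in parts}
        if len(parts) == 2 and min(per_part.values()) >= 2:
            ang = angle_state_convergence(
                subtree, Z, {s: diet_of[s] for s in subtree.labels}, d,
                partitions={s: part_of[s] for s in subtree.labels},
                n_null=config.convergence_sims, seed=seeds["convergence"])
            entry["ang_state"] = ang.ang_state
            entry["ang_state_time"] = ang.ang_state_time
            entry["ang_p"] = ang.p_ang
            entry["ang_time_p"] = ang.p_ang_time
        elif len(parts) == 2:
            entry["angle_skipped"] = "a partition has a single species"
        conv[d] = entry
    summary["convergence"] = conv
    with open(out / "convergence.json", "w") as fh:
        json.dump(_jsonable(conv), fh, indent=1)

    # -- evolutionary models ------------------------------------------------
    if config.fit_models:
        log.info("stage models")
        part_states = {s: part_of[s] for s in subtree.labels}
        diet_states = {s: diet_of[s] for s in subtree.labels}
        mtable, params = fit_all_models(
            subtree, Z, part_states, diet_states,
            n_maps=config.n_maps, seed=seeds["models"])
        mtable.to_csv(out / "model_table.csv", index=False)
        summary["models"] = {
            "table": mtable.to_dict(orient="records"),
            "best": mtable.iloc[0]["model"],
            "best_supported": mtable.loc[mtable["dAICc"] < 2, "model"].tolist(),
        }
        with open(out / "model_params.json", "w") as fh:
            json.dump(_jsonable({m: {k: v for k, v in p.items()}
                                 for m, p in params.items()}), fh, indent=1,
                      default=str)

    summary["runtime_s"] = round(time.time() - t_start, 2)
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=1, sort_keys=True)
    log.info("pipeline done in %.1fs", summary["runtime_s"])
    return summary
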