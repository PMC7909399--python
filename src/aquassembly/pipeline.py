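"""End-to-end analysis pipeline.

From a count table + metadata (real files or the synthetic generator) to a
report directory: preprocessing, rarefaction, alpha diversity with
Kruskal-Wallis letters, Bray-Curtis beta diversity with UPGMA clustering
and group overlap, Mantel correlations, RDA with forward selection for
community and functional composition, distance-decay, PCNM variation
partitioning, and the null-model stochasticity ratio.  A single master
seed makes the whole run reproducible; every stage seed is recorded in a
JSON manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (CommunityMatrix, DEFAULT_HABITAT_RULES, load_community,
                   load_metadata, preprocess, rarefy, save_community)
from .diversity import (DistanceMatrix, alpha_diversity, bray_curtis_matrix,
                        group_overlap, upgma_tree, within_group_beta)
from .functions import apply_mapping, bundled_mapping, load_mapping
from .nullmodel import (assembly_significance, expected_similarity,
                        stochasticity_ratio)
from .ordination import (forward_select, geographic_distance_matrix,
                         hellinger_transform, pcnm_axes, project_coordinates,
                         rda_fit, distance_decay, variation_partition)
from .permtests import anosim, kruskal_letters, mantel, permanova
from .simulate import SimConfig, simulate_dataset

logger = logging.getLogger("aquassembly")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, resolvable from one YAML file."""

    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    mapping_path: str | None = None
    simulate: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    min_total_reads: int = 10
    exclude_patterns: tuple = ("Chloroplast",)
    rarefaction_depth: int | None = None     # None -> smallest sample total
    n_perm_group: int = 999                  # ANOSIM / PERMANOVA / RDA
    n_perm_mantel: int = 9999
    n_rand_null: int = 1000
    alpha_group: float = 0.05
    alpha_sr: float = 0.01
    master_seed: int = 0
    out_dir: str = "aquassembly_report"

    def __post_init__(self) -> None:
        if min(self.n_perm_group, self.n_perm_mantel, self.n_rand_null) < 99:
            raise ValueError("permutation counts must be >= 99")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = SimConfig(**sim_raw)
        return cfg


def _stage_seed(master: int, k: int) -> int:
    return (int(master) * 1009 + 97 * k) % (2 ** 31 - 1)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return "".join(sorted(o))
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and write the report directory; returns its path."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "master_seed": cfg.master_seed,
                      "stage_seeds": {}, "stages": []}

    def seed_for(name: str, k: int) -> int:
        s = _stage_seed(cfg.master_seed, k)
        manifest["stage_seeds"][name] = s
        return s

    def stage(name: str):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    # ---- input ----------------------------------------------------------
    stage("input")
    try:
        if cfg.simulate:
            sim_cfg = SimConfig(**{**asdict(cfg.sim), "seed":
                                   seed_for("simulate", 0)})
            cm_raw, md, truth = simulate_dataset(sim_cfg)
            with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
                json.dump(truth.to_json_dict(), fh, default=_json_default)
        else:
            if cfg.counts_path is None or cfg.metadata_path is None:
                raise ValueError("counts_path and metadata_path are required "
                                 "unless simulate=true")
            cm_raw = load_community(cfg.counts_path, cfg.taxonomy_path)
            md = load_metadata(cfg.metadata_path)
            if "habitat_group" not in md.columns:
                from .core import assign_groups
                md = assign_groups(md, DEFAULT_HABITAT_RULES)
        md = md.loc[cm_raw.sample_ids]
        groups = md["habitat_group"]
    except Exception as exc:
        raise RuntimeError(f"stage 'input' failed: {exc}") from exc

    # ---- preprocessing --------------------------------------------------
    stage("preprocess")
    cm_filtered = preprocess(cm_raw, cfg.min_total_reads, cfg.exclude_patterns)
    depth = cfg.rarefaction_depth or int(cm_filtered.sample_totals.min())
    cm = rarefy(cm_filtered, depth, seed_for("rarefy", 1))
    with open(out / "preprocessing.json", "w", encoding="utf-8") as fh:
        json.dump({
            "otus_input": cm_raw.data.shape[1],
            "otus_after_filter": cm_filtered.data.shape[1],
            "rarefaction_depth": depth,
            "min_total_reads": cfg.min_total_reads,
            "exclude_patterns": list(cfg.exclude_patterns),
        }, fh, indent=2)

    # ---- alpha diversity ------------------------------------------------
    stage("alpha_diversity")
    alpha = alpha_diversity(cm)
    alpha.to_csv(out / "alpha_diversity.csv")
    alpha_tests = {}
    for index in ("chao1", "shannon", "inv_simpson"):
        kw = kruskal_letters(alpha[index].to_numpy(), groups.to_numpy(),
                             alpha=cfg.alpha_group)
        kw["pairwise"] = {f"{a}|{b}": v for (a, b), v in kw["pairwise"].items()}
        alpha_tests[index] = kw
    with open(out / "alpha_group_tests.json", "w", encoding="utf-8") as fh:
        json.dump(alpha_tests, fh, indent=2, default=_json_default)

    # ---- beta diversity -------------------------------------------------
    stage("beta_diversity")
    bc = bray_curtis_matrix(cm)
    bc.to_frame().to_csv(out / "bray_curtis.tsv", sep="\t")
    (out / "upgma.nwk").write_text(upgma_tree(bc) + "\n", encoding="utf-8")
    within_group_beta(bc, groups).to_csv(out / "within_group_beta.csv")
    with open(out / "group_overlap.json", "w", encoding="utf-8") as fh:
        json.dump(group_overlap(cm, groups), fh, indent=2,
                  default=_json_default)

    res_anosim = anosim(bc, groups, cfg.n_perm_group, seed_for("anosim", 2))
    res_permanova = permanova(bc, groups, cfg.n_perm_group,
                              seed_for("permanova", 3))
    with open(out / "group_tests.json", "w", encoding="utf-8") as fh:
        json.dump({
            "anosim": {"R": res_anosim.statistic, "p": res_anosim.p_value},
            "permanova": {"F": res_permanova.statistic,
                          "R2": res_permanova.extra["R2"],
                          "p": res_permanova.p_value},
        }, fh, indent=2)

    # ---- function profile ----------------------------------------------
    stage("function_profile")
    mapping = (load_mapping(cfg.mapping_path) if cfg.mapping_path
               else bundled_mapping())
    ft = apply_mapping(cm, mapping)
    ft.relative.to_csv(out / "function_profile.tsv", sep="\t")
    bfc_bc = DistanceMatrix(
        list(ft.relative.columns),
        bray_curtis_matrix(CommunityMatrix(
            (ft.counts.T).astype(np.int64))).values,
        "dissimilarity")

    # ---- Mantel correlations (environment vs community/function) -------
    stage("mantel")
    env_cols = [c for c in md.columns
                if c not in ("ecosystem", "habitat_group", "latitude",
                             "longitude")]
    env = md[env_cols].astype(float)
    env_z = (env - env.mean()) / env.std(ddof=1)
    env.corr(method="pearson").to_csv(out / "env_pearson.csv")
    geo = geographic_distance_matrix(md)
    mantel_rows = []
    k = 10
    from scipy.spatial.distance import pdist, squareform
    for name in env_cols + ["geographic_distance"]:
        if name == "geographic_distance":
            D2 = geo
        else:
            D2 = DistanceMatrix(list(md.index),
                                squareform(pdist(env_z[[name]].to_numpy())),
                                "geographic")
        for label, D1 in (("community", bc), ("function", bfc_bc)):
            k += 1
            res = mantel(D1, D2, "spearman", cfg.n_perm_mantel,
                         seed_for(f"mantel_{label}_{name}", k))
            mantel_rows.append({"variable": name, "target": label,
                                "mantel_r": res.statistic, "p": res.p_value})
    pd.DataFrame(mantel_rows).to_csv(out / "mantel_tests.csv", index=False)

    # ---- RDA with forward selection (BCC and BFC) -----------------------
    stage("rda")
    hel = hellinger_transform(cm)
    rda_summary = {}
    for label, Y in (("community", hel),
                     ("function", hellinger_transform(
                         pd.DataFrame(ft.counts.T + 0.0)))):
        k += 1
        trace = forward_select(Y.to_numpy(), env, alpha=cfg.alpha_group,
                               n_perm=cfg.n_perm_group,
                               seed=seed_for(f"forward_{label}", k))
        sel = trace.selected
        entry = {"selected": sel, "steps": trace.steps,
                 "dropped_for_vif": trace.dropped_for_vif,
                 "vif": trace.vif_final}
        if sel:
            k += 1
            fit = rda_fit(Y.to_numpy(), env[sel].to_numpy(),
                          cfg.n_perm_group, seed_for(f"rda_{label}", k))
            entry.update({"r2": fit.r2, "adj_r2": fit.adj_r2,
                          "pseudo_f": fit.pseudo_f, "p": fit.p_value})
            pd.DataFrame(fit.site_scores, index=list(md.index)).to_csv(
                out / f"rda_site_scores_{label}.tsv", sep="\t")
        rda_summary[label] = entry
    with open(out / "rda_selection.json", "w", encoding="utf-8") as fh:
        json.dump(rda_summary, fh, indent=2, default=_json_default)

    # ---- distance decay -------------------------------------------------
    stage("distance_decay")
    sim_matrix = bc.to_similarity()
    dd = {"overall": distance_decay(sim_matrix, geo, cfg.n_perm_group,
                                    seed_for("distdecay", 40))}
    for g in pd.unique(groups):
        idx = [i for i, s in enumerate(bc.ids) if groups[s] == g]
        if len(idx) < 4:
            dd[str(g)] = {"skipped": "fewer than 4 samples"}
            continue
        ids_g = [bc.ids[i] for i in idx]
        sub_sim = DistanceMatrix(ids_g,
                                 sim_matrix.values[np.ix_(idx, idx)],
                                 "similarity")
        sub_geo = DistanceMatrix(ids_g, geo.values[np.ix_(idx, idx)],
                                 "geographic")
        try:
            dd[str(g)] = distance_decay(sub_sim, sub_geo, cfg.n_perm_group,
                                        seed_for(f"distdecay_{g}", 41))
        except ValueError as exc:
            dd[str(g)] = {"skipped": str(exc)}
    with open(out / "distance_decay.json", "w", encoding="utf-8") as fh:
        json.dump(dd, fh, indent=2)

    # ---- variation partitioning ----------------------------------------
    stage("variation_partition")
    E_sel = rda_summary["community"]["selected"] or env_cols
    E = env[E_sel]
    basis = pcnm_axes(geo)
    trend = project_coordinates(md)
    trend = trend - trend.mean()
    # forward-select spatial axes so the partition stays well-posed
    k += 1
    s_trace = forward_select(hel.to_numpy(), basis.vectors,
                             alpha=cfg.alpha_group, n_perm=cfg.n_perm_group,
                             seed=seed_for("forward_pcnm", k))
    S_sel = basis.vectors[s_trace.selected] if s_trace.selected else None
    k += 1
    part = variation_partition(hel.to_numpy(), E, S_sel, trend,
                               n_perm=cfg.n_perm_group,
                               seed=seed_for("varpart", k))
    with open(out / "variation_partition.json", "w", encoding="utf-8") as fh:
        json.dump({
            "fractions": {"".join(sorted(key)): v
                          for key, v in part.fractions.items()},
            "subset_adj_r2": part.subset_adj_r2,
            "total_explained": part.total_explained,
            "residual": part.residual,
            "pure_p_values": part.pure_p_values,
            "pcnm_axes_selected": s_trace.selected,
            "env_selected": E_sel,
        }, fh, indent=2, default=_json_default)

    # ---- stochasticity ratio -------------------------------------------
    stage("stochasticity")
    k += 1
    ens = expected_similarity(cm, cfg.n_rand_null, seed_for("null_ens", k))
    sr = stochasticity_ratio(sim_matrix, ens, groups, alpha=cfg.alpha_sr)
    sr.pair_table.to_csv(out / "stochasticity_pairs.csv", index=False)
    sr.sr_per_group.rename("SR_percent").to_csv(out / "sr_per_group.csv")
    k += 1
    sig = assembly_significance(cm, groups, cfg.n_rand_null,
                                seed_for("null_f", k))
    pd.Series(sig["null_f"], name="null_F").to_csv(out / "null_f.csv",
                                                   index=False)
    with open(out / "stochasticity_summary.json", "w", encoding="utf-8") as fh:
        json.dump({
            "sr_per_group": sr.sr_per_group.to_dict(),
            "letters": sr.letters,
            "pairwise_q": {f"{a}|{b}": v for (a, b), v in sr.pairwise_q.items()},
            "observed_f": sig["observed_f"],
            "null_f_p": sig["p_value"],
        }, fh, indent=2, default=_json_default)

    # ---- manifest -------------------------------------------------------
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
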