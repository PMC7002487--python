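"""End-to-end orchestration: sightings + genetics -> structured report.

Stage order: filter -> association indices and structural predictors ->
MRQAP screen -> GAI fit -> data-stream permutation test -> classification
-> modularity clustering -> reproductive-condition tests -> kinship tests.
The report is a plain JSON-serializable dict that mirrors the study's
three summary tables (predictor screen, affiliation-class summary,
cluster summary) and records every permutation count and seed next to the
p-value it produced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import affiliation as aff
from . import associations as assoc
from . import clustering as clu
from . import kinship as kin
from . import ranges as rng_mod
from .dyadmatrix import DyadMatrix
from .genepop import read_genepop

__all__ = ["PipelineConfig", "validate_inputs", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Inputs and tunables for a full pipeline run."""

    sightings: str = "sightings.csv"
    genotypes: str | None = "genotypes.gen"
    haplotypes: str | None = "haplotypes.csv"
    reproductive: str | None = "reproductive.csv"
    females: str | None = None  # optional one-column CSV of sexed females

    min_identified_fraction: float = 0.75
    min_sightings: int = 11  # strictly-greater-than rule
    bandwidth_m: float = 550.0
    cell_m: float = 50.0
    udoi_level: float = 0.95
    classification_threshold: float = 2.5
    alpha: float = 0.05
    relatedness_mode: str = "triadic"

    n_perm_mrqap: int = 1_000
    n_perm_bejder: int = 1_000
    flips_per_perm: int = 100
    n_perm_mantel: int = 10_000
    n_perm_class: int = 10_000
    n_perm_chisq: int = 10_000
    bejder_index: str = "gai"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.min_identified_fraction <= 1:
            raise ValueError("min_identified_fraction must be in (0, 1]")
        if self.min_sightings < 0:
            raise ValueError("min_sightings must be non-negative")
        if self.bandwidth_m <= 0 or self.cell_m <= 0:
            raise ValueError("bandwidth and cell size must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_inputs(config: PipelineConfig, base_dir=".") -> list[dict]:
    """Schema and cross-file consistency checks.

    Returns diagnostics [{level: 'fatal'|'warning'|'note', message}, ...];
    malformed primary inputs raise :class:`PipelineError`.
    """
    base = Path(base_dir)
    diags: list[dict] = []

    def note(level, msg):
        diags.append({"level": level, "message": msg})

    spath = base / config.sightings
    if not spath.exists():
        raise PipelineError("validate", "missing-input", f"sightings file not found: {spath}")
    try:
        rec = assoc.validate_sightings(pd.read_csv(spath))
    except ValueError as e:
        raise PipelineError("validate", "malformed-sightings", str(e)) from e
    sighted = set(rec["individual_id"])
    if (rec[["x_m", "y_m"]] < 0).any().any():
        note("note", "negative projected coordinates present (allowed)")
    for name, path_attr, col in (
        ("haplotypes", config.haplotypes, "haplotype"),
        ("reproductive", config.reproductive, "category"),
    ):
        if path_attr is None:
            continue
        p = base / path_attr
        if not p.exists():
            note("warning", f"{name} file not found: {p}; related tests will be skipped")
            continue
        df = pd.read_csv(p)
        if "individual_id" not in df.columns or col not in df.columns:
            raise PipelineError("validate", f"malformed-{name}",
                                f"{name} file must have columns individual_id, {col}")
        extra = set(df["individual_id"].astype(str)) - sighted
        for i in sorted(extra):
            note("warning", f"{name}: individual {i} absent from sightings; excluded")
    if config.genotypes is not None:
        p = base / config.genotypes
        if p.exists():
            try:
                gt = read_genepop(p)
            except ValueError as e:
                raise PipelineError("validate", "malformed-genepop", str(e)) from e
            for i in sorted(set(gt.ids) - sighted):
                note("warning", f"genotypes: individual {i} absent from sightings; excluded")
        else:
            note("warning", f"genotype file not found: {p}; kinship tests will be skipped")
    return diags


def _class_table(classes, haplo: DyadMatrix | None, rel: DyadMatrix | None,
                 rel_ids: set | None) -> dict:
    out = {}
    for label in ("preferred", "casual", "avoided"):
        sub = classes.table[classes.table["label"] == label]
        entry = {"n_pairs": int(len(sub))}
        if len(sub):
            entry["mean_gai"] = float(sub["gai"].mean())
            entry["sd_gai"] = float(sub["gai"].std(ddof=1)) if len(sub) > 1 else 0.0
        if haplo is not None:
            hids = set(haplo.ids)
            pairs = [(a, b) for a, b in zip(sub["id_i"], sub["id_j"])
                     if a in hids and b in hids]
            shared = sum(haplo[(a, b)] for a, b in pairs)
            entry["n_pairs_haplotype"] = len(pairs)
            entry["n_sharing_haplotype"] = int(shared)
            if pairs:
                entry["pct_sharing_haplotype"] = 100.0 * shared / len(pairs)
        if rel is not None:
            pairs = [(a, b) for a, b in zip(sub["id_i"], sub["id_j"])
                     if a in rel_ids and b in rel_ids]
            entry["n_pairs_microsat"] = len(pairs)
            if pairs:
                entry["mean_relatedness"] = float(np.mean([rel[(a, b)] for a, b in pairs]))
        out[label] = entry
    return out


def run_pipeline(config: PipelineConfig, base_dir=".") -> dict:
    """Run every stage and return the consolidated report dict."""
    base = Path(base_dir)
    diags = validate_inputs(config, base_dir)
    report: dict = {"config": config.to_dict(), "diagnostics": diags}
    seed = int(config.seed)

    # ---- stage: filter -------------------------------------------------
    try:
        raw = pd.read_csv(base / config.sightings)
        females = None
        if config.females is not None and (base / config.females).exists():
            females = set(pd.read_csv(base / config.females).iloc[:, 0].astype(str))
        records, ids = assoc.filter_sightings(
            raw, config.min_identified_fraction, config.min_sightings, females)
    except ValueError as e:
        raise PipelineError("filter", "no-individuals", str(e)) from e
    report["counts"] = {
        "n_surveys": int(raw["date"].nunique()),
        "n_groups_raw": int(raw.groupby(["date", "group_id"]).ngroups),
        "n_groups_retained": int(records.groupby(["date", "group_id"]).ngroups),
        "n_individuals_retained": len(ids),
        "n_dyads": len(ids) * (len(ids) - 1) // 2,
    }
    logger.info("pipeline: %s", report["counts"])

    # ---- stage: association indices and predictors ---------------------
    try:
        counts = assoc.dyad_counts(records, ids)
        hwi_mat = assoc.hwi(counts)
        uds = rng_mod.individual_uds(records, ids, h=config.bandwidth_m, cell=config.cell_m)
        predictors = {
            "overlap": rng_mod.udoi_matrix(uds, level=config.udoi_level),
            "gregariousness": assoc.gregariousness_predictor(hwi_mat),
            "dyad_sightings": assoc.dyad_sightings_predictor(records, ids),
        }
    except (ValueError, KeyError) as e:
        raise PipelineError("predictors", "computation", str(e)) from e

    # ---- stage: MRQAP screen ------------------------------------------
    screen = aff.mrqap_screen(hwi_mat, predictors, n_perm=config.n_perm_mrqap,
                              alpha=config.alpha, seed=seed + 11)
    report["table1_predictor_screen"] = {
        k: {"partial_r": screen.partial_r[k], "p": screen.p_values[k],
            "retained": k in screen.retained, "n_perm": screen.n_perm,
            "seed": seed + 11}
        for k in screen.names
    }

    # ---- stage: GAI ----------------------------------------------------
    retained = {k: predictors[k] for k in screen.retained}
    try:
        gai_res = aff.fit_gai(counts, retained)
    except RuntimeError as e:
        raise PipelineError("gai", "non-convergence", str(e)) from e
    g = gai_res.gai.dyad_values()[gai_res.dyad_mask]
    report["gai"] = {
        "retained_predictors": screen.retained,
        "coefficients": gai_res.params,
        "range": [float(g.min()), float(g.max())],
        "mean": float(g.mean()), "sd": float(g.std(ddof=1)),
        "n_dyads": int(gai_res.dyad_mask.sum()),
        "predictor_residual_corr": gai_res.predictor_correlations(),
    }

    # ---- stage: permutation test --------------------------------------
    perm = aff.preferred_avoided_test(
        records, ids, predictors=retained, index=config.bejder_index,
        n_perm=config.n_perm_bejder, flips_per_perm=config.flips_per_perm,
        seed=seed + 23)
    report["preferred_avoided_test"] = {
        "observed_sd": perm.observed, "random_sd": perm.null_mean, "p": perm.p,
        "statistic": perm.statistic, "n_perm": perm.n_perm,
        "flips_per_perm": perm.flips_per_perm, "seed": seed + 23,
    }

    # ---- stage: classification and clustering -------------------------
    classes = gai_res.classify(config.classification_threshold)
    partition = clu.newman_partition(gai_res.gai)
    sizes = partition.sizes
    report["clusters"] = {
        "n_clusters": partition.n_clusters,
        "q_max": partition.q,
        "sizes": {str(k): v for k, v in sizes.items()},
        "size_mean": float(np.mean(list(sizes.values()))),
        "size_sd": float(np.std(list(sizes.values()), ddof=1)) if len(sizes) > 1 else 0.0,
        "assignment": {i: int(l) for i, l in zip(partition.ids, partition.labels)},
    }
    ranges_by_cluster = clu.cluster_ranges(partition, records,
                                           h=config.bandwidth_m, cell=config.cell_m)
    report["cluster_ranges_km2"] = {
        str(k): {"area95": v["area95_m2"] / 1e6, "area50": v["area50_m2"] / 1e6}
        for k, v in ranges_by_cluster.items()
    }

    # ---- stage: reproductive condition --------------------------------
    if config.reproductive is not None and (base / config.reproductive).exists():
        rc = pd.read_csv(base / config.reproductive)
        cats = {str(r.individual_id): int(r.category) for r in rc.itertuples()
                if str(r.individual_id) in set(ids)}
        if len(cats) >= 3:
            sim = aff.reproductive_similarity(cats)
            gai_sub, sim_sub = gai_res.gai.align_with(sim)
            r_cond, p_cond = aff.mantel(gai_sub, sim_sub,
                                        n_perm=config.n_perm_mantel, seed=seed + 31)
            med_same, med_diff, u_stat, p_u = aff.gai_by_condition(gai_sub, sim_sub)
            report["reproductive_condition"] = {
                "mantel_r": r_cond, "mantel_p": p_cond,
                "n_perm": config.n_perm_mantel, "seed": seed + 31,
                "median_gai_same": med_same, "median_gai_different": med_diff,
                "mannwhitney_u": u_stat, "mannwhitney_p": p_u,
                "n_category1": int(sum(1 for v in cats.values() if v == 1)),
                "n_category2": int(sum(1 for v in cats.values() if v == 2)),
            }

    # ---- stage: kinship -------------------------------------------------
    haplo = rel_matrix = None
    rel_ids: set = set()
    if config.haplotypes is not None and (base / config.haplotypes).exists():
        hp = pd.read_csv(base / config.haplotypes)
        hmap = {str(r.individual_id): str(r.haplotype) for r in hp.itertuples()
                if str(r.individual_id) in set(ids)}
        if len(hmap) >= 3:
            haplo = kin.haplotype_matrix(hmap)
            gai_h, haplo_al = gai_res.gai.align_with(haplo)
            r_h, p_h = aff.mantel(gai_h, haplo_al, n_perm=config.n_perm_mantel,
                                  seed=seed + 41)
            report["kinship_mantel"] = {
                "gai_vs_haplotype": {"r": r_h, "p": p_h,
                                     "n_perm": config.n_perm_mantel, "seed": seed + 41}
            }
    if config.genotypes is not None and (base / config.genotypes).exists():
        gt = read_genepop(base / config.genotypes)
        keep = [i for i in gt.ids if i in set(ids)]
        if len(keep) >= 4:
            gt = gt.subset(keep)
            relres = kin.ml_relatedness(gt, mode=config.relatedness_mode,
                                        seed=seed + 43)
            rel_matrix = relres.matrix
            rel_ids = set(rel_matrix.ids)
            gai_r, rel_al = gai_res.gai.align_with(rel_matrix)
            r_r, p_r = aff.mantel(gai_r, rel_al, n_perm=config.n_perm_mantel,
                                  seed=seed + 47)
            report.setdefault("kinship_mantel", {})["gai_vs_relatedness"] = {
                "r": r_r, "p": p_r, "n_perm": config.n_perm_mantel, "seed": seed + 47}

    report["table2_affiliation_classes"] = _class_table(classes, haplo, rel_matrix, rel_ids)

    # class-level tests
    if rel_matrix is not None:
        cc = kin.class_comparison(rel_matrix, classes, n_perm=config.n_perm_class,
                                  seed=seed + 53)
        report["relatedness_by_class"] = {
            c: {"n_dyads": int(cc.loc[c, "n_dyads"]), "mean": float(cc.loc[c, "mean"]),
                "p": float(cc.loc[c, "p"]), "n_perm": config.n_perm_class,
                "seed": seed + 53}
            for c in cc.index
        }
    if haplo is not None:
        t2 = report["table2_affiliation_classes"]
        tab = [[t2[c]["n_sharing_haplotype"],
                t2[c]["n_pairs_haplotype"] - t2[c]["n_sharing_haplotype"]]
               for c in ("preferred", "casual", "avoided")
               if t2[c].get("n_pairs_haplotype", 0) > 0]
        if len(tab) >= 2:
            chi2, p_chi = kin.haplotype_class_chisq(np.array(tab),
                                                    n_mc=config.n_perm_chisq,
                                                    seed=seed + 59)
            report["haplotype_class_chisq"] = {
                "chi2": chi2, "p": p_chi, "n_perm": config.n_perm_chisq,
                "seed": seed + 59}

    # cluster-level summary (table 3) and tests
    t3: dict = {}
    for cl in sorted(sizes):
        members = set(partition.members(cl))
        sub = classes.table[classes.table["id_i"].isin(members)
                            & classes.table["id_j"].isin(members)]
        entry = {"n_individuals": sizes[cl], "n_pairs": int(len(sub))}
        if len(sub):
            entry["mean_gai"] = float(sub["gai"].mean())
            entry["sd_gai"] = float(sub["gai"].std(ddof=1)) if len(sub) > 1 else 0.0
        t3[str(cl)] = entry
    report["table3_clusters"] = t3

    if rel_matrix is not None and partition.n_clusters >= 2:
        try:
            w_mean, b_mean, p_wb = kin.within_between_test(
                rel_matrix, partition, n_perm=config.n_perm_class, seed=seed + 61)
            report["relatedness_within_between"] = {
                "mean_within": w_mean, "mean_between": b_mean, "p": p_wb,
                "n_perm": config.n_perm_class, "seed": seed + 61}
        except ValueError as e:
            report["relatedness_within_between"] = {"skipped": str(e)}
    if haplo is not None and partition.n_clusters >= 2:
        lab = {i: l for i, l in zip(partition.ids, partition.labels)}
        hids = [i for i in haplo.ids if i in lab]
        if len(hids) >= 3:
            hm = haplo.reindex(hids)
            iu, ju = hm.triu_indices()
            same = np.array([lab[hids[a]] == lab[hids[b]] for a, b in zip(iu, ju)])
            vals = hm.dyad_values()
            tab = np.array([
                [vals[same].sum(), (~vals[same].astype(bool)).sum()],
                [vals[~same].sum(), (~vals[~same].astype(bool)).sum()],
            ])
            if (tab.sum(axis=1) > 0).all():
                chi2, p_chi = kin.haplotype_class_chisq(tab, n_mc=config.n_perm_chisq,
                                                        seed=seed + 67)
                report["haplotype_within_between"] = {
                    "n_within": int(tab[0].sum()), "n_sharing_within": int(tab[0, 0]),
                    "n_between": int(tab[1].sum()), "n_sharing_between": int(tab[1, 0]),
                    "chi2": chi2, "p": p_chi, "n_perm": config.n_perm_chisq,
                    "seed": seed + 67}

    # overlap vs relatedness confound check
    if rel_matrix is not None and haplo is not None:
        udoi = predictors["overlap"]
        ctl = kin.overlap_relatedness_control(udoi, rel_matrix, haplo,
                                              n_perm=config.n_perm_mantel,
                                              seed=seed + 71)
        report["overlap_relatedness_control"] = {
            k: {"r": v[0], "p": v[1], "n_perm": config.n_perm_mantel, "seed": seed + 71}
            for k, v in ctl.items()
        }
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
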