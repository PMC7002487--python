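"""Calibration and parameter-recovery experiments on synthetic data.

These experiments are the package's substitute for ground truth the field
data cannot provide: under the simulator's null (all homophily effects
zero) every permutation test must reject at its nominal level, and under
planted structure the pipeline must recover what was planted.  They are
used by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import affiliation as aff
from . import associations as assoc
from . import clustering as clu
from . import ranges as rngm
from .dyadmatrix import DyadMatrix
from .kinship import ml_relatedness, within_between_test
from .simulate import SimulationConfig, simulate_pedigree, simulate_surveys

__all__ = [
    "bejder_null_rejection_rate",
    "mantel_null_rejection_rate",
    "mrqap_null_rejection_rate",
    "within_between_null_rejection_rate",
    "cluster_recovery",
    "kin_mantel_power",
    "parent_offspring_recovery",
    "analyse_survey_data",
]

_NULL_SIM = dict(n_females=20, n_clusters=3, n_days=60, detect_prob=0.35,
                 beta_cluster=0.0, beta_kin=0.0, beta_repro=0.0,
                 n_loci=4, alleles_per_locus=4)


def _null_dataset(seed: int):
    cfg = SimulationConfig(seed=seed, **_NULL_SIM)
    truth = simulate_pedigree(cfg)
    surveys = simulate_surveys(truth, cfg)
    rec, ids = assoc.filter_sightings(surveys, min_sightings=5)
    return truth, rec, ids


def bejder_null_rejection_rate(n_reps: int = 200, seed: int = 0,
                               alpha: float = 0.05) -> float:
    """Rejection rate of the preferred/avoided permutation test when the
    simulator plants no social preference at all."""
    rej = 0
    for rep in range(n_reps):
        _, rec, ids = _null_dataset(seed * 100_003 + rep)
        res = aff.preferred_avoided_test(rec, ids, predictors={}, index="gai",
                                         n_perm=100, flips_per_perm=100,
                                         seed=seed * 7 + rep)
        rej += res.p <= alpha
    return rej / n_reps


def mantel_null_rejection_rate(n_reps: int = 200, seed: int = 0,
                               alpha: float = 0.05, n: int = 20) -> float:
    """Mantel test between independent random matrices."""
    rng = np.random.default_rng(seed)
    m = n * (n - 1) // 2
    rej = 0
    for rep in range(n_reps):
        a = DyadMatrix.from_dyad_values(range(n), rng.normal(size=m))
        b = DyadMatrix.from_dyad_values(range(n), rng.normal(size=m))
        _, p = aff.mantel(a, b, n_perm=199, seed=seed * 11 + rep)
        rej += p <= alpha
    return rej / n_reps


def mrqap_null_rejection_rate(n_reps: int = 200, seed: int = 0,
                              alpha: float = 0.05, n: int = 20) -> float:
    """MRQAP screen on a pure-noise predictor."""
    rng = np.random.default_rng(seed)
    m = n * (n - 1) // 2
    rej = 0
    for rep in range(n_reps):
        y = DyadMatrix.from_dyad_values(range(n), rng.normal(size=m))
        noise = DyadMatrix.from_dyad_values(range(n), rng.normal(size=m))
        scr = aff.mrqap_screen(y, {"noise": noise}, n_perm=199,
                               alpha=alpha, seed=seed * 13 + rep)
        rej += scr.p_values["noise"] < alpha
    return rej / n_reps


def within_between_null_rejection_rate(n_reps: int = 200, seed: int = 0,
                                       alpha: float = 0.05, n: int = 20) -> float:
    """Within/between-cluster comparison with random cluster labels."""
    rng = np.random.default_rng(seed)
    m = n * (n - 1) // 2
    labels = np.repeat(np.arange(4), n // 4)
    rej = 0
    for rep in range(n_reps):
        vals = DyadMatrix.from_dyad_values(range(n), rng.normal(size=m))
        part = clu.Partition(ids=[str(i) for i in range(n)],
                             labels=rng.permutation(labels), q=0.0)
        _, _, p = within_between_test(vals, part, n_perm=199, seed=seed * 17 + rep)
        rej += p <= alpha
    return rej / n_reps


def analyse_survey_data(truth, surveys, screen_seed: int, n_perm_mrqap: int = 200):
    """Filter -> HWI -> predictors -> MRQAP -> GAI, returning the pieces."""
    rec, ids = assoc.filter_sightings(surveys)
    counts = assoc.dyad_counts(rec, ids)
    hwi_mat = assoc.hwi(counts)
    uds = rngm.individual_uds(rec, ids)
    predictors = {
        "overlap": rngm.udoi_matrix(uds),
        "gregariousness": assoc.gregariousness_predictor(hwi_mat),
        "dyad_sightings": assoc.dyad_sightings_predictor(rec, ids),
    }
    screen = aff.mrqap_screen(hwi_mat, predictors, n_perm=n_perm_mrqap,
                              seed=screen_seed)
    gai_res = aff.fit_gai(counts, {k: predictors[k] for k in screen.retained})
    return rec, ids, counts, hwi_mat, predictors, screen, gai_res


def cluster_recovery(n_reps: int = 10, seed: int = 0) -> dict:
    """Planted-partition recovery through the full GAI pipeline.

    Clusters are made spatially homogeneous (shared centers) so the
    planted structure is purely social, and the grouping threshold sits
    above the affinity noise scale so groups essentially never mix
    clusters — the planted-partition setting with a strong cluster
    effect.  Returns the mean adjusted Rand index vs. truth, plus
    cluster counts and Q values.
    """
    from sklearn.metrics import adjusted_rand_score as ari

    aris, ks, qs = [], [], []
    for rep in range(n_reps):
        cfg = SimulationConfig(seed=seed * 1009 + rep, beta_cluster=6.0,
                               beta_kin=0.0, beta_repro=0.0,
                               cluster_centers=[(0.0, 0.0)] * 7,
                               group_threshold=(2.5, 4.0))
        truth = simulate_pedigree(cfg)
        surveys = simulate_surveys(truth, cfg)
        *_, gai_res = analyse_survey_data(truth, surveys, screen_seed=seed + rep)
        part = clu.newman_partition(gai_res.gai)
        lab = {i: c for i, c in zip(truth.ids, truth.cluster)}
        aris.append(float(ari([lab[i] for i in part.ids], part.labels)))
        ks.append(part.n_clusters)
        qs.append(part.q)
    return {"mean_ari": float(np.mean(aris)), "aris": aris,
            "n_clusters": ks, "q": qs}


def kin_mantel_power(n_reps: int = 10, seed: int = 0, alpha: float = 0.05) -> dict:
    """Fraction of default-condition runs where the GAI-vs-relatedness
    Mantel test detects the planted kin homophily."""
    sig = 0
    rs = []
    for rep in range(n_reps):
        cfg = SimulationConfig(seed=seed * 2003 + rep)
        truth = simulate_pedigree(cfg)
        surveys = simulate_surveys(truth, cfg)
        _, ids, *_rest, gai_res = analyse_survey_data(truth, surveys,
                                                      screen_seed=seed + rep)
        rel = ml_relatedness(truth.genotypes.subset(ids), mode="dyadic").matrix
        g2, r2 = gai_res.gai.align_with(rel)
        r, p = aff.mantel(g2, r2, n_perm=499, seed=seed * 19 + rep)
        rs.append(r)
        sig += p <= alpha
    return {"power": sig / n_reps, "mantel_r": rs}


def parent_offspring_recovery(n_dyads: int = 200, n_loci: int = 8,
                              n_alleles: int = 8, seed: int = 0,
                              mode: str = "dyadic") -> dict:
    """Mean ML relatedness across simulated parent-offspring dyads."""
    from .genepop import GenotypeTable

    rng = np.random.default_rng(seed)
    freqs = [rng.dirichlet(np.ones(n_alleles)) for _ in range(n_loci)]
    ids, rows, pairs = [], [], []
    for f in range(n_dyads):
        mom = np.stack([rng.choice(n_alleles, size=2, p=freqs[l]) + 1
                        for l in range(n_loci)])
        dad = np.stack([rng.choice(n_alleles, size=2, p=freqs[l]) + 1
                        for l in range(n_loci)])
        kid = np.stack([[mom[l, rng.integers(2)], dad[l, rng.integers(2)]]
                        for l in range(n_loci)])
        ids += [f"m{f}", f"k{f}"]
        rows += [mom, kid]
        pairs.append((f"m{f}", f"k{f}"))
    gt = GenotypeTable(ids=ids, loci=[f"L{l}" for l in range(n_loci)],
                       alleles=np.stack(rows))
    res = ml_relatedness(gt, mode=mode, pairs=pairs, seed=seed)
    vals = np.array([res.matrix[p] for p in pairs])
    return {"mean_r": float(vals.mean()), "sd_r": float(vals.std(ddof=1)),
            "n_dyads": n_dyads}
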