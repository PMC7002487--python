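"""Genetic relatedness matrices and kinship hypothesis tests.

Two relatedness proxies are built per dyad: a binary mtDNA
haplotype-sharing indicator (matrilineal kinship) and a maximum-likelihood
pairwise relatedness from codominant microsatellites (biparental kinship).

The ML estimator maximizes, over the IBD-sharing coefficients
(k0, k1, k2) on the 2-simplex, the multilocus likelihood

    L(k) = prod_loci [ k0 P0 + k1 P1 + k2 P2 ]

where Pm is the probability of the observed genotype pair given m alleles
identical by descent (no inbreeding), and reports r = k1/2 + k2.  The
log-likelihood is concave in k (a sum of logs of linear functions), so a
coarse simplex grid followed by a fine local grid finds the optimum
deterministically.  A triadic mode re-estimates each dyad with third
individuals as references and averages (see ``ml_relatedness``).

Hypothesis tests mirror the permutation procedures standard in this
literature: class-mean permutation tests across affiliation classes,
Monte-Carlo chi-square for haplotype-sharing contingency tables, and a
node-permutation within/between-cluster comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .affiliation import AffiliationClasses, mantel
from .clustering import Partition
from .dyadmatrix import DyadMatrix
from .genepop import GenotypeTable

__all__ = [
    "haplotype_matrix",
    "allele_frequencies",
    "RelatednessMatrix",
    "ml_relatedness",
    "pair_ibd_likelihoods",
    "class_comparison",
    "haplotype_class_chisq",
    "within_between_test",
    "overlap_relatedness_control",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def haplotype_matrix(haplotypes: dict | pd.Series) -> DyadMatrix:
    """Binary matrilineal-kinship proxy: 1 if same mtDNA haplotype, else 0.

    Individuals with a missing label are excluded from the matrix (and
    hence from every downstream test) with a warning.
    """
    if isinstance(haplotypes, pd.Series):
        haplotypes = haplotypes.to_dict()
    labeled = {
        str(k): str(v)
        for k, v in haplotypes.items()
        if v is not None and not (isinstance(v, float) and np.isnan(v))
    }
    dropped = len(haplotypes) - len(labeled)
    if dropped:
        logger.warning("haplotype_matrix: %d individuals without a haplotype excluded", dropped)
    ids = list(labeled)
    arr = np.array([labeled[i] for i in ids])
    return DyadMatrix(ids, (arr[:, None] == arr[None, :]).astype(float))


# ---------------------------------------------------------------------------
# allele frequencies and the ML estimator
# ---------------------------------------------------------------------------

def allele_frequencies(genotypes: GenotypeTable) -> dict[str, pd.Series]:
    """Sample allele frequencies per locus by gene counting (missing skipped)."""
    out: dict[str, pd.Series] = {}
    for l, locus in enumerate(genotypes.loci):
        alleles = genotypes.alleles[:, l, :].ravel()
        alleles = alleles[alleles > 0]
        if len(alleles) == 0:
            raise ValueError(f"locus {locus!r} has no non-missing genotypes")
        vals, counts = np.unique(alleles, return_counts=True)
        freqs = pd.Series(counts / counts.sum(), index=vals)
        if len(vals) == 1:
            logger.warning("locus %r is monomorphic (uninformative)", locus)
        out[locus] = freqs
    return out


def pair_ibd_likelihoods(g1: np.ndarray, g2: np.ndarray, freqs: pd.Series) -> tuple[float, float, float]:
    """(P0, P1, P2): probability of an unordered genotype pair given 0, 1
    or 2 alleles shared identical by descent, no inbreeding."""
    p = freqs
    a, b = sorted(g1)
    c, d = sorted(g2)

    def pg(x, y):
        return p[x] ** 2 if x == y else 2 * p[x] * p[y]

    p0 = pg(a, b) * pg(c, d)
    p2 = pg(a, b) if (a, b) == (c, d) else 0.0
    # one IBD allele shared
    if a == b and c == d:
        p1 = p[a] ** 3 if a == c else 0.0
    elif a == b:  # (aa, cd) c != d
        p1 = p[a] ** 2 * (p[d] if c == a else (p[c] if d == a else 0.0))
    elif c == d:  # (ab, cc)
        p1 = p[c] ** 2 * (p[b] if a == c else (p[a] if b == c else 0.0))
    else:  # both heterozygous
        if (a, b) == (c, d):
            p1 = p[a] * p[b] * (p[a] + p[b])
        else:
            shared = set((a, b)) & set((c, d))
            if len(shared) == 1:
                s = shared.pop()
                o1 = b if a == s else a
                o2 = d if c == s else c
                p1 = p[s] * p[o1] * p[o2]
            else:
                p1 = 0.0
    return float(p0), float(p1), float(p2)


def _simplex_grid(step: float) -> np.ndarray:
    """All (k0, k1, k2) on the 2-simplex at the given resolution."""
    ks = []
    m = int(round(1.0 / step))
    for i1 in range(m + 1):
        for i2 in range(m + 1 - i1):
            k1, k2 = i1 * step, i2 * step
            ks.append((1.0 - k1 - k2, k1, k2))
    return np.asarray(ks)


def _local_grid(k1: float, k2: float, width: float, step: float) -> np.ndarray:
    a = np.arange(max(0.0, k1 - width), min(1.0, k1 + width) + step / 2, step)
    b = np.arange(max(0.0, k2 - width), min(1.0, k2 + width) + step / 2, step)
    g1, g2 = np.meshgrid(a, b, indexing="ij")
    keep = g1 + g2 <= 1.0 + 1e-12
    k1v, k2v = g1[keep], g2[keep]
    return np.column_stack([1.0 - k1v - k2v, k1v, k2v])


def _maximize_k(P: np.ndarray, coarse: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximize sum_l log(P_l . k) over the simplex; P is (L, 3)."""
    with np.errstate(divide="ignore"):
        ll = np.log(np.clip(coarse @ P.T, 1e-300, None)).sum(axis=1)
    best = int(np.argmax(ll))
    k = coarse[best]
    fine = _local_grid(k[1], k[2], width=0.02, step=0.001)
    llf = np.log(np.clip(fine @ P.T, 1e-300, None)).sum(axis=1)
    bf = int(np.argmax(llf))
    return fine[bf], float(llf[bf])


@dataclass
class RelatednessMatrix:
    """Pairwise relatedness r-hat in [0, 1] plus usable-locus counts."""

    matrix: DyadMatrix
    usable_loci: np.ndarray  # (n, n) int
    mode: str
    ibd: np.ndarray | None = None  # (n, n, 3) k-hat, dyadic mode only

    @property
    def ids(self) -> list[str]:
        return self.matrix.ids


def _error_blend(P: np.ndarray, error_rate: float) -> np.ndarray:
    """Mix each IBD-state likelihood with the no-IBD one to absorb a small
    genotyping error rate (a mistyped allele breaks apparent sharing)."""
    if error_rate == 0:
        return P
    out = P.copy()
    e = min(error_rate, 0.1)
    out[:, 1] = (1 - e) * P[:, 1] + e * P[:, 0]
    out[:, 2] = (1 - e) ** 2 * P[:, 2] + (1 - (1 - e) ** 2) * P[:, 0]
    return out


def ml_relatedness(
    genotypes: GenotypeTable,
    freqs: dict[str, pd.Series] | None = None,
    mode: str = "dyadic",
    error_rate: float = 0.0,
    max_references: int = 10,
    min_loci: int = 2,
    seed: int | None = None,
    pairs: list[tuple] | None = None,
) -> RelatednessMatrix:
    """Maximum-likelihood pairwise relatedness from microsatellites.

    ``mode="dyadic"`` maximizes the two-individual likelihood over
    (k0, k1, k2).  ``mode="triadic"`` repeats the estimate with up to
    ``max_references`` third individuals: each reference's alleles are
    added as pseudo-counts to the allele-frequency estimate (sharpening
    the distinction between identity by descent and identity by state for
    alleles the reference also carries), references are weighted by their
    non-missing locus count over the dyad's usable loci, and the weighted
    mean is reported.  With error_rate 0 and uninformative references the
    triadic mean approaches the dyadic estimate.

    Dyads with fewer than ``min_loci`` jointly typed loci get NaN.  If
    ``pairs`` is given, only those dyads are estimated (the rest of the
    matrix stays zero with usable-locus count 0).
    """
    if not 0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    if mode not in ("dyadic", "triadic"):
        raise ValueError(f"unknown mode: {mode!r}")
    if freqs is None:
        freqs = allele_frequencies(genotypes)
    n = genotypes.n
    L = len(genotypes.loci)
    miss = genotypes.missing_mask()
    coarse = _simplex_grid(0.02)
    rng = np.random.default_rng(seed)

    # per-locus gene counts for triadic pseudo-count updates
    counts = {
        locus: (freqs[locus] * (~miss[:, l]).sum() * 2).astype(float)
        for l, locus in enumerate(genotypes.loci)
    }

    def dyad_estimate(i: int, j: int, fr: dict[str, pd.Series]):
        rows = []
        for l, locus in enumerate(genotypes.loci):
            if miss[i, l] or miss[j, l]:
                continue
            rows.append(pair_ibd_likelihoods(genotypes.alleles[i, l], genotypes.alleles[j, l], fr[locus]))
        if len(rows) < min_loci:
            return None, len(rows)
        P = _error_blend(np.asarray(rows), error_rate)
        k, _ = _maximize_k(P, coarse)
        return k, len(rows)

    r = np.zeros((n, n))
    usable = np.zeros((n, n), dtype=int)
    ibd = np.zeros((n, n, 3))
    if pairs is None:
        dyads = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        pos = {iid: k for k, iid in enumerate(genotypes.ids)}
        dyads = [(pos[str(a)], pos[str(b)]) for a, b in pairs]
    for i, j in dyads:
        if mode == "dyadic":
            k, nl = dyad_estimate(i, j, freqs)
            if k is None:
                val = np.nan
            else:
                val = k[1] / 2 + k[2]
                ibd[i, j] = ibd[j, i] = k
        else:
            others = [o for o in range(n) if o not in (i, j)]
            if len(others) > max_references:
                others = list(rng.choice(others, size=max_references, replace=False))
            ests, weights, nl = [], [], 0
            for ref in others:
                fr = {}
                for l, locus in enumerate(genotypes.loci):
                    c = counts[locus].copy()
                    if not miss[ref, l]:
                        for a in genotypes.alleles[ref, l]:
                            c[a] = c.get(a, 0.0) + 1.0
                    fr[locus] = c / c.sum()
                k, nl = dyad_estimate(i, j, fr)
                if k is None:
                    ests = []
                    break
                ests.append(k[1] / 2 + k[2])
                weights.append((~miss[ref]).sum() / max(1, L))
            val = float(np.average(ests, weights=weights)) if ests else np.nan
        r[i, j] = r[j, i] = np.nan if np.isnan(val) else float(np.clip(val, 0.0, 1.0))
        usable[i, j] = usable[j, i] = nl
    mat = DyadMatrix(genotypes.ids, np.nan_to_num(r))
    return RelatednessMatrix(matrix=mat, usable_loci=usable, mode=mode,
                             ibd=ibd if mode == "dyadic" else None)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def class_comparison(
    values: DyadMatrix,
    classes: AffiliationClasses,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean dyadic value per affiliation class vs. a label-permutation null.

    The class labels are permuted across dyads (the PERM-style test); the
    two-sided p compares each class mean to its permutation distribution.
    Dyads are not independent, so p-values are descriptive.
    """
    tab = classes.labels_for(values)
    tab = tab[np.isfinite(tab["value"])]
    labels = tab["label"].to_numpy()
    vals = tab["value"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    present = [c for c in ("preferred", "casual", "avoided") if (labels == c).sum() > 0]
    masks = {c: labels == c for c in present}
    perms = np.empty((n_perm, len(present)))
    for t in range(n_perm):
        shuffled = rng.permutation(vals)
        for ci, c in enumerate(present):
            perms[t, ci] = shuffled[masks[c]].mean()
    for ci, c in enumerate(present):
        obs = float(vals[masks[c]].mean())
        null = perms[:, ci]
        hi = (null >= obs - 1e-12).sum()
        lo = (null <= obs + 1e-12).sum()
        p = min(1.0, 2.0 * (1 + min(hi, lo)) / (1 + n_perm))
        out.append({"class": c, "n_dyads": int(masks[c].sum()), "mean": obs,
                    "null_mean": float(null.mean()), "p": p})
    return pd.DataFrame(out).set_index("class")


def haplotype_class_chisq(
    table: np.ndarray | pd.DataFrame,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Randomization chi-square on a classes x {shared, not shared} table.

    The Pearson chi-square of the observed table is compared with tables
    built by randomly permuting the sharing indicators across pairs while
    holding the class sizes fixed; p = (1 + #{chi2_perm >= chi2_obs}) /
    (1 + n_mc).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[1] != 2:
        raise ValueError("table must be classes x {shared, not shared}")
    if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be non-negative integers")
    if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
        raise ValueError("zero row or column margin in contingency table")
    chi2_obs = scipy.stats.chi2_contingency(tab, correction=False).statistic
    rng = np.random.default_rng(seed)
    class_sizes = tab.sum(axis=1).astype(int)
    n_shared = int(tab[:, 0].sum())
    total = int(class_sizes.sum())
    flags = np.zeros(total, dtype=np.int8)
    flags[:n_shared] = 1
    edges = np.concatenate([[0], np.cumsum(class_sizes)])
    count = 0
    for _ in range(n_mc):
        rng.shuffle(flags)
        shared = np.add.reduceat(flags, edges[:-1])
        perm_tab = np.column_stack([shared, class_sizes - shared])
        with np.errstate(invalid="ignore"):
            chi2_p = scipy.stats.chi2_contingency(perm_tab, correction=False).statistic
        if chi2_p >= chi2_obs - 1e-12:
            count += 1
    return float(chi2_obs), (1 + count) / (1 + n_mc)


def within_between_test(
    values: DyadMatrix,
    partition: Partition,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Mean within-cluster minus between-cluster dyadic value, with a
    node-permutation null (cluster labels shuffled across individuals,
    sizes preserved); one-sided p for the within > between direction."""
    ids = [i for i in partition.ids if i in set(values.ids)]
    if len(ids) < 3:
        raise ValueError("too few individuals with data")
    lab = np.array([partition.labels[partition.ids.index(i)] for i in ids])
    if len(set(lab)) < 2:
        raise ValueError("within/between test needs at least two clusters")
    vals = values.reindex(ids).values
    iu, ju = np.triu_indices(len(ids), k=1)
    v = vals[iu, ju]

    def stat(l):
        same = l[iu] == l[ju]
        return v[same].mean() - v[~same].mean()

    obs = float(stat(lab))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat(rng.permutation(lab)) >= obs - 1e-12:
            count += 1
    same = lab[iu] == lab[ju]
    return float(v[same].mean()), float(v[~same].mean()), (1 + count) / (1 + n_perm)


def overlap_relatedness_control(
    udoi: DyadMatrix,
    relatedness: DyadMatrix,
    haplo: DyadMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Confound check: Mantel tests of home-range overlap against
    biparental relatedness and against mtDNA haplotype sharing."""
    out = {}
    out["udoi_vs_relatedness"] = mantel(udoi, relatedness, n_perm=n_perm, seed=seed)
    out["udoi_vs_haplotype"] = mantel(udoi, haplo, n_perm=n_perm,
                                      seed=None if seed is None else seed + 1)
    return out
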