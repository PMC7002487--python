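"""Haplotype sharing, ML relatedness and kinship permutation tests."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from finsoc.affiliation import classify
from finsoc.clustering import Partition
from finsoc.dyadmatrix import DyadMatrix
from finsoc.genepop import GenotypeTable
from finsoc.kinship import (
    allele_frequencies,
    class_comparison,
    haplotype_class_chisq,
    haplotype_matrix,
    ml_relatedness,
    pair_ibd_likelihoods,
    within_between_test,
)


class TestHaplotypeMatrix:
    def test_sharing_rule(self):
        m = haplotype_matrix({"a": "A", "b": "A", "c": "B"})
        assert m["a", "b"] == 1.0 and m["a", "c"] == 0.0

    def test_two_haplotype_population_sharing_fraction(self):
        """23:21 split: random-pair sharing = (C(23,2)+C(21,2))/C(44,2)."""
        haps = {f"i{k}": ("A" if k < 23 else "B") for k in range(44)}
        m = haplotype_matrix(haps)
        frac = m.dyad_values().mean()
        expected = (comb(23, 2) + comb(21, 2)) / comb(44, 2)
        assert frac == pytest.approx(expected)
        assert expected == pytest.approx(463 / 946)

    def test_missing_labels_excluded(self):
        m = haplotype_matrix({"a": "A", "b": None, "c": "A"})
        assert set(m.ids) == {"a", "c"}

    def test_monomorphic_all_ones(self):
        m = haplotype_matrix({k: "A" for k in "abcd"})
        assert (m.dyad_values() == 1.0).all()


class TestAlleleFrequencies:
    def test_gene_counting(self):
        alleles = np.array([[[1, 1]], [[1, 2]], [[2, 2]]])
        gt = GenotypeTable(ids=["a", "b", "c"], loci=["L1"], alleles=alleles)
        f = allele_frequencies(gt)["L1"]
        assert f[1] == pytest.approx(0.5) and f[2] == pytest.approx(0.5)

    def test_missing_excluded_and_recount(self, rng):
        n, L, A = 10, 3, 4
        alleles = rng.integers(1, A + 1, size=(n, L, 2))
        alleles[0, 1] = 0  # one missing genotype
        gt = GenotypeTable(ids=[f"i{k}" for k in range(n)],
                           loci=[f"L{l}" for l in range(L)], alleles=alleles)
        freqs = allele_frequencies(gt)
        for l, locus in enumerate(gt.loci):
            pool = alleles[:, l, :].ravel()
            pool = pool[pool > 0]
            for a in np.unique(pool):
                assert freqs[locus][a] == pytest.approx((pool == a).mean())
            assert freqs[locus].sum() == pytest.approx(1.0)


class TestIBDLikelihoods:
    def test_k0_limit_is_hardy_weinberg_product(self):
        """With k=(1,0,0) the pair likelihood is the product of HW
        genotype probabilities — checked across genotype configurations."""
        p = pd.Series({1: 0.5, 2: 0.3, 3: 0.2})

        def hw(g):
            a, b = g
            return p[a] ** 2 if a == b else 2 * p[a] * p[b]

        for g1 in [(1, 1), (1, 2), (2, 3)]:
            for g2 in [(1, 1), (1, 3), (2, 2), (2, 3)]:
                p0, _, _ = pair_ibd_likelihoods(np.array(g1), np.array(g2), p)
                assert p0 == pytest.approx(hw(g1) * hw(g2))

    def test_states_marginalize_to_first_genotype(self):
        # for each IBD state, summing the pair probability over every
        # possible second genotype must recover P(G1) under Hardy-Weinberg
        p = pd.Series({1: 0.6, 2: 0.4})
        genos = [(1, 1), (1, 2), (2, 2)]

        def hw(g):
            a, b = g
            return p[a] ** 2 if a == b else 2 * p[a] * p[b]

        for g1 in genos:
            for state in range(3):
                total = sum(pair_ibd_likelihoods(np.array(g1), np.array(g2), p)[state]
                            for g2 in genos)
                assert total == pytest.approx(hw(g1))


def simulate_families(rng, n_fam, L=8, A=8, drop=0.0):
    freqs = [rng.dirichlet(np.ones(A)) for _ in range(L)]
    ids, rows = [], []
    for f in range(n_fam):
        mom = np.stack([rng.choice(A, size=2, p=freqs[l]) + 1 for l in range(L)])
        dad = np.stack([rng.choice(A, size=2, p=freqs[l]) + 1 for l in range(L)])
        kid = np.stack([[mom[l, rng.integers(2)], dad[l, rng.integers(2)]]
                        for l in range(L)])
        ids += [f"m{f}", f"k{f}"]
        rows += [mom, kid]
    alleles = np.stack(rows)
    if drop:
        mask = rng.random((len(ids), L)) < drop
        alleles[mask] = 0
    return GenotypeTable(ids=ids, loci=[f"L{l}" for l in range(L)], alleles=alleles)


class TestMLRelatedness:
    def test_parent_offspring_recovery(self, rng):
        gt = simulate_families(rng, 60)
        pairs = [(f"m{f}", f"k{f}") for f in range(60)]
        res = ml_relatedness(gt, pairs=pairs)
        vals = np.array([res.matrix[p] for p in pairs])
        assert abs(vals.mean() - 0.5) < 0.05
        assert (vals >= 0).all() and (vals <= 1).all()

    def test_unrelated_median_near_zero(self, rng):
        gt = simulate_families(rng, 60)
        pairs = [(f"m{f}", f"m{f + 1}") for f in range(59)]
        res = ml_relatedness(gt, pairs=pairs)
        vals = np.array([res.matrix[p] for p in pairs])
        assert vals.mean() > 0  # boundary bias is upward
        assert np.median(vals) < 0.05

    def test_allele_relabeling_invariance(self, rng):
        gt = simulate_families(rng, 6, L=5, A=4)
        pairs = [(f"m{f}", f"k{f}") for f in range(6)]
        r1 = ml_relatedness(gt, pairs=pairs)
        relab = gt.alleles.copy()
        relab[relab > 0] = 5 - relab[relab > 0]  # bijection 1..4 -> 4..1
        gt2 = GenotypeTable(ids=gt.ids, loci=gt.loci, alleles=relab)
        r2 = ml_relatedness(gt2, pairs=pairs)
        for p in pairs:
            assert r1.matrix[p] == pytest.approx(r2.matrix[p], abs=1e-12)

    def test_optimum_beats_simplex_vertices(self, rng):
        """The fitted k must be at least as likely as the PO/FS/UR corners."""
        gt = simulate_families(rng, 8, L=6, A=5)
        freqs = allele_frequencies(gt)
        res = ml_relatedness(gt, pairs=[(f"m{f}", f"k{f}") for f in range(8)])
        miss = gt.missing_mask()
        for f in range(8):
            i, j = gt.ids.index(f"m{f}"), gt.ids.index(f"k{f}")
            P = np.array([
                pair_ibd_likelihoods(gt.alleles[i, l], gt.alleles[j, l], freqs[gt.loci[l]])
                for l in range(6) if not (miss[i, l] or miss[j, l])
            ])
            khat = res.ibd[i, j]
            ll_hat = np.log(np.clip(P @ khat, 1e-300, None)).sum()
            for vertex in np.eye(3):
                ll_v = np.log(np.clip(P @ vertex, 1e-300, None)).sum()
                assert ll_hat >= ll_v - 1e-9

    def test_grid_refinement_matches_exhaustive(self, rng):
        """Coarse+local search equals an exhaustive 0.001-step grid."""
        from finsoc.kinship import _maximize_k, _simplex_grid
        gt = simulate_families(rng, 3, L=6, A=5)
        freqs = allele_frequencies(gt)
        exhaustive = _simplex_grid(0.001)
        for f in range(3):
            i, j = gt.ids.index(f"m{f}"), gt.ids.index(f"k{f}")
            P = np.array([
                pair_ibd_likelihoods(gt.alleles[i, l], gt.alleles[j, l], freqs[gt.loci[l]])
                for l in range(6)
            ])
            k_fast, ll_fast = _maximize_k(P, _simplex_grid(0.02))
            ll_ex = np.log(np.clip(exhaustive @ P.T, 1e-300, None)).sum(axis=1)
            assert ll_fast == pytest.approx(ll_ex.max(), abs=1e-9)

    def test_sparse_dyad_missing(self, rng):
        gt = simulate_families(rng, 2, L=3, A=4)
        a = gt.alleles.copy()
        a[0, :2] = 0  # m0 typed at one locus only
        a[1, 1:] = 0  # k0 typed at another
        gt2 = GenotypeTable(ids=gt.ids, loci=gt.loci, alleles=a)
        res = ml_relatedness(gt2, pairs=[("m0", "k0")])
        assert res.usable_loci[0, 1] < 2
        assert np.isnan(res.matrix.values[0, 1]) or res.matrix.values[0, 1] == 0.0

    def test_bad_error_rate(self, rng):
        gt = simulate_families(rng, 2)
        with pytest.raises(ValueError):
            ml_relatedness(gt, error_rate=0.5)


class TestClassComparison:
    def test_all_values_equal_gives_p_one(self, rng):
        n = 12
        gai = DyadMatrix.from_dyad_values([f"i{k}" for k in range(n)],
                                          rng.normal(size=66) * 3)
        cls = classify(gai)
        flat = DyadMatrix(gai.ids, np.ones((n, n)) * 0.1)
        out = class_comparison(flat, cls, n_perm=99, seed=0)
        assert (out["p"] == 1.0).all()

    def test_elevated_class_detected(self, rng):
        n = 16
        vals = rng.normal(size=120) * 0.1
        gai_vals = np.where(np.arange(120) < 20, 5.0, 0.0)  # 20 preferred dyads
        vals[:20] += 1.0  # those dyads carry higher relatedness
        ids = [f"i{k}" for k in range(n)]
        cls = classify(DyadMatrix.from_dyad_values(ids, gai_vals))
        out = class_comparison(DyadMatrix.from_dyad_values(ids, vals), cls,
                               n_perm=999, seed=1)
        assert out.loc["preferred", "p"] < 0.01
        assert out.loc["preferred", "mean"] > out.loc["casual", "mean"]


class TestChiSquare:
    def test_equal_proportions_p_near_one(self):
        _, p = haplotype_class_chisq(np.array([[50, 50], [50, 50]]), n_mc=999, seed=0)
        assert p > 0.5

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            haplotype_class_chisq(np.array([[0, 0], [5, 5]]))

    def test_monte_carlo_matches_asymptotic_on_large_table(self):
        import scipy.stats
        tab = np.array([[44, 35], [405, 440], [14, 8]])
        chi2, p_mc = haplotype_class_chisq(tab, n_mc=10_000, seed=7)
        p_asy = scipy.stats.chi2_contingency(tab, correction=False).pvalue
        assert abs(p_mc - p_asy) < 0.02


class TestWithinBetween:
    def test_single_cluster_rejected(self, rng):
        vals = DyadMatrix.from_dyad_values(list("abcd"), rng.normal(size=6))
        part = Partition(ids=list("abcd"), labels=np.zeros(4, dtype=int), q=0.0)
        with pytest.raises(ValueError, match="two clusters"):
            within_between_test(vals, part, n_perm=9)

    def test_planted_within_effect_detected(self, rng):
        n = 20
        labels = np.repeat([0, 1], 10)
        ids = [f"i{k}" for k in range(n)]
        m = np.zeros((n, n))
        iu, ju = np.triu_indices(n, 1)
        same = labels[iu] == labels[ju]
        vals = rng.normal(size=len(iu)) * 0.3 + same * 1.0
        m[iu, ju] = vals
        m[ju, iu] = vals
        w, b, p = within_between_test(DyadMatrix(ids, m),
                                      Partition(ids=ids, labels=labels, q=0.0),
                                      n_perm=499, seed=0)
        assert w > b and p < 0.01
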