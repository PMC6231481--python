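"""Allele frequencies, diversity, Weir-Cockerham FST, IBD and Mantel."""
import itertools

import numpy as np
import pandas as pd
import pytest

from landgen.genio import MISSING
from landgen.popgen import (
    diversity_fis,
    geo_distance_matrix,
    haversine_km,
    ibd_mantel,
    mantel_test,
    pop_allele_freqs,
    wc_fst,
)
from landgen.simulate import LandscapeConfig, simulate_genotypes, simulate_landscape

from conftest import toy_matrix


class TestAlleleFreqs:
    def test_simple_counting(self):
        # pop A: {0,0,2}; pop B: {2,2,2} -> pooled alt freq 8/12, minor = ref
        m = toy_matrix([[0], [0], [2], [2], [2], [2]], pops=["A"] * 3 + ["B"] * 3)
        f = pop_allele_freqs(m)
        assert not f.minor_is_alt[0]
        assert f.freq[0, 0] == pytest.approx(4 / 6)   # ref freq in pop A
        assert f.freq[1, 0] == pytest.approx(0.0)

    def test_minor_allele_when_alt_is_rare(self):
        m = toy_matrix([[0], [0], [2]], pops=["A"] * 3)
        f = pop_allele_freqs(m)
        assert f.minor_is_alt[0]
        assert f.freq[0, 0] == pytest.approx(2 / 6)

    def test_monomorphic_locus_zero_everywhere(self):
        m = toy_matrix([[0], [0], [0], [0]], pops=["A", "A", "B", "B"])
        f = pop_allele_freqs(m)
        np.testing.assert_array_equal(f.freq[:, 0], 0.0)

    def test_zero_call_cell_is_absent(self):
        m = toy_matrix([[MISSING], [MISSING], [1], [1]], pops=["A", "A", "B", "B"])
        f = pop_allele_freqs(m)
        assert np.isnan(f.freq[0, 0]) and f.n_alleles[0, 0] == 0

    def test_matches_brute_force_on_fixture(self, fixture_system):
        _, _, _, m = fixture_system
        f = pop_allele_freqs(m)
        rng = np.random.default_rng(0)
        pops = np.array(m.population_ids)
        for l in rng.choice(m.n_loci, 25, replace=False):
            col = m.genotypes[:, l]
            called = col != MISSING
            alt = col[called].sum()
            tot = 2 * called.sum()
            minor_alt = alt / tot <= 0.5
            for j, pop in enumerate(f.populations):
                sel = (pops == pop) & called
                if sel.sum() == 0:
                    assert np.isnan(f.freq[j, l])
                    continue
                fa = col[sel].sum() / (2 * sel.sum())
                expect = fa if minor_alt else 1 - fa
                assert f.freq[j, l] == pytest.approx(expect)


class TestDiversity:
    def test_all_heterozygotes_negative_fis(self):
        m = toy_matrix([[1], [1], [1], [1]], pops=["A"] * 4)
        d = diversity_fis(m)
        assert d.loc["A", "HO"] == 1.0
        assert d.loc["A", "FIS"] < 0

    def test_he_limit_half_at_balanced_freq(self):
        rng = np.random.default_rng(0)
        G = rng.binomial(2, 0.5, size=(2000, 1)).astype(np.int16)
        d = diversity_fis(toy_matrix(G))
        assert d.loc["A", "HE"] == pytest.approx(0.5, abs=0.02)

    def test_hand_computed_two_pop_values(self):
        # pop A genotypes {0,1,1}: p=2/3 of ref... alt freq 2/6=1/3
        m = toy_matrix([[0], [1], [1], [2], [2], [1]], pops=["A"] * 3 + ["B"] * 3)
        d = diversity_fis(m)
        # pop A: p_alt=1/3 -> 1-p^2-q^2 = 4/9; unbiased: 6/5 * 4/9 = 8/15
        assert d.loc["A", "HE"] == pytest.approx(6 / 5 * 4 / 9)
        assert d.loc["A", "HO"] == pytest.approx(2 / 3)
        # pop B {2,2,1}: p_alt=5/6 -> 2pq=5/18; unbiased: 6/5*5/18 = 1/3
        assert d.loc["B", "HE"] == pytest.approx(1 / 3)
        assert d.loc["B", "FIS"] == pytest.approx(1 - (1 / 3) / (1 / 3))


def wc_two_pop_oracle(counts_a, counts_b):
    """Scalar Weir & Cockerham (1984) components for one diallelic locus,
    written directly from the published estimator."""
    def summarize(geno):
        geno = np.asarray(geno)
        n = len(geno)
        p = geno.sum() / (2 * n)
        het = np.mean(geno == 1)
        return n, p, het

    (n1, p1, h1), (n2, p2, h2) = summarize(counts_a), summarize(counts_b)
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWcFst:
    def test_two_pop_toy_matches_hand_formula(self):
        ga = [0, 1, 1, 2, 0]
        gb = [2, 2, 1, 2, 2]
        m = toy_matrix(np.array([ga + gb]).T, pops=["A"] * 5 + ["B"] * 5)
        res = wc_fst(m)
        a, b, c = wc_two_pop_oracle(ga, gb)
        assert res.a[0] == pytest.approx(a)
        assert res.b[0] == pytest.approx(b)
        assert res.c[0] == pytest.approx(c)
        assert res.multilocus_fst == pytest.approx(a / (a + b + c))

    def test_no_differentiation_limit(self):
        rng = np.random.default_rng(5)
        G = rng.binomial(2, 0.4, size=(60, 2000)).astype(np.int16)
        m = toy_matrix(G, pops=["A"] * 20 + ["B"] * 20 + ["C"] * 20)
        assert abs(wc_fst(m).multilocus_fst) < 0.01

    def test_fixed_difference_approaches_one(self):
        G = np.array([[0]] * 50 + [[2]] * 50, dtype=np.int16)
        m = toy_matrix(G, pops=["A"] * 50 + ["B"] * 50)
        res = wc_fst(m, pairwise=True)
        assert res.pairwise.loc["A", "B"] > 0.97

    def test_pairwise_matrix_matches_two_pop_runs(self, fixture_system):
        _, _, _, m = fixture_system
        sub = m.subset_loci(np.arange(80))
        res = wc_fst(sub, pairwise=True)
        pops = np.array(sub.population_ids)
        for pa, pb in [("P01", "P09"), ("P03", "P17")]:
            two = sub.subset_individuals(np.isin(pops, [pa, pb]))
            direct = wc_fst(two).multilocus_fst
            assert res.pairwise.loc[pa, pb] == pytest.approx(direct)

    def test_invariant_to_locus_order_and_pop_labels(self, fixture_system):
        _, _, _, m = fixture_system
        sub = m.subset_loci(np.arange(120))
        base = wc_fst(sub).multilocus_fst
        perm = np.random.default_rng(1).permutation(120)
        assert wc_fst(sub.subset_loci(perm)).multilocus_fst == pytest.approx(base)
        relabeled = toy_matrix(
            sub.genotypes,
            pops=[f"Z{p}" for p in sub.population_ids],
            positions=list(sub.loci["pos"]),
        )
        assert wc_fst(relabeled).multilocus_fst == pytest.approx(base)

    def test_parameter_recovery_at_study_fst(self):
        ests = []
        for seed in range(8):
            cfg = LandscapeConfig(n_neutral=800, n_highfst=0, n_clim=0, seed=seed)
            _, sites = simulate_landscape(cfg)
            ests.append(wc_fst(simulate_genotypes(sites, cfg)).multilocus_fst)
        assert np.mean(ests) == pytest.approx(0.056, abs=0.01)


class TestDistancesMantel:
    def test_haversine_one_degree_longitude_at_equator(self):
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.01)

    def test_distance_matrix_metric_properties(self, fixture_system):
        _, _, sites, _ = fixture_system
        D = geo_distance_matrix(sites)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)
        n = len(D)
        for i, j, k in itertools.combinations(range(n), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_duplicate_coordinates_raise(self):
        sites = pd.DataFrame({"pop": ["a", "b"], "lat": [1.0, 1.0], "lon": [2.0, 2.0]})
        with pytest.raises(ValueError, match="duplicate"):
            geo_distance_matrix(sites)

    def test_identical_matrices_give_r1_minimal_p(self):
        rng = np.random.default_rng(0)
        X = rng.random((8, 8))
        A = (X + X.T) / 2
        np.fill_diagonal(A, 0)
        z, r, p = mantel_test(A, A, n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_constant_matrix_flagged_degenerate(self):
        A = np.ones((5, 5)) - np.eye(5)
        B = np.zeros((5, 5))
        with pytest.raises(ValueError, match="degenerate"):
            mantel_test(A, B, n_perm=99, seed=0)

    def test_exhaustive_permutation_oracle_5x5(self):
        rng = np.random.default_rng(7)
        def sym(x):
            M = (x + x.T) / 2
            np.fill_diagonal(M, 0)
            return M
        A, B = sym(rng.random((5, 5))), sym(rng.random((5, 5)))
        iu = np.triu_indices(5, k=1)
        z_obs = float(A[iu] @ B[iu])
        count = sum(
            float(A[np.ix_(p, p)][iu] @ B[iu]) >= z_obs
            for p in itertools.permutations(range(5))
        )
        exact_p = count / 120
        z, r, p = mantel_test(A, B, n_perm=9999, seed=1)
        assert z == pytest.approx(z_obs)
        assert r == pytest.approx(np.corrcoef(A[iu], B[iu])[0, 1])
        # sampled p within binomial error of the exhaustive enumeration
        assert abs(p - exact_p) < 4 * np.sqrt(exact_p * (1 - exact_p) / 9999) + 1e-4

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, mantel

        rng = np.random.default_rng(3)
        def sym(x):
            M = (x + x.T) / 2
            np.fill_diagonal(M, 0)
            return np.abs(M)
        A, B = sym(rng.random((8, 8))), sym(rng.random((8, 8)))
        z, r, p = mantel_test(A, B, n_perm=9999, seed=2)
        r_sk, p_sk, _ = mantel(DistanceMatrix(A), DistanceMatrix(B),
                               method="pearson", permutations=9999,
                               alternative="greater")
        assert r == pytest.approx(r_sk)
        assert abs(p - p_sk) < 0.02

    def test_ibd_on_spatial_fixture(self, fixture_system):
        _, _, sites, m = fixture_system
        fst = wc_fst(m.subset_loci(np.arange(200)), pairwise=True)
        res = ibd_mantel(fst, sites, n_perm=499, seed=0)
        assert 0 < res.mantel_p <= 1
        iu = np.triu_indices(len(sites), k=1)
        lin = fst.pairwise.to_numpy() / (1 - fst.pairwise.to_numpy())
        D = geo_distance_matrix(sites.set_index("pop").loc[fst.populations].reset_index())
        assert res.mantel_z == pytest.approx(float(lin[iu] @ np.log(D[iu])))
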