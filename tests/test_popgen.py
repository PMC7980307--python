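"""Unit and property tests for the population-genetic statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skyisland.popgen import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    SequenceAlignment,
    collapse_haplotypes,
    diversity_landuse_regression,
    inbreeding_ml,
    jost_d,
    marker_qc,
    microsat_summaries,
    mtdna_divergence,
    mtdna_diversity,
    pairwise_differentiation,
    weir_cockerham_theta,
)

from conftest import genotypes_from_lists


# ---------------------------------------------------------------------------
# haplotypes and mtDNA diversity
# ---------------------------------------------------------------------------


class TestCollapseHaplotypes:
    def test_identical_sequences_collapse_to_one(self):
        aln = SequenceAlignment([f"i{k}" for k in range(5)], ["ACGT"] * 5)
        table = collapse_haplotypes(aln)
        assert table.n_haplotypes == 1
        assert table.counts.tolist() == [5]

    def test_two_identical_pairs(self, toy_alignment):
        table = collapse_haplotypes(toy_alignment)
        assert table.n_haplotypes == 2
        assert sorted(table.counts.tolist()) == [2, 2]
        assert sum(table.counts) == toy_alignment.n

    def test_partition_scope(self, toy_alignment):
        # the two haplotypes only differ in the right partition
        assert collapse_haplotypes(toy_alignment, scope="left").n_haplotypes == 1
        assert collapse_haplotypes(toy_alignment, scope="right").n_haplotypes == 2

    def test_n_is_mismatch_by_default_but_merges_when_asked(self):
        aln = SequenceAlignment(["a", "b"], ["ACGT", "ACGN"])
        assert collapse_haplotypes(aln).n_haplotypes == 2
        merged = collapse_haplotypes(aln, ambiguous_merge=True)
        assert merged.n_haplotypes == 1
        assert merged.sequences == ["ACGT"]  # resolved state retained

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            SequenceAlignment(["a", "b"], ["ACGT", "ACG"])


class TestMtdnaDiversity:
    @pytest.mark.parametrize(
        "n, hap, expected_hd",
        [(7, 6, 0.952), (9, 8, 0.972), (12, 11, 0.985)],
    )
    def test_forced_configurations_match_reported_diversity(self, n, hap, expected_hd):
        """One duplicated haplotype plus singletons: Hd to three decimals."""
        seqs = []
        L = 20
        for h in range(hap):
            s = list("A" * L)
            s[h] = "C"
            seqs.append("".join(s))
        seqs.append(seqs[0])  # duplicate the first haplotype
        assert len(seqs) == n
        aln = SequenceAlignment([f"i{k}" for k in range(n)], seqs)
        nh, hd, _ = mtdna_diversity(aln)
        assert nh == hap
        assert round(hd, 3) == expected_hd

    def test_monomorphic_gives_zero_diversity(self):
        aln = SequenceAlignment(["a", "b", "c"], ["ACGT"] * 3)
        nh, hd, pi = mtdna_diversity(aln)
        assert (nh, hd, pi) == (1, 0.0, 0.0)

    def test_pi_matches_bruteforce_pair_count(self):
        # s1 == s2; s3 differs from both at 2 of 10 sites
        aln = SequenceAlignment(
            ["s1", "s2", "s3"],
            ["AAAAAAAAAA", "AAAAAAAAAA", "TTAAAAAAAA"],
        )
        _, _, pi = mtdna_diversity(aln)
        assert pi == pytest.approx((0 + 2 + 2) / (3 * 10), abs=1e-12)

    def test_pairwise_deletion_of_ambiguous_sites(self):
        aln = SequenceAlignment(["a", "b"], ["ANGT", "ACGT"])
        _, _, pi = mtdna_diversity(aln)
        assert pi == 0.0  # the N site is excluded pairwise

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            mtdna_diversity(SequenceAlignment(["a"], ["ACGT"]))


class TestMtdnaDivergence:
    def test_fixed_difference_populations(self):
        aln = SequenceAlignment(
            ["a1", "a2", "b1", "b2"],
            ["AAAAAAAAAA", "AAAAAAAAAA", "TTTAAAAAAA", "TTTAAAAAAA"],
        )
        popmap = PopulationMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        dxy, fst = mtdna_divergence(aln, popmap)
        assert dxy.pair("A", "B") == pytest.approx(3 / 10)
        assert fst.pair("A", "B") == pytest.approx(1.0)

    def test_identical_haplotype_pools_give_near_zero_fst(self):
        # identical monomorphic pools: exactly zero
        aln = SequenceAlignment(
            ["a1", "a2", "b1", "b2"], ["ACGTACGTAC"] * 4
        )
        popmap = PopulationMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        _, fst = mtdna_divergence(aln, popmap)
        assert fst.pair("A", "B") == 0.0
        # identical polymorphic pools: the estimator's small-sample bias is
        # -1/(n-1), so with n=20 per pool the value sits near zero
        seqs = (["ACGTACGTAC"] * 10 + ["AAGTACGTAC"] * 10) * 2
        ids = [f"a{k}" for k in range(20)] + [f"b{k}" for k in range(20)]
        aln = SequenceAlignment(ids, seqs)
        popmap = PopulationMap({i: i[0].upper() for i in ids})
        _, fst = mtdna_divergence(aln, popmap)
        assert abs(fst.pair("A", "B")) < 0.06

    def test_matches_exhaustive_enumeration(self):
        seqs = {"a1": "AACCGGTTAA", "a2": "AACCGGTTAT",
                "b1": "TACCGGTAAA", "b2": "TACCGGCTAA"}
        aln = SequenceAlignment(list(seqs), list(seqs.values()))
        popmap = PopulationMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        dxy, fst = mtdna_divergence(aln, popmap)

        def diff(x, y):
            return sum(c1 != c2 for c1, c2 in zip(seqs[x], seqs[y])) / 10

        pi_a = diff("a1", "a2")
        pi_b = diff("b1", "b2")
        between = np.mean([diff(a, b) for a in ("a1", "a2") for b in ("b1", "b2")])
        assert dxy.pair("A", "B") == pytest.approx(between, abs=1e-12)
        assert fst.pair("A", "B") == pytest.approx(
            1 - 0.5 * (pi_a + pi_b) / between, abs=1e-12
        )


# ---------------------------------------------------------------------------
# microsatellite summaries
# ---------------------------------------------------------------------------


class TestMicrosatSummaries:
    def test_monomorphic_locus(self):
        gt = genotypes_from_lists([[(100, 100)], [(100, 100)], [(100, 100)]])
        popmap = PopulationMap({"ind0": "A", "ind1": "A", "ind2": "A"})
        tab = microsat_summaries(gt, popmap, rarefaction_g=2)
        row = tab.loc["A"]
        assert row.Na == 1 and row.Ar == 1 and row.He == 0 and row.Ho == 0

    def test_rarefaction_identity_at_full_sample(self):
        gt = genotypes_from_lists([[(100, 102)], [(104, 100)]])
        popmap = PopulationMap({"ind0": "A", "ind1": "A"})
        tab = microsat_summaries(gt, popmap, rarefaction_g=4)
        assert tab.loc["A", "Ar"] == pytest.approx(tab.loc["A", "Na"])

    def test_rarefied_richness_matches_exhaustive_subsampling(self):
        # allele copies {A: 3, B: 1}; expected distinct alleles in pairs of genes
        gt = genotypes_from_lists([[(100, 100)], [(100, 102)]])
        popmap = PopulationMap({"ind0": "A", "ind1": "A"})
        tab = microsat_summaries(gt, popmap, rarefaction_g=2)
        genes = [100, 100, 100, 102]
        brute = np.mean(
            [len(set(c)) for c in itertools.combinations(genes, 2)]
        )
        assert brute == pytest.approx(1.5)
        assert tab.loc["A", "Ar"] == pytest.approx(brute, abs=1e-12)

    def test_rarefaction_monotone_in_g(self):
        rows = [[(100 + 2 * (k % 4), 100 + 2 * ((k + 1) % 4))] for k in range(8)]
        gt = genotypes_from_lists(rows)
        popmap = PopulationMap({f"ind{k}": "A" for k in range(8)})
        ars = [
            microsat_summaries(gt, popmap, rarefaction_g=g).loc["A", "Ar"]
            for g in range(1, 17)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(ars, ars[1:]))
        assert ars[0] == pytest.approx(1.0)

    def test_private_alleles_counted_once_per_population(self, two_pop_toy):
        gt, popmap = two_pop_toy
        tab = microsat_summaries(gt, popmap, rarefaction_g=2)
        # pop A: 100,102 and 200,202 private; pop B: 104,106 and 204
        assert tab.loc["A", "Pa"] == 4
        assert tab.loc["B", "Pa"] == 3

    def test_missing_calls_reduce_gene_counts(self):
        gt = genotypes_from_lists(
            [[(100, 102)], [(MISSING, MISSING)], [(100, 100)]]
        )
        popmap = PopulationMap({"ind0": "A", "ind1": "A", "ind2": "A"})
        tab = microsat_summaries(gt, popmap, rarefaction_g=4)
        # 4 scored genes: He = (4/3) * (1 - (3/4)^2 - (1/4)^2)
        assert tab.loc["A", "He"] == pytest.approx(4 / 3 * (1 - 9 / 16 - 1 / 16))


class TestInbreedingML:
    def test_fully_heterozygous_individual_has_zero_inbreeding(self):
        gt = genotypes_from_lists(
            [[(100, 102), (200, 202)], [(100, 102), (200, 202)],
             [(100, 100), (202, 202)]]
        )
        popmap = PopulationMap({f"ind{k}": "A" for k in range(3)})
        f = inbreeding_ml(gt, popmap)
        assert f["ind0"] == pytest.approx(0.0, abs=1e-6)

    def test_fully_homozygous_individual_hits_upper_boundary(self):
        gt = genotypes_from_lists(
            [[(100, 100), (200, 200)], [(100, 102), (200, 202)],
             [(102, 102), (202, 202)]]
        )
        popmap = PopulationMap({f"ind{k}": "A" for k in range(3)})
        f = inbreeding_ml(gt, popmap)
        assert f["ind0"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        gt = genotypes_from_lists(
            [[(100, 100), (200, 202)], [(100, 102), (200, 200)],
             [(102, 102), (202, 202)], [(100, 102), (200, 202)]]
        )
        popmap = PopulationMap({f"ind{k}": "A" for k in range(4)})
        f = inbreeding_ml(gt, popmap)

        # independent oracle: 1e-4-step grid search on the same likelihood
        freqs = []
        for locus in range(2):
            calls = gt.calls[:, locus].reshape(-1)
            alleles, counts = np.unique(calls, return_counts=True)
            freqs.append(dict(zip(alleles.tolist(), (counts / counts.sum()).tolist())))

        def loglik(F, ind):
            total = 0.0
            for locus in range(2):
                a, b = gt.calls[ind, locus]
                pa, pb = freqs[locus][int(a)], freqs[locus][int(b)]
                if a == b:
                    total += math.log(pa**2 + F * pa * (1 - pa))
                else:
                    total += math.log(2 * pa * pb * (1 - F))
            return total

        grid = np.arange(0, 1.0, 1e-4)
        for ind in range(4):
            best = grid[int(np.argmax([loglik(F, ind) for F in grid]))]
            assert f[f"ind{ind}"] == pytest.approx(best, abs=2e-4)


class TestMarkerQC:
    def test_hwe_proportions_give_large_p(self):
        # 2-allele locus at exact HWE proportions: 4 AA, 8 AB, 4 BB
        rows = [[(100, 100)]] * 4 + [[(100, 102)]] * 8 + [[(102, 102)]] * 4
        gt = genotypes_from_lists(rows)
        popmap = PopulationMap({f"ind{k}": "A" for k in range(16)})
        qc = marker_qc(gt, popmap, n_perm=400, seed=1)
        assert qc.hwe_p.iloc[0] > 0.5

    def test_total_homozygote_excess_rejected(self):
        rows = [[(100, 100)]] * 10 + [[(102, 102)]] * 10
        gt = genotypes_from_lists(rows)
        popmap = PopulationMap({f"ind{k}": "A" for k in range(20)})
        qc = marker_qc(gt, popmap, n_perm=1000, seed=2)
        assert qc.hwe_p.iloc[0] < 0.01
        assert not qc.retain.iloc[0]

    def test_null_allele_frequency_formula(self):
        # He = 0.5, Ho = 0.4 -> r = 0.1 / 0.9
        assert max(0.0, (0.5 - 0.4) / (0.5 + 0.4)) == pytest.approx(0.1111, abs=1e-4)
        # heterozygote deficit: 4 hom-100, 2 het, 4 hom-102
        rows = [[(100, 100)]] * 4 + [[(100, 102)]] * 2 + [[(102, 102)]] * 4
        gt = genotypes_from_lists(rows)
        popmap = PopulationMap({f"ind{k}": "A" for k in range(10)})
        qc = marker_qc(gt, popmap, n_perm=200, seed=3)
        he = 20 / 19 * (1 - 0.5**2 - 0.5**2)
        ho = 0.2
        assert qc.null_freq.iloc[0] == pytest.approx((he - ho) / (he + ho))
        # heterozygote excess floors at zero
        rows = [[(100, 100)]] * 6 + [[(100, 102)]] * 4
        gt = genotypes_from_lists(rows)
        qc = marker_qc(gt, popmap, n_perm=200, seed=3)
        assert qc.null_freq.iloc[0] == 0.0

    def test_monomorphic_locus_p_is_one(self):
        gt = genotypes_from_lists([[(100, 100)], [(100, 100)]])
        popmap = PopulationMap({"ind0": "A", "ind1": "A"})
        qc = marker_qc(gt, popmap, n_perm=200, seed=4)
        assert qc.hwe_p.iloc[0] == 1.0

    def test_seed_required(self, two_pop_toy):
        gt, popmap = two_pop_toy
        with pytest.raises(ValueError, match="seed"):
            marker_qc(gt, popmap, n_perm=200)


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------


class TestDifferentiation:
    def test_fixed_differences_give_unit_theta_and_d(self):
        gt = genotypes_from_lists(
            [[(100, 100), (200, 200)]] * 4 + [[(104, 104), (204, 204)]] * 4
        )
        popmap = PopulationMap(
            {f"ind{k}": ("A" if k < 4 else "B") for k in range(8)}
        )
        theta, d = pairwise_differentiation(gt, popmap)
        assert theta.pair("A", "B") == pytest.approx(1.0)
        assert d.pair("A", "B") == pytest.approx(1.0, abs=1e-9)

    def test_identical_tables_give_non_positive_theta_and_zero_d(self):
        rows = [[(100, 102)], [(100, 100)], [(102, 102)], [(100, 102)]]
        gt = genotypes_from_lists(rows * 2)
        popmap = PopulationMap(
            {f"ind{k}": ("A" if k < 4 else "B") for k in range(8)}
        )
        theta, d = pairwise_differentiation(gt, popmap)
        assert theta.pair("A", "B") <= 1e-9  # reported raw, may be negative
        assert d.pair("A", "B") == pytest.approx(0.0, abs=1e-9)

    def test_theta_matches_hand_computed_variance_components(self):
        """Single biallelic locus, two populations; a, b, c from first principles."""
        gt = genotypes_from_lists(
            [[(100, 100)], [(100, 102)], [(100, 102)],
             [(102, 102)], [(102, 102)], [(100, 102)]]
        )
        popmap = PopulationMap(
            {f"ind{k}": ("A" if k < 3 else "B") for k in range(6)}
        )
        theta = weir_cockerham_theta(gt, popmap)

        # Weir & Cockerham (1984) components for allele "100", r = 2
        n1 = n2 = 3.0
        p1, p2 = 4 / 6, 1 / 6
        h1, h2 = 2 / 3, 1 / 3
        r = 2.0
        nbar = 3.0
        nc = (6 - (9 + 9) / 6) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / 6
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / 6
        a = (nbar / nc) * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        expected = 2 * a / (2 * (a + b + c))  # both alleles contribute equally
        assert theta == pytest.approx(expected, abs=1e-12)

    def test_statistics_invariant_to_order_and_allele_relabeling(self, two_pop_toy):
        gt, popmap = two_pop_toy
        theta1, d1 = pairwise_differentiation(gt, popmap)
        perm = [2, 0, 3, 1]
        gt2 = GenotypeMatrix(
            [gt.ids[i] for i in perm], gt.loci, gt.calls[perm]
        )
        theta2, d2 = pairwise_differentiation(gt2, popmap)
        assert theta1.pair("A", "B") == pytest.approx(theta2.pair("A", "B"))
        assert d1.pair("A", "B") == pytest.approx(d2.pair("A", "B"))
        # relabel allele sizes through a monotone-breaking bijection
        relabeled = gt.calls.copy()
        mapping = {100: 7, 102: 93, 104: 2, 106: 55, 200: 11, 202: 4, 204: 68}
        for old, new in mapping.items():
            relabeled[gt.calls == old] = new
        gt3 = GenotypeMatrix(gt.ids, gt.loci, relabeled)
        theta3, d3 = pairwise_differentiation(gt3, popmap)
        assert theta1.pair("A", "B") == pytest.approx(theta3.pair("A", "B"))
        assert d1.pair("A", "B") == pytest.approx(d3.pair("A", "B"))

    def test_panmictic_data_concentrates_near_zero(self):
        """Theta and D on one panmictic deme split arbitrarily into two."""
        from skyisland.demography import simulate_dataset

        rng = np.random.default_rng(42)
        params = dict(N_S=5000.0, N_N=5000.0, N_A=5000.0, t_split=0.01)
        thetas, ds = [], []
        for rep in range(200):
            sim = simulate_dataset(1, params, n_s=25, n_n=25, seed=rng)
            theta, d = pairwise_differentiation(sim.genotypes, sim.popmap)
            thetas.append(theta.pair("S", "N"))
            ds.append(d.pair("S", "N"))
        assert abs(np.mean(thetas)) < 0.02
        assert abs(np.mean(ds)) < 0.02


# ---------------------------------------------------------------------------
# diversity ~ land use
# ---------------------------------------------------------------------------


class TestDiversityRegression:
    def test_collinear_data_has_unit_r2(self):
        import pandas as pd

        x = pd.Series([1.0, 2, 3, 4, 5])
        res = diversity_landuse_regression(2 * x + 1, x)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_flat_response_gives_zero_f(self):
        import pandas as pd

        x = pd.Series([1.0, 2, 3, 4, 5])
        res = diversity_landuse_regression(pd.Series([3.0] * 5), x)
        assert res["F"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        import pandas as pd

        x = np.array([0.1, 0.4, 0.5, 0.7, 0.9])
        y = np.array([6.1, 5.2, 5.5, 4.4, 4.0])
        res = diversity_landuse_regression(pd.Series(y), pd.Series(x))
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        rss = resid @ resid
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1 - rss / tss
        f = (tss - rss) / 1 / (rss / 3)
        assert res["slope"] == pytest.approx(beta[1])
        assert res["r2"] == pytest.approx(r2)
        assert res["F"] == pytest.approx(f)
        assert (res["df1"], res["df2"]) == (1, 3)

    def test_degenerate_covariate_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="variance"):
            diversity_landuse_regression(
                pd.Series([1.0, 2, 3]), pd.Series([5.0, 5, 5])
            )


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


@settings(max_examples=30, deadline=None)
@given(st.lists(st.integers(0, 3), min_size=2, max_size=30))
def test_haplotype_diversity_bounds(codes):
    seqs = ["ACGT"[c] * 5 for c in codes]
    aln = SequenceAlignment([f"i{k}" for k in range(len(codes))], seqs)
    _, hd, pi = mtdna_diversity(aln)
    assert -1e-12 <= hd <= 1 + 1e-12
    assert pi >= 0


@settings(max_examples=20, deadline=None)
@given(st.data())
def test_differentiation_bounds_and_symmetry(data):
    rng_seed = data.draw(st.integers(0, 10_000))
    rng = np.random.default_rng(rng_seed)
    n, L = 8, 3
    calls = rng.choice([100, 102, 104], size=(n, L, 2))
    gt = GenotypeMatrix([f"i{k}" for k in range(n)], [f"l{j}" for j in range(L)],
                        calls)
    popmap = PopulationMap({f"i{k}": ("A" if k < 4 else "B") for k in range(n)})
    theta, d = pairwise_differentiation(gt, popmap)
    assert theta.values[0, 1] == theta.values[1, 0]
    assert theta.pair("A", "B") <= 1 + 1e-9
    assert -1e-9 <= d.pair("A", "B") <= 1 + 1e-9
    assert d.values[0, 0] == 0.0
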