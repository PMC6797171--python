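"""Estimators, the top-percentile pdSNP rule, and population trees."""

import itertools
import io as _io

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo
from hypothesis import given, settings, strategies as st

from popdiff import fst


def wc_theta_oracle(n1, p1, h1, n2, p2, h2):
    """Straight-line transcription of the two-deme variance-components
    theta-hat (a / (a+b+c)), kept independent of the vectorised path."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - 1 / (nbar - 1)
                       * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c)


class TestWcFst:
    def test_fixed_difference_scores_one(self):
        assert fst.wc_fst(50, 0.0, 0.0, 50, 1.0, 0.0) == pytest.approx(1.0)
        assert wc_theta_oracle(50, 0.0, 0.0, 50, 1.0, 0.0) == pytest.approx(1.0)

    def test_identical_populations_score_nonpositive(self):
        theta = fst.wc_fst(50, 0.3, 0.42, 50, 0.3, 0.42)
        assert theta <= 0
        assert theta == pytest.approx(wc_theta_oracle(50, 0.3, 0.42, 50, 0.3, 0.42))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n1=st.integers(5, 200), n2=st.integers(5, 200),
        a1=st.integers(0, 400), a2=st.integers(0, 400),
        het1=st.integers(0, 400), het2=st.integers(0, 400),
    )
    def test_matches_scalar_oracle(self, n1, n2, a1, a2, het1, het2):
        # build a consistent site: alt count <= alleles, het <= diploids
        alt1, alt2 = a1 % (2 * n1 + 1), a2 % (2 * n2 + 1)
        p1, p2 = alt1 / (2 * n1), alt2 / (2 * n2)
        h1 = (het1 % (min(alt1, 2 * n1 - alt1) + 1)) / n1
        h2 = (het2 % (min(alt2, 2 * n2 - alt2) + 1)) / n2
        if alt1 + alt2 == 0 or alt1 + alt2 == 2 * (n1 + n2):
            return  # pooled-monomorphic: undefined, filtered upstream
        got = float(fst.wc_fst(n1, p1, h1, n2, p2, h2))
        want = wc_theta_oracle(n1, p1, h1, n2, p2, h2)
        assert got == pytest.approx(want, abs=1e-12)

    def test_clamp_option_floors_at_zero(self):
        assert fst.wc_fst(50, 0.3, 0.42, 50, 0.3, 0.42, clamp=True) == 0.0

    def test_recovers_planted_divergence(self, two_pop_scan_factory):
        _, _, counts, _ = two_pop_scan_factory(F=0.1, seed=21)
        assert fst.multilocus_fst(counts, "POP1", "POP2") == pytest.approx(0.1, abs=0.02)

    def test_agrees_with_hudson_on_balanced_design(self, two_pop_scan_factory):
        gm, _, counts, _ = two_pop_scan_factory(F=0.1, seed=22, n_snps=5000)
        wc = fst.pairwise_fst(counts, "wc")[("POP1", "POP2")]
        hu = fst.pairwise_fst(counts, "hudson")[("POP1", "POP2")]
        assert abs(np.nanmean(wc) - np.nanmean(hu)) < 0.02


class TestHudsonFst:
    def test_limit_cases(self):
        # equal frequencies: squared difference 0, bias terms vanish at large n
        assert fst.hudson_fst(0.4, 0.4, 10_000_000, 10_000_000) == pytest.approx(0.0, abs=1e-6)
        assert fst.hudson_fst(1.0, 0.0, 20, 20) == pytest.approx(1.0)

    def test_closed_form_value(self):
        assert fst.hudson_fst(0.2, 0.8, 20, 20) == pytest.approx(0.5046439628, abs=1e-9)

    def test_undefined_when_both_fixed_same_allele(self):
        assert np.isnan(fst.hudson_fst(0.0, 0.0, 20, 20))


class TestCallPdsnps:
    def test_two_hundred_distinct_scores_select_two(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(np.linspace(0, 1, 200))
        threshold, mask = fst.call_pdsnps(scores, 0.01)
        assert mask.sum() == 2
        assert set(scores[mask]) == set(np.sort(scores)[-2:])
        assert threshold == np.sort(scores)[-2]

    def test_ties_match_bruteforce_sort_oracle(self):
        rng = np.random.default_rng(1)
        # heavy ties: scores drawn from a tiny discrete set
        scores = rng.choice([0.0, 0.1, 0.1, 0.5, 0.5, 0.9], size=500)
        q = 0.01
        threshold, mask = fst.call_pdsnps(scores, q)
        k = int(np.ceil(q * len(scores)))
        cut = np.sort(scores)[::-1][k - 1]
        oracle = scores >= cut
        assert np.array_equal(mask, oracle)
        assert threshold == cut
        # every selected score >= every unselected score
        assert scores[mask].min() >= scores[~mask].max()

    def test_q_one_selects_everything(self):
        scores = np.array([0.5, 0.1, np.nan, 0.9])
        _, mask = fst.call_pdsnps(scores, 1.0)
        assert mask.tolist() == [True, True, False, True]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fst.call_pdsnps(np.array([np.nan]), 0.01)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, width=16), min_size=1, max_size=300),
           st.sampled_from([0.01, 0.05, 0.25, 1.0]))
    def test_selected_fraction_bounded_below_by_q(self, scores, q):
        scores = np.asarray(scores, dtype=float)
        _, mask = fst.call_pdsnps(scores, q)
        n = len(scores)
        assert mask.sum() >= np.ceil(q * n)
        if mask.sum() < n:
            assert scores[mask].min() >= scores[~mask].max()


class TestPdUnion:
    def test_disjoint_and_identical_sets(self):
        u = fst.pd_union({("A", "B"): {f"s{i}" for i in range(10)},
                          ("A", "C"): {f"t{i}" for i in range(5)}})
        assert len(u) == 15 and set(u.unique()) == {1}
        v = fst.pd_union({("A", "B"): {"x", "y"}, ("A", "C"): {"x", "y"}})
        assert len(v) == 2 and set(v) == {2}

    def test_union_matches_naive_set_oracle(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(100)]
        sets = {("A", f"P{k}"): set(rng.choice(ids, size=20, replace=False))
                for k in range(5)}
        u = fst.pd_union(sets)
        naive = set().union(*sets.values())
        assert set(u.index) == naive
        for snp in naive:
            assert u[snp] == sum(snp in s for s in sets.values())


class TestMeanPdFstMatrix:
    @staticmethod
    def _summaries(pops, value=0.3):
        return [fst.PairSummary(pair=p, n_scored=100, threshold=0.1,
                                n_pd=1, mean_pd_fst=value)
                for p in itertools.combinations(pops, 2)]

    def test_fourteen_populations_give_91_pairs(self):
        pops = [f"P{i:02d}" for i in range(14)]
        assert len(fst.population_pairs(pops)) == 91
        mat = fst.mean_pd_fst_matrix(self._summaries(pops))
        off_diag = mat.to_numpy()[~np.eye(14, dtype=bool)]
        assert off_diag.size == 182  # 91 unordered pairs, mirrored
        assert np.allclose(mat, mat.T) and np.all(np.diag(mat) == 0)

    def test_two_population_case(self):
        mat = fst.mean_pd_fst_matrix(self._summaries(["A", "B"], 0.42))
        assert mat.loc["A", "B"] == 0.42

    def test_missing_pair_reported(self):
        s = self._summaries(["A", "B", "C"])[:-1]
        with pytest.raises(ValueError, match="missing pairs"):
            fst.mean_pd_fst_matrix(s)


def cophenetic_from_newick(newick):
    tree = Phylo.read(_io.StringIO(newick), "newick")
    leaves = sorted(tree.get_terminals(), key=lambda t: t.name)
    names = [t.name for t in leaves]
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tree.distance(leaves[i], leaves[j])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


class TestPopulationTree:
    def test_three_taxon_hand_execution(self):
        d = pd.DataFrame([[0, 0.1, 0.4], [0.1, 0, 0.4], [0.4, 0.4, 0]],
                         index=list("ABC"), columns=list("ABC"))
        nwk = fst.build_population_tree(d, "upgma")
        coph = cophenetic_from_newick(nwk)
        assert coph.loc["A", "B"] == pytest.approx(0.1)
        assert coph.loc["A", "C"] == pytest.approx(0.4)  # root height 0.2
        assert fst.tree_splits(nwk) == {frozenset({"A", "B"})}

    def test_reproduces_ultrametric_input_exactly(self):
        # build an ultrametric matrix with scipy average linkage, then
        # check UPGMA returns the identical cophenetic matrix
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(3)
        pts = rng.random((8, 4))
        Z = average(pdist(pts))
        ultra = squareform(cophenet(Z))
        labels = [f"L{i}" for i in range(8)]
        d = pd.DataFrame(ultra, index=labels, columns=labels)
        coph = cophenetic_from_newick(fst.build_population_tree(d, "upgma"))
        assert np.allclose(coph.loc[labels, labels].to_numpy(), ultra, atol=1e-9)

    def test_matches_skbio_upgma_on_generic_matrix(self):
        from skbio import DistanceMatrix
        from skbio.tree import upgma

        rng = np.random.default_rng(4)
        pts = rng.random((6, 3))
        from scipy.spatial.distance import pdist, squareform
        mat = squareform(pdist(pts))
        labels = [f"P{i}" for i in range(6)]
        d = pd.DataFrame(mat, index=labels, columns=labels)
        mine = cophenetic_from_newick(fst.build_population_tree(d, "upgma"))
        ref = upgma(DistanceMatrix(mat, ids=labels))
        ref_coph = np.zeros((6, 6))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    dd = ref.find(a).distance(ref.find(b))
                    ref_coph[i, j] = ref_coph[j, i] = dd
        assert np.allclose(mine.loc[labels, labels].to_numpy(), ref_coph, atol=1e-9)

    def test_nj_method_returns_all_leaves(self):
        rng = np.random.default_rng(5)
        pts = rng.random((5, 3))
        from scipy.spatial.distance import pdist, squareform
        mat = squareform(pdist(pts))
        labels = [f"P{i}" for i in range(5)]
        nwk = fst.build_population_tree(
            pd.DataFrame(mat, index=labels, columns=labels), "nj")
        tree = Phylo.read(_io.StringIO(nwk), "newick")
        assert {t.name for t in tree.get_terminals()} == set(labels)

    def test_invalid_matrix_rejected(self):
        bad = pd.DataFrame([[0, 1], [2, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            fst.build_population_tree(bad)

    def test_two_group_simulation_recovers_grouping(self, two_pop_scan_factory):
        from conftest import two_group_tree_spec
        from popdiff import io as pio, simulate

        ok = 0
        n_rep = 10
        for seed in range(n_rep):
            cfg = simulate.SimulationConfig(
                samples_per_pop=30, n_snps=2000,
                tree_spec=two_group_tree_spec(), seed=100 + seed)
            gm, panel, _ = simulate.simulate_genotypes(cfg)
            counts = pio.allele_counts(gm, panel)
            gm = gm.subset_sites(pio.filter_monomorphic(counts))
            counts = pio.allele_counts(gm, panel)
            scores = fst.pairwise_fst(counts)
            summaries, _ = fst.pair_summaries(scores, gm.sites["snp_id"])
            nwk = fst.build_population_tree(fst.mean_pd_fst_matrix(summaries))
            splits = fst.tree_splits(nwk)
            ok += (frozenset({"A1", "A2"}) in splits
                   and frozenset({"B1", "B2"}) in splits)
        assert ok == n_rep
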