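"""Signal dissection: TIGER rates, quartet mapping, RELL/AU, polytomy, PI."""

import math

import numpy as np
import pytest
from scipy.stats import chi2

from olpiphy import markerset as ms
from olpiphy import signal as sg
from olpiphy import synthdata as sd
from olpiphy import treekit as tk


class TestTigerScores:
    def test_constant_site_attains_maximum(self):
        rows = {"a": "AAC", "b": "ABC", "c": "BAC", "d": "BBC"}
        sc = sg.tiger_site_scores(rows)
        assert sc[2] == sc.max() == 1.0

    def test_identical_sites_agree_fully(self):
        rows = {"a": "AA", "b": "AA", "c": "BB", "d": "BB"}
        sc = sg.tiger_site_scores(rows)
        assert np.allclose(sc, 1.0)

    def test_conflicting_binary_patterns_score_zero(self):
        # AABB vs ABAB: neither site's state sets nest in the other's
        rows = {"a": "AA", "b": "AB", "c": "BA", "d": "BB"}
        assert np.allclose(sg.tiger_site_scores(rows), 0.0)

    def test_duplicating_a_site_never_decreases_its_score(self):
        rng = np.random.default_rng(5)
        taxa = [f"t{i}" for i in range(6)]
        base = rng.choice(list("ACGT"), size=(6, 30))
        rows = {t: "".join(base[i]) for i, t in enumerate(taxa)}
        sc = sg.tiger_site_scores(rows)
        for j in (0, 7, 29):
            dup = {t: rows[t] + rows[t][j] for t in taxa}
            sc2 = sg.tiger_site_scores(dup)
            assert sc2[j] >= sc[j] - 1e-12

    def test_all_gap_site_flagged(self):
        rows = {"a": "A-", "b": "C-", "c": "A-"}
        with pytest.warns(UserWarning, match="undefined"):
            sc = sg.tiger_site_scores(rows)
        assert np.isnan(sc[1])


class TestBinRates:
    def test_extremes(self):
        rc = sg.bin_rates(np.array([1.0, 0.0]), 10)
        assert list(rc.categories) == [1, 10]

    def test_constant_scores_single_category(self):
        rc = sg.bin_rates(np.full(5, 0.7), 10)
        assert list(rc.categories) == [1] * 5

    def test_boundary_ties_go_to_lower_category(self):
        # width 0.1; score exactly at 0.9 is the cat-1/cat-2 edge -> cat 1
        rc = sg.bin_rates(np.array([0.0, 0.9, 1.0]), 10)
        assert rc.categories[1] == 1

    def test_uniform_scores_fill_bins_evenly(self):
        rng = np.random.default_rng(1)
        scores = rng.random(10_000)
        rc = sg.bin_rates(scores, 10)
        occ = np.bincount(rc.categories, minlength=11)[1:]
        se = math.sqrt(0.1 * 0.9 / 10_000)
        assert np.all(np.abs(occ / 10_000 - 0.1) < 3 * se + 2e-3)

    def test_nan_scores_fastest_category(self):
        with pytest.warns(UserWarning):
            rc = sg.bin_rates(np.array([0.2, np.nan, 0.8]), 10)
        assert rc.categories[1] == 10


@pytest.fixture(scope="module")
def stripping_setup():
    nwk, groups = sd.four_group_species_tree(2.0, n_per_group=2)
    spec = sd.CoalescentSpec(
        species_newick=nwk, n_genes=10, sites_per_gene=60, seed=3
    )
    sim = sd.simulate_marker_dataset(spec)
    sm = ms.concatenate(sim.alignments)
    scores = sg.tiger_site_scores(sm.rows)
    cats = sg.bin_rates(scores, 10)
    focal = {"f": set(groups["G1"]) | set(groups["G2"])}
    return sm, cats, focal


class TestSequentialRemoval:
    def test_bookkeeping(self, stripping_setup, jc):
        sm, cats, focal = stripping_setup
        table = sg.sequential_site_removal(
            sm, cats, jc, focal, n_replicates=20, seed=1
        )
        assert len(table) == 10
        assert table["sites_remaining"].iloc[0] == sm.n_sites
        assert table["sites_remaining"].is_monotonic_decreasing
        for k in range(10):
            expected = int((cats.categories <= 10 - k).sum())
            assert table["sites_remaining"].iloc[k] == expected

    def test_round_zero_equals_plain_support(self, stripping_setup, jc):
        sm, cats, focal = stripping_setup
        table = sg.sequential_site_removal(
            sm, cats, jc, focal, n_replicates=20, seed=1
        )
        direct = tk.bootstrap_bipartition_support(
            sm.rows, focal, jc, n_replicates=20, seed=1
        )
        assert table["f"].iloc[0] == direct["f"]


class TestQuartetPosteriors:
    def test_identical_sequences_symmetric(self, jc):
        rows = {t: "ACGTACGTAC" for t in "ABCD"}
        p = sg.quartet_posteriors(rows, jc)
        assert np.allclose(p, 1 / 3, atol=1e-6)

    def test_strong_topology_resolved(self, jc, quartet_alignment):
        p = sg.quartet_posteriors(
            quartet_alignment, jc, taxa=["A", "B", "C", "D"]
        )
        assert p[0] >= 0.99

    def test_relabeling_equivariance(self, jc, quartet_alignment):
        p1 = sg.quartet_posteriors(quartet_alignment, jc, taxa=["A", "B", "C", "D"])
        p2 = sg.quartet_posteriors(quartet_alignment, jc, taxa=["A", "C", "B", "D"])
        # swapping the inner pair maps topology 1 <-> 2
        assert p1[0] == pytest.approx(p2[1], abs=0.01)
        assert p1[1] == pytest.approx(p2[0], abs=0.01)

    def test_all_gap_rejected(self, jc):
        rows = {t: "----" for t in "ABCD"}
        with pytest.raises(ValueError):
            sg.quartet_posteriors(rows, jc)


class TestLikelihoodMapping:
    def test_singleton_groups_single_quartet(self, jc, quartet_alignment):
        groups = {g: [t] for g, t in zip("WXYZ", "ABCD")}
        res = sg.likelihood_mapping(
            quartet_alignment, groups, n_quartets=10, model=jc, seed=1
        )
        assert res.n_sampled == 1
        assert res.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_strong_branch_hits_corner(self, jc):
        nwk, groups = sd.four_group_species_tree(3.0, n_per_group=2)
        spec = sd.CoalescentSpec(
            species_newick=nwk, n_genes=20, sites_per_gene=80, seed=2
        )
        sim = sd.simulate_marker_dataset(spec)
        sm = ms.concatenate(sim.alignments)
        res = sg.likelihood_mapping(sm, groups, n_quartets=16, model=jc, seed=3)
        assert res.corners[0] >= 0.9
        assert res.strongly_resolved_for == 0

    def test_star_data_concentrates_in_center(self, jc):
        rows, groups = sd.star_quartet_scenario(seed=4, n_per_group=3, n_sites=2000)
        res = sg.likelihood_mapping(rows, groups, n_quartets=60, model=jc, seed=5)
        assert res.center > max(res.edges.max(), res.corners.max())
        assert res.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_group_rejected(self, jc, quartet_alignment):
        groups = {"W": ["A"], "X": ["B"], "Y": ["C"], "Z": ["nope"]}
        with pytest.raises(ValueError):
            sg.likelihood_mapping(quartet_alignment, groups, model=jc)


class TestRell:
    def test_dominant_tree_wins_always(self):
        m = np.vstack([np.full(50, -1.0), np.full(50, -2.0)])
        tbl = sg.SiteLikelihoodTable(["a", "b"], m)
        props = sg.rell_bootstrap(tbl, 1.0, 200, seed=1)
        assert props[0] == 1.0

    def test_identical_rows_split_evenly(self):
        m = np.vstack([np.full(50, -1.0), np.full(50, -1.0)])
        tbl = sg.SiteLikelihoodTable(["a", "b"], m)
        props = sg.rell_bootstrap(tbl, 1.0, 400, seed=2)
        assert props[0] == pytest.approx(0.5, abs=1e-12)  # exact tie split

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(3)
        m = rng.normal(-2, 0.5, size=(4, 80))
        tbl = sg.SiteLikelihoodTable([f"t{i}" for i in range(4)], m)
        for scale in (0.5, 1.0, 1.4):
            props = sg.rell_bootstrap(tbl, scale, 100, seed=4)
            assert props.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scale_changes_replicate_size(self):
        m = np.vstack([np.full(10, -1.0), np.full(10, -1.1)])
        tbl = sg.SiteLikelihoodTable(["a", "b"], m)
        with pytest.raises(ValueError):
            sg.rell_bootstrap(tbl, 0.0, 10, seed=1)


class TestAuTest:
    def test_identical_likelihood_trees_near_half(self):
        rng = np.random.default_rng(1)
        row = rng.normal(-2, 0.4, size=300)
        tbl = sg.SiteLikelihoodTable(["a", "b"], np.vstack([row, row]))
        res = sg.au_test(tbl, B=2000, seed=2)
        assert np.all(np.abs(res.pvalues - 0.5) < 0.05)

    def test_dominant_tree_clamped_limits(self):
        m = np.vstack([np.full(200, -1.0), np.full(200, -1.3)])
        tbl = sg.SiteLikelihoodTable(["a", "b"], m)
        res = sg.au_test(tbl, B=1000, seed=3)
        assert res.clamped.all()
        assert res.pvalues[0] == pytest.approx(1 - 1 / 2000)
        assert res.pvalues[1] == pytest.approx(1 / 2000)

    def test_ranking_matches_rell_at_scale_one(self, jc):
        # with well-separated trees, p_AU ordering agrees with BP ordering
        tree = tk.read_tree("((A:0.1,B:0.1):0.15,(C:0.1,D:0.1):0.15,E:0.2);")
        aln = sd.simulate_alignment(tree, jc, 400, seed=4)
        cands = {f"t{i}": t for i, t in enumerate(tk.regraft_candidates(tree, "E"))}
        tbl = sg.compute_site_likelihoods(cands, aln.rows, jc)
        res = sg.au_test(tbl, B=1000, seed=5)
        bp1 = sg.rell_bootstrap(tbl, 1.0, 1000, seed=6)
        assert np.argmax(res.pvalues) == np.argmax(bp1)

    def test_needs_two_trees(self):
        tbl = sg.SiteLikelihoodTable(["a"], np.full((1, 10), -1.0))
        with pytest.raises(ValueError):
            sg.au_test(tbl)


class TestClassifyMarkers:
    def test_reference_best_is_similar(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(-2, 0.3, 100)
        other = ref - 0.05 - rng.random(100) * 0.01
        tbl = sg.SiteLikelihoodTable(["reference", "alt"], np.vstack([ref, other]))
        out = sg.classify_markers_au({"m1": tbl}, alpha=0.05, B=500, seed=2)
        assert out.loc["m1", "class"] == "AU_similar"

    def test_conflicting_marker_is_better(self, jc):
        true = tk.read_tree("((A:0.1,B:0.1):0.4,(C:0.1,D:0.1):0.4,E:0.2);")
        wrong = tk.read_tree("((A:0.1,C:0.1):0.4,(B:0.1,D:0.1):0.4,E:0.2);")
        aln = sd.simulate_alignment(true, jc, 600, seed=3)
        tbl = sg.compute_site_likelihoods(
            {"reference": wrong, "best": true}, aln.rows, jc
        )
        out = sg.classify_markers_au({"m": tbl}, alpha=0.05, B=500, seed=4)
        assert out.loc["m", "class"] == "AU_better"

    def test_missing_table_ineligible(self):
        out = sg.classify_markers_au({"m": None})
        assert out.loc["m", "class"] == "ineligible"


class TestPolytomy:
    def test_hand_arithmetic(self):
        res = sg.polytomy_test((40, 30, 30))
        assert res.chi2 == pytest.approx(2.0)
        assert res.pvalue == pytest.approx(math.exp(-1.0))

    def test_equal_counts_p_one(self):
        res = sg.polytomy_test((50, 50, 50))
        assert res.chi2 == 0.0 and res.pvalue == 1.0

    @pytest.mark.parametrize("counts", [(40, 30, 30), (90, 10, 5), (7, 7, 7)])
    def test_closed_form_matches_chi2_survival(self, counts):
        res = sg.polytomy_test(counts)
        assert res.pvalue == pytest.approx(chi2.sf(res.chi2, df=2), abs=1e-12)

    def test_zero_informative_flagged(self):
        res = sg.polytomy_test((0, 0, 0))
        assert res.insufficient and math.isnan(res.pvalue)

    def test_counts_around_branch_concordant_trees(self):
        nwk = sd.quartet_species_tree(1.0)
        sp = tk.read_tree(nwk)
        gts = [tk.read_tree("((A:1,B:1):1,(C:1,D:1):1);") for _ in range(20)]
        counts = sg.quartet_counts_around_branch(
            gts, groups=[{"A"}, {"B"}, {"C"}, {"D"}], collapse_threshold=None
        )
        assert counts == (20, 0, 0)

    def test_star_gene_trees_all_skipped(self):
        gts = [tk.read_tree("(A:1,B:1,C:1,D:1);") for _ in range(5)]
        counts = sg.quartet_counts_around_branch(
            gts, groups=[{"A"}, {"B"}, {"C"}, {"D"}], collapse_threshold=None
        )
        assert sum(counts) == 0
        res = sg.polytomy_test(counts)
        assert res.insufficient

    def test_collapse_threshold_discards_weak_resolution(self):
        gts = [
            tk.read_tree("((A:1,B:1)10:1,(C:1,D:1)10:1);") for _ in range(5)
        ]
        counts = sg.quartet_counts_around_branch(
            gts, groups=[{"A"}, {"B"}, {"C"}, {"D"}], collapse_threshold=30
        )
        assert sum(counts) == 0

    def test_msc_counts_track_closed_form(self):
        spec = sd.CoalescentSpec(
            species_newick=sd.quartet_species_tree(1.0), n_genes=1000, seed=6
        )
        trees = sd.simulate_msc_gene_trees(spec)
        n1, n2, n3 = sg.quartet_counts_around_branch(
            trees, groups=[{"A"}, {"B"}, {"C"}, {"D"}], collapse_threshold=None
        )
        n = n1 + n2 + n3
        expected = 1 - (2 / 3) * math.exp(-1.0)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(n1 / n - expected) < 3 * se

    def test_groups_derived_from_species_tree(self):
        sp = tk.read_tree("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1,G:1);")
        groups = sg.four_groups_around_edge(sp, {"A", "B", "C", "D"})
        assert groups[0] == {"A", "B"} and groups[1] == {"C", "D"}
        assert {frozenset(groups[2]), frozenset(groups[3])} == {
            frozenset({"E", "F"}),
            frozenset({"G"}),
        }


class TestPhylogeneticInformativeness:
    def test_invariant_marker_ranks_last(self):
        rates = {"slow": np.zeros(10), "fast": np.full(10, 1.0)}
        rank = sg.pi_rank(rates, focal_time=0.5)
        assert rank.ranked_ids == ["fast", "slow"]
        assert rank.table.loc["slow", "pi"] == 0.0

    def test_informativeness_peaks_at_inverse_time(self):
        # rho decreases beyond lambda = 1/t, so at lambda = 2/t the slower
        # of (lambda, 2*lambda) markers ranks first
        t = 0.5
        lam = 2 / t
        rates = {"slower": np.full(10, lam), "faster": np.full(10, 2 * lam)}
        rank = sg.pi_rank(rates, focal_time=t)
        assert rank.ranked_ids == ["slower", "faster"]

    def test_pi_additive_in_length(self):
        lam = np.full(10, 0.7)
        r = sg.pi_rank(
            {"short": lam, "long": np.concatenate([lam, lam])}, focal_time=1.0
        )
        assert r.table.loc["long", "pi"] == pytest.approx(
            2 * r.table.loc["short", "pi"]
        )

    def test_estimated_rates_separate_fast_and_slow_markers(self, jc):
        alns, _, _ = sd.graded_informativeness_scenario(
            seed=8, n_markers=20, n_top=5, sites_per_marker=60
        )
        sm = ms.concatenate(alns)
        gm = tk.SubstModel(n_states=4, gamma_shape=1.0)
        rates = sg.estimate_site_rates(sm.rows, gm)
        assert rates.mean() == pytest.approx(1.0)
        assert rates.std() > 0

    def test_default_schedule_shape(self):
        sched = sg.default_schedule(100)
        assert sched[0] == 5 and sched[-1] == 100
        assert sched == sorted(set(sched))


class TestStepwiseSeries:
    def test_full_schedule_matches_direct_support(self, jc):
        alns, focal, _ = sd.graded_informativeness_scenario(
            seed=9, n_markers=10, n_top=5, sites_per_marker=50
        )
        traj = sg.stepwise_concat_series(
            alns, [5, 10], jc, {"f": focal}, seed=1, n_replicates=30
        )
        sm = ms.concatenate(alns)
        direct = tk.bootstrap_bipartition_support(
            sm.rows, {"f": focal}, jc, n_replicates=30, seed=1 + 10
        )
        assert traj.loc["f", 10] == direct["f"]

    def test_cells_in_range(self, jc):
        alns, focal, _ = sd.graded_informativeness_scenario(
            seed=10, n_markers=10, n_top=5, sites_per_marker=50
        )
        traj = sg.stepwise_concat_series(
            alns, [5, 10], jc, {"f": focal}, seed=2, n_replicates=20
        )
        vals = traj.values.ravel()
        assert np.all((vals[~np.isnan(vals)] >= 0) & (vals[~np.isnan(vals)] <= 100))

    def test_schedule_beyond_markers_rejected(self, jc):
        alns, focal, _ = sd.graded_informativeness_scenario(
            seed=11, n_markers=10, n_top=5, sites_per_marker=40
        )
        with pytest.raises(ValueError):
            sg.stepwise_concat_series(alns, [20], jc, {"f": focal})


class TestSiteLikelihoodTableIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        tbl = sg.SiteLikelihoodTable(
            ["t1", "t2", "t3"], rng.normal(-2, 0.4, size=(3, 25))
        )
        path = tmp_path / "sitelh.txt"
        tbl.write(path)
        back = sg.SiteLikelihoodTable.read(path)
        assert back.tree_ids == tbl.tree_ids
        assert np.allclose(back.matrix, tbl.matrix, atol=1e-6)
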