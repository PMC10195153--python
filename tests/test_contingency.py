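"""Dice similarity, randomization tests, ANOSIM, enrichment and FDR."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import contevo as ce

from conftest import make_labeling, make_pa

region_sets = st.frozensets(
    st.sampled_from(["g1", "g2", "g3", "g4", "g5", "g6"]), max_size=6
)


class TestDiceCoefficient:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"g1", "g2"}, {"g1", "g2"}, 1.0),
            ({"g1"}, {"g2"}, 0.0),
            ({"g1", "g2", "g3"}, {"g2", "g3", "g4"}, 2 * 2 / 6),
        ],
    )
    def test_closed_form(self, a, b, expected):
        assert ce.dice_coefficient(a, b) == pytest.approx(expected)

    def test_both_empty_is_undefined(self):
        with pytest.raises(ValueError):
            ce.dice_coefficient(set(), set())

    @given(region_sets, region_sets)
    def test_symmetric_bounded_and_extremes(self, a, b):
        if not a and not b:
            return
        d = ce.dice_coefficient(a, b)
        assert d == ce.dice_coefficient(b, a)
        assert 0.0 <= d <= 1.0
        if a and b:
            assert (d == 1.0) == (a == b)
        assert (d == 0.0) == (not a & b)


class TestDscContrast:
    def test_all_equal_similarities_give_zero_difference(self):
        pa = make_pa({
            "r1": {"a": 1}, "r2": {"b": 1}, "p1": {"c": 1}, "p2": {"d": 1},
        })
        sim = ce.similarity_matrix(pa)
        lab = make_labeling(
            r1=("rho", "f1"), r2=("rho", "f2"),
            p1=("rpoB", "f3"), p2=("rpoB", "f4"),
        )
        c = ce.dsc_contrast(sim, lab)
        assert c.difference == 0.0

    def test_perfect_modularity_gives_difference_one(self):
        pa = make_pa({
            "r1": {"a": 1, "b": 1}, "r2": {"a": 1, "b": 1},
            "p1": {"c": 1, "d": 1}, "p2": {"c": 1, "d": 1},
        })
        sim = ce.similarity_matrix(pa)
        lab = make_labeling(
            r1=("rho", "f1"), r2=("rho", "f2"),
            p1=("rpoB", "f3"), p2=("rpoB", "f4"),
        )
        c = ce.dsc_contrast(sim, lab)
        assert c.within_mean == 1.0 and c.between_mean == 0.0

    def test_five_population_toy_matches_hand_enumeration(self):
        pa = make_pa({
            "r1": {"a": 1, "b": 1, "c": 1},
            "r2": {"a": 1, "b": 1},
            "p1": {"b": 1, "c": 1},
            "p2": {"c": 1, "d": 1},
            "anc": {"a": 1, "d": 1},
        })
        lab = make_labeling(
            r1=("rho", "f1"), r2=("rho", "f2"),
            p1=("rpoB", "f3"), p2=("rpoB", "f4"),
            anc=("ancestor", "ancestor"),
        )
        sim = ce.similarity_matrix(pa)
        sets = pa.region_sets()
        within_pairs = [("r1", "r2"), ("p1", "p2")]
        between_pairs = [("r1", "p1"), ("r1", "p2"), ("r2", "p1"), ("r2", "p2")]
        wm = np.mean([ce.dice_coefficient(sets[a], sets[b])
                      for a, b in within_pairs])
        bm = np.mean([ce.dice_coefficient(sets[a], sets[b])
                      for a, b in between_pairs])
        c = ce.dsc_contrast(sim, lab)
        assert c.within_mean == pytest.approx(wm)
        assert c.between_mean == pytest.approx(bm)
        assert c.n_within_pairs == 2 and c.n_between_pairs == 4
        # ancestor pairs are reported per class, not mixed into the contrast
        assert "ancestor|rho" in c.per_class_means

    def test_empty_pair_policy(self):
        table = pd.DataFrame(
            [[1, 0], [1, 1], [0, 0], [0, 0]],
            index=["r1", "r2", "p1", "p2"], columns=["a", "b"], dtype=np.int8,
        )
        pa = ce.PresenceAbsenceMatrix(table, "fixed", 0.85)
        sim = ce.similarity_matrix(pa)
        lab = make_labeling(
            r1=("rho", "f1"), r2=("rho", "f2"),
            p1=("rpoB", "f3"), p2=("rpoB", "f4"),
        )
        excl = ce.dsc_contrast(sim, lab, empty_pair_policy="exclude")
        zero = ce.dsc_contrast(sim, lab, empty_pair_policy="zero")
        # p1-p2 pair (both empty) only exists under the zero policy
        assert excl.n_within_pairs == 1
        assert zero.n_within_pairs == 2
        assert zero.within_mean < excl.within_mean or excl.within_mean == 0


class TestDscRandomization:
    def test_perfect_structure_gives_minimal_p(self):
        pa = make_pa({
            **{f"r{i}": {"a": 1, "b": 1} for i in range(4)},
            **{f"p{i}": {"c": 1, "d": 1} for i in range(4)},
        })
        lab = make_labeling(
            **{f"r{i}": ("rho", f"f{i // 2}") for i in range(4)},
            **{f"p{i}": ("rpoB", f"g{i // 2}") for i in range(4)},
        )
        sim = ce.similarity_matrix(pa)
        res = ce.dsc_randomization_test(sim, lab, n_iter=500, seed=1)
        assert res.observed == 1.0
        assert res.p_value <= 0.05
        assert res.p_value_smoothed <= (res.p_value * res.n_iterations + 1) / (
            res.n_iterations + 1
        )

    def test_four_populations_match_exhaustive_enumeration(self):
        pa = make_pa({
            "r1": {"a": 1, "b": 1}, "r2": {"a": 1},
            "p1": {"b": 1, "c": 1}, "p2": {"c": 1},
        })
        lab = make_labeling(
            r1=("rho", "f1"), r2=("rho", "f2"),
            p1=("rpoB", "f3"), p2=("rpoB", "f4"),
        )
        sim = ce.similarity_matrix(pa)
        sets = pa.region_sets()
        pops = ["r1", "r2", "p1", "p2"]

        def stat(rho_pair):
            rho = set(rho_pair)
            rpob = set(pops) - rho
            within = [
                ce.dice_coefficient(sets[a], sets[b])
                for grp in (rho, rpob)
                for a, b in itertools.combinations(sorted(grp), 2)
            ]
            between = [
                ce.dice_coefficient(sets[a], sets[b])
                for a in rho for b in rpob
            ]
            return np.mean(within) - np.mean(between)

        observed = stat(("r1", "r2"))
        null = [stat(pair) for pair in itertools.combinations(pops, 2)]
        p_oracle = np.mean([s >= observed for s in null])

        res = ce.dsc_randomization_test(sim, lab, n_iter=5000, seed=0)
        assert res.exact
        assert res.observed == pytest.approx(observed)
        assert res.p_value == pytest.approx(p_oracle)

    def test_value_permutation_mode_runs(self):
        pa = make_pa({
            "r1": {"a": 1, "b": 1}, "r2": {"a": 1}, "r3": {"b": 1},
            "p1": {"b": 1, "c": 1}, "p2": {"c": 1}, "p3": {"a": 1, "c": 1},
        })
        lab = make_labeling(
            r1=("rho", "f1"), r2=("rho", "f1"), r3=("rho", "f2"),
            p1=("rpoB", "f3"), p2=("rpoB", "f3"), p3=("rpoB", "f4"),
        )
        sim = ce.similarity_matrix(pa)
        res = ce.dsc_randomization_test(
            sim, lab, n_iter=200, seed=3, permute="values"
        )
        assert 0.0 <= res.p_value <= 1.0

    def test_deterministic_given_seed(self, study_dataset):
        pa = ce.presence_absence(study_dataset.mutation_table)
        sim = ce.similarity_matrix(pa)
        a = ce.dsc_randomization_test(sim, study_dataset.labeling,
                                      n_iter=200, seed=9)
        b = ce.dsc_randomization_test(sim, study_dataset.labeling,
                                      n_iter=200, seed=9)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_sample, b.null_sample)


class TestAnosim:
    def test_separated_groups_give_r_one(self):
        d = np.array([
            [0, 1, 5, 6],
            [1, 0, 7, 8],
            [5, 7, 0, 2],
            [6, 8, 2, 0],
        ], float)
        res = ce.anosim(d, ["a", "a", "b", "b"], n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_four_point_toy_matches_hand_ranks(self):
        # condensed distances: d01=1, d02=2, d03=3, d12=4, d13=5, d23=3
        # ranks: 1, 2, 3.5, 5, 6, 3.5; within = {d01, d23} -> mean 2.25
        # between mean = 4.125; R = (4.125 - 2.25) / 3 = 0.625
        d = np.array([
            [0, 1, 2, 3],
            [1, 0, 4, 5],
            [2, 4, 0, 3],
            [3, 5, 3, 0],
        ], float)
        res = ce.anosim(d, ["a", "a", "b", "b"], n_permutations=99, seed=0)
        assert res.r == pytest.approx(0.625)

    def test_matches_skbio_on_random_matrices(self):
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import anosim as skb_anosim

        rng = np.random.default_rng(0)
        for n, k in [(8, 2), (9, 3), (12, 3)]:
            x = rng.normal(size=(n, 4))
            d = squareform(pdist(x))
            groups = [f"g{i % k}" for i in range(n)]
            ours = ce.anosim(d, groups, n_permutations=9, seed=0).r
            ids = [str(i) for i in range(n)]
            theirs = float(
                skb_anosim(SkDM(d, ids=ids), grouping=groups,
                           permutations=0)["test statistic"]
            )
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        from scipy.spatial.distance import pdist, squareform

        x = rng.normal(size=(10, 3))
        d = squareform(pdist(x))
        groups = ["a"] * 5 + ["b"] * 5
        r1 = ce.anosim(d, groups, n_permutations=9, seed=0).r
        r2 = ce.anosim(d**2, groups, n_permutations=9, seed=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_random_labels_give_mean_r_near_zero(self):
        rng = np.random.default_rng(5)
        from scipy.spatial.distance import pdist, squareform

        x = rng.normal(size=(10, 3))
        d = squareform(pdist(x))
        rs = []
        for _ in range(500):
            groups = rng.permutation(["a"] * 5 + ["b"] * 5)
            rs.append(ce.anosim(d, groups, n_permutations=0 + 1, seed=0).r)
        rs = np.asarray(rs)
        assert abs(rs.mean()) <= 3 * rs.std() / np.sqrt(len(rs))

    def test_identical_distances_give_zero_r_unit_p(self):
        d = np.ones((4, 4)) - np.eye(4)
        res = ce.anosim(d, ["a", "a", "b", "b"], n_permutations=19, seed=0)
        assert res.r == 0.0 and res.p_value == 1.0

    def test_smoothed_p_minimum(self):
        d = np.array([
            [0, 1, 5, 6],
            [1, 0, 7, 8],
            [5, 7, 0, 2],
            [6, 8, 2, 0],
        ], float)
        res = ce.anosim(d, ["a", "a", "b", "b"], n_permutations=999, seed=0)
        assert res.p_value >= 1 / (res.n_permutations + 1)


def _fet_two_sided_oracle(a, b, c, d):
    """Sum hypergeometric probabilities of tables at least as extreme."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)

    def pr(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > n - r1:
            return 0.0
        return comb(r1, x) * comb(n - r1, c1 - x) / denom

    p_obs = pr(a)
    return sum(
        pr(x) for x in range(0, min(r1, c1) + 1)
        if pr(x) <= p_obs * (1 + 1e-9)
    )


class TestRegionEnrichment:
    def _pa_and_lab(self, hits_rho, hits_rpob, n=5):
        table = {}
        lab = {}
        for i in range(n):
            p = f"r{i}"
            table[p] = {"target": 1 if i < hits_rho else 0, "bg": 1}
            lab[p] = ("rho", "f_rho")
        for i in range(n):
            p = f"p{i}"
            table[p] = {"target": 1 if i < hits_rpob else 0, "bg": 1}
            lab[p] = ("rpoB", "f_rpob")
        return make_pa(table), ce.GroupLabeling(lab)

    def test_five_vs_zero_of_five(self):
        pa, lab = self._pa_and_lab(5, 0, n=5)
        df = ce.region_enrichment(pa, lab)
        row = df[df.region_id == "target"].iloc[0]
        assert row.p_value == pytest.approx(2 / 252)
        assert row.pathway_enriched == "rho"

    def test_three_vs_zero_of_three(self):
        pa, lab = self._pa_and_lab(3, 0, n=3)
        df = ce.region_enrichment(pa, lab)
        row = df[df.region_id == "target"].iloc[0]
        assert row.p_value == pytest.approx(0.10)

    def test_equal_proportions_give_p_one(self):
        pa, lab = self._pa_and_lab(3, 3, n=5)
        df = ce.region_enrichment(pa, lab)
        row = df[df.region_id == "target"].iloc[0]
        assert row.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle_up_to_n_12(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n_a = int(rng.integers(2, 7))
            n_b = int(rng.integers(2, 7))
            a = int(rng.integers(0, n_a + 1))
            b = int(rng.integers(0, n_b + 1))
            if a + b == 0:
                continue
            pa, lab = None, None
            table = {f"r{i}": {"t": 1 if i < a else 0, "bg": 1}
                     for i in range(n_a)}
            table.update({f"p{i}": {"t": 1 if i < b else 0, "bg": 1}
                          for i in range(n_b)})
            labd = {f"r{i}": ("rho", "f") for i in range(n_a)}
            labd.update({f"p{i}": ("rpoB", "g") for i in range(n_b)})
            df = ce.region_enrichment(make_pa(table), ce.GroupLabeling(labd))
            got = df[df.region_id == "t"].iloc[0].p_value
            want = _fet_two_sided_oracle(a, n_a - a, b, n_b - b)
            assert got == pytest.approx(want, abs=1e-10)

    def test_untested_regions_excluded_and_sorted(self, study_dataset):
        pa = ce.presence_absence(study_dataset.mutation_table)
        df = ce.region_enrichment(pa, study_dataset.labeling)
        assert (df.p_value.diff().dropna() >= 0).all()
        assert (df.q_value >= df.p_value - 1e-15).all()
        # every tested region is mutated in >=1 rho or rpoB population
        assert ((df.n_mutated_a + df.n_mutated_b) >= 1).all()


class TestBhFdr:
    def test_reported_smallest_adjusted_value(self):
        # 163-test family, smallest raw p = 8.20e-5 -> adjusted 0.013
        raw = [8.20e-5, 0.002, 0.005, 0.005, 0.022, 0.028, 0.034]
        raw += list(np.linspace(0.05, 1.0, 156))
        adj = ce.bh_fdr(raw)
        assert adj[0] == pytest.approx(8.20e-5 * 163, rel=1e-9)
        assert round(adj[0], 3) == 0.013

    def test_single_p_unchanged(self):
        assert ce.bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_step_up_by_hand(self):
        adj = ce.bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_empty_input(self):
        assert len(ce.bh_fdr([])) == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_never_below_raw_and_monotone(self, ps):
        adj = ce.bh_fdr(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestTypeProportionTest:
    def test_identical_proportions_give_p_one(self):
        spectrum = pd.DataFrame(
            {"rho": [40, 30, 20], "rpoB": [40, 30, 20]},
            index=["intergenic", "nonsynonymous", "frameshift"],
        )
        res = ce.type_proportion_test(spectrum)
        assert res["p_value"] == pytest.approx(1.0)

    def test_2x2_agrees_with_fisher_within_mc_error(self):
        from scipy.stats import fisher_exact

        spectrum = pd.DataFrame(
            {"rho": [8, 2], "rpoB": [3, 7]},
            index=["intergenic", "nonsynonymous"],
        )
        res = ce.type_proportion_test(spectrum, n_monte_carlo=20000, seed=1)
        assert res["method"].endswith("(Monte-Carlo p)")
        _, p_fet = fisher_exact([[8, 2], [3, 7]])
        assert res["p_value"] == pytest.approx(p_fet, abs=0.03)

    def test_zero_margin_dropped(self):
        spectrum = pd.DataFrame(
            {"rho": [40, 0, 20], "rpoB": [40, 0, 25]},
            index=["intergenic", "synonymous", "frameshift"],
        )
        res = ce.type_proportion_test(spectrum)
        assert res["n_dropped_margins"] == 1

    def test_spectra_from_one_multinomial_are_calibrated(self):
        rng = np.random.default_rng(8)
        probs = np.array([0.5, 0.3, 0.2])
        rejections = 0
        n_sims = 200
        for i in range(n_sims):
            a = rng.multinomial(300, probs)
            b = rng.multinomial(300, probs)
            spectrum = pd.DataFrame({"rho": a, "rpoB": b})
            res = ce.type_proportion_test(spectrum, seed=i)
            rejections += res["p_value"] < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09
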