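from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.spatial.distance import squareform

import connectomdmr as cdm
from connectomdmr.errors import InvalidParameterError, ValidationError


def hand_example():
    """Two groups of two; d^2 = 1 within each group, 4 across groups."""
    d2 = np.full((4, 4), 4.0)
    d2[0, 1] = d2[1, 0] = 1.0
    d2[2, 3] = d2[3, 2] = 1.0
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2), cdm.GroupDesign.from_labels(["g1", "g1", "g2", "g2"])


class TestSumsOfSquares:
    def test_single_pair(self):
        d = np.array([[0.0, np.sqrt(2.0)], [np.sqrt(2.0), 0.0]])
        assert cdm.total_ss(d) == pytest.approx(1.0)

    def test_zero_distances(self):
        assert cdm.total_ss(np.zeros((5, 5))) == 0.0

    def test_hand_worked_total(self):
        d, _ = hand_example()
        # six unordered pairs: 1 + 1 + 4*4, divided by N=4
        assert cdm.total_ss(d) == pytest.approx(4.5)

    def test_hand_worked_within(self):
        d, design = hand_example()
        assert cdm.within_ss(d, design) == pytest.approx(1.0)

    def test_all_zero_within_distances(self):
        d = np.full((4, 4), 2.0)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.0
        np.fill_diagonal(d, 0.0)
        design = cdm.GroupDesign.from_labels(["a", "a", "b", "b"])
        assert cdm.within_ss(d, design) == 0.0

    def test_single_group_within_equals_total(self, rng):
        d = squareform(rng.uniform(0.1, 2.0, size=15))
        design = cdm.GroupDesign.from_labels(["only"] * 6)
        assert cdm.within_ss(d, design) == pytest.approx(cdm.total_ss(d), abs=1e-12)

    def test_misaligned_design_rejected(self):
        d, _ = hand_example()
        with pytest.raises(ValidationError):
            cdm.within_ss(d, cdm.GroupDesign.from_labels(["a", "a", "b", "b", "b"]))


class TestPseudoF:
    def test_hand_worked_decomposition(self):
        d, design = hand_example()
        res = cdm.pseudo_f(d, design)
        assert res.ss_total == pytest.approx(4.5)
        assert res.ss_within == pytest.approx(1.0)
        assert res.ss_between == pytest.approx(3.5)
        assert res.pseudo_f == pytest.approx(7.0)

    def test_perfect_separation_flagged_infinite(self):
        d = np.full((4, 4), 2.0)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.0
        np.fill_diagonal(d, 0.0)
        design = cdm.GroupDesign.from_labels(["a", "a", "b", "b"])
        res = cdm.pseudo_f(d, design)
        assert np.isinf(res.pseudo_f)
        assert "perfect-separation" in res.flags

    def test_degenerate_all_zero_flagged(self):
        design = cdm.GroupDesign.from_labels(["a", "a", "b", "b"])
        res = cdm.pseudo_f(np.zeros((4, 4)), design)
        assert np.isnan(res.pseudo_f)
        assert "degenerate" in res.flags

    def test_single_group_rejected(self):
        with pytest.raises(InvalidParameterError, match="2 groups"):
            cdm.pseudo_f(np.zeros((4, 4)), cdm.GroupDesign.from_labels(["a"] * 4))

    def test_misaligned_matrix_rejected(self):
        with pytest.raises(ValidationError):
            cdm.pseudo_f(
                np.zeros((5, 5)),
                cdm.GroupDesign.from_labels(["a", "a", "b", "b", "c", "c"]),
            )

    def test_anova_equivalence_on_univariate_data(self, rng):
        """Euclidean distance on univariate data reduces pseudo-F to ANOVA F."""
        for _ in range(25):
            m = rng.integers(3, 6)
            sizes = rng.integers(4, 11, size=m)
            samples = [rng.normal(rng.normal(0, 1), 1.0, size=s) for s in sizes]
            x = np.concatenate(samples)
            labels = np.repeat([f"g{j}" for j in range(m)], sizes)
            d = np.abs(x[:, None] - x[None, :])
            res = cdm.pseudo_f(d, cdm.GroupDesign.from_labels(labels))
            f_classic = stats.f_oneway(*samples).statistic
            assert res.pseudo_f == pytest.approx(f_classic, abs=1e-8)

    def test_identity_ssb_and_scale_invariance(self, rng):
        d = squareform(rng.uniform(0.05, 2.0, size=45))
        design = cdm.GroupDesign.from_labels(["a"] * 4 + ["b"] * 3 + ["c"] * 3)
        res = cdm.pseudo_f(d, design)
        assert res.ss_between == pytest.approx(res.ss_total - res.ss_within, abs=1e-12)
        scaled = cdm.pseudo_f(3.7 * d, design)
        assert scaled.pseudo_f == pytest.approx(res.pseudo_f, rel=1e-12)

    def test_gower_trace_cross_check(self, rng):
        """Pairwise-sum SS formulas match the centred-matrix trace formulation."""
        for _ in range(10):
            n = int(rng.integers(6, 12))
            d = squareform(rng.uniform(0.05, 2.0, size=n * (n - 1) // 2))
            labels = rng.choice(["a", "b"], size=n)
            while min((labels == "a").sum(), (labels == "b").sum()) < 2:
                labels = rng.choice(["a", "b"], size=n)
            design = cdm.GroupDesign.from_labels(labels)
            g = cdm.gower_center(d)
            assert np.trace(g) == pytest.approx(cdm.total_ss(d), abs=1e-8)
            ssw_trace = 0.0
            for lab in ("a", "b"):
                idx = np.where(labels == lab)[0]
                ssw_trace += np.trace(cdm.gower_center(d[np.ix_(idx, idx)]))
            assert ssw_trace == pytest.approx(cdm.within_ss(d, design), abs=1e-8)


class TestPermutationTest:
    def test_boundary_p_when_no_permutation_exceeds(self):
        d, design = hand_example()  # F_obs = 7 is the maximum over relabelings
        # every permuted F <= F_obs, so under the strict-greater tie rule the
        # add-one p attains its floor 1/(1+n_perm)
        strict = cdm.permutation_test(d, design, n_perm=99, seed=0, tie_rule="gt")
        assert strict.p_raw == pytest.approx(1 / 100)
        # under ">=", relabelings equivalent to the original (1/3 of the six
        # balanced splits) tie with F_obs
        res = cdm.permutation_test(d, design, n_perm=99, seed=0)
        assert res.p_raw == pytest.approx(1 / 3, abs=0.15)

    def test_literal_convention_counts_over_n_perm(self):
        d, design = hand_example()
        res = cdm.permutation_test(
            d, design, n_perm=99, seed=0, tie_rule="gt", p_convention="literal"
        )
        assert res.p_raw == 0.0

    def test_group_preserving_relabeling_ties_exactly(self, rng):
        """A permutation that maps each group onto itself reproduces F_obs."""
        n = 8
        d = squareform(rng.uniform(0.1, 2.0, size=n * (n - 1) // 2))
        design = cdm.GroupDesign.from_labels(["a"] * 4 + ["b"] * 4)
        res = cdm.permutation_test(d, design, n_perm=500, seed=1, tie_rule="ge")
        swapped = cdm.GroupDesign.from_labels(["b"] * 4 + ["a"] * 4)
        f_swapped = cdm.pseudo_f(d, swapped).pseudo_f
        assert f_swapped == pytest.approx(res.pseudo_f, rel=1e-12)

    def test_permuting_labels_equals_permuting_distance_rows(self, rng):
        n = 9
        d = squareform(rng.uniform(0.1, 2.0, size=n * (n - 1) // 2))
        labels = np.array(["a"] * 4 + ["b"] * 5)
        perm = rng.permutation(n)
        inverse = np.argsort(perm)
        f_perm_labels = cdm.pseudo_f(
            d, cdm.GroupDesign.from_labels(labels[perm])
        ).pseudo_f
        f_perm_dist = cdm.pseudo_f(
            d[np.ix_(inverse, inverse)], cdm.GroupDesign.from_labels(labels)
        ).pseudo_f
        assert f_perm_labels == pytest.approx(f_perm_dist, rel=1e-10)

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        """N=6, two groups of 3: MC p within 3 SE of the exact 20-split p."""
        n = 6
        d = squareform(rng.uniform(0.1, 2.0, size=15))
        labels = np.array(["a"] * 3 + ["b"] * 3)
        design = cdm.GroupDesign.from_labels(labels)
        f_obs = cdm.pseudo_f(d, design).pseudo_f
        f_all = []
        for combo in combinations(range(n), 3):
            lab = np.array(["b"] * n)
            lab[list(combo)] = "a"
            f_all.append(cdm.pseudo_f(d, cdm.GroupDesign.from_labels(lab)).pseudo_f)
        p_exact = np.mean(np.array(f_all) >= f_obs - 1e-12)
        res = cdm.permutation_test(d, design, n_perm=10_000, seed=7)
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(res.p_raw - p_exact) <= 3 * se + 1e-4

    def test_invalid_n_perm_rejected(self):
        d, design = hand_example()
        with pytest.raises(InvalidParameterError):
            cdm.permutation_test(d, design, n_perm=0)


class TestFDR:
    def test_single_p_unchanged(self):
        assert cdm.fdr_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_step_up(self):
        adjusted = cdm.fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adjusted, [0.03, 0.03, 0.03])

    def test_bounds_and_monotonicity(self, rng):
        p = rng.uniform(0.001, 1.0, size=20)
        q = cdm.fdr_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= np.minimum(1.0, 20 * p) + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [np.nan, 0.5], []])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            cdm.fdr_adjust(bad)


class TestRunMDMR:
    def test_one_result_per_module_with_fdr(self, small_cohort, small_matrices):
        results = cdm.run_mdmr(small_matrices, small_cohort, n_perm=99, seed=5)
        assert len(results) == 6
        assert [r.module for r in results] == list(range(1, 7))
        for r in results:
            assert 0 < r.p_raw <= 1
            assert r.p_fdr >= r.p_raw - 1e-15
            assert r.ss_between == pytest.approx(r.ss_total - r.ss_within, abs=1e-10)

    def test_deterministic_given_seed(self, small_cohort, small_matrices):
        a = cdm.run_mdmr(small_matrices, small_cohort, n_perm=99, seed=5)
        b = cdm.run_mdmr(small_matrices, small_cohort, n_perm=99, seed=5)
        assert [r.p_raw for r in a] == [r.p_raw for r in b]
        c = cdm.run_mdmr(small_matrices, small_cohort, n_perm=99, seed=6)
        assert [r.p_raw for r in a] != [r.p_raw for r in c]

    def test_effect_recovery_single_run(self):
        spec = cdm.CohortSpec(n_modules=20, group_sizes={"A": 15, "B": 15}, seed=42)
        template = cdm.make_template(spec, edge_mean=50, seed=43)
        effect = cdm.EffectSpec(
            target_module=5,
            affected_partners=cdm.default_partners(5, 20),
            multiplier=0.4,
            applies_to_groups=frozenset({"B"}),
        )
        cohort, mats = cdm.generate_cohort(spec, template, [effect])
        results = cdm.run_mdmr(mats, cohort, n_perm=199, seed=44)
        assert cdm.rank_modules(results)[0].module == 5
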