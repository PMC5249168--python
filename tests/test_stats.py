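"""Ensemble-comparison statistics: closed forms, identities, aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from rotamerlab import (BOLTZMANN_KCAL, RotamerDistribution, XrayAssignment,
                        build_distribution, classify_region, compare_residue,
                        conf_entropy, delta_entropy, kl_divergence,
                        likelihood_quotient, likelihood_score,
                        overlap_coefficient, residue_composition,
                        rotamer_agreement, segment_uncertainty,
                        summarize_sets)
from rotamerlab.stats import dominant_states
from rotamerlab.torsions import ResidueId, RotamerStateSeries

RID = ResidueId("A", 1, "LEU")


def _dist(p, condition="solution", rid=RID, n_frames=100):
    return RotamerDistribution(rid, condition, np.asarray(p, dtype=float),
                               n_frames)


def _series(states, condition="solution", copy="A1", rid=RID):
    return RotamerStateSeries(rid, condition, copy, np.asarray(states))


probability_vectors = st.integers(2, 4).flatmap(
    lambda n: st.lists(st.floats(0.001, 1.0), min_size=n, max_size=n)
).map(lambda w: np.array(w) / np.sum(w))


class TestBuildDistribution:
    def test_counts_normalized_with_zero_states_retained(self):
        d = build_distribution(_series([1, 1, 2, 2]), 4)
        assert d.probabilities == pytest.approx([0.5, 0.5, 0.0, 0.0])

    def test_pooling_across_copies(self):
        d = build_distribution([_series([1, 1], copy="A1"),
                                _series([2, 2], copy="A2")], 4)
        assert d.probabilities == pytest.approx([0.5, 0.5, 0.0, 0.0])
        assert d.n_frames == 4

    def test_empty_window_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_distribution(_series([1, 2, 3]), 4, window=(3, 3))

    def test_mixture_frequencies_within_three_binomial_se(self, rng):
        w = np.array([0.7, 0.3])
        states = rng.choice([1, 2], size=10_000, p=w)
        d = build_distribution(_series(states), 2)
        se = np.sqrt(w * (1 - w) / 10_000)
        assert np.all(np.abs(d.probabilities - w) <= 3 * se)


class TestLikelihood:
    def test_uniform_distribution_ratio_is_one(self):
        dists = {RID: _dist([0.25] * 4)}
        xray = {RID: XrayAssignment(RID, 2)}
        assert likelihood_score(dists, xray) == pytest.approx(1.0)

    def test_delta_distribution_ratio_is_n(self):
        dists = {RID: _dist([0, 1, 0, 0])}
        xray = {RID: XrayAssignment(RID, 2)}
        assert likelihood_score(dists, xray) == pytest.approx(4.0)

    def test_two_residue_hand_computation(self):
        r2 = ResidueId("A", 2, "SER")
        dists = {RID: _dist([0.8, 0.1, 0.05, 0.05]),
                 r2: _dist([0.3, 0.3, 0.4], rid=r2)}
        xray = {RID: XrayAssignment(RID, 1), r2: XrayAssignment(r2, 1)}
        # (0.8*4 + 0.3*3) / 2 = 2.05
        assert likelihood_score(dists, xray) == pytest.approx(2.05)

    def test_residue_without_xray_state_is_excluded(self):
        r2 = ResidueId("A", 2, "SER")
        dists = {RID: _dist([0.25] * 4), r2: _dist([1, 0, 0], rid=r2)}
        xray = {RID: XrayAssignment(RID, 1)}
        assert likelihood_score(dists, xray) == pytest.approx(1.0)

    @pytest.mark.parametrize("lc,ls,expected",
                             [(2.0, 2.0, 1.0), (3.42, 2.49, 1.37),
                              (2.0, 4.0, 0.5)])
    def test_quotient(self, lc, ls, expected):
        assert likelihood_quotient(lc, ls) == pytest.approx(expected, abs=5e-3)

    def test_quotient_degenerate_solution_likelihood(self):
        with pytest.raises(ValueError):
            likelihood_quotient(1.0, 0.0)


class TestOverlapAndKL:
    def test_identical_distributions_full_overlap(self):
        p = np.array([0.2, 0.3, 0.5])
        assert overlap_coefficient(p, p) == pytest.approx(1.0)

    def test_disjoint_supports_zero_overlap(self):
        assert overlap_coefficient([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_term_by_term_min_sum(self):
        assert overlap_coefficient([0.6, 0.4, 0.0], [0.2, 0.3, 0.5]) == \
            pytest.approx(0.5)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            overlap_coefficient([1.0], [0.5, 0.5])

    @given(p=probability_vectors, q=probability_vectors)
    @settings(max_examples=60, deadline=None)
    def test_overlap_symmetric_bounded_and_l1_identity(self, p, q):
        if len(p) != len(q):
            q = np.resize(q, len(p))
            q = q / q.sum()
        oc = overlap_coefficient(p, q)
        assert oc == pytest.approx(overlap_coefficient(q, p))
        assert 0.0 <= oc <= 1.0 + 1e-12
        assert 1.0 - oc == pytest.approx(0.5 * np.abs(p - q).sum(), abs=1e-10)

    def test_kl_zero_iff_identical(self):
        p = np.array([0.5, 0.3, 0.2])
        assert kl_divergence(p, p) == pytest.approx(0.0)
        assert kl_divergence(p, [0.2, 0.3, 0.5]) > 0

    def test_kl_closed_form_ln2(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == \
            pytest.approx(math.log(2))

    def test_kl_unsmoothed_zero_bin_is_infinite(self):
        assert kl_divergence([0.5, 0.5], [1.0, 0.0]) == math.inf

    def test_kl_pseudocount_smoothing_is_finite(self):
        assert np.isfinite(kl_divergence([0.5, 0.5], [1.0, 0.0],
                                         pseudocount=0.01))

    def test_kl_anticorrelates_with_overlap_on_synthetic_cohort(self, rng):
        ocs, kls = [], []
        for _ in range(60):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            ocs.append(overlap_coefficient(p, q))
            kls.append(kl_divergence(p, q, pseudocount=1e-4))
        rho = sps.spearmanr(ocs, kls).statistic
        assert rho < 0


class TestEntropy:
    def test_delta_distribution_zero_entropy(self):
        assert conf_entropy([0, 1, 0, 0, 0]) == pytest.approx(0.0)

    @pytest.mark.parametrize("n,expected", [(5, 0.959), (3, 0.655)])
    def test_uniform_closed_form(self, n, expected):
        ts = conf_entropy(np.ones(n) / n)
        assert ts == pytest.approx(BOLTZMANN_KCAL * 300 * math.log(n))
        assert ts == pytest.approx(expected, abs=1e-3)

    def test_uniform_maximizes_entropy(self, rng):
        n = 6
        uniform = conf_entropy(np.ones(n) / n)
        for _ in range(25):
            assert conf_entropy(rng.dirichlet(np.ones(n))) <= uniform + 1e-12

    def test_freezing_in_crystal_loses_uniform_entropy(self):
        sol = _dist(np.ones(5) / 5)
        cry = _dist([1, 0, 0, 0, 0], "crystal")
        assert delta_entropy(sol, cry) == pytest.approx(-0.959, abs=1e-3)

    def test_antisymmetric_under_condition_swap(self):
        a = _dist([0.6, 0.3, 0.1])
        b = _dist([0.2, 0.5, 0.3], "crystal")
        assert delta_entropy(a, b) == pytest.approx(
            -delta_entropy(_dist(b.probabilities),
                           _dist(a.probabilities, "crystal")))


class TestAgreementAndRegions:
    def test_xray_at_argmax_agrees(self):
        d = _dist([0.6, 0.3, 0.1])
        assert rotamer_agreement(d, XrayAssignment(RID, 1))

    def test_xray_at_third_rank_disagrees(self):
        d = _dist([0.5, 0.3, 0.15, 0.05])
        assert not rotamer_agreement(d, XrayAssignment(RID, 3))

    def test_xray_outside_top_two_like_frozen_lysine_disagrees(self):
        # the top two sampled states differ from the X-ray state
        d = _dist([0.55, 0.40, 0.05, 0.0])
        assert not rotamer_agreement(d, XrayAssignment(RID, 4))

    def test_second_rank_ties_all_included(self):
        d = _dist([0.5, 0.2, 0.2, 0.1])
        assert rotamer_agreement(d, XrayAssignment(RID, 2))
        assert rotamer_agreement(d, XrayAssignment(RID, 3))

    def test_unvisited_states_never_dominate(self):
        assert dominant_states(np.array([1.0, 0, 0, 0])) == {1}

    @pytest.mark.parametrize("oc,tds,region", [
        (0.83, -0.10, "I"),    # non-contacting leucine: no effect
        (0.32, -1.06, "III"),  # contacting glutamine: conformation+dynamics
        (0.06, -0.36, "II"),   # contacting glutamate: conformation only
        (0.9, 1.2, "IV"),
        (0.5, 0.5, "I"),       # boundaries inclusive toward I
    ])
    def test_quadrant_classification(self, oc, tds, region):
        assert classify_region(oc, tds) == region

    def test_oc_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_region(1.2, 0.0)


class TestSegmentUncertainty:
    def test_identical_halves_zero_width_bounds(self):
        sol = {RID: [_series([1, 2, 1, 2])]}
        cry = {RID: [_series([1, 1, 1, 1], "crystal")]}
        bounds, _ = segment_uncertainty(sol, cry, {RID: 3}, "oc")
        low, high = bounds[RID]
        assert low == high == pytest.approx(0.5)

    def test_odd_frame_count_first_half_gets_extra(self):
        sol = {RID: [_series([1, 1, 2, 2, 2])]}
        cry = {RID: [_series([1, 1, 1, 1, 1], "crystal")]}
        bounds, _ = segment_uncertainty(sol, cry, {RID: 2}, "oc")
        # halves: [1,1,2] vs [2,2] -> OC 2/3 and 0
        assert bounds[RID] == pytest.approx((0.0, 2 / 3))

    def test_too_few_frames_is_error(self):
        sol = {RID: [_series([1])]}
        cry = {RID: [_series([1], "crystal")]}
        with pytest.raises(ValueError):
            segment_uncertainty(sol, cry, {RID: 2}, "oc")

    def test_stationary_ensembles_have_reproducible_halves(self, rng):
        """Cross-segment correlation of OC over residues approaches 1 for
        long stationary series."""
        sol, cry, n_states = {}, {}, {}
        for i in range(20):
            rid = ResidueId("A", i + 1, "LEU")
            w1 = rng.dirichlet(np.ones(5))
            w2 = rng.dirichlet(np.ones(5))
            sol[rid] = [_series(rng.choice(5, 10_000, p=w1) + 1, rid=rid)]
            cry[rid] = [_series(rng.choice(5, 10_000, p=w2) + 1, "crystal",
                                rid=rid)]
            n_states[rid] = 5
        bounds, r = segment_uncertainty(sol, cry, n_states, "oc")
        assert r >= 0.9
        for rid in sol:
            full = overlap_coefficient(
                build_distribution(sol[rid], 5).probabilities,
                build_distribution(cry[rid], 5).probabilities)
            low, high = bounds[rid]
            assert low - 0.05 <= full <= high + 0.05


class TestSummaries:
    def _cohort(self):
        rids = [ResidueId("A", i + 1, "LEU") for i in range(2)]
        dists_s, dists_c, xray, comparisons, contacting = {}, {}, {}, {}, {}
        specs = [((0.8, 0.2, 0, 0, 0), (1.0, 0, 0, 0, 0)),
                 ((0.4, 0.6, 0, 0, 0), (0.2, 0.4, 0.4, 0, 0))]
        for rid, (ws, wc) in zip(rids, specs):
            dists_s[rid] = _dist(ws, rid=rid)
            dists_c[rid] = _dist(wc, "crystal", rid=rid)
            xray[rid] = XrayAssignment(rid, 1)
            comparisons[rid] = compare_residue(dists_s[rid], dists_c[rid],
                                               xray[rid], kl_pseudocount=1e-3)
        contacting = {rids[0]: True, rids[1]: False}
        return rids, dists_s, dists_c, xray, comparisons, contacting

    def test_summary_matches_direct_recomputation(self):
        rids, ds, dc, xray, comparisons, contacting = self._cohort()
        summaries = summarize_sets(comparisons, ds, dc, xray, contacting, "A")
        by_set = {s.residue_set: s for s in summaries}
        assert set(by_set) == {"all", "contacting", "non-contacting"}
        all_ = by_set["all"]
        ocs = [comparisons[r].oc for r in rids]
        assert all_.n_residues == 2
        assert all_.mean_oc == pytest.approx(np.mean(ocs))
        assert all_.sd_oc == pytest.approx(np.std(ocs))  # population SD
        assert all_.likelihood_solution == pytest.approx(
            np.mean([0.8 * 5, 0.4 * 5]))
        assert all_.likelihood_quotient == pytest.approx(
            all_.likelihood_crystal / all_.likelihood_solution)

    def test_mean_and_population_sd_of_two_values(self):
        rids, ds, dc, xray, comparisons, contacting = self._cohort()
        comparisons[rids[0]].oc = 0.4
        comparisons[rids[1]].oc = 0.8
        s = {x.residue_set: x for x in summarize_sets(
            comparisons, ds, dc, xray, contacting, "A")}["all"]
        assert (s.mean_oc, s.sd_oc) == (pytest.approx(0.6), pytest.approx(0.2))

    def test_singleton_set_sd_zero(self):
        rids, ds, dc, xray, comparisons, contacting = self._cohort()
        s = {x.residue_set: x for x in summarize_sets(
            comparisons, ds, dc, xray, contacting, "A")}["contacting"]
        assert s.n_residues == 1
        assert s.sd_oc == 0.0


class TestComposition:
    def test_frequencies_normalized_and_ordered(self, library):
        rids = {"contacting": [ResidueId("A", 1, "GLN"),
                               ResidueId("A", 2, "GLN"),
                               ResidueId("A", 3, "SER"),
                               ResidueId("A", 4, "THR")],
                "non-contacting": []}
        comp = residue_composition(rids, library)
        assert comp["contacting"] == pytest.approx(
            {"GLN": 0.5, "SER": 0.25, "THR": 0.25})
        # GLN (9 states) must precede SER/THR (3 states) in the ordering
        keys = list(comp["contacting"])
        assert keys[0] == "GLN"
        assert sum(comp["contacting"].values()) == pytest.approx(1.0)
        assert comp["non-contacting"] == {}


class TestBruteForceToyOracle:
    def test_all_statistics_agree_with_direct_enumeration(self, rng):
        """On small explicit distributions every statistic equals the
        textbook loop-based computation to near machine precision."""
        for _ in range(20):
            n = int(rng.integers(2, 5))
            p = rng.dirichlet(np.ones(n))
            q = rng.dirichlet(np.ones(n))
            oc_direct = sum(min(p[i], q[i]) for i in range(n))
            kl_direct = sum(p[i] * math.log(p[i] / q[i]) for i in range(n)
                            if p[i] > 0)
            s_direct = -BOLTZMANN_KCAL * sum(
                p[i] * math.log(p[i]) for i in range(n) if p[i] > 0)
            assert overlap_coefficient(p, q) == pytest.approx(
                oc_direct, abs=1e-12)
            assert kl_divergence(p, q) == pytest.approx(kl_direct, abs=1e-12)
            assert conf_entropy(p) == pytest.approx(300 * s_direct, abs=1e-12)
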