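"""K2P pairwise distances, matrices, and group summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phylopop as pp
from phylopop.simulate import SimulationParams, simulate_split

from conftest import CPWP, EP


class TestK2P:
    def test_identical_sequences(self):
        result = pp.k2p("ACGT", "ACGT")
        assert result.d == 0.0
        assert result.L == 4 and result.s == 0 and result.v == 0

    def test_pure_transition_closed_form(self):
        # P = 0.25, Q = 0: d = -1/2 ln(0.5)
        result = pp.k2p("AAAA", "GAAA")
        assert result.d == pytest.approx(-0.5 * math.log(0.5), abs=1e-6)
        assert result.d == pytest.approx(0.346574, abs=1e-6)
        assert (result.s, result.v) == (1, 0)

    def test_pure_transversion_closed_form(self):
        # P = 0, Q = 0.25: d = -1/2 ln(0.75 sqrt(0.5))
        result = pp.k2p("AAAA", "CAAA")
        assert result.d == pytest.approx(-0.5 * math.log(0.75 * math.sqrt(0.5)), abs=1e-6)
        assert result.d == pytest.approx(0.317128, abs=1e-6)
        assert (result.s, result.v) == (0, 1)

    def test_16s_reference_vs_east_pacific_haplotype(self, table16s):
        """Type 1 vs Type 12: indel column deleted pairwise, 5 transitions."""
        ref, t12 = table16s.resolved_patterns()[0], table16s.resolved_patterns()[11]
        pad = "A" * (535 - 17)
        result = pp.k2p(ref + pad, t12 + pad)
        assert result.L == 534
        assert (result.s, result.v) == (5, 0)
        assert result.d == pytest.approx(-0.5 * math.log(1 - 2 * 5 / 534), abs=1e-9)
        assert result.d == pytest.approx(0.00945, abs=5e-5)

    def test_pairwise_deletion_of_gaps_and_n(self):
        result = pp.k2p("AC-TN", "ACGTA")
        assert result.L == 3

    def test_no_usable_sites_is_an_error(self):
        with pytest.raises(pp.UndefinedDistanceError):
            pp.k2p("NNNN", "ACGT")

    def test_saturated_pair_is_an_error(self):
        with pytest.raises(pp.SaturationError):
            pp.k2p("AAAA", "GGGG")

    @given(st.text(alphabet="ACGT-N", min_size=4, max_size=30).flatmap(
        lambda a: st.tuples(
            st.just(a), st.text(alphabet="ACGT-N", min_size=len(a), max_size=len(a))
        )
    ))
    @settings(deadline=None)
    def test_symmetry_and_mismatch_lower_bound(self, pair):
        a, b = pair
        try:
            fwd = pp.k2p(a, b)
        except (pp.UndefinedDistanceError, pp.SaturationError):
            return
        rev = pp.k2p(b, a)
        assert fwd.d == rev.d
        assert fwd.d >= (fwd.s + fwd.v) / fwd.L - 1e-12
        assert (fwd.d == 0.0) == (fwd.s == 0 and fwd.v == 0)

    def test_monotone_in_transitions(self):
        L = 100
        dists = [
            pp.k2p_from_counts(s, 2, L) for s in range(0, 20)
        ]
        assert all(b > a for a, b in zip(dists, dists[1:]))

    @given(st.integers(0, 3), st.integers(0, 3))
    def test_first_order_agreement_with_p_distance(self, s, v):
        L = 200
        d = pp.k2p_from_counts(s, v, L)
        p = (s + v) / L
        assert abs(d - p) <= 2.0 * p * p + 1e-12


class TestDistanceMatrix:
    def test_16s_groups_are_separated(self, aln16s, matrix16s):
        ep = aln16s.group_indices(EP)
        cw = aln16s.group_indices(CPWP)
        within_ep = max(matrix16s.d[i, j] for i in ep for j in ep if i < j)
        between = min(matrix16s.d[i, j] for i in ep for j in cw)
        assert within_ep < between
        assert np.allclose(matrix16s.d, matrix16s.d.T)
        assert np.all(np.diag(matrix16s.d) == 0.0)

    def test_identical_pair_gives_zero_matrix(self):
        aln = pp.Alignment(ids=["a", "b"], seqs=["ACGT", "ACGT"])
        assert pp.distance_matrix(aln).d.sum() == 0.0

    def test_all_n_sequence_names_offending_pair(self):
        aln = pp.Alignment(ids=["a", "bad"], seqs=["ACGT", "NNNN"])
        with pytest.raises(pp.UndefinedDistanceError, match="bad"):
            pp.distance_matrix(aln)

    def test_filler_base_does_not_affect_distances(self, table16s, groups16s):
        matrices = [
            pp.distance_matrix(pp.expand_table(table16s, groups16s, filler=f)).d
            for f in "AG"
        ]
        assert np.array_equal(matrices[0], matrices[1])


class TestGroupMean:
    def test_16s_means_match_published_rounding(self, aln16s, matrix16s):
        between = pp.group_mean(
            aln16s, "between", groups=(EP, CPWP), matrix=matrix16s, bootstrap=0
        )
        ep = pp.group_mean(aln16s, "within", group=EP, matrix=matrix16s, bootstrap=0)
        cw = pp.group_mean(aln16s, "within", group=CPWP, matrix=matrix16s, bootstrap=0)
        assert between.n_pairs == 7 * 13
        assert ep.n_pairs == 21
        assert cw.n_pairs == 78
        assert round(100 * between.mean_d, 1) == 1.0
        assert round(100 * ep.mean_d, 1) == 0.1
        assert round(100 * cw.mean_d, 1) == 0.5

    def test_mean_lies_within_pair_range(self, aln16s, matrix16s):
        summary = pp.group_mean(
            aln16s, "between", groups=(EP, CPWP), matrix=matrix16s, bootstrap=0
        )
        ep = aln16s.group_indices(EP)
        cw = aln16s.group_indices(CPWP)
        pair_d = [matrix16s.d[i, j] for i in ep for j in cw]
        assert min(pair_d) <= summary.mean_d <= max(pair_d)

    def test_identical_group_has_zero_mean_and_se(self):
        aln = pp.Alignment(
            ids=list("abc"), seqs=["ACGT"] * 3, group=["g"] * 3
        )
        summary = pp.group_mean(aln, "within", group="g", bootstrap=50, seed=0)
        assert summary.mean_d == 0.0
        assert summary.se_d == 0.0

    def test_bootstrap_se_is_seeded(self, aln16s):
        a = pp.group_mean(aln16s, "between", groups=(EP, CPWP), bootstrap=100, seed=3)
        b = pp.group_mean(aln16s, "between", groups=(EP, CPWP), bootstrap=100, seed=3)
        c = pp.group_mean(aln16s, "between", groups=(EP, CPWP), bootstrap=100, seed=4)
        assert a.se_d == b.se_d
        assert a.se_d != c.se_d
        assert a.se_d > 0

    def test_small_group_rejected(self, aln16s):
        with pytest.raises(pp.InputError):
            pp.group_mean(aln16s, "within", group="absent")


class TestOutgroupDistance:
    def test_identical_outgroup(self, aln16s):
        summary = pp.outgroup_distance(
            aln16s, aln16s.seqs[0], group=None, bootstrap=0
        )
        assert summary.n_pairs == 20
        assert summary.mean_d >= 0.0

    def test_outgroup_equal_to_members_gives_zero(self):
        aln = pp.Alignment(ids=["a", "b"], seqs=["ACGTACGT"] * 2, group=["g", "g"])
        summary = pp.outgroup_distance(aln, "ACGTACGT", bootstrap=0)
        assert summary.mean_d == 0.0

    def test_single_member_group(self):
        aln = pp.Alignment(ids=["a"], seqs=["ACGTACGTAC"], group=["g"])
        summary = pp.outgroup_distance(aln, "ACGTACGTAT", group="g", bootstrap=50)
        assert summary.n_pairs == 1
        assert summary.se_d is not None

    def test_simulated_outgroup_recovers_expected_distance(self):
        """A synthetic outgroup diverged by D sits within 3 bootstrap SE of D."""
        params = SimulationParams(
            L=2000, n_a=5, n_b=1, mu=0.02, kappa=5.0, T_split=2.0,
            theta_w=0.0, seed=11,
        )
        data = simulate_split(params)
        aln = data.alignment
        outgroup = aln.seqs[-1]
        members = aln.subset(aln.group_indices("A"))
        summary = pp.outgroup_distance(members, outgroup, bootstrap=200, seed=0)
        expected = 2.0 * params.mu * params.T_split
        assert abs(summary.mean_d - expected) <= 3.0 * summary.se_d
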