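"""Parameter validation, exact probability tables, and the scaling invariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikeburst import (
    ConstraintError,
    SpikingBurstingModel,
    dichotomous_joint,
    independent_spike_table,
    model_from_config,
    one_time_dist,
    rho_eps_convert,
    scaling_transform,
    subsystem_spike_table,
    two_time_joint,
    validate_dichotomous,
)
from spikeburst.model import SpikeTable, admissible_alpha_range

from conftest import brute_force_marginal


class TestDichotomousParams:
    def test_boundary_of_ps_max_is_valid(self):
        p = validate_dichotomous(0.5, 1.0)
        assert p.ps_max == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "ps,eps",
        [(0.6, 1.0), (0.0, 0.1), (1.0, 0.1), (0.5, -0.1), (0.2, 4.5)],
    )
    def test_invalid_pairs_rejected(self, ps, eps):
        with pytest.raises(ConstraintError):
            validate_dichotomous(ps, eps)

    def test_derived_quantities(self):
        p = validate_dichotomous(0.6, 0.5)
        assert p.pb == pytest.approx(0.4)
        assert p.eps_max == pytest.approx(2.0 / 3.0)
        assert p.rho == pytest.approx(0.5 * 0.6 / 0.4)

    def test_rho_eps_roundtrip_and_bounds(self):
        assert rho_eps_convert(0.3, 0.0) == 0.0
        # rho = 1 maps to the maximal eps = pb/ps
        assert rho_eps_convert(0.6, 1.0) == pytest.approx(2.0 / 3.0)
        eps = 0.1
        rho = rho_eps_convert(0.7, eps, "eps_to_rho")
        assert rho_eps_convert(0.7, rho, "rho_to_eps") == pytest.approx(eps, abs=1e-15)


class TestDichotomousJoint:
    def test_perfect_correlation_diagonal(self):
        jt = dichotomous_joint(validate_dichotomous(0.5, 1.0))
        np.testing.assert_allclose(jt.as_array(), [[0.5, 0.0], [0.0, 0.5]], atol=1e-15)

    def test_zero_eps_factorizes(self):
        jt = dichotomous_joint(validate_dichotomous(0.3, 0.0))
        np.testing.assert_allclose(
            jt.as_array(), np.outer([0.3, 0.7], [0.3, 0.7]), atol=1e-15
        )

    def test_row_sums_reproduce_marginals(self):
        jt = dichotomous_joint(validate_dichotomous(0.7, 0.1))
        assert jt.ps == pytest.approx(0.7, abs=1e-15)
        assert jt.pb == pytest.approx(0.3, abs=1e-15)
        assert jt.psb == jt.pbs

    def test_persistent_boundary_eps_max(self):
        ps = 0.4
        jt = dichotomous_joint(validate_dichotomous(ps, (1 - ps) / ps))
        assert jt.psb == pytest.approx(0.0, abs=1e-15)


class TestSpikeTable:
    def test_uniform_half_probabilities(self):
        t = independent_spike_table([0.5, 0.5])
        np.testing.assert_allclose(t.probs, 0.25)

    def test_equal_rate_from_target_s1(self):
        s1 = 0.1
        t = independent_spike_table([s1 ** (1 / 6)] * 6)
        assert t.s1 == pytest.approx(s1, rel=1e-12)

    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=5))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_table_normalized_for_any_rates(self, rates):
        t = independent_spike_table(rates)
        assert t.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(t.probs >= 0)

    def test_subsystem_marginal_matches_bruteforce(self):
        t = independent_spike_table([0.2, 0.35, 0.5, 0.65])
        for mask in (0b0011, 0b0101, 0b1010, 0b1001, 0b0110):
            sub = subsystem_spike_table(t, mask)
            np.testing.assert_allclose(
                sub.probs, brute_force_marginal(t.probs, 4, mask), atol=1e-14
            )

    def test_full_mask_is_identity(self):
        t = independent_spike_table([0.2, 0.7])
        np.testing.assert_allclose(subsystem_spike_table(t, 0b11).probs, t.probs)

    def test_independent_bipartition_product(self):
        t = independent_spike_table([0.2, 0.35, 0.5, 0.65])
        sa = subsystem_spike_table(t, 0b0011).s1
        sb = subsystem_spike_table(t, 0b1100).s1
        assert sa * sb == pytest.approx(t.s1, rel=1e-13)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            subsystem_spike_table(independent_spike_table([0.5, 0.5]), 0)


class TestExactTables:
    def test_one_time_dist_structure(self, model_n3):
        dist = one_time_dist(model_n3)
        d = model_n3.dichotomous
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert dist.p1 == pytest.approx(d.ps * model_n3.s1 + d.pb)
        # non-all-ones words carry probability ps * s_x
        assert dist.probs[3] == pytest.approx(d.ps * model_n3.spikes.probs[3])

    def test_all_ones_mass_when_s1_zero(self):
        probs = np.array([0.5, 0.3, 0.2, 0.0])
        m = SpikingBurstingModel(
            spikes=SpikeTable(2, probs), dichotomous=validate_dichotomous(0.7, 0.1)
        )
        assert one_time_dist(m).p1 == pytest.approx(0.3)

    def test_two_time_marginals_and_symmetry(self, model_n3):
        joint = two_time_joint(model_n3)
        dist = one_time_dist(model_n3)
        np.testing.assert_allclose(joint.marginal_x().probs, dist.probs, atol=1e-13)
        np.testing.assert_allclose(joint.marginal_y().probs, dist.probs, atol=1e-13)
        np.testing.assert_allclose(joint.probs, joint.probs.T, atol=1e-15)
        assert joint.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_time_factorizes_at_zero_eps(self, model_n3):
        m = SpikingBurstingModel(model_n3.spikes, validate_dichotomous(0.7, 0.0))
        joint = two_time_joint(m)
        p = one_time_dist(m).probs
        np.testing.assert_allclose(joint.probs, np.outer(p, p), atol=1e-14)

    def test_pi_and_p11_direct_formulas(self, model_n2):
        jt = dichotomous_joint(model_n2.dichotomous)
        s1 = model_n2.s1
        pi = jt.pss * s1 + jt.psb
        p11 = jt.pss * s1 ** 2 + 2 * jt.psb * s1 + jt.pbb
        joint = two_time_joint(model_n2)
        assert joint.probs[0, -1] == pytest.approx(pi * model_n2.spikes.probs[0])
        assert joint.p11 == pytest.approx(p11)


class TestScalingInvariance:
    def test_alpha_one_is_identity(self, model_n2):
        m = scaling_transform(model_n2, 1.0)
        np.testing.assert_allclose(m.spikes.probs, model_n2.spikes.probs)
        assert m.dichotomous.ps == model_n2.dichotomous.ps

    def test_two_time_joint_invariant(self, model_n2):
        m = scaling_transform(model_n2, 0.9)
        np.testing.assert_allclose(
            two_time_joint(m).probs, two_time_joint(model_n2).probs, atol=1e-12
        )
        np.testing.assert_allclose(
            one_time_dist(m).probs, one_time_dist(model_n2).probs, atol=1e-12
        )

    def test_eps_invariant(self, model_n2):
        for alpha in (0.88, 0.95, 1.05, 1.3):
            m = scaling_transform(model_n2, alpha)
            assert m.dichotomous.eps == pytest.approx(
                model_n2.dichotomous.eps, rel=1e-12
            )

    def test_inadmissible_alpha_reports_interval(self, model_n2):
        lo, hi = admissible_alpha_range(model_n2)
        with pytest.raises(ConstraintError, match="admissible interval"):
            scaling_transform(model_n2, hi * 1.5)
        with pytest.raises(ConstraintError):
            scaling_transform(model_n2, lo * 0.5)

    @given(frac=st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_invariance_across_admissible_range(self, frac):
        base = SpikingBurstingModel(
            spikes=independent_spike_table([0.3, 0.3, 0.3]),
            dichotomous=validate_dichotomous(0.7, 0.1),
        )
        lo, hi = admissible_alpha_range(base)
        alpha = lo + (hi - lo) * frac
        if not lo < alpha < hi:
            return
        m = scaling_transform(base, alpha)
        np.testing.assert_allclose(
            two_time_joint(m).probs, two_time_joint(base).probs, atol=1e-12
        )


class TestConfig:
    def test_independent_config(self):
        m = model_from_config(
            {"n_nodes": 3, "spike": {"mode": "independent", "p": 0.3},
             "dichotomous": {"ps": 0.7, "eps": 0.1}}
        )
        assert m.n_nodes == 3
        assert m.s1 == pytest.approx(0.3 ** 3)

    def test_pb_rho_parameterization(self):
        m = model_from_config(
            {"n_nodes": 2, "spike": {"mode": "independent", "p": [0.4, 0.4]},
             "dichotomous": {"pb": 0.4, "rho": 0.3}}
        )
        assert m.dichotomous.ps == pytest.approx(0.6)
        assert m.dichotomous.eps == pytest.approx(0.3 * 0.4 / 0.6)

    def test_explicit_table_config_word_order(self):
        m = model_from_config(
            {"n_nodes": 2,
             "spike": {"mode": "table",
                       "probs": {"00": 0.4, "10": 0.3, "01": 0.2, "11": 0.1}},
             "dichotomous": {"ps": 0.8, "eps": 0.05}}
        )
        # word strings list node 0 first; "10" means node 0 spikes -> index 1
        np.testing.assert_allclose(m.spikes.probs, [0.4, 0.3, 0.2, 0.1])
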