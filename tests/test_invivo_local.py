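import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import amynet as an
from amynet.invivo_local import ClearanceSpec


class TestClearanceRates:
    def test_constant(self):
        spec = ClearanceSpec.constant(10.0)
        assert an.clearance_rate(spec, 2) == 10.0
        assert an.clearance_rate(spec, 137) == 10.0

    def test_linear_in_size(self):
        assert an.clearance_rate(ClearanceSpec.linear_in_size(2.0), 5) == 10.0

    def test_inverse_size(self):
        assert an.clearance_rate(ClearanceSpec.inverse_size(12.0), 4) == 3.0

    def test_windowed_reference_values(self):
        """Drug window [5, 15] over background 10 with increment 1e5."""
        spec = ClearanceSpec.windowed(10.0, 1e5, 5, 15)
        assert an.clearance_rate(spec, 10) == pytest.approx(100010.0)
        assert an.clearance_rate(spec, 20) == pytest.approx(10.0)
        assert an.clearance_rate(spec, 5) == pytest.approx(100010.0)
        assert an.clearance_rate(spec, 4) == pytest.approx(10.0)

    @given(i=st.integers(min_value=2, max_value=500))
    def test_windowed_membership(self, i):
        spec = ClearanceSpec.windowed(7.0, 3.0, 11, 40)
        expected = 10.0 if 11 <= i <= 40 else 7.0
        assert an.clearance_rate(spec, i) == pytest.approx(expected)

    def test_tabulated_extends_last_entry(self):
        spec = ClearanceSpec.tabulated([1.0, 2.0, 3.0])
        assert an.clearance_rate(spec, 4) == 3.0
        assert an.clearance_rate(spec, 40) == 3.0

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            an.clearance_rate(ClearanceSpec.constant(1.0), 1)

    def test_parse_round_trip(self):
        spec = ClearanceSpec.parse("windowed:10,1e5,5,15")
        assert spec == ClearanceSpec.windowed(10.0, 1e5, 5, 15)
        with pytest.raises(ValueError):
            ClearanceSpec.parse("bogus:1")


class TestFixedPointConstant:
    def test_reference_equilibrium_mass(self, params_scaled):
        """The diseased fixed point at clearance 13.571 carries M2 ~ 3.76."""
        fp = an.fixed_point_constant(params_scaled, 13.571)
        assert fp.exists
        assert fp.M_star == pytest.approx(3.764, abs=0.005)
        assert fp.M_star == pytest.approx(float(fp.sizes @ fp.p_star), rel=1e-8)

    def test_vanishes_at_bifurcation(self, params_scaled):
        lam_star = an.bifurcation_threshold(params_scaled)
        assert an.fixed_point_constant(params_scaled, lam_star * (1 + 1e-12)).exists is False
        fp = an.fixed_point_constant(params_scaled, lam_star * (1 - 1e-9))
        assert fp.exists and fp.M_star < 1e-3

    def test_mass_scales_with_sqrt_KM(self, params_scaled):
        base = an.fixed_point_constant(params_scaled, 1e3).M_star
        quad = an.fixed_point_constant(params_scaled.replace(K_M=4 * params_scaled.K_M), 1e3).M_star
        assert quad == pytest.approx(2 * base, rel=1e-10)

    def test_rejects_nonpositive_clearance(self, params_scaled):
        with pytest.raises(ValueError):
            an.fixed_point_constant(params_scaled, 0.0)


class TestCriticalClearance:
    def test_constant_reference_value(self, params_scaled):
        """Closed form ~1.287e4 /h for the reference kinetics."""
        assert an.critical_clearance(params_scaled, "constant") == pytest.approx(
            1.2869e4, rel=1e-3
        )

    def test_no_secondary_nucleation_means_zero(self, params_scaled):
        p = params_scaled.replace(k_2=1e-300)
        assert an.critical_clearance(p, "constant") == pytest.approx(0.0, abs=1e-140)

    def test_inverse_size_reference_value(self, params_scaled):
        """~1.31e5 /h, close to the 2a = 1.2e5 approximation."""
        v = an.critical_clearance(params_scaled, "inverse_size")
        a2 = 4 * params_scaled.k_plus * params_scaled.m_0
        assert v == pytest.approx(1.31e5, rel=0.005)
        assert a2 == pytest.approx(1.2e5)
        assert v == pytest.approx(a2, rel=0.15)

    def test_unsupported_variant(self, params_scaled):
        with pytest.raises(ValueError):
            an.critical_clearance(params_scaled, "windowed")


class TestBifurcation:
    def test_transcritical_exchange_of_stability(self, params_scaled):
        """5% above the closed-form threshold the seeded mass dies out;
        5% below it relaxes to the diseased fixed point."""
        lam_c = an.critical_clearance(params_scaled, "constant")
        above = an.simulate_invivo_moments(params_scaled, 1.05 * lam_c, t_end=2.0)
        assert above.M[-1] < 1e-9 * params_scaled.m_0
        below = an.simulate_invivo_moments(params_scaled, 0.95 * lam_c, t_end=2.0)
        fp = an.fixed_point_constant(params_scaled, 0.95 * lam_c)
        assert fp.exists
        assert below.M[-1] == pytest.approx(fp.M_star, rel=0.01)

    def test_bisection_matches_fixed_point_boundary(self, params_scaled):
        """The ODE transition sits at the radicand-vanishing threshold to
        well within 0.5%."""
        emp = an.empirical_critical_clearance(params_scaled, 6e3, 2e4)
        exact = an.bifurcation_threshold(params_scaled)
        assert emp == pytest.approx(exact, rel=0.005)
        # and that exact boundary agrees with the conventional closed form
        # to within its ~1.3% internal spread
        assert exact == pytest.approx(
            an.critical_clearance(params_scaled, "constant"), rel=0.02
        )


class TestSimulateInvivo:
    def test_supercritical_seeded_decay(self, params_scaled):
        # above threshold no steady distribution exists and the decaying
        # remnant marches past any truncation, so the tail check is off
        spec = ClearanceSpec.constant(2e4)
        tr = an.simulate_invivo(params_scaled, spec, t_end=0.01, N=100, check_tail=False)
        assert tr.M[-1] < 1e-6 * tr.M[0]

    def test_zero_everything_stays_zero(self, params_scaled):
        p = params_scaled.replace(k_n=1e-300)
        tr = an.simulate_invivo(p, ClearanceSpec.constant(0.0), seed={}, t_end=0.01, N=50)
        assert np.max(tr.M) == 0.0

    def test_seeded_growth_peak_then_relaxation(self, params_scaled):
        """Subcritical clearance: growth to a toxic peak above the final
        equilibrium, then relaxation (moment level, clearance 10)."""
        tr = an.simulate_invivo_moments(params_scaled, 10.0, t_end=2.0, n_out=2000)
        M2 = tr.metadata["M2"]
        M_max, tau1, tau2 = an.peak_and_timescales(tr, epsilon=0.01 * M2)
        assert M_max > M2 > 0
        assert 0 < tau1 < tau2

    def test_peak_and_timescales_decrease_with_clearance(self, params_scaled):
        results = []
        for lam in (5.0, 10.0, 20.0):
            tr = an.simulate_invivo_moments(params_scaled, lam, t_end=3.0, n_out=3000)
            M_max, tau1, tau2 = an.peak_and_timescales(tr, epsilon=0.01 * tr.metadata["M2"])
            results.append((M_max, tr.metadata["M2"], tau1, tau2))
        arr = np.array(results)
        assert np.all(np.diff(arr, axis=0) < 0)

    def test_monotone_trajectory_has_no_peak(self, params_scaled):
        # pure-mass seed (no aggregate number) decays monotonically above
        # threshold: no interior peak to report
        tr = an.simulate_invivo_moments(
            params_scaled, 2e4, seed_moments=(0.0, 6e-4), t_end=0.01
        )
        out = an.peak_and_timescales(tr, epsilon=1e-6)
        assert all(math.isnan(v) for v in out)

    def test_moments_match_size_resolved(self, params_scaled):
        """Constant clearance 1e3: the 2-ODE closure tracks the truncated
        size-resolved system."""
        spec = ClearanceSpec.constant(1e3)
        tr = an.simulate_invivo(params_scaled, spec, t_end=0.05, N=500)
        mom = an.simulate_invivo_moments(params_scaled, 1e3, t_end=0.05)
        Mi = np.interp(tr.t, mom.t, mom.M)
        assert np.max(np.abs(tr.M - Mi)) / np.max(Mi) < 0.02

    def test_moment_closure_rejects_size_dependence(self, params_scaled):
        with pytest.raises(ValueError, match="size-independent"):
            an.simulate_invivo_moments(params_scaled, ClearanceSpec.linear_in_size(2.0))


class TestEquilibriumDistribution:
    @pytest.mark.parametrize("lam", [1e3, 5e3, 1.2e4])
    def test_geometric_law_for_constant_clearance(self, params_scaled, lam):
        """p*_{i+1}/p*_i is the size-independent delta = a0/(lam + a0)."""
        a0 = 2 * params_scaled.k_plus * params_scaled.m_0
        fp = an.equilibrium_distribution(params_scaled, ClearanceSpec.constant(lam))
        assert fp.exists
        keep = fp.p_star > 1e-250 * fp.p_star.max()  # skip underflowed tail
        ratios = fp.p_star[keep][1:] / fp.p_star[keep][:-1]
        assert np.allclose(ratios, a0 / (lam + a0), rtol=1e-12)

    def test_recurrence_ratio_half_at_lam_equal_a(self, params_scaled):
        """At lam = 2 k_plus m_0 the recurrence ratio is exactly 1/2."""
        a0 = 2 * params_scaled.k_plus * params_scaled.m_0
        delta = a0 / (an.clearance_rate(ClearanceSpec.constant(a0), 5) + a0)
        assert delta == 0.5

    def test_matches_ode_steady_state(self, params_scaled):
        spec = ClearanceSpec.constant(1e3)
        tr = an.simulate_invivo(params_scaled, spec, t_end=0.05, N=500)
        fp = an.equilibrium_distribution(params_scaled, spec, N=500)
        # exclude the reflecting top bin, which the truncated ODE treats
        # differently by construction
        rel = np.abs(tr.p[-1][:-1] - fp.p_star[:-1]) / fp.p_star[:-1]
        assert np.max(rel) < 0.01

    def test_matches_ode_linear_in_size(self, params_scaled):
        spec = ClearanceSpec.linear_in_size(100.0)
        tr = an.simulate_invivo(params_scaled, spec, t_end=0.1, N=200)
        fp = an.equilibrium_distribution(params_scaled, spec, N=200)
        keep = fp.p_star > 1e-12 * fp.p_star.max()
        keep[-1] = False
        rel = np.abs(tr.p[-1][keep] - fp.p_star[keep]) / fp.p_star[keep]
        assert np.max(rel) < 0.01

    def test_matches_ode_windowed(self, params_scaled):
        spec = ClearanceSpec.windowed(1e3, 1e4, 5, 15)
        tr = an.simulate_invivo(params_scaled, spec, t_end=0.2, N=500, check_tail=False)
        fp = an.equilibrium_distribution(params_scaled, spec, N=500)
        rel = np.abs(tr.p[-1][:-1] - fp.p_star[:-1]) / fp.p_star[:-1]
        assert np.max(rel) < 0.01

    def test_inverse_size_supercritical_decays(self, params_scaled):
        """Above the inverse-size threshold, no equilibrium exists and the
        seeded ODE decays to zero."""
        spec = ClearanceSpec.inverse_size(3e5)
        fp = an.equilibrium_distribution(params_scaled, spec, N=200)
        assert not fp.exists
        tr = an.simulate_invivo(params_scaled, spec, t_end=0.01, N=200, check_tail=False)
        assert tr.M[-1] < 1e-6 * tr.M[0]

    def test_constant_agrees_with_moment_fixed_point(self, params_scaled):
        fp_sum = an.equilibrium_distribution(params_scaled, ClearanceSpec.constant(1e3))
        fp_mom = an.fixed_point_constant(params_scaled, 1e3)
        assert fp_sum.M_star == pytest.approx(fp_mom.M_star, rel=1e-6)

    def test_heightened_clearance_spares_oligomers(self, params_scaled):
        """Raising constant clearance suppresses large aggregates far more
        than small oligomers: the per-size suppression ratio decreases
        monotonically with size."""
        fp_lo = an.equilibrium_distribution(params_scaled, ClearanceSpec.constant(1e3))
        fp_hi = an.equilibrium_distribution(params_scaled, ClearanceSpec.constant(4e3))
        n = min(len(fp_lo.p_star), len(fp_hi.p_star))
        ratio = fp_hi.p_star[:n] / fp_lo.p_star[:n]
        assert np.all(np.diff(ratio) < 0)
        # small oligomers barely change relative to the large-size tail
        assert ratio[0] / ratio[100] > 10


class TestWindowedTargeting:
    def test_no_drug_reduces_to_constant(self, params_scaled):
        base = an.equilibrium_distribution(params_scaled, ClearanceSpec.constant(10.0))
        win = an.interval_mass_reduction(params_scaled, 10.0, 0.0, 5, 15)
        assert win == pytest.approx(base.M_star, rel=1e-9)

    def test_smaller_windows_remove_more_mass(self, params_scaled):
        """Equilibrium toxic mass increases as the heavily cleared window
        moves to larger sizes."""
        masses = [
            an.interval_mass_reduction(params_scaled, 10.0, 1e5, n0, n0 + 10)
            for n0 in (5, 15, 25, 35)
        ]
        assert np.all(np.diff(masses) > 0)

    def test_total_blockade_at_the_nucleus(self, params_scaled):
        """An infinitely strong window starting at the dimer shuts the
        aggregation pathway down entirely."""
        m = an.interval_mass_reduction(params_scaled, 10.0, 1e12, 2, 12)
        assert m == 0.0

    def test_interval_mass_ordering_beyond_the_peak(self, params_scaled):
        """Among equal windows beyond the per-size mass peak (size ~a0/lam),
        the lower window holds more equilibrium mass."""
        lam = 1e3
        a0 = 2 * params_scaled.k_plus * params_scaled.m_0
        lo = int(a0 / lam) + 10  # safely past the k p_k* maximum
        removed = an.compare_interval_targets(
            params_scaled, lam, [(lo, lo + 9), (lo + 20, lo + 29)]
        )
        assert removed[0] > removed[1]

    def test_interval_mass_ordering_reverses_below_the_peak(self, params_scaled):
        """k p_k* still grows with k below size ~a0/lam, so the static
        removed-mass comparison flips there even though the sustained
        windowed equilibrium always favors small-size targeting."""
        removed = an.compare_interval_targets(params_scaled, 1e3, [(3, 12), (13, 22)])
        assert removed[0] < removed[1]

    def test_identical_intervals_remove_equal_mass(self, params_scaled):
        a = an.compare_interval_targets(params_scaled, 1e3, [(3, 12)])
        b = an.compare_interval_targets(params_scaled, 1e3, [(3, 12)])
        assert a == b

    @pytest.mark.parametrize("lam", [150.0, 1500.0, 10000.0])
    def test_tail_ordering_holds_across_clearance_decades(self, params_scaled, lam):
        a0 = 2 * params_scaled.k_plus * params_scaled.m_0
        lo = int(a0 / lam) + 10
        removed = an.compare_interval_targets(
            params_scaled, lam, [(lo, lo + 7), (lo + 10, lo + 17), (lo + 20, lo + 27)]
        )
        assert removed[0] > removed[1] > removed[2]

    def test_overlapping_intervals_rejected(self, params_scaled):
        with pytest.raises(ValueError, match="overlap"):
            an.compare_interval_targets(params_scaled, 1e3, [(3, 12), (10, 19)])
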