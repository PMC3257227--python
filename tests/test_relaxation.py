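import math

import numpy as np
import pytest
from scipy import stats

from ribodyn import relaxation as rx
from ribodyn.constants import DEFAULT_CONSTANTS
from ribodyn.peakio import RelaxationRecord, ResidueID
from ribodyn.synthetic_data import GeneratorSpec, gen_relaxation

FIELD = 500.13


def _j_reference(S2, tau_e, tau_c, omega):
    """Independent plain-python evaluation of the spectral density."""
    omega = abs(omega)
    j = S2 * tau_c / (1.0 + (omega * tau_c) ** 2)
    if tau_e > 0:
        tau = tau_c * tau_e / (tau_c + tau_e)
        j += (1.0 - S2) * tau / (1.0 + (omega * tau) ** 2)
    return 0.4 * j


class TestSpectralDensity:
    def test_rigid_limit_at_zero_frequency(self):
        tau_c = 7.9e-9
        assert rx.spectral_density(1.0, 50e-12, tau_c, 0.0) == pytest.approx(
            0.4 * tau_c, rel=1e-14)

    def test_vanishes_at_high_frequency_monotonically(self):
        omegas = np.geomspace(1e6, 1e13, 50)
        j = rx.spectral_density(0.9, 30e-12, 7.9e-9, omegas)
        assert np.all(np.diff(j) < 0)
        assert j[-1] < 1e-15

    def test_matches_direct_arithmetic(self):
        wn = DEFAULT_CONSTANTS.omega_n(FIELD)
        got = rx.spectral_density(0.9, 30e-12, 7.9e-9, wn)
        want = _j_reference(0.9, 30e-12, 7.9e-9, wn)
        assert got == pytest.approx(want, rel=1e-12)


class TestForwardRates:
    def test_extreme_narrowing_r1_equals_r2(self):
        # the CSA secular term keeps a ~1% R2/R1 gap even with a flat J,
        # so equality is asserted at the dipolar-dominance level
        r = rx.forward_rates(1.0, 0.0, 1e-13, 0.0, FIELD)
        assert r.R2 == pytest.approx(r.R1, rel=0.02)

    def test_rex_pure_additivity(self):
        a = rx.forward_rates(0.9, 30e-12, 7.9e-9, 0.0, FIELD)
        b = rx.forward_rates(0.9, 30e-12, 7.9e-9, 5.0, FIELD)
        assert b.R2 - a.R2 == pytest.approx(5.0, abs=1e-12)
        assert b.R1 == a.R1 and b.NOE != a.NOE or b.R1 == a.R1
        assert b.eta_xy == a.eta_xy

    def test_r2_over_r1_against_arithmetic_oracle(self):
        c = DEFAULT_CONSTANTS
        wh, wn = c.omega_h(FIELD), c.omega_n(FIELD)
        d, cc = c.d_dipolar, c.c_csa(FIELD)
        tau_c = 7.9e-9
        J = lambda w: _j_reference(1.0, 0.0, tau_c, w)  # noqa: E731
        r1 = d * d / 4.0 * (J(wh - wn) + 3 * J(wn) + 6 * J(wh + wn)) \
            + cc * cc * J(wn)
        r2 = d * d / 8.0 * (4 * J(0) + J(wh - wn) + 3 * J(wn) + 6 * J(wh)
                            + 6 * J(wh + wn)) \
            + cc * cc / 6.0 * (4 * J(0) + 3 * J(wn))
        got = rx.forward_rates(1.0, 0.0, tau_c, 0.0, FIELD)
        assert got.R2 / got.R1 == pytest.approx(r2 / r1, rel=1e-10)

    def test_noe_below_one_for_slow_tumbling(self):
        r = rx.forward_rates(0.9, 30e-12, 7.9e-9, 0.0, FIELD)
        assert 0.5 < r.NOE < 1.0


class TestModelFreeFit:
    def _records(self, S2, tau_e_ps=30.0, tau_c_ns=7.9, n=15, rex=0.0):
        recs = []
        for i in range(n):
            r = rx.forward_rates(S2, tau_e_ps * 1e-12, tau_c_ns * 1e-9,
                                 rex, FIELD)
            recs.append(RelaxationRecord(
                ResidueID(i + 2, "ALA"), float(r.R1), float(r.R2),
                float(r.NOE), field_MHz=FIELD))
        return recs

    @pytest.mark.parametrize("s2", [0.5, 0.7, 0.9, 1.0])
    def test_round_trip_noiseless(self, s2):
        res = rx.fit_model_free(self._records(s2))
        assert res.tau_c_ns == pytest.approx(7.9, rel=0.005)
        np.testing.assert_allclose(res.S2, s2, rtol=0.005)
        if s2 < 1.0:  # tau_e is unidentifiable in the rigid limit
            np.testing.assert_allclose(res.tau_e_ps, 30.0, rtol=0.005)

    def test_rigid_rotor_all_s2_near_one(self):
        res = rx.fit_model_free(self._records(1.0, tau_e_ps=0.0))
        assert np.all(res.S2 >= 0.99)

    def test_planted_dips_rank_order(self):
        spec = GeneratorSpec(seed=21, n_residues=40, noise_level=0.0)
        recs, truth = gen_relaxation(spec, S2_mean=0.9, S2_sd=0.03,
                                     flexible_residues=(18, 19, 20),
                                     flexible_S2=0.6)
        res = rx.fit_model_free(recs)
        rho = stats.spearmanr(truth["S2_true"], res.S2).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)
        fitted = dict(zip((r.seq_number for r in res.residues), res.S2))
        assert all(fitted[i] < 0.65 for i in (18, 19, 20))

    def test_insufficient_residues(self):
        with pytest.raises(ValueError, match="10 usable"):
            rx.fit_model_free(self._records(0.9, n=5))

    def test_negative_noe_excluded_with_reason(self):
        recs = self._records(0.9, n=12)
        bad = RelaxationRecord(ResidueID(50, "GLY"), recs[0].R1, recs[0].R2,
                               -0.4, field_MHz=FIELD)
        res = rx.fit_model_free(recs + [bad])
        assert ("GLY50", "negative NOE") in res.excluded
        assert len(res.residues) == 12

    def test_caller_exclusions_recorded(self):
        recs = self._records(0.9, n=12)
        res = rx.fit_model_free(recs, exclusions=("ALA2",))
        assert ("ALA2", "excluded by caller") in res.excluded

    def test_monte_carlo_intervals_bracket_truth(self):
        spec = GeneratorSpec(seed=8, n_residues=15, noise_level=0.02)
        recs, truth = gen_relaxation(spec)
        res = rx.fit_model_free(recs, n_mc=60, seed=1)
        inside = np.mean((res.S2_ci90[:, 0] <= truth["S2_true"])
                         & (truth["S2_true"] <= res.S2_ci90[:, 1]))
        assert inside >= 0.6  # nominal 90%, small-sample slack

    def test_back_calculation_report_present(self):
        res = rx.fit_model_free(self._records(0.9))
        assert set(res.back_calc) == {"T1", "T2", "NOE"}
        assert all(v < 1e-4 for v in res.back_calc.values())


class TestReducedSpectralDensity:
    def test_rigid_point_lies_on_rigid_curve(self):
        tau_c = 8e-9
        r = rx.forward_rates(1.0, 0.0, tau_c, 0.0, FIELD)
        rec = RelaxationRecord(ResidueID(5, "ALA"), float(r.R1), float(r.R2),
                               float(r.NOE), field_MHz=FIELD)
        t = rx.reduced_spectral_density(rec)
        wn = DEFAULT_CONSTANTS.omega_n(FIELD)
        assert t.J0 == pytest.approx(_j_reference(1, 0, tau_c, 0), rel=0.005)
        assert t.J_wN == pytest.approx(_j_reference(1, 0, tau_c, wn),
                                       rel=0.005)

    @pytest.mark.parametrize("tau_c_ns", [4.0, 6.0, 8.0, 10.0, 12.0])
    def test_forward_inverse_bias_below_three_percent(self, tau_c_ns):
        tau_c = tau_c_ns * 1e-9
        r = rx.forward_rates(0.9, 30e-12, tau_c, 0.0, FIELD)
        rec = RelaxationRecord(ResidueID(5, "ALA"), float(r.R1), float(r.R2),
                               float(r.NOE), field_MHz=FIELD)
        t = rx.reduced_spectral_density(rec)
        wn = DEFAULT_CONSTANTS.omega_n(FIELD)
        wh = DEFAULT_CONSTANTS.omega_h(FIELD)
        assert t.J0 == pytest.approx(
            _j_reference(0.9, 30e-12, tau_c, 0.0), rel=0.03)
        assert t.J_wN == pytest.approx(
            _j_reference(0.9, 30e-12, tau_c, wn), rel=0.03)
        assert t.J_087wH == pytest.approx(
            _j_reference(0.9, 30e-12, tau_c, 0.87 * wh), rel=0.2)

    def test_rex_raises_j0_only(self):
        base = rx.forward_rates(0.9, 30e-12, 8e-9, 0.0, FIELD)
        a = rx.reduced_spectral_density(RelaxationRecord(
            ResidueID(5, "ALA"), float(base.R1), float(base.R2),
            float(base.NOE), field_MHz=FIELD))
        b = rx.reduced_spectral_density(RelaxationRecord(
            ResidueID(5, "ALA"), float(base.R1), float(base.R2) + 8.0,
            float(base.NOE), field_MHz=FIELD))
        assert b.J0 > a.J0
        assert b.J_wN == pytest.approx(a.J_wN, rel=1e-12)

    def test_unit_noe_zeroes_high_frequency_density(self):
        rec = RelaxationRecord(ResidueID(5, "ALA"), 2.0, 10.0, 1.0,
                               field_MHz=FIELD)
        t = rx.reduced_spectral_density(rec)
        assert t.flagged
        assert math.isnan(t.J_087wH)

    def test_rigid_body_curve_shape(self):
        j0, jn = rx.rigid_body_curve(FIELD)
        assert np.all(np.diff(j0) > 0)
        assert np.all(jn <= j0 + 1e-18)


class TestDetectExchange:
    def test_no_flags_on_clean_uniform_set(self):
        spec = GeneratorSpec(seed=31, n_residues=50, noise_level=0.0)
        recs, _ = gen_relaxation(spec, S2_sd=0.0)
        out = rx.detect_exchange(recs)
        assert sum(out["flags"].values()) == 0
        assert not out["global_offset_warning"]

    def test_planted_rex_exact_recovery(self):
        spec = GeneratorSpec(seed=3, n_residues=51, noise_level=0.0)
        recs, _ = gen_relaxation(spec, rex={10: 6.0, 20: 6.0, 30: 6.0})
        out = rx.detect_exchange(recs)
        flagged = sorted(r.seq_number for r, f in out["flags"].items() if f)
        assert flagged == [10, 20, 30]

    def test_uniform_rex_absorbed_with_warning(self):
        spec = GeneratorSpec(seed=31, n_residues=50, noise_level=0.0)
        recs, _ = gen_relaxation(spec, S2_sd=0.0,
                                 rex={i: 4.0 for i in range(2, 51)})
        out = rx.detect_exchange(recs)
        assert sum(out["flags"].values()) == 0
        assert out["global_offset_warning"]

    def test_needs_five_eta_records(self):
        spec = GeneratorSpec(seed=31, n_residues=4, noise_level=0.0)
        recs, _ = gen_relaxation(spec)
        with pytest.raises(ValueError):
            rx.detect_exchange(recs)


class TestEmpiricalTauc:
    def test_monomer_size_at_experiment_temperature(self):
        assert round(rx.empirical_tauc(124, 300.0), 1) == 8.5

    def test_power_law_in_size(self):
        ratio = rx.empirical_tauc(248, 300.0) / rx.empirical_tauc(124, 300.0)
        assert ratio == pytest.approx(2.0 ** 0.93, rel=1e-12)

    def test_decreases_with_temperature(self):
        assert rx.empirical_tauc(124, 310.0) < rx.empirical_tauc(124, 300.0)

    def test_small_protein_rejected(self):
        with pytest.raises(ValueError):
            rx.empirical_tauc(5, 300.0)
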