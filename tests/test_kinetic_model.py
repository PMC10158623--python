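import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdoe_carrier.kinetic_model import (
    CarrierSpec,
    CultureSetup,
    CultureState,
    KineticParameters,
    attachment_rate,
    culture_metrics,
    derivatives,
    simulate_batch,
    specific_death_rate,
    specific_growth_rate,
    uptake_rates,
    xv_max,
)

TINY = 1e-30  # stand-in for "off" given strict positivity of rate constants


class TestXvMax:
    def test_no_carriers_no_surface(self, carrier):
        setup = CultureSetup(carrier=carrier, c_MC=0.0, seed_density=0.0, c_Glc=25.0, c_Gln=4.0)
        assert xv_max(setup) == 0.0

    def test_hand_arithmetic(self):
        # 2 g/L x 1000 cm^2/g x 1e5 cells/cm^2 = 2e8 cells/L = 2e5 cells/mL
        carrier = CarrierSpec("toy", area_per_gram=1000.0, max_area_density=1e5)
        setup = CultureSetup(carrier=carrier, c_MC=2.0, seed_density=6000.0, c_Glc=25.0, c_Gln=4.0)
        assert xv_max(setup) == pytest.approx(2.0e5)

    def test_linearity_in_carrier_loading(self, carrier):
        a = CultureSetup(carrier=carrier, c_MC=3.0, seed_density=6000.0, c_Glc=25.0, c_Gln=4.0)
        b = CultureSetup(carrier=carrier, c_MC=6.0, seed_density=6000.0, c_Glc=25.0, c_Gln=4.0)
        assert xv_max(b) == pytest.approx(2.0 * xv_max(a))

    def test_negative_inputs_rejected(self, carrier):
        with pytest.raises(ValueError):
            CultureSetup(carrier=carrier, c_MC=-1.0, seed_density=6000.0, c_Glc=25.0, c_Gln=4.0)
        with pytest.raises(ValueError):
            CarrierSpec("bad", area_per_gram=-1.0, max_area_density=1e5)


class TestGrowthRate:
    def test_zero_substrate_zero_growth(self, params):
        assert specific_growth_rate(0.0, 0.0, 1e6, params) == 0.0

    def test_full_surface_zero_growth(self, params):
        assert specific_growth_rate(1.0, 1e6, 1e6, params) == 0.0

    def test_half_saturation_identity(self, params):
        mu = specific_growth_rate(params.K_S_LS, 0.0, 1e6, params)
        assert mu == pytest.approx(params.mu_max / 2)

    def test_degenerate_setup_rejected(self, params):
        with pytest.raises(ValueError):
            specific_growth_rate(1.0, 0.0, 0.0, params)

    @settings(max_examples=50, deadline=None)
    @given(c_ls=st.floats(0.0, 10.0), frac=st.floats(0.0, 1.0))
    def test_bounded_by_mu_max(self, c_ls, frac, params):
        mu = specific_growth_rate(c_ls, frac * 1e6, 1e6, params)
        assert 0.0 <= mu <= params.mu_max


class TestDeathRate:
    def test_depleted_substrate_floor(self, params):
        assert specific_death_rate(0.0, params) == pytest.approx(params.mu_d_min)

    def test_saturation_limit(self, params):
        mu_d = specific_death_rate(1e12, params)
        assert mu_d == pytest.approx(params.mu_d_min + params.mu_d_max, rel=1e-6)

    def test_half_saturation_identity(self, params):
        mu_d = specific_death_rate(params.K_d_LS, params)
        assert mu_d == pytest.approx(params.mu_d_min + params.mu_d_max / 2)

    def test_inverse_orientation(self, params):
        inv = params.with_values(inverse_death=True)
        assert specific_death_rate(0.0, inv) == pytest.approx(inv.mu_d_min + inv.mu_d_max)
        assert specific_death_rate(1e12, inv) == pytest.approx(inv.mu_d_min, rel=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(c_ls=st.floats(0.0, 100.0))
    def test_bounds(self, c_ls, params):
        mu_d = specific_death_rate(c_ls, params)
        assert params.mu_d_min <= mu_d <= params.mu_d_min + params.mu_d_max


class TestUptakeRates:
    def test_zero_glucose_zero_uptake(self, params):
        state = CultureState(0, 1e5, 1e4, 0, 0.0, 4.0, 1.0, 0, 0)
        q_glc, _, _ = uptake_rates(state, 1e6, params)
        assert q_glc == 0.0

    def test_growth_coupled(self, params):
        # mu = 0 via full surface -> no glucose or glutamine uptake
        state = CultureState(0, 1e6, 1e6, 0, 25.0, 4.0, 1.0, 0, 0)
        q_glc, q_gln, _ = uptake_rates(state, 1e6, params)
        assert q_glc == 0.0 and q_gln == 0.0

    def test_ls_half_saturation(self, params):
        state = CultureState(0, 1e5, 1e4, 0, 25.0, 4.0, params.k_LS, 0, 0)
        _, _, q_ls = uptake_rates(state, 1e6, params)
        assert q_ls == pytest.approx(params.q_LS_max / 2)


class TestAttachmentRate:
    def test_window_open(self, params):
        assert attachment_rate(0.0, params) == params.k_att_max

    def test_right_closed_at_window_end(self, params):
        assert attachment_rate(params.t_att, params) == 0.0

    def test_zero_window_always_closed(self, params):
        p = params.with_values(t_att=0.0)
        assert attachment_rate(0.0, p) == 0.0
        assert attachment_rate(100.0, p) == 0.0


class TestDerivatives:
    def test_fixed_point(self, setup, params):
        state = CultureState(0, 0, 0, 0, 0, 0, 0, 0, 0)
        assert np.allclose(derivatives(50.0, state, setup, params), 0.0)

    def test_hand_arithmetic_oracle(self, setup, params):
        """Scalar recomputation of every equation, to 10 significant digits."""
        state = CultureState(t=10.0, X_t=2.0e5, X_V=1.5e5, X_Sus=4.0e4,
                             c_Glc=20.0, c_Gln=3.0, c_LS=0.8, c_Lac=2.0, c_Amm=0.5)
        xvm = xv_max(setup)
        space = (xvm - state.X_V) / xvm
        mu = params.mu_max * state.c_LS / (state.c_LS + params.K_S_LS) * space
        mu_d = params.mu_d_min + params.mu_d_max * state.c_LS / (state.c_LS + params.K_d_LS)
        q_glc = mu / params.Y_X_Glc * state.c_Glc / (state.c_Glc + params.k_Glc) * space
        q_gln = mu / params.Y_X_Gln * state.c_Gln / (state.c_Gln + params.k_Gln) * space
        q_ls = params.q_LS_max * state.c_LS / (state.c_LS + params.k_LS)
        k_att = params.k_att_max  # t=10 < t_att=20
        xv_litre = state.X_V * 1000.0  # substrate balances are per litre
        expected = np.array([
            mu * state.X_V - params.K_Lys * (state.X_t - state.X_V),
            (mu - mu_d) * state.X_V + k_att * space * state.X_Sus,
            mu_d * state.X_V - k_att * space * state.X_Sus,
            -q_glc * xv_litre,
            -q_gln * xv_litre,
            -q_ls * xv_litre,
            params.Y_Lac_Glc * q_glc * xv_litre,
            params.Y_Amm_Gln * q_gln * xv_litre,
        ])
        got = derivatives(10.0, state, setup, params)
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_suspension_static_without_attachment_and_death(self, setup, params):
        p = params.with_values(t_att=0.0, mu_d_min=TINY, mu_d_max=TINY)
        state = CultureState(30.0, 1e5, 5e4, 3e4, 25.0, 4.0, 1.0, 0, 0)
        d = derivatives(30.0, state, setup, p)
        assert d[2] == pytest.approx(0.0, abs=1e-20)

    def test_non_finite_state_rejected(self, setup, params):
        state = CultureState(0, float("nan"), 0, 0, 0, 0, 0, 0, 0)
        with pytest.raises(FloatingPointError):
            derivatives(0.0, state, setup, params)


class TestSimulateBatch:
    def test_zero_inoculum_nothing_happens(self, carrier, params, t_grid):
        setup = CultureSetup(carrier=carrier, c_MC=1.0, seed_density=0.0, c_Glc=25.0, c_Gln=4.0)
        traj = simulate_batch(setup, params, t_grid)
        assert np.all(traj.states[:, :3] == 0.0)
        np.testing.assert_allclose(traj.column("c_Glc"), 25.0, rtol=1e-9)
        np.testing.assert_allclose(traj.column("c_LS"), 1.0, rtol=1e-9)

    def test_exponential_limit_closed_form(self, params):
        """Unlimited regime: constant rates, X_V grows as a pure exponential."""
        carrier = CarrierSpec("vast", area_per_gram=2700.0, max_area_density=1e12)
        setup = CultureSetup(carrier=carrier, c_MC=10.0, seed_density=1.0, c_Glc=25.0, c_Gln=4.0)
        p = params.with_values(q_LS_max=TINY, K_S_LS=1e-6, t_att=0.0)
        x0 = CultureState(0.0, 1e4, 1e4, 0.0, 25.0, 4.0, 1.0, 0.0, 0.0)
        t = np.linspace(0.0, 100.0, 26)
        traj = simulate_batch(setup, p, t, initial_state=x0)
        mu = p.mu_max * 1.0 / (1.0 + p.K_S_LS)
        mu_d = p.mu_d_min + p.mu_d_max * 1.0 / (1.0 + p.K_d_LS)
        closed = 1e4 * np.exp((mu - mu_d) * t)
        np.testing.assert_allclose(traj.column("X_V"), closed, rtol=1e-4)

    def test_lactate_glucose_stoichiometric_coupling(self, setup, params, t_grid):
        traj = simulate_batch(setup, params, t_grid)
        d_glc = traj.column("c_Glc")[0] - traj.column("c_Glc")
        d_lac = traj.column("c_Lac") - traj.column("c_Lac")[0]
        np.testing.assert_allclose(d_lac, params.Y_Lac_Glc * d_glc, rtol=1e-6, atol=1e-8)

    def test_ammonia_glutamine_stoichiometric_coupling(self, setup, params, t_grid):
        traj = simulate_batch(setup, params, t_grid)
        d_gln = traj.column("c_Gln")[0] - traj.column("c_Gln")
        d_amm = traj.column("c_Amm") - traj.column("c_Amm")[0]
        np.testing.assert_allclose(d_amm, params.Y_Amm_Gln * d_gln, rtol=1e-6, atol=1e-8)

    def test_substrate_monotonicity(self, setup, params, t_grid):
        traj = simulate_batch(setup, params, t_grid)
        for col in ("c_Glc", "c_Gln", "c_LS"):
            assert np.all(np.diff(traj.column(col)) <= 1e-9), col
        for col in ("c_Lac", "c_Amm"):
            assert np.all(np.diff(traj.column(col)) >= -1e-9), col

    def test_state_invariants(self, setup, params, t_grid):
        traj = simulate_batch(setup, params, t_grid)
        assert np.all(traj.states >= 0.0)
        assert np.all(traj.column("X_V") <= xv_max(setup) * (1 + 1e-12))
        assert np.all(traj.column("X_t") >= traj.column("X_V"))

    def test_attachment_conserves_cells(self, carrier, t_grid):
        p = KineticParameters(mu_max=TINY, mu_d_min=TINY, mu_d_max=TINY, K_Lys=TINY)
        setup = CultureSetup(carrier=carrier, c_MC=1.0, seed_density=6000.0, c_Glc=25.0, c_Gln=4.0)
        traj = simulate_batch(setup, p, t_grid)
        total = traj.column("X_V") + traj.column("X_Sus")
        np.testing.assert_allclose(total, total[0], rtol=1e-7)

    def test_area_yield_monotone_in_carrier_loading(self, carrier, params, t_grid):
        peaks = []
        for c_mc in (1.0, 3.0, 5.0, 10.0, 20.0):
            setup = CultureSetup(carrier=carrier, c_MC=c_mc, seed_density=6000.0,
                                 c_Glc=25.0, c_Gln=4.0)
            traj = simulate_batch(setup, params, t_grid)
            peaks.append(culture_metrics(traj).X_max_per_cm2)
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))

    def test_bad_grid_rejected(self, setup, params):
        with pytest.raises(ValueError):
            simulate_batch(setup, params, [1.0, 2.0])
        with pytest.raises(ValueError):
            simulate_batch(setup, params, [0.0, 2.0, 2.0])


class TestCultureMetrics:
    def _traj_with_peak(self, setup, peak_per_cm2: float):
        area = setup.area_per_ml
        t = np.array([0.0, 24.0, 48.0])
        states = np.zeros((3, 8))
        states[:, 1] = np.array([0.1, 1.0, 0.5]) * peak_per_cm2 * area
        states[:, 0] = states[:, 1]
        from mdoe_carrier.kinetic_model import Trajectory

        return Trajectory(t=t, states=states, setup=setup, params=KineticParameters())

    def test_fold_expansion_row8(self, setup):
        m = culture_metrics(self._traj_with_peak(setup, 39.8e4), setup)
        assert m.VF == pytest.approx(66.3, abs=0.05)
        assert m.t_at_max == 24.0

    def test_fold_expansion_row7(self, setup):
        m = culture_metrics(self._traj_with_peak(setup, 22.5e4), setup)
        assert m.VF == pytest.approx(37.5)

    def test_no_expansion(self, setup):
        m = culture_metrics(self._traj_with_peak(setup, setup.seed_density), setup)
        assert m.VF == pytest.approx(1.0)
        assert m.PD == pytest.approx(0.0, abs=1e-12)

    def test_zero_seed_rejected(self, carrier, params):
        setup = CultureSetup(carrier=carrier, c_MC=1.0, seed_density=0.0, c_Glc=25.0, c_Gln=4.0)
        traj = simulate_batch(setup, params, np.array([0.0, 24.0]))
        with pytest.raises(ValueError):
            culture_metrics(traj, setup)


class TestParameterValidation:
    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            KineticParameters(mu_max=0.0)
        with pytest.raises(ValueError):
            KineticParameters(Y_X_Glc=-1.0)

    def test_negative_attachment_window_rejected(self):
        with pytest.raises(ValueError):
            KineticParameters(t_att=-1.0)

    def test_zero_window_allowed(self):
        KineticParameters(t_att=0.0)
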