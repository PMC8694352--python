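import numpy as np
import pytest

import bubbleflux as bf
from bubbleflux.bubble_dynamics import (
    DISSOLUTION_CUTOFF,
    InvalidDiameterError,
    NoThresholdError,
    diameter_from_moles,
)
from bubbleflux.physical_system import GRAVITY, R_GAS

from euler_oracle import euler_dissolution_time


class TestBubblePressure:
    def test_laplace_term(self, tea_medium, tea_column):
        """4σ/d adds ~2.5 kPa to a 100 μm bubble."""
        at_surface = bf.bubble_pressure(100e-6, tea_column.fill_height, tea_medium, tea_column)
        assert at_surface - tea_column.ambient_pressure == pytest.approx(2512.0, rel=1e-3)

    def test_hydrostatic_head_at_sparger(self, tea_medium, tea_column):
        d = 100e-6
        p_bottom = bf.bubble_pressure(d, 0.0, tea_medium, tea_column)
        p_top = bf.bubble_pressure(d, tea_column.fill_height, tea_medium, tea_column)
        head = tea_medium.density * GRAVITY * tea_column.fill_height
        assert p_bottom - p_top == pytest.approx(head, rel=1e-9)
        assert head == pytest.approx(1518.0, rel=1e-3)

    def test_reduces_to_ambient(self, tea_medium, tea_column):
        p = bf.bubble_pressure(10.0, tea_column.fill_height, tea_medium, tea_column)
        assert p == pytest.approx(tea_column.ambient_pressure, rel=1e-6)

    def test_invalid_diameter(self, tea_medium, tea_column):
        with pytest.raises(InvalidDiameterError):
            bf.bubble_pressure(0.0, 0.0, tea_medium, tea_column)


class TestRiseVelocity:
    def test_zero_diameter(self, tea_medium):
        assert bf.rise_velocity(0.0, tea_medium, law=bf.RiseLaw.STOKES) == 0.0

    def test_stokes_100um(self, tea_medium):
        v = bf.rise_velocity(100e-6, tea_medium, gas_density=1.8, law=bf.RiseLaw.STOKES)
        assert v == pytest.approx(4.38e-3, rel=1e-2)

    @pytest.mark.parametrize("d", [10e-6, 100e-6, 500e-6])
    def test_hadamard_rybczynski_is_1_5x_stokes(self, tea_medium, d):
        vs = bf.rise_velocity(d, tea_medium, gas_density=1.8, law=bf.RiseLaw.STOKES)
        vh = bf.rise_velocity(
            d, tea_medium, gas_density=1.8, law=bf.RiseLaw.HADAMARD_RYBCZYNSKI
        )
        assert vh == pytest.approx(1.5 * vs, rel=1e-14)


class TestFilmCoefficient:
    def test_stagnant_limit(self, tea_medium):
        """v = 0 gives Sh = 2, k_L = 2D/d, for every gas."""
        co2 = tea_medium.state_of("CO2").species
        assert bf.film_coefficient(100e-6, 0.0, co2, tea_medium) == pytest.approx(
            2.28e-5, rel=1e-3
        )
        for name in ("O2", "N2"):
            sp = tea_medium.state_of(name).species
            k = bf.film_coefficient(50e-6, 0.0, sp, tea_medium)
            assert k == pytest.approx(2.0 * sp.diffusivity / 50e-6, rel=1e-12)

    def test_ranz_marshall_rising_bubble(self, tea_medium):
        co2 = tea_medium.state_of("CO2").species
        k = bf.film_coefficient(100e-6, 6.57e-3, co2, tea_medium)
        assert k == pytest.approx(7.4e-5, rel=0.02)

    def test_grows_as_bubble_shrinks(self, tea_medium):
        co2 = tea_medium.state_of("CO2").species
        ks = [bf.film_coefficient(d, 0.0, co2, tea_medium) for d in (100e-6, 50e-6, 10e-6)]
        assert ks[0] < ks[1] < ks[2]

    def test_invalid_diameter(self, tea_medium):
        with pytest.raises(InvalidDiameterError):
            bf.film_coefficient(-1e-6, 0.0, tea_medium.state_of("CO2").species, tea_medium)


class TestDiameterInversion:
    @pytest.mark.parametrize("d_true", [2e-6, 1e-5, 1e-4, 1e-3])
    @pytest.mark.parametrize("z", [0.0, 0.1])
    def test_round_trip(self, tea_medium, tea_column, d_true, z):
        """Moles computed from d invert back to d through the cubic closure."""
        pb = bf.bubble_pressure(d_true, z, tea_medium, tea_column)
        n = pb * np.pi / 6.0 * d_true**3 / (R_GAS * tea_medium.temperature)
        assert diameter_from_moles(n, z, tea_medium, tea_column) == pytest.approx(
            d_true, rel=1e-10
        )

    def test_zero_moles(self, tea_medium, tea_column):
        assert diameter_from_moles(0.0, 0.0, tea_medium, tea_column) == 0.0


@pytest.fixture(scope="module")
def traj_100um(tea_medium, tea_column):
    """The reference scenario: 100 μm pure CO2 in air-saturated CO2-free TEA."""
    return bf.simulate_bubble(100e-6, {"CO2": 1.0}, tea_medium, tea_column)


class TestSimulateBubble:
    def test_dissolves_before_surfacing(self, traj_100um):
        assert traj_100um.terminal_event == "dissolved"
        assert traj_100um.dissolution_time is not None
        assert traj_100um.rise_distance < 0.152

    def test_time_strictly_increasing(self, traj_100um):
        assert np.all(np.diff(traj_100um.time) > 0.0)

    def test_rise_distance_non_negative(self, traj_100um):
        assert traj_100um.rise_distance >= 0.0

    def test_final_diameter_at_cutoff(self, traj_100um):
        assert traj_100um.diameter[-1] <= DISSOLUTION_CUTOFF * 1.01

    def test_ideal_gas_closure_every_step(self, tea_medium, tea_column, traj_100um):
        """P_b (π/6) d³ = n R T at every stored step, recomputed independently."""
        rt = R_GAS * tea_medium.temperature
        for i in range(len(traj_100um.time)):
            d = traj_100um.diameter[i]
            if d <= 0.0:
                continue
            pb = bf.bubble_pressure(d, traj_100um.height[i], tea_medium, tea_column)
            lhs = pb * np.pi / 6.0 * d**3
            rhs = traj_100um.moles[i].sum() * rt
            assert lhs == pytest.approx(rhs, rel=1e-9)
            assert traj_100um.pressure[i] == pytest.approx(pb, rel=1e-12)

    def test_monotone_dissolution_when_undersaturated(self, tea_medium, tea_column):
        """With all bulk ratios below 1, total moles never increase."""
        medium = tea_medium.with_saturations(CO2=0.0, O2=0.5, N2=0.5)
        traj = bf.simulate_bubble(60e-6, {"CO2": 1.0}, medium, tea_column)
        n_tot = traj.moles.sum(axis=1)
        assert np.all(np.diff(n_tot) <= 1e-12 * n_tot[0])

    def test_co2_fraction_collapses_before_dissolution(self, traj_100um):
        """The bubble exchanges its CO2 for dissolved air well before it dies."""
        x = traj_100um.mole_fractions
        x_co2 = x[:, list(traj_100um.species).index("CO2")]
        assert x_co2[0] == pytest.approx(1.0)
        alive = traj_100um.diameter > 5e-6  # still far from the cutoff
        assert x_co2[alive].min() < 0.1
        x_air = 1.0 - x_co2
        assert x_air[alive].max() > 0.9

    def test_equilibrium_is_steady_state(self, tea_column):
        """No surface tension + saturated bulk = zero net flux while rising."""
        base = bf.default_system().medium.with_saturations(CO2=1.0, O2=0.0, N2=0.0)
        from dataclasses import replace

        medium = replace(base, surface_tension=0.0)
        traj = bf.simulate_bubble(
            100e-6, {"CO2": 1.0}, medium, tea_column, t_max=60.0
        )
        assert traj.terminal_event == "surfaced"
        n_tot = traj.moles.sum(axis=1)
        assert n_tot[-1] == pytest.approx(n_tot[0], rel=1e-6)

    def test_laplace_acceleration(self, tea_column):
        """When only the excess pressure drives dissolution, shrinkage speeds
        up as the bubble gets smaller."""
        medium = bf.default_system().medium.with_saturations(CO2=1.0, O2=0.0, N2=0.0)
        traj = bf.simulate_bubble(
            60e-6, {"CO2": 1.0}, medium, tea_column, t_max=600.0
        )
        assert traj.terminal_event == "dissolved"
        d, t = traj.diameter, traj.time
        rate = -np.diff(d) / np.diff(t)
        # compare mean shrinkage rate in the large-d and small-d halves
        mid = d[:-1] > 0.5 * d[0]
        assert rate[~mid].mean() > rate[mid].mean()

    def test_bad_composition_rejected(self, tea_medium, tea_column):
        with pytest.raises(ValueError):
            bf.simulate_bubble(100e-6, {"CO2": 0.7}, tea_medium, tea_column)
        with pytest.raises(ValueError):
            bf.simulate_bubble(100e-6, {"He": 1.0}, tea_medium, tea_column)

    def test_too_small_initial_diameter_rejected(self, tea_medium, tea_column):
        with pytest.raises(InvalidDiameterError):
            bf.simulate_bubble(0.5e-6, {"CO2": 1.0}, tea_medium, tea_column)

    def test_trajectory_frame_columns(self, traj_100um):
        df = traj_100um.to_frame()
        assert list(df.columns) == [
            "t_s", "z_m", "d_m", "P_b_Pa", "x_CO2", "x_O2", "x_N2", "n_total_mol",
        ]
        assert len(df) == len(traj_100um.time)

    def test_state_accessor(self, traj_100um):
        s = traj_100um.state(0)
        assert s.mole_fractions["CO2"] == pytest.approx(1.0)
        assert s.total_moles == pytest.approx(traj_100um.moles[0].sum())


class TestEulerOracleAgreement:
    def test_dissolution_time_matches_fixed_step_oracle(self, tea_medium, tea_column):
        """Adaptive integration agrees with an independent explicit-Euler
        integration (Δt = 1e-4 s) of the same mass balance within 1%."""
        traj = bf.simulate_bubble(50e-6, {"CO2": 1.0}, tea_medium, tea_column)
        t_oracle = euler_dissolution_time(50e-6, tea_medium, tea_column)
        assert traj.terminal_event == "dissolved"
        assert traj.dissolution_time == pytest.approx(t_oracle, rel=0.01)


class TestSurfacingThreshold:
    def test_single_flip_over_diameter_scan(self, tea_column):
        """Terminal outcome flips exactly once from dissolved to surfaced."""
        medium = bf.default_system().medium.with_saturations(CO2=0.0, O2=0.0, N2=0.0)
        outcomes = []
        for d_um in range(480, 601, 10):
            traj = bf.simulate_bubble(
                d_um * 1e-6, {"CO2": 1.0}, medium, tea_column,
                law=bf.RiseLaw.STOKES, t_max=900.0,
            )
            outcomes.append(traj.terminal_event == "surfaced")
        flips = sum(a != b for a, b in zip(outcomes, outcomes[1:]))
        assert flips == 1
        assert not outcomes[0] and outcomes[-1]

    def test_no_threshold_when_nothing_dissolves(self, tea_column):
        """σ = 0 and saturated bulk: no bubble dissolves, no bracket exists."""
        from dataclasses import replace

        medium = replace(
            bf.default_system().medium.with_saturations(CO2=1.0, O2=1.0, N2=1.0),
            surface_tension=0.0,
        )
        with pytest.raises(NoThresholdError):
            bf.surfacing_threshold(medium, tea_column, t_max=5.0)

    def test_bad_range_rejected(self, tea_medium, tea_column):
        with pytest.raises(ValueError):
            bf.surfacing_threshold(tea_medium, tea_column, d_range=(1e-3, 1e-6))
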