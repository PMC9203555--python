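"""Unit and oracle tests for the per-cell kinetic model."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from dnakflow.errors import ValidationError
from dnakflow.kinetics import (CellState, KineticParams, LogisticGrowth,
                               fraction_unfolded, maturation_fraction,
                               simulate_cell)
from dnakflow.variants import VariantSpec

from conftest import ConstantGrowth


class TestFractionUnfolded:
    def test_equal_occupancy_at_melt(self):
        assert fraction_unfolded(55.0, 55.0, 0.25) == pytest.approx(0.5)

    def test_zero_slope_gives_half(self):
        for tm in (-10.0, 37.0, 80.0):
            assert fraction_unfolded(tm, 37.0, 0.0) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # direct evaluation of 1/(1+exp(s(Tm-T)/(R T_K))) with
        # R = 1.987e-3 kcal/mol/K, T_K = 310.15
        assert fraction_unfolded(55.0, 37.0, 0.25) == pytest.approx(
            0.0006737231345949618, rel=1e-12)

    def test_strictly_decreasing_in_tm(self):
        tms = np.linspace(0, 80, 33)
        f = [fraction_unfolded(tm, 37.0, 0.25) for tm in tms]
        assert np.all(np.diff(f) < 0)
        assert all(0 < v < 1 for v in f)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValidationError):
            fraction_unfolded(float("nan"), 37.0, 0.25)
        with pytest.raises(ValidationError):
            fraction_unfolded(55.0, -300.0, 0.25)
        with pytest.raises(ValidationError):
            fraction_unfolded(55.0, 37.0, -0.1)


class TestMaturationFraction:
    @pytest.mark.parametrize("t, t50, expected",
                             [(0.0, 42.0, 0.0),
                              (42.0, 42.0, 0.5),
                              (84.0, 42.0, 0.75),
                              (14.0, 14.0, 0.5)])
    def test_half_time_definition(self, t, t50, expected):
        assert maturation_fraction(t, t50) == pytest.approx(expected, abs=1e-12)

    def test_monotone_with_unit_limit(self):
        t = np.linspace(0, 500, 100)
        f = [maturation_fraction(ti, 42.0) for ti in t]
        assert np.all(np.diff(f) > 0)
        assert maturation_fraction(5000.0, 42.0) == pytest.approx(1.0, abs=1e-12)

    def test_rejects_negative_time(self):
        with pytest.raises(ValidationError):
            maturation_fraction(-1.0, 42.0)
        with pytest.raises(ValidationError):
            maturation_fraction(1.0, 0.0)


def _oracle_linear_solution(params, variant, mu, times, y0):
    """Matrix-exponential solution of the constant-coefficient system.

    Independent of the ODE solver: builds the 5x5 rate matrix plus the
    constant input and propagates the augmented system with expm.
    """
    f_u = params.f_u(variant)
    kR, kG = params.k_mat_red, params.k_mat_green
    kd = params.k_deg_basal + params.k_deg_unfolded * f_u
    ka = params.k_agg
    a, b = params.alpha_translation, params.beta_unfolded
    syn = params.k_syn
    m = np.array([
        [-(kR + kd + ka + mu), 0, 0, 0, 0],
        [kR, -(kd + ka + mu), 0, 0, 0],
        [ka, ka, -mu, 0, 0],
        [b * f_u, b * f_u, 0, -(kG + mu), 0],
        [0, 0, 0, kG, -mu],
    ])
    g = np.array([syn, 0, 0, params.basal_promoter + a * syn, 0])
    aug = np.zeros((6, 6))
    aug[:5, :5] = m
    aug[:5, 5] = g
    out = np.empty((len(times), 5))
    z0 = np.concatenate([y0, [1.0]])
    for i, t in enumerate(times):
        out[i] = (expm(aug * t) @ z0)[:5]
    return out


class TestSimulateCell:
    def test_no_synthesis_gives_zero_trajectory(self, wt_variant, short_schedule):
        params = KineticParams(k_syn=0.0, leak_fraction=0.0, basal_promoter=0.0)
        traj = simulate_cell(wt_variant, params, short_schedule)
        assert np.all(traj.states == 0.0)

    def test_pure_accumulation_is_linear(self, wt_variant, short_schedule):
        # no losses and instantaneous-maturation limit: total POI = k_syn*c*t
        params = KineticParams(k_syn=2.0, leak_fraction=0.0, basal_promoter=0.0,
                               k_deg_basal=0.0, k_deg_unfolded=0.0, k_agg=0.0,
                               t50_red_min=1e-7, t50_green_min=1e-7,
                               preinduction_min=0.0, beta_unfolded=0.0,
                               alpha_translation=0.0)
        traj = simulate_cell(wt_variant, params, short_schedule, copy_number=3.0)
        total = traj.channel("poi_immature") + traj.channel("poi_mature")
        assert total == pytest.approx(2.0 * 3.0 * short_schedule, rel=1e-6)

    def test_matches_matrix_exponential_oracle(self, short_schedule):
        """Criterion: numerical ODE equals the closed form to 1e-6 relative
        for 10 random parameter draws (constant coefficients)."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            params = KineticParams(
                k_syn=float(rng.uniform(0.1, 3.0)),
                leak_fraction=0.0, preinduction_min=0.0,
                k_deg_basal=float(rng.uniform(0, 0.01)),
                k_deg_unfolded=float(rng.uniform(0, 0.08)),
                k_agg=float(rng.uniform(0, 0.01)),
                basal_promoter=float(rng.uniform(0, 0.2)),
                alpha_translation=float(rng.uniform(0.2, 2.0)),
                beta_unfolded=float(rng.uniform(0, 0.2)),
                tau_pqc_min=0.0, tau_stress_min=0.0,  # constant coefficients
                t50_red_min=float(rng.uniform(10, 60)),
                t50_green_min=float(rng.uniform(5, 30)))
            variant = VariantSpec("v", float(rng.uniform(5, 65)))
            mu = float(rng.uniform(0, 0.02))
            y0 = rng.uniform(0, 50, size=5)
            traj = simulate_cell(variant, params, short_schedule,
                                 growth=ConstantGrowth(mu),
                                 initial=CellState(*y0))
            exact = _oracle_linear_solution(params, variant, mu,
                                            short_schedule, y0)
            scale = np.abs(exact).max()
            assert np.abs(traj.states - exact).max() <= 1e-6 * scale

    def test_dilution_conservation(self, wt_variant, short_schedule):
        """With synthesis and losses off, every pool decays as exp(-mu t)."""
        params = KineticParams(k_syn=0.0, leak_fraction=0.0, basal_promoter=0.0,
                               beta_unfolded=0.0, k_deg_basal=0.0,
                               k_deg_unfolded=0.0, k_agg=0.0,
                               preinduction_min=0.0)
        init = CellState(0.0, 80.0, 10.0, 0.0, 40.0)
        mu = 0.013
        traj = simulate_cell(wt_variant, params, short_schedule,
                             growth=ConstantGrowth(mu), initial=init)
        decay = np.exp(-mu * short_schedule)
        for name, v0 in (("poi_mature", 80.0), ("poi_dark", 10.0),
                         ("gfp_mature", 40.0)):
            rel = np.abs(traj.channel(name) - v0 * decay) / (v0 * decay)
            assert rel.max() < 1e-8

    def test_maturation_consistency_after_synthesis_stop(self, wt_variant):
        """With synthesis stopped, the matured fraction of the initial
        immature pool follows 1 - 2^(-t/t50) exactly (mu = k_deg = 0)."""
        params = KineticParams(k_syn=0.0, leak_fraction=0.0, basal_promoter=0.0,
                               beta_unfolded=0.0, k_deg_basal=0.0,
                               k_deg_unfolded=0.0, k_agg=0.0,
                               preinduction_min=0.0, t50_red_min=42.0)
        i0 = 100.0
        times = np.array([0.0, 10.5, 21.0, 42.0, 84.0, 168.0])
        traj = simulate_cell(wt_variant, params, times,
                             initial=CellState(i0, 0, 0, 0, 0))
        matured = traj.channel("poi_mature") / i0
        expected = 1.0 - 2.0 ** (-times / 42.0)
        assert matured == pytest.approx(expected, abs=1e-9)

    def test_positivity_all_pools(self, panel, short_schedule):
        params = KineticParams()
        for variant in panel[:3]:
            growth = LogisticGrowth(0.5, 0.019, 1.5)
            traj = simulate_cell(variant, params, short_schedule, growth=growth)
            assert np.all(traj.states >= 0.0)

    def test_stability_monotonicity_noiseless_means(self, panel, quiet_params):
        """At fixed late time, mature POI is nondecreasing in Tm and the
        unfolded promoter drive is nonincreasing in Tm."""
        reds, drives = [], []
        times = np.array([0.0, 60.0, 120.0])
        for v in sorted(panel, key=lambda v: v.tm_celsius):
            traj = simulate_cell(v, quiet_params, times)
            reds.append(traj.channel("poi_mature")[-1])
            f_u = quiet_params.f_u(v)
            drives.append(f_u * (traj.channel("poi_immature")[-1]
                                 + traj.channel("poi_mature")[-1]))
        assert np.all(np.diff(reds) >= -1e-12)
        assert np.all(np.diff(drives) <= 1e-12)

    def test_toxicity_switch_shuts_off_synthesis(self, wt_variant):
        times = np.linspace(0, 240, 25)[1:]
        base = dict(k_syn=1.0, leak_fraction=0.0, preinduction_min=0.0,
                    k_deg_basal=0.0, k_deg_unfolded=0.0, k_agg=0.0)
        on = KineticParams(toxicity_enabled=True, toxicity_threshold=50.0, **base)
        off = KineticParams(toxicity_enabled=False, **base)
        t_on = simulate_cell(wt_variant, on, times)
        t_off = simulate_cell(wt_variant, off, times)
        assert t_on.toxicity_off_time is not None
        assert t_on.toxicity_off_time == pytest.approx(50.0, rel=1e-6)
        total_on = t_on.channel("poi_immature") + t_on.channel("poi_mature")
        total_off = t_off.channel("poi_immature") + t_off.channel("poi_mature")
        assert total_on[-1] < total_off[-1]
        # total POI is capped at the threshold when nothing removes it
        assert total_on.max() <= 50.0 * (1 + 1e-6)


class TestLogisticGrowth:
    def test_mu_is_r_times_headroom(self):
        g = LogisticGrowth(0.05, 0.02, 1.2)
        assert g.mu(0.0) == pytest.approx(0.02 * (1 - 0.05 / 1.2))
        # deep in saturation the per-capita rate vanishes
        assert g.mu(5000.0) == pytest.approx(0.0, abs=1e-12)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValidationError):
            LogisticGrowth(1.5, 0.02, 1.2)
        with pytest.raises(ValidationError):
            LogisticGrowth(0.5, -0.1, 1.2)
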