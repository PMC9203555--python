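"""Per-cell kinetic model of the dual fluorescent reporter system.

A cell carries a plasmid with two reporters: an RFP fusion to a protein
of interest (POI) expressed from an inducible promoter, and a GFP
expressed from the DnaK (Hsp70) heat-shock promoter.  The model tracks
five per-cell species, all in arbitrary protein units:

* ``poi_immature`` / ``poi_mature`` -- POI-RFP with chromophore not yet
  / already matured.  Only the mature pool fluoresces red.
* ``poi_dark``     -- POI-RFP lost to an aggregated (non-fluorescent)
  pool at a variant-independent first-order rate.
* ``gfp_immature`` / ``gfp_mature`` -- GFP expressed from the DnaK
  promoter; only the mature pool fluoresces green.

Folding of the POI is treated as an instantaneous two-state equilibrium:
the unfolded pool is ``U(t) = f_u * (poi_immature + poi_mature)`` with
``f_u`` set by the variant's melting temperature through a linear
free-energy model ``dG_unf(T) = s * (Tm - T)`` and the Boltzmann factor.
The DnaK promoter activity is a minimal linear form

    A(t) = basal + alpha_translation * synthesis_rate
           + beta_unfolded * ramp(t) * U(t)

so the early response tracks translation while the late response tracks
the stability-dependent unfolded pool.  The unfolded-pool arm switches
on first order with time constant ``tau_stress_min``: the pre-existing
chaperone pool buffers the first wave of misfolded protein, so sigma32
release (and with it the stability-coupled part of the promoter
response) builds up over tens of minutes rather than instantly.
Unfolded protein is degraded faster than folded protein
(``k_deg_unfolded`` acts on the fraction ``f_u`` of the POI pool), and
that protease capacity is likewise induced with time constant
``tau_pqc_min`` -- degradation is minimal right after induction and
grows as the quality-control response matures.  GFP is not degraded,
only diluted by growth.
Growth dilution enters every species as a continuous per-capita rate
``mu(t)`` taken from a logistic growth curve; cell division is not
simulated explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, ValidationError
from .variants import VariantSpec

__all__ = [
    "R_KCAL_PER_MOL_K",
    "CELSIUS_OFFSET",
    "KineticParams",
    "CellState",
    "CellTrajectory",
    "LogisticGrowth",
    "GrowthCurve",
    "fraction_unfolded",
    "maturation_fraction",
    "simulate_cell",
]

#: Gas constant in kcal mol^-1 K^-1, the unit of the stability slope.
R_KCAL_PER_MOL_K = 1.987e-3
CELSIUS_OFFSET = 273.15


def fraction_unfolded(tm_celsius: float, temp_celsius: float, stability_slope_s: float) -> float:
    """Equilibrium unfolded fraction of a two-state protein.

    The unfolding free energy is linear in temperature around the melt:
    ``dG_unf = s * (Tm - T)`` (kcal/mol), so the unfolded occupancy is
    ``1 / (1 + exp(dG_unf / (R T_K)))``.  At ``T = Tm`` (or ``s = 0``)
    both states are equally populated and the result is exactly 0.5.

    Parameters
    ----------
    tm_celsius
        Melting temperature of the variant, degC.
    temp_celsius
        Growth temperature, degC; must be above absolute zero.
    stability_slope_s
        d(dG_unf)/d(Tm) in kcal mol^-1 degC^-1; must be >= 0.
    """
    for name, v in (("tm_celsius", tm_celsius), ("temp_celsius", temp_celsius),
                    ("stability_slope_s", stability_slope_s)):
        if not math.isfinite(v):
            raise ValidationError(f"{name} must be finite, got {v!r}")
    if temp_celsius <= -CELSIUS_OFFSET:
        raise ValidationError("temp_celsius must be above absolute zero")
    if stability_slope_s < 0:
        raise ValidationError("stability_slope_s must be >= 0")
    t_kelvin = temp_celsius + CELSIUS_OFFSET
    dg = stability_slope_s * (tm_celsius - temp_celsius)
    # logistic form is numerically safe for any dG
    return float(1.0 / (1.0 + math.exp(min(dg / (R_KCAL_PER_MOL_K * t_kelvin), 700.0))))


def maturation_fraction(t_min: float, t50_min: float) -> float:
    """Fraction of a fluorophore pulse matured after ``t_min`` minutes.

    First-order maturation with rate ``ln2 / t50``: exactly one half of
    a pulse has matured after one half-time.
    """
    if t50_min <= 0 or not math.isfinite(t50_min):
        raise ValidationError("t50_min must be positive and finite")
    if not math.isfinite(t_min) or t_min < 0:
        raise ValidationError("t_min must be non-negative and finite")
    return float(-math.expm1(-math.log(2.0) * t_min / t50_min))


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the per-cell reporter model and the noise layers.

    Rates are per minute, temperatures degC, fluorescence in arbitrary
    units (a.u.).  Defaults describe a realistic overexpression
    experiment at 37 degC: a ~20-copy plasmid with broad copy-number
    spread, strong induced synthesis with a few percent leak, RFP/GFP
    maturation half-times of 42 and 14 min, and a DnaK promoter that
    responds both to translation (alpha) and to the unfolded pool
    (beta).
    """

    # plasmid copy number: lognormal in natural-log space
    copy_number_logmean: float = 3.0
    copy_number_logsd: float = 0.35
    # synthesis
    k_syn: float = 1.0                      # POI a.u. per plasmid copy per min, induced
    k_syn_variant_cv: float = 0.4           # between-variant translation-rate spread
    k_syn_replicate_cv: float = 0.15        # day-to-day induction strength variation
    leak_fraction: float = 0.02             # pre-induction synthesis fraction, in [0, 1)
    preinduction_min: float = 60.0          # leaky-expression window simulated before t=0
    initial_poi_mature: float = 0.0         # pre-expressed mature POI per plasmid copy
    # stability
    stability_slope_s: float = 0.10         # kcal mol^-1 degC^-1
    growth_temp_celsius: float = 37.0
    # degradation / aggregation
    k_deg_basal: float = 0.002
    k_deg_unfolded: float = 0.05            # extra degradation applied to the unfolded pool
    tau_pqc_min: float = 120.0               # protease-induction ramp time; 0 = instantaneous
    k_agg: float = 0.004                    # variant-independent loss to the dark pool
    # DnaK promoter activity A = basal + alpha * synthesis + beta * unfolded
    basal_promoter: float = 0.05            # constitutive activity per plasmid copy per min
    alpha_translation: float = 1.0
    beta_unfolded: float = 0.065
    tau_stress_min: float = 120.0            # activation ramp of the unfolded-pool arm; 0 = instant
    # fluorophore maturation half-times
    t50_red_min: float = 42.0
    t50_green_min: float = 14.0
    # measurement layer
    gain_red: float = 1.0
    gain_green: float = 1.0
    noise_cv: float = 0.25                  # multiplicative lognormal measurement noise
    background_red: float = 300.0
    background_green: float = 600.0
    # scatter channels (carried for gating only)
    fsc_logmean: float = 10.8
    fsc_logsd: float = 0.25
    ssc_logmean: float = 9.2
    ssc_logsd: float = 0.3
    # growth-curve generation (logistic), r interpolated linearly in Tm
    growth_n0: float = 0.5
    growth_k_cap: float = 1.5
    growth_r_min: float = 0.018             # min^-1 at the least stable end
    growth_r_max: float = 0.020             # min^-1 at the most stable end
    growth_r_replicate_cv: float = 0.05
    od_noise_cv: float = 0.01
    # toxicity switch: synthesis shuts off permanently above a POI load
    toxicity_enabled: bool = False
    toxicity_threshold: float = 2500.0       # total POI a.u. per cell
    # master seed for the generator
    rng_seed: int = 0

    def __post_init__(self) -> None:
        nonneg = ("k_syn", "k_syn_variant_cv", "k_syn_replicate_cv",
                  "stability_slope_s", "k_deg_basal",
                  "k_deg_unfolded", "k_agg", "basal_promoter", "alpha_translation",
                  "beta_unfolded", "noise_cv", "od_noise_cv",
                  "growth_r_replicate_cv", "preinduction_min", "tau_pqc_min",
                  "tau_stress_min", "initial_poi_mature")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 <= self.leak_fraction < 1):
            raise ValidationError("leak_fraction must lie in [0, 1)")
        for name in ("t50_red_min", "t50_green_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("background_red", "background_green"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0 (positivity floor)")

    @property
    def k_mat_red(self) -> float:
        return math.log(2.0) / self.t50_red_min

    @property
    def k_mat_green(self) -> float:
        return math.log(2.0) / self.t50_green_min

    def f_u(self, variant: VariantSpec) -> float:
        return fraction_unfolded(variant.tm_celsius, self.growth_temp_celsius,
                                 self.stability_slope_s)


STATE_NAMES = ("poi_immature", "poi_mature", "poi_dark", "gfp_immature", "gfp_mature")


@dataclass(frozen=True)
class CellState:
    """Per-cell species amounts (a.u.) at one instant."""

    poi_immature: float
    poi_mature: float
    poi_dark: float
    gfp_immature: float
    gfp_mature: float
    copy_number: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.poi_immature, self.poi_mature, self.poi_dark,
                         self.gfp_immature, self.gfp_mature], dtype=float)

    @property
    def poi_total(self) -> float:
        return self.poi_immature + self.poi_mature + self.poi_dark

    def unfolded(self, f_u: float) -> float:
        """Equilibrium unfolded pool U = f_u * (immature + mature POI)."""
        return f_u * (self.poi_immature + self.poi_mature)


@dataclass(frozen=True)
class GrowthCurve:
    """A sampled OD600 curve: strictly increasing times, positive OD."""

    times_min: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.shape != od.shape or t.ndim != 1:
            raise ValidationError("times_min and od600 must be 1-d arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError("times_min must be strictly increasing")
        if np.any(od <= 0):
            raise ValidationError("od600 must be positive")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "od600", od)


@dataclass(frozen=True)
class LogisticGrowth:
    """Logistic growth N(t) = K / (1 + (K/N0 - 1) exp(-r t)).

    ``mu(t) = d ln N / dt = r (1 - N/K)`` is the per-capita (dilution)
    rate fed into the cell ODE.  The curve extends naturally to t < 0,
    which covers the leaky-expression window before induction.
    """

    n0: float
    r: float
    k_cap: float

    def __post_init__(self) -> None:
        if not (0 < self.n0 < self.k_cap) or self.r <= 0:
            raise ValidationError("require 0 < n0 < k_cap and r > 0")

    def od(self, t_min):
        t = np.asarray(t_min, dtype=float)
        a = self.k_cap / self.n0 - 1.0
        return self.k_cap / (1.0 + a * np.exp(-self.r * t))

    def mu(self, t_min):
        return self.r * (1.0 - self.od(t_min) / self.k_cap)

    def curve(self, times_min) -> GrowthCurve:
        t = np.asarray(times_min, dtype=float)
        return GrowthCurve(t, np.asarray(self.od(t)))


@dataclass(frozen=True)
class CellTrajectory:
    """Deterministic solution of the cell ODE on a time grid."""

    times_min: np.ndarray
    states: np.ndarray            # shape (n_times, 5), columns = STATE_NAMES
    copy_number: float
    toxicity_off_time: float | None = None   # synthesis shutoff time, if triggered

    def state_at(self, i: int) -> CellState:
        return CellState(*self.states[i], copy_number=self.copy_number)

    def channel(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]


def _rhs_factory(params: KineticParams, f_u: float, k_syn_eff: float,
                 basal_eff: float, mu):
    """Right-hand side of the cell ODE for a fixed induction level.

    ``mu`` is a callable t -> per-capita growth rate (min^-1).
    """
    k_matR, k_matG = params.k_mat_red, params.k_mat_green
    k_agg = params.k_agg
    alpha, beta = params.alpha_translation, params.beta_unfolded
    kd0, kdu = params.k_deg_basal, params.k_deg_unfolded
    tau_pqc, tau_stress = params.tau_pqc_min, params.tau_stress_min

    def ramp(t, tau):
        # first-order activation of the induced arms of the response:
        # proteases (degradation) and the sigma32-mediated promoter
        # coupling to the unfolded pool both build up after t = 0
        if tau <= 0:
            return 1.0
        return -math.expm1(-max(t, 0.0) / tau)

    def rhs(t, y, induction):
        poi_i, poi_m, dark, gfp_i, gfp_m = y
        m = mu(t)
        kd = kd0 + kdu * f_u * ramp(t, tau_pqc)
        syn = k_syn_eff * induction
        a_prom = (basal_eff + alpha * syn
                  + beta * ramp(t, tau_stress) * f_u * (poi_i + poi_m))
        return [
            syn - (k_matR + kd + k_agg + m) * poi_i,
            k_matR * poi_i - (kd + k_agg + m) * poi_m,
            k_agg * (poi_i + poi_m) - m * dark,
            a_prom - (k_matG + m) * gfp_i,
            k_matG * gfp_i - m * gfp_m,
        ]

    return rhs


def simulate_cell(variant: VariantSpec, params: KineticParams, schedule_times,
                  growth: LogisticGrowth | None = None, copy_number: float = 1.0,
                  k_syn_replicate_factor: float = 1.0,
                  initial: CellState | None = None) -> CellTrajectory:
    """Integrate one cell's reporter ODE and report it on ``schedule_times``.

    Time 0 is induction.  If ``params.preinduction_min > 0`` and no
    explicit ``initial`` state is given, the cell is first equilibrated
    from an empty state over that window with synthesis scaled by
    ``leak_fraction``, so the t = 0 sample carries a leaky-expression
    baseline.  With ``toxicity_enabled``, synthesis shuts off
    permanently once the total POI pool (including the dark fraction)
    exceeds ``toxicity_threshold``; the shutoff time is recorded on the
    returned trajectory.

    The system is linear in the state, so for fixed growth and
    induction the solution scales linearly with ``copy_number`` (used by
    the population generator as a fast path when toxicity is off).
    """
    schedule = np.asarray(schedule_times, dtype=float)
    if schedule.ndim != 1 or schedule.size == 0:
        raise ValidationError("schedule_times must be a non-empty 1-d sequence")
    if np.any(np.diff(schedule) <= 0):
        raise ValidationError("schedule_times must be strictly increasing")
    if schedule[0] < 0:
        raise ValidationError("schedule starts at or after induction (t = 0)")
    if copy_number <= 0:
        raise ValidationError("copy_number must be > 0")

    f_u = params.f_u(variant)
    k_syn_eff = params.k_syn * k_syn_replicate_factor * copy_number
    basal_eff = params.basal_promoter * copy_number
    mu = growth.mu if growth is not None else (lambda t: 0.0)
    rhs = _rhs_factory(params, f_u, k_syn_eff, basal_eff, mu)

    if initial is not None:
        y0 = initial.as_array()
    else:
        y0 = np.zeros(5)
        y0[1] = params.initial_poi_mature * copy_number
        if params.preinduction_min > 0:
            sol = solve_ivp(rhs, (-params.preinduction_min, 0.0), y0,
                            args=(params.leak_fraction,), method="LSODA",
                            rtol=1e-9, atol=1e-12)
            if not sol.success or not np.all(np.isfinite(sol.y)):
                raise IntegrationError(
                    f"ODE integration failed near t = {sol.t[-1]:.3f} min (pre-induction)")
            y0 = sol.y[:, -1]

    out = np.empty((schedule.size, 5))
    start = 0
    if schedule[0] == 0.0:
        out[0] = y0
        start = 1
    t_rest = schedule[start:]
    tox_time: float | None = None

    if t_rest.size:
        if params.toxicity_enabled:
            thr = params.toxicity_threshold

            def hit_threshold(t, y, induction):
                return y[0] + y[1] + y[2] - thr

            hit_threshold.terminal = True
            hit_threshold.direction = 1.0
            sol = solve_ivp(rhs, (0.0, t_rest[-1]), y0, t_eval=t_rest,
                            args=(1.0,), method="LSODA", rtol=1e-9, atol=1e-12,
                            events=hit_threshold)
            if not sol.success or not np.all(np.isfinite(sol.y)):
                reached = sol.t[-1] if sol.t.size else 0.0
                raise IntegrationError(f"ODE integration failed near t = {reached:.3f} min")
            got = np.asarray(sol.t).size
            if got:
                out[start:start + got] = np.asarray(sol.y).T
            if sol.status == 1:  # threshold hit: continue with synthesis off
                tox_time = float(sol.t_events[0][0])
                y_ev = sol.y_events[0][0]
                remaining = t_rest[got:]
                if remaining.size:
                    sol2 = solve_ivp(rhs, (tox_time, t_rest[-1]), y_ev,
                                     t_eval=remaining, args=(0.0,), method="LSODA",
                                     rtol=1e-9, atol=1e-12)
                    if not sol2.success or not np.all(np.isfinite(sol2.y)):
                        reached = sol2.t[-1] if sol2.t.size else tox_time
                        raise IntegrationError(
                            f"ODE integration failed near t = {reached:.3f} min")
                    out[start + got:] = sol2.y.T
        else:
            sol = solve_ivp(rhs, (0.0, t_rest[-1]), y0, t_eval=t_rest,
                            args=(1.0,), method="LSODA", rtol=1e-9, atol=1e-12)
            if not sol.success or not np.all(np.isfinite(sol.y)):
                reached = sol.t[-1] if sol.t.size else 0.0
                raise IntegrationError(f"ODE integration failed near t = {reached:.3f} min")
            out[start:] = sol.y.T

    # integration of a non-negative linear system can undershoot zero at
    # the solver tolerance; clip so downstream positivity holds exactly
    np.clip(out, 0.0, None, out=out)
    return CellTrajectory(schedule, out, copy_number, tox_time)
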