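"""Logistic growth fitting, maximum specific growth rate, dilution bias.

OD600 curves are fit to the logistic model

    N(t) = K / (1 + (K/N0 - 1) exp(-r t))

by nonlinear least squares.  Uncertainty comes from a seeded residual
bootstrap by default (500 refits), or from an affine-invariant MCMC
ensemble with uniform priors behind the same interface.  The maximum
growth rate is the maximum of the *specific* (per-capita) rate
``mu(t) = d ln N / dt = r (1 - N(t)/K)`` over the observed window,
evaluated numerically for each posterior draw (a switch to the
absolute rate dN/dt is provided).

Growth also biases fluorescence rates: dilution depresses every
per-cell concentration, so the relative rate of a fluorescence summary
is lowered by the time-averaged specific growth rate over the same
window,

    <mu> = [ln N(t_end) - ln N(t_start)] / (t_end - t_start),

which :func:`dilution_bias` computes from a fitted curve and
:func:`dilution_spread` summarises across variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import GrowthFitError, ValidationError
from .kinetics import GrowthCurve, LogisticGrowth

__all__ = [
    "GrowthFit",
    "fit_logistic",
    "max_growth_rate",
    "dilution_bias",
    "dilution_spread",
]


def _logistic(t, n0, r, k_cap):
    a = k_cap / n0 - 1.0
    return k_cap / (1.0 + a * np.exp(-r * t))


@dataclass
class GrowthFit:
    """Point estimate and posterior draws of a logistic growth fit."""

    n0: float
    r: float            # min^-1
    k_cap: float
    times_min: np.ndarray
    od600: np.ndarray
    posterior_samples: np.ndarray          # (m, 3) rows of (n0, r, k_cap)
    mu_max: float | None = None            # filled by max_growth_rate
    mu_max_sd: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.n0 < self.k_cap) or self.r <= 0:
            raise ValidationError("growth fit requires 0 < n0 < k_cap and r > 0")

    @property
    def model(self) -> LogisticGrowth:
        return LogisticGrowth(self.n0, self.r, self.k_cap)


_BOUNDS = ((1e-8, 1e-8, 1e-8), (100.0, 1.0, 1e4))


def _point_fit(t: np.ndarray, od: np.ndarray) -> np.ndarray:
    n0_init = max(float(od[0]), 1e-6)
    k_init = max(float(od.max()) * 1.05, n0_init * 1.5)
    # crude r from the log-slope of the first half of the curve
    half = max(len(t) // 2, 2)
    r_init = max(float(np.polyfit(t[:half], np.log(od[:half]), 1)[0]), 1e-4)
    p0 = (n0_init, min(r_init, 0.5), k_init)
    popt, _ = curve_fit(_logistic, t, od, p0=p0, bounds=_BOUNDS, maxfev=20000)
    return popt


def fit_logistic(curve: GrowthCurve, uncertainty: str = "bootstrap",
                 n_samples: int = 500, seed: int = 0) -> GrowthFit:
    """Fit the logistic model and populate posterior samples.

    ``uncertainty='bootstrap'`` refits ``n_samples`` residual-resampled
    curves (seeded).  ``uncertainty='mcmc'`` runs an emcee ensemble with
    uniform priors on (n0, r, K) over the fitting bounds and a Gaussian
    likelihood whose sigma is the residual standard deviation.
    """
    t = np.asarray(curve.times_min, dtype=float)
    od = np.asarray(curve.od600, dtype=float)
    if t.size < 5:
        raise ValidationError(f"need >= 5 growth points, got {t.size}")
    if np.any(od <= 0):
        raise ValidationError("OD values must be positive")
    if np.all(np.diff(od) <= 0):
        raise ValidationError("monotone-decreasing OD curve is not growth")
    if float(np.ptp(od)) / float(od.mean()) < 1e-9:
        raise ValidationError("constant OD curve: growth rate unidentifiable")
    try:
        popt = _point_fit(t, od)
    except RuntimeError as exc:
        resid = "n/a"
        raise GrowthFitError(f"logistic fit did not converge: {exc}; "
                             f"residual diagnostics: {resid}") from exc
    fitted = _logistic(t, *popt)
    residuals = od - fitted

    if uncertainty == "bootstrap":
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        draws = []
        for _ in range(n_samples):
            od_b = fitted + rng.choice(residuals, size=residuals.size, replace=True)
            od_b = np.maximum(od_b, 1e-9)
            try:
                draws.append(_point_fit(t, od_b))
            except RuntimeError:
                continue  # rare non-convergent resample; skip
        if not draws:
            raise GrowthFitError("all bootstrap refits failed")
        samples = np.asarray(draws)
    elif uncertainty == "mcmc":
        samples = _mcmc_samples(t, od, popt, residuals, n_samples, seed)
    else:
        raise ValidationError(f"unknown uncertainty method {uncertainty!r}")
    return GrowthFit(float(popt[0]), float(popt[1]), float(popt[2]),
                     t, od, samples)


def _mcmc_samples(t, od, popt, residuals, n_samples, seed):
    import emcee

    sigma = max(float(np.std(residuals)), 1e-9)
    lo = np.asarray(_BOUNDS[0])
    hi = np.asarray(_BOUNDS[1])

    def log_prob(theta):
        if np.any(theta <= lo) or np.any(theta >= hi) or theta[0] >= theta[2]:
            return -np.inf
        resid = od - _logistic(t, *theta)
        return -0.5 * float(resid @ resid) / sigma**2

    nwalkers, ndim = 16, 3
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p0 = popt * (1.0 + 1e-3 * rng.standard_normal((nwalkers, ndim)))
    p0 = np.clip(p0, lo * 1.01, hi * 0.99)
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob)
    state = sampler.run_mcmc(p0, 500 + max(n_samples // nwalkers, 1),
                             progress=False, skip_initial_state_check=True,
                             rstate0=np.random.RandomState(seed).get_state())
    chain = sampler.get_chain(discard=500, flat=True)
    return chain[:n_samples]


def max_growth_rate(fit: GrowthFit, absolute: bool = False,
                    n_grid: int = 481) -> tuple[float, float]:
    """Posterior mean and sd of the maximum growth rate over the window.

    For each posterior draw the growth-rate curve is evaluated on a
    time grid spanning the observed window and its maximum taken:
    specific rate ``mu(t) = r (1 - N/K)`` by default, absolute rate
    ``dN/dt = r N (1 - N/K)`` with ``absolute=True``.  Results are
    cached on ``fit.mu_max`` / ``fit.mu_max_sd``.
    """
    if fit.posterior_samples.size == 0:
        raise ValidationError("posterior_samples is empty")
    grid = np.linspace(fit.times_min[0], fit.times_min[-1], n_grid)
    maxima = []
    for n0, r, k in fit.posterior_samples:
        n = _logistic(grid, n0, r, k)
        mu = r * (1.0 - n / k)
        if absolute:
            mu = mu * n
        maxima.append(float(mu.max()))
    maxima = np.asarray(maxima)
    mu_max = float(maxima.mean())
    mu_sd = float(maxima.std(ddof=1)) if maxima.size > 1 else 0.0
    fit.mu_max, fit.mu_max_sd = mu_max, mu_sd
    return mu_max, mu_sd


def dilution_bias(fit: GrowthFit, window: tuple[float, float]) -> float:
    """Time-averaged specific growth rate over a window (min^-1).

    This is the additive depression that growth dilution alone imposes
    on a per-cell relative fluorescence rate over the same window.
    """
    lo, hi = window
    if not (lo < hi):
        raise ValidationError(f"degenerate window {window}")
    t0, t1 = fit.times_min[0], fit.times_min[-1]
    if lo < t0 - 1e-9 or hi > t1 + 1e-9:
        raise ValidationError(f"window {window} outside observed times [{t0:g}, {t1:g}]")
    model = fit.model
    return float((math.log(model.od(hi)) - math.log(model.od(lo))) / (hi - lo))


def dilution_spread(fits: list[GrowthFit], window: tuple[float, float],
                    reference_rate: float | None = None) -> dict:
    """Mean and sample sd (ddof=1) of dilution bias across fits.

    With ``reference_rate`` the sd is also expressed as a percentage of
    that relative rate, the scale on which dilution distorts the
    fluorescence-rate comparisons.
    """
    if len(fits) < 2:
        raise ValidationError("need >= 2 growth fits to compute a spread")
    biases = np.asarray([dilution_bias(f, window) for f in fits])
    out = {"window": (float(window[0]), float(window[1])),
           "mean": float(biases.mean()), "sd": float(biases.std(ddof=1)),
           "n": len(fits), "sd_convention": "sample (ddof=1)"}
    if reference_rate is not None:
        if reference_rate == 0:
            raise ValidationError("reference_rate must be nonzero")
        out["sd_percent_of_reference"] = 100.0 * out["sd"] / abs(reference_rate)
        out["mean_percent_of_reference"] = 100.0 * out["mean"] / abs(reference_rate)
    return out
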