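"""Synthetic single-cell fluorescence time series and OD600 curves.

Emulates a flow-cytometry time course: a panel of protein variants with
different melting temperatures, each expressed in triplicate, sampled on
a dense early / sparse late schedule with ~3000 events per sample.  The
per-cell kinetics live in :mod:`dnakflow.kinetics`; this module adds the
population layers on top:

* per-replicate synthesis-strength variation (day-to-day induction),
* lognormal plasmid copy-number spread across cells,
* multiplicative lognormal measurement noise plus additive background
  on both fluorescence channels (the background floor keeps every
  channel strictly positive, so log transforms are always defined),
* stationary lognormal forward/side scatter placeholders for gating,
* a logistic growth curve per variant/replicate whose per-capita rate
  feeds back into the cell ODE as dilution.

With toxicity off the cell ODE is linear in copy number, so one
unit-copy trajectory per variant/replicate is integrated and scaled per
cell -- each timepoint then draws a fresh set of cells, as a cytometer
sampling from a large culture does.  With toxicity on, cells switch
synthesis off at a copy-number-dependent time, so a fixed cohort of
cells is integrated individually instead.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .kinetics import GrowthCurve, KineticParams, LogisticGrowth, simulate_cell
from .variants import VariantSpec, tm_map

__all__ = [
    "DEFAULT_SCHEDULE",
    "EventRecord",
    "TimepointSample",
    "default_schedule",
    "growth_model_for",
    "simulate_population",
    "generate_panel",
    "noiseless_mean_red",
    "write_dataset",
    "read_dataset",
]

#: Sampling schedule (minutes after induction): just before induction,
#: 2 min, every 5 min to 30 min, every 10 min to 120 min, every 30 min
#: to 240 min.  21 timepoints.
DEFAULT_SCHEDULE = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0,
                    40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0, 110.0, 120.0,
                    150.0, 180.0, 210.0, 240.0)

# Tm range (degC) over which the growth-rate interpolation spans;
# matches the span of the default variant panel.
GROWTH_TM_LO = 8.0
GROWTH_TM_HI = 61.0

EVENT_COLUMNS = ("fsc", "ssc", "red", "green")


def default_schedule() -> np.ndarray:
    return np.asarray(DEFAULT_SCHEDULE, dtype=float)


@dataclass(frozen=True)
class EventRecord:
    """One cytometry event; all channels strictly positive."""

    fsc: float
    ssc: float
    red: float
    green: float

    def __post_init__(self) -> None:
        for name in EVENT_COLUMNS:
            if not (getattr(self, name) > 0):
                raise ValidationError(f"event channel {name} must be > 0")


@dataclass
class TimepointSample:
    """All events for one variant / replicate / timepoint.

    ``events`` is a DataFrame with columns fsc, ssc, red, green; rows
    are exchangeable (event order carries no meaning).
    """

    variant: str
    replicate: int
    time_min: float
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError("replicate must be >= 1")
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValidationError(f"events table missing columns {missing}")
        self.events = self.events.loc[:, list(EVENT_COLUMNS)].astype(float).reset_index(drop=True)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def key(self) -> tuple[str, int, float]:
        return (self.variant, self.replicate, self.time_min)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size)


def growth_model_for(variant: VariantSpec, params: KineticParams,
                     replicate_factor: float = 1.0) -> LogisticGrowth:
    """Logistic growth model for a variant.

    The intrinsic rate interpolates linearly in Tm between
    ``growth_r_min`` and ``growth_r_max`` (more stable variants burden
    the cell less and grow faster), scaled by a per-replicate factor.
    """
    frac = (variant.tm_celsius - GROWTH_TM_LO) / (GROWTH_TM_HI - GROWTH_TM_LO)
    frac = min(max(frac, 0.0), 1.0)
    r = (params.growth_r_min + (params.growth_r_max - params.growth_r_min) * frac)
    return LogisticGrowth(params.growth_n0, r * replicate_factor, params.growth_k_cap)


def _emit_events(rng: np.random.Generator, params: KineticParams, n_cells: int,
                 poi_mature_per_copy: float, gfp_mature_per_copy: float,
                 copy_numbers: np.ndarray | None = None) -> pd.DataFrame:
    if copy_numbers is None:
        copy_numbers = rng.lognormal(params.copy_number_logmean,
                                     params.copy_number_logsd, n_cells)
    red = (params.gain_red * copy_numbers * poi_mature_per_copy + params.background_red)
    green = (params.gain_green * copy_numbers * gfp_mature_per_copy + params.background_green)
    red = red * _lognormal_noise(rng, params.noise_cv, n_cells)
    green = green * _lognormal_noise(rng, params.noise_cv, n_cells)
    fsc = rng.lognormal(params.fsc_logmean, params.fsc_logsd, n_cells)
    ssc = rng.lognormal(params.ssc_logmean, params.ssc_logsd, n_cells)
    return pd.DataFrame({"fsc": fsc, "ssc": ssc, "red": red, "green": green})


def simulate_population(variant: VariantSpec, params: KineticParams,
                        n_cells: int = 3000, replicate_seed: int = 0,
                        replicate: int = 1, schedule=None,
                        variant_syn_factor: float = 1.0,
                        ) -> tuple[list[TimepointSample], GrowthCurve]:
    """Simulate one variant/replicate culture over the sampling schedule.

    ``variant_syn_factor`` is the variant-level translation-rate factor
    (shared by all replicates of a variant; drawn by
    :func:`generate_panel`); on top of it each replicate draws its own
    induction-strength factor.  Returns one :class:`TimepointSample`
    per schedule time plus the replicate's (noisy) OD600 curve.
    Identical seed, factor and parameters reproduce the output exactly.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    schedule = default_schedule() if schedule is None else np.asarray(schedule, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(replicate_seed))

    # replicate-level draws, in a fixed order for reproducibility
    k_syn_factor = variant_syn_factor * float(
        _lognormal_noise(rng, params.k_syn_replicate_cv, ()))
    growth_factor = float(_lognormal_noise(rng, params.growth_r_replicate_cv, ()))
    growth = growth_model_for(variant, params, growth_factor)

    samples: list[TimepointSample] = []
    if params.toxicity_enabled:
        # fixed cohort: each cell has its own shutoff time via its copy number
        copy_numbers = rng.lognormal(params.copy_number_logmean,
                                     params.copy_number_logsd, n_cells)
        poi_m = np.empty((n_cells, schedule.size))
        gfp_m = np.empty((n_cells, schedule.size))
        for i, c in enumerate(copy_numbers):
            traj = simulate_cell(variant, params, schedule, growth=growth,
                                 copy_number=float(c),
                                 k_syn_replicate_factor=k_syn_factor)
            poi_m[i] = traj.channel("poi_mature")
            gfp_m[i] = traj.channel("gfp_mature")
        for j, t in enumerate(schedule):
            # per-cell amounts are already copy-scaled: emit with unit copies
            events = _emit_events(rng, params, n_cells, 0.0, 0.0,
                                  copy_numbers=np.ones(n_cells))
            red = (params.gain_red * poi_m[:, j] + params.background_red)
            green = (params.gain_green * gfp_m[:, j] + params.background_green)
            events["red"] = red * _lognormal_noise(rng, params.noise_cv, n_cells)
            events["green"] = green * _lognormal_noise(rng, params.noise_cv, n_cells)
            samples.append(TimepointSample(variant.name, replicate, float(t), events))
    else:
        unit = simulate_cell(variant, params, schedule, growth=growth,
                             copy_number=1.0, k_syn_replicate_factor=k_syn_factor)
        poi_m = unit.channel("poi_mature")
        gfp_m = unit.channel("gfp_mature")
        for j, t in enumerate(schedule):
            events = _emit_events(rng, params, n_cells, poi_m[j], gfp_m[j])
            samples.append(TimepointSample(variant.name, replicate, float(t), events))

    od = np.asarray(growth.od(schedule)) * _lognormal_noise(rng, params.od_noise_cv,
                                                            schedule.size)
    return samples, GrowthCurve(schedule, od)


def generate_panel(panel: list[VariantSpec], params: KineticParams,
                   n_replicates: int = 3, n_cells: int = 3000, schedule=None,
                   master_seed: int | None = None,
                   ) -> tuple[list[TimepointSample], dict[tuple[str, int], GrowthCurve]]:
    """Simulate the full variant panel with independent replicate streams.

    Per-replicate seeds are spawned deterministically from the master
    seed (default ``params.rng_seed``) keyed by variant index and
    replicate number, so any subset of the panel reproduces exactly.
    """
    if master_seed is None:
        master_seed = params.rng_seed
    tm_map(panel)  # validates distinct names
    samples: list[TimepointSample] = []
    growth_curves: dict[tuple[str, int], GrowthCurve] = {}
    for vi, variant in enumerate(panel):
        vrng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(vi,)))
        v_factor = float(_lognormal_noise(vrng, params.k_syn_variant_cv, ()))
        for rep in range(1, n_replicates + 1):
            ss = np.random.SeedSequence(master_seed, spawn_key=(vi, rep))
            rep_seed = int(ss.generate_state(1)[0])
            s, g = simulate_population(variant, params, n_cells=n_cells,
                                       replicate_seed=rep_seed, replicate=rep,
                                       schedule=schedule,
                                       variant_syn_factor=v_factor)
            samples.extend(s)
            growth_curves[(variant.name, rep)] = g
    return samples, growth_curves


def noiseless_mean_red(variant: VariantSpec, params: KineticParams, schedule=None,
                       ) -> np.ndarray:
    """Deterministic population-mean red channel (no noise layers).

    Uses the unit-copy ODE solution scaled by the mean plasmid copy
    number; the replicate jitter and measurement noise are excluded.
    Useful as an exact reference for monotonicity checks.
    """
    schedule = default_schedule() if schedule is None else np.asarray(schedule, dtype=float)
    growth = growth_model_for(variant, params)
    unit = simulate_cell(variant, params, schedule, growth=growth)
    c_bar = math.exp(params.copy_number_logmean + params.copy_number_logsd ** 2 / 2.0)
    return params.gain_red * c_bar * unit.channel("poi_mature") + params.background_red


# ---------------------------------------------------------------------------
# on-disk format: one comma-delimited table per sample + YAML manifest


def _time_token(t: float) -> str:
    return f"{t:g}".replace(".", "p")


def _sample_filename(s: TimepointSample) -> str:
    return f"{s.variant}_{s.replicate}_{_time_token(s.time_min)}min.csv"


def write_dataset(samples: list[TimepointSample],
                  growth_curves: dict[tuple[str, int], GrowthCurve],
                  out_dir, params: KineticParams | None = None,
                  panel: list[VariantSpec] | None = None,
                  seed: int | None = None) -> dict:
    """Write event tables, growth tables and a YAML manifest.

    One ``{variant}_{replicate}_{time}min.csv`` per sample (columns
    fsc,ssc,red,green), one ``{variant}_{replicate}_growth.csv`` per
    growth curve (columns time_min,od600).  Floats are written with
    round-tripping precision so :func:`read_dataset` restores the data
    exactly.  Returns the manifest dict (also written to
    ``manifest.yaml``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    event_tables = []
    for s in samples:
        fname = _sample_filename(s)
        s.events.to_csv(out / fname, index=False, float_format="%.17g")
        event_tables.append({"file": fname, "variant": s.variant,
                             "replicate": int(s.replicate),
                             "time_min": float(s.time_min),
                             "n_events": int(s.n_events)})
    growth_tables = []
    for (variant, rep), curve in sorted(growth_curves.items()):
        fname = f"{variant}_{rep}_growth.csv"
        pd.DataFrame({"time_min": curve.times_min,
                      "od600": curve.od600}).to_csv(out / fname, index=False,
                                    float_format="%.17g")
        growth_tables.append({"file": fname, "variant": variant, "replicate": int(rep)})
    manifest: dict = {
        "format": "dnakflow-dataset/1",
        "event_tables": event_tables,
        "growth_tables": growth_tables,
    }
    if panel is not None:
        manifest["variants"] = [
            {"name": v.name, "tm_celsius": float(v.tm_celsius),
             "is_wild_type": bool(v.is_wild_type), "description": v.description}
            for v in panel]
    if params is not None:
        manifest["parameters"] = {k: (float(v) if isinstance(v, (int, float)) and
                                      not isinstance(v, bool) else v)
                                  for k, v in dataclasses.asdict(params).items()}
    if seed is not None:
        manifest["seed"] = int(seed)
    schedule = sorted({float(e["time_min"]) for e in event_tables})
    manifest["schedule"] = schedule
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def read_dataset(in_dir) -> tuple[list[TimepointSample],
                                  dict[tuple[str, int], GrowthCurve], dict]:
    """Read a dataset written by :func:`write_dataset`."""
    root = Path(in_dir)
    manifest_path = root / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.yaml in {root}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    samples = []
    for entry in manifest.get("event_tables", []):
        events = pd.read_csv(root / entry["file"], float_precision="round_trip")
        samples.append(TimepointSample(entry["variant"], int(entry["replicate"]),
                                       float(entry["time_min"]), events))
    growth_curves = {}
    for entry in manifest.get("growth_tables", []):
        df = pd.read_csv(root / entry["file"], float_precision="round_trip")
        growth_curves[(entry["variant"], int(entry["replicate"]))] = GrowthCurve(
            df["time_min"].to_numpy(), df["od600"].to_numpy())
    return samples, growth_curves, manifest
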