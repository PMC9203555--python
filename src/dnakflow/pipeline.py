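"""End-to-end pipeline: generate -> summarize -> correlate -> cluster ->
growth/dilution, with a single self-describing report.

A run is fully determined by a :class:`PipelineConfig` (variant panel,
kinetic parameters, gate, windows, mixture and growth settings, master
seed): rerunning with the same config and seed reproduces every output
table byte for byte.  Per-stage randomness is derived from the master
seed with fixed stream keys, so stages stay reproducible even if run
selectively.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation_analysis import rate_track_vs_tm, rate_vs_rate, track_vs_tm
from .errors import ConfigError, ValidationError
from .growth_analysis import dilution_spread, fit_logistic, max_growth_rate
from .kinetics import KineticParams
from .population_structure import MixtureConfig, effective_components, fit_mixture
from .summaries_rates import (DEFAULT_WINDOWS, GateSpec, percentile_gate,
                              rate_table, summarize)
from .synthetic_data import (default_schedule, generate_panel, write_dataset)
from .variants import VariantSpec, default_panel, tm_map, validate_panel

logger = logging.getLogger("dnakflow.pipeline")

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]

#: Windows used for the headline rate statistics.
EARLY_WINDOW = (0.0, 30.0)
LATE_WINDOW = (150.0, 180.0)
RATIO_TIME = 120.0


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs."""

    panel: list[VariantSpec] = field(default_factory=default_panel)
    params: KineticParams = field(default_factory=KineticParams)
    n_replicates: int = 3
    n_cells: int = 3000
    windows: tuple = DEFAULT_WINDOWS
    gate_percentiles: tuple[float, float] = (1.0, 99.0)
    gate: GateSpec | None = None            # explicit gate overrides percentiles
    ratio_of_means: bool = False
    mixture: MixtureConfig = field(default_factory=MixtureConfig)
    mixture_variants: list[str] | None = None   # default: least stable + wild type
    mixture_times: tuple = (0.0, 90.0, 240.0)
    mixture_replicate: int = 1
    growth_uncertainty: str = "bootstrap"
    growth_n_samples: int = 200
    seed: int = 0
    out_dir: str = "dnakflow_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            try:
                raw = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        panel = [VariantSpec(**v) for v in raw.pop("panel")] if "panel" in raw else default_panel()
        params = KineticParams(**raw.pop("params", {}))
        mixture = MixtureConfig(**raw.pop("mixture", {}))
        gate = raw.pop("gate", None)
        if gate is not None:
            gate = GateSpec(tuple(gate["fsc_bounds"]), tuple(gate["ssc_bounds"]))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("windows", "mixture_times"):
            if key in raw:
                raw[key] = tuple(tuple(w) if isinstance(w, (list, tuple)) else w
                                 for w in raw[key])
        return cls(panel=panel, params=params, mixture=mixture, gate=gate, **raw)

    def to_dict(self) -> dict:
        return {
            "panel": [dataclasses.asdict(v) for v in self.panel],
            "params": dataclasses.asdict(self.params),
            "mixture": dataclasses.asdict(self.mixture),
            "gate": None if self.gate is None else dataclasses.asdict(self.gate),
            **{f.name: getattr(self, f.name) for f in dataclasses.fields(self)
               if f.name not in ("panel", "params", "mixture", "gate")},
        }


def validate_config(config: PipelineConfig) -> list[str]:
    """Human-readable findings; empty list means the config is valid."""
    findings: list[str] = []
    try:
        validate_panel(config.panel)
    except ValidationError as exc:
        findings.append(str(exc))
    tmm = {v.name: v.tm_celsius for v in config.panel}
    schedule = default_schedule()
    span = (schedule[0], schedule[-1])
    for lo, hi in config.windows:
        if not (lo < hi):
            findings.append(f"window [{lo:g}, {hi:g}] is degenerate")
        elif lo < span[0] or hi > span[1]:
            findings.append(f"window [{lo:g}, {hi:g}] lies outside the "
                            f"schedule span [{span[0]:g}, {span[1]:g}]")
    for name in (config.mixture_variants or []):
        if name not in tmm:
            findings.append(f"mixture variant {name!r} is not in the panel")
    for t in config.mixture_times:
        if t not in schedule:
            findings.append(f"mixture time {t:g} min is not a schedule time")
    if config.n_replicates < 1:
        findings.append("n_replicates must be >= 1")
    if config.n_cells < 1:
        findings.append("n_cells must be >= 1")
    if config.seed is None:
        findings.append("master seed must be set")
    return findings


@dataclass
class RunReport:
    """Manifest of produced tables plus the headline metrics."""

    manifest: dict
    metrics: dict
    config: dict
    version: str = __version__

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "metrics": self.metrics,
                       "manifest": self.manifest, "config": self.config},
                      fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _write_csv(df: pd.DataFrame, out: Path, name: str, manifest: dict) -> None:
    df.to_csv(out / name, index=False)
    manifest.setdefault("tables", []).append(name)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order and write every table under out_dir."""
    findings = validate_config(config)
    if findings:
        raise ConfigError("invalid config: " + "; ".join(findings))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"out_dir": str(out)}
    metrics: dict = {}
    tmm = tm_map(config.panel)
    t_start = time.time()

    def stage(name):
        logger.info("stage %-10s start (t+%.1fs)", name, time.time() - t_start)

    try:
        stage("generate")
        samples, growth_curves = generate_panel(
            config.panel, config.params, n_replicates=config.n_replicates,
            n_cells=config.n_cells, master_seed=config.seed)
        write_dataset(samples, growth_curves, out / "dataset",
                      params=config.params, panel=config.panel, seed=config.seed)
        manifest["dataset"] = str(out / "dataset")
        logger.info("generated %d samples", len(samples))

        stage("summarize")
        gate = config.gate or percentile_gate(samples, *config.gate_percentiles)
        summaries = []
        for v in config.panel:
            for rep in range(1, config.n_replicates + 1):
                group = [s for s in samples
                         if s.variant == v.name and s.replicate == rep]
                summaries.append(summarize(group, gate,
                                           ratio_of_means=config.ratio_of_means))
        _write_csv(pd.concat([s.to_frame() for s in summaries]),
                   out, "summaries.csv", manifest)
        rates = rate_table(summaries, windows=config.windows)
        _write_csv(rates, out, "rates.csv", manifest)

        stage("correlate")
        tracks = {
            "red_vs_tm": track_vs_tm(summaries, tmm, "red"),
            "green_vs_tm": track_vs_tm(summaries, tmm, "green"),
            "ratio_vs_tm": track_vs_tm(summaries, tmm, "ratio"),
            "green_rate_vs_tm": rate_track_vs_tm(rates, tmm, "green"),
            "red_rate_vs_tm": rate_track_vs_tm(rates, tmm, "red"),
            "ratio_rate_vs_tm": rate_track_vs_tm(rates, tmm, "ratio"),
            "green_rate_vs_red_rate": rate_vs_rate(
                rates[rates["channel"] == "green"],
                rates[rates["channel"] == "red"]),
        }
        _write_csv(pd.concat([t.to_frame() for t in tracks.values()]),
                   out, "correlations.csv", manifest)
        metrics["early_green_vs_red_rate_rho"] = tracks[
            "green_rate_vs_red_rate"].rho_at(EARLY_WINDOW)
        metrics["late_green_rate_vs_tm_rho"] = tracks[
            "green_rate_vs_tm"].rho_at(LATE_WINDOW)
        metrics["ratio_vs_tm_rho_at_120min"] = tracks["ratio_vs_tm"].rho_at(RATIO_TIME)

        stage("cluster")
        mix_variants = config.mixture_variants
        if mix_variants is None:
            by_tm = sorted(config.panel, key=lambda v: v.tm_celsius)
            wt = next(v for v in config.panel if v.is_wild_type)
            mix_variants = list(dict.fromkeys([by_tm[0].name, wt.name]))
        mixture_rows = []
        eff_counts: dict[str, dict[float, int]] = {}
        for name in mix_variants:
            eff_counts[name] = {}
            for t in config.mixture_times:
                sample = next(s for s in samples
                              if s.variant == name
                              and s.replicate == config.mixture_replicate
                              and s.time_min == t)
                seed_k = int(np.random.SeedSequence(
                    config.seed, spawn_key=(zlib.crc32(name.encode()), int(t))
                ).generate_state(1)[0] % 2**31)
                fit = fit_mixture(sample.events, config.mixture, seed=seed_k)
                n_eff = effective_components(fit)
                eff_counts[name][t] = n_eff
                mixture_rows.append(dict(
                    variant=name, time_min=t, n_effective=n_eff,
                    converged=fit.converged, elbo=fit.elbo,
                    weights=";".join(f"{w:.4f}" for w in
                                     sorted(fit.weights, reverse=True))))
        _write_csv(pd.DataFrame(mixture_rows), out, "mixtures.csv", manifest)
        metrics["effective_components"] = eff_counts

        stage("growth")
        growth_rows = []
        fits = {}
        for (vname, rep), curve in sorted(growth_curves.items()):
            seed_g = int(np.random.SeedSequence(
                config.seed, spawn_key=(zlib.crc32(vname.encode()), rep, 7)
            ).generate_state(1)[0] % 2**31)
            fit = fit_logistic(curve, uncertainty=config.growth_uncertainty,
                               n_samples=config.growth_n_samples, seed=seed_g)
            mu, sd = max_growth_rate(fit)
            fits[(vname, rep)] = fit
            growth_rows.append(dict(variant=vname, replicate=rep, n0=fit.n0,
                                    r=fit.r, k_cap=fit.k_cap,
                                    mu_max=mu, mu_max_sd=sd))
        _write_csv(pd.DataFrame(growth_rows), out, "growth_fits.csv", manifest)
        metrics["mu_max_per_variant"] = {
            v.name: float(np.mean([fits[(v.name, r)].mu_max
                                   for r in range(1, config.n_replicates + 1)]))
            for v in config.panel}

        early_ok = rates[(rates["channel"] == "red") & (rates["status"] == "ok")
                         & (rates["window_start"] == EARLY_WINDOW[0])
                         & (rates["window_end"] == EARLY_WINDOW[1])]
        ref = float(early_ok["relative_rate"].mean())
        dil_rows = []
        for window in (EARLY_WINDOW, (60.0, 90.0), LATE_WINDOW):
            spread = dilution_spread(list(fits.values()), window, reference_rate=ref)
            dil_rows.append(dict(window_start=window[0], window_end=window[1],
                                 **{k: v for k, v in spread.items()
                                    if k != "window"}))
        _write_csv(pd.DataFrame(dil_rows), out, "dilution.csv", manifest)
        metrics["dilution_sd_pct_early"] = dil_rows[0]["sd_percent_of_reference"]
        metrics["dilution_sd_pct_late"] = dil_rows[-1]["sd_percent_of_reference"]
    except Exception:
        manifest["status"] = "aborted"
        (out / "MANIFEST.partial.json").write_text(
            json.dumps(manifest, indent=2, default=_jsonable))
        raise

    manifest["status"] = "complete"
    report = RunReport(manifest, metrics, config.to_dict())
    report.to_json(out / "report.json")
    return report
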