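import numpy as np
import pytest

from dnakflow.correlation_analysis import (rate_track_vs_tm, rate_vs_rate,
                                           track_vs_tm)
from dnakflow.kinetics import KineticParams
from dnakflow.summaries_rates import percentile_gate, rate_table, summarize
from dnakflow.synthetic_data import generate_panel
from dnakflow.variants import VariantSpec, default_panel, tm_map


class ConstantGrowth:
    """Constant per-capita growth rate, for closed-form comparisons."""

    def __init__(self, mu):
        self._mu = mu

    def mu(self, t):
        return self._mu


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def wt_variant():
    return VariantSpec("wt", 55.0, is_wild_type=True)


@pytest.fixture
def quiet_params():
    """Parameters with all noise layers off: deterministic trajectories."""
    return KineticParams(k_syn_variant_cv=0.0, k_syn_replicate_cv=0.0,
                         noise_cv=0.0, od_noise_cv=0.0,
                         growth_r_replicate_cv=0.0, copy_number_logsd=0.0)


@pytest.fixture
def short_schedule():
    return np.array([0.0, 5.0, 10.0, 20.0, 30.0, 60.0, 120.0, 240.0])


def panel_headline_stats(seed, n_cells=3000):
    """Run the full statistical chain on one default-panel realisation.

    Returns the headline rank correlations: early green-vs-red rate,
    early green rate vs Tm, late (150-180 min) green rate vs Tm,
    GFP/RFP ratio at 120 min vs Tm, and mean red at 120 min vs Tm.
    """
    panel = default_panel()
    tmm = tm_map(panel)
    params = KineticParams(rng_seed=seed)
    samples, _ = generate_panel(panel, params, n_cells=n_cells)
    gate = percentile_gate(samples)
    summaries = []
    for v in panel:
        for rep in (1, 2, 3):
            group = [s for s in samples
                     if s.variant == v.name and s.replicate == rep]
            summaries.append(summarize(group, gate))
    rates = rate_table(summaries)
    early = (0.0, 30.0)
    late = (150.0, 180.0)
    gr = rate_vs_rate(rates[rates["channel"] == "green"],
                      rates[rates["channel"] == "red"])
    g_tm = rate_track_vs_tm(rates, tmm, "green")
    ratio_track = track_vs_tm(summaries, tmm, "ratio")
    red_track = track_vs_tm(summaries, tmm, "red")
    return {
        "early_green_vs_red": gr.rho_at(early),
        "early_green_vs_tm": g_tm.rho_at(early),
        "late_green_vs_tm": g_tm.rho_at(late),
        "ratio120_vs_tm": ratio_track.rho_at(120.0),
        "red120_vs_tm": red_track.rho_at(120.0),
    }


@pytest.fixture(scope="session")
def headline_stats_20_seeds():
    """Headline statistics across 20 independent panel realisations."""
    return [panel_headline_stats(seed) for seed in range(20)]
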