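"""Synthetic datasets with known ground truth for every experiment class.

``generate`` simulates a protocol under a truth parameter set, maps the
trajectory to the measured signal and adds seeded i.i.d. Gaussian noise:
a fraction of the signal's dynamic range for optical traces and
titrations, an absolute concentration (a fraction of total DNA) for
quench-flow tables.  ``generate_suite`` emits the full multi-experiment
suite for one substrate, and ``recovery_experiment`` runs the
generate -> global-fit loop over seeds and reports recovered vs truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigurationError, RateConstantSet
from .fitting import FitDataset, GlobalFitProblem, inner_filter_factor
from .mechanisms import ObservableScaling, load_rate_table
from .protocols import (
    ExperimentProtocol,
    ProtocolSimulator,
    load_protocol,
    preincubation_initial_state,  # noqa: F401  (re-exported, see module role)
)

#: default noise levels: fraction of dynamic range for stopped-flow and
#: titration signals, fraction of total DNA (absolute uM) for quench tables
DEFAULT_NOISE_FRAC = 0.02
DEFAULT_QUENCH_FRAC = 0.03

#: the multi-experiment suite for each substrate
SUITES = {
    "ssdna": (
        "ssdna_binding_e100",
        "ssdna_binding_e400",
        "ssdna_offrate",
        "ssdna_titration",
        "ssdna_excision_e250",
        "ssdna_excision_e1250",
        "ssdna_excision_dcmp",
    ),
    "mm3": (
        "mm3_binding_e100",
        "mm3_binding_e400",
        "mm3_offrate",
        "mm3_titration",
        "mm3_excision_mix",
        "mm3_excision_mgstart",
        "mm3_melting_mgstart",
        "mm3_excision_extension",
        "mm3_melting_extension",
    ),
    "bmm": (
        "bmm_binding_e100",
        "bmm_binding_e400",
        "bmm_offrate",
        "bmm_titration",
        "bmm_excision_mix",
        "bmm_excision_mgstart",
        "bmm_melting_mgstart",
        "bmm_excision_extension",
        "bmm_melting_extension",
    ),
}

TRUTH_TABLES = {"ssdna": "table2", "mm3": "table3", "bmm": "table4"}


@dataclass
class SyntheticDataset:
    """One noisy dataset plus everything needed to reproduce it."""

    protocol: ExperimentProtocol
    truth: RateConstantSet
    scaling: ObservableScaling
    noise_sigma: float
    seed: int
    data: pd.DataFrame
    noiseless: pd.DataFrame = field(repr=False, default=None)

    def as_fit_dataset(self, weight=1.0):
        return FitDataset(protocol=self.protocol, data=self.data, weight=weight)


def generate(
    protocol,
    rates=None,
    scaling=None,
    noise_frac=DEFAULT_NOISE_FRAC,
    quench_frac=DEFAULT_QUENCH_FRAC,
    seed=0,
    simulator=None,
):
    """Simulate ``protocol`` under ``rates`` and add seeded Gaussian noise."""
    sim = simulator or ProtocolSimulator()
    if rates is None:
        rates = sim.default_rates(protocol)
    scaling = scaling or ObservableScaling()
    rng = np.random.default_rng(seed)
    pred = sim.predict(protocol, rates)
    if protocol.signal == "primer-length-table":
        sigma = quench_frac * protocol.dna_uM
        clean = pred.table
        # gel quantification reports nonnegative band intensities
        noisy = (clean + rng.normal(0.0, sigma, size=clean.shape)).clip(lower=0.0)
        tidy = (
            noisy.reset_index()
            .melt(id_vars="time_s", var_name="series", value_name="conc_uM")
            .sort_values(["series", "time_s"], kind="stable")
            .reset_index(drop=True)
        )
        clean_tidy = (
            clean.reset_index()
            .melt(id_vars="time_s", var_name="series", value_name="conc_uM")
            .sort_values(["series", "time_s"], kind="stable")
            .reset_index(drop=True)
        )
        return SyntheticDataset(protocol, rates, scaling, sigma, seed, tidy, clean_tidy)
    y = pred.signal(scaling)
    if protocol.kind == "titration":
        factor = inner_filter_factor(protocol.titration.epsilon * pred.x)
        raw = y * factor
        sigma = noise_frac * (raw.max() - raw.min())
        noisy = raw + rng.normal(0.0, sigma, size=raw.shape)
        df = pd.DataFrame(
            {
                "enzyme_uM": pred.x,
                "dna_uM": protocol.dna_uM * pred.dilution,
                "dilution_factor": pred.dilution,
                "value": noisy,
            }
        )
        clean = df.assign(value=raw)
        return SyntheticDataset(protocol, rates, scaling, sigma, seed, df, clean)
    sigma = noise_frac * (y.max() - y.min())
    noisy = y + rng.normal(0.0, sigma, size=y.shape)
    df = pd.DataFrame({"time_s": pred.x, "value": noisy, "series": protocol.name})
    clean = df.assign(value=y)
    return SyntheticDataset(protocol, rates, scaling, sigma, seed, df, clean)


def generate_suite(
    substrate,
    seed,
    rates=None,
    scaling=None,
    noise_frac=DEFAULT_NOISE_FRAC,
    quench_frac=DEFAULT_QUENCH_FRAC,
    simulator=None,
):
    """All datasets of a substrate's suite, with per-dataset derived seeds."""
    if substrate not in SUITES:
        raise ConfigurationError(f"unknown suite {substrate!r}")
    sim = simulator or ProtocolSimulator()
    if rates is None:
        rates = load_rate_table(TRUTH_TABLES[substrate])
    child_seeds = np.random.SeedSequence(seed).generate_state(len(SUITES[substrate]))
    out = []
    for name, s in zip(SUITES[substrate], child_seeds):
        protocol = load_protocol(name)
        out.append(
            generate(
                protocol,
                rates=rates,
                scaling=scaling,
                noise_frac=noise_frac,
                quench_frac=quench_frac,
                seed=int(s % (2**31)),
                simulator=sim,
            )
        )
    return out


@dataclass
class RecoveryReport:
    """Recovered-vs-truth record of a multi-seed recovery experiment."""

    substrate: str
    results: pd.DataFrame  # seed, symbol, truth, fitted, converged, chi2
    n_seeds: int

    def median(self, symbol):
        sub = self.results[self.results.symbol == symbol]
        return float(sub.fitted.median())

    def summary(self):
        g = self.results.groupby("symbol", sort=False)
        return pd.DataFrame(
            {
                "truth": g.truth.first(),
                "median": g.fitted.median(),
                "rel_bias": (g.fitted.median() - g.truth.first()) / g.truth.first(),
                "spread": g.fitted.std(),
                "n_converged": g.converged.sum(),
            }
        )


def recovery_experiment(
    substrate,
    seeds,
    noise_frac=DEFAULT_NOISE_FRAC,
    quench_frac=DEFAULT_QUENCH_FRAC,
    start_jitter_decades=0.15,
    fit_rtol=1e-6,
    fit_atol=1e-10,
    max_nfev=None,
    progress=None,
):
    """Generate the suite, global-fit it, and record recovery per seed.

    Starting guesses for the free parameters are the truth values jittered
    uniformly by up to ``start_jitter_decades`` in log10 per seed, so every
    fit must move back to the truth on its own.  Unconverged fits are
    recorded, not dropped.
    """
    truth = load_rate_table(TRUTH_TABLES[substrate])
    rows = []
    for seed in seeds:
        sim = ProtocolSimulator(rtol=fit_rtol, atol=fit_atol)
        suite = generate_suite(
            substrate, seed, rates=truth,
            noise_frac=noise_frac, quench_frac=quench_frac, simulator=sim,
        )
        problem = GlobalFitProblem(
            [d.as_fit_dataset() for d in suite], truth, simulator=sim
        )
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA5]).generate_state(1)[0])
        start = {}
        for sym in problem.free_symbols:
            j = rng.uniform(-start_jitter_decades, start_jitter_decades)
            lo, hi = truth[sym].bounds
            start[sym] = float(np.clip(truth[sym].value * 10**j, lo * 1.01, hi * 0.99))
        result = problem.fit(start=start, max_nfev=max_nfev)
        for sym in problem.free_symbols:
            rows.append(
                {
                    "seed": seed,
                    "symbol": sym,
                    "truth": truth[sym].value,
                    "start": start[sym],
                    "fitted": result.rates[sym].value,
                    "converged": bool(result.success),
                    "chi2": result.chi2,
                }
            )
        if progress is not None:
            progress(substrate, seed, result)
    return RecoveryReport(substrate, pd.DataFrame(rows), n_seeds=len(seeds))
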