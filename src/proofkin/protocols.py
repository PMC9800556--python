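"""Machine-readable mixing/titration/quench experiment protocols.

An :class:`ExperimentProtocol` records final (after-mixing) concentrations,
the time grid or titration schedule, and which signal is read out:

* ``anisotropy`` — stopped-flow anisotropy of labeled DNA (free vs bound);
* ``fluorescence`` — the fluorescent-cytosine-analog melting signal,
  a * sum(b_class * occupancy);
* ``primer-length-table`` — quench-flow product concentrations per primer
  length (gel bands), aggregated into the protocol's ``series``.

Protocols mirroring each of the study's experiments are bundled as JSON
under ``data/protocols`` and loaded by name.  :class:`ProtocolSimulator`
turns a protocol plus a rate-constant set into a linear signal basis (for
traces and titrations, so observable scalings can be profiled out) or a
primer-length table (for quench experiments).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    RateConstantSet,
    equilibrium_distribution,
    simulate,
)
from .mechanisms import (
    FLUOR_BASIS_CLASSES,
    anisotropy_basis,
    build_mechanism,
    class_occupancies,
    primer_length_table,
)

KINDS = frozenset(
    {
        "mix-binding",
        "trap-offrate",
        "titration",
        "quench-mix",
        "quench-preincubate-Mg",
        "stopped-preincubate-Mg",
        "excision-extension",
    }
)
SIGNALS = frozenset({"anisotropy", "fluorescence", "primer-length-table"})

#: Site occupancies of bound DNA after preincubation without Mg2+, as
#: fractions of total DNA (pol, intermediate, exo); the remainder is free.
#: These are the values the global fits report for the no-Mg equilibrium;
#: the tabulated (with-Mg) constants do not reproduce them, so "+Mg-start"
#: protocols are initialized from these numbers directly.
PREINCUBATION_FRACTIONS = {
    "mm3": {"pol": 0.34, "intermediate": 0.57, "exo": 0.08},
    "bmm": {"pol": 0.27, "intermediate": 0.64, "exo": 0.09},
}

#: default per-uM attenuation-equivalent of the titrant (enzyme) used in
#: the inverse-inner-filter correction of titration fluorescence
DEFAULT_EPSILON = 0.805


@dataclass(frozen=True)
class TitrationSchedule:
    """Stepwise titrant addition into a stirred cuvette.

    ``titrant_max_uM`` is the in-cuvette titrant concentration after the
    final addition; cumulative dilution of the cuvette contents is tracked
    from the added volume.
    """

    n_points: int = 12
    titrant_max_uM: float = 0.4
    cuvette_ul: float = 280.0
    added_ul: float = 20.5
    epsilon: float = DEFAULT_EPSILON

    def points(self):
        """(titrant_uM_in_cuvette, dilution_factor) arrays."""
        v = self.added_ul * np.arange(1, self.n_points + 1) / self.n_points
        dilution = self.cuvette_ul / (self.cuvette_ul + v)
        vmax = self.added_ul
        stock = self.titrant_max_uM * (self.cuvette_ul + vmax) / vmax
        titrant = stock * v / (self.cuvette_ul + v)
        return titrant, dilution


@dataclass(frozen=True)
class ExperimentProtocol:
    """One mixing/titration/quench experiment (final concentrations, uM)."""

    name: str
    substrate: str  # "ssdna" | "mm3" | "bmm"
    kind: str
    signal: str
    dna_uM: float
    enzyme_uM: float = 0.0
    trap_uM: float = 0.0
    dcmp_uM: float = 0.0
    dntps: bool = False
    chemistry: bool = True  # False -> hydrolysis-resistant phosphorothioate
    time_max_s: float = 1.0
    time_min_s: float = 1e-3  # first nonzero point for log spacing
    n_times: int = 50
    time_spacing: str = "linear"  # or "log"
    series: tuple = ()  # quench only: ((label, (lengths...)), ...)
    titration: TitrationSchedule | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown protocol kind {self.kind!r}")
        if self.signal not in SIGNALS:
            raise ConfigurationError(f"unknown signal {self.signal!r}")
        if self.kind == "titration" and self.titration is None:
            object.__setattr__(self, "titration", TitrationSchedule())
        if self.kind == "trap-offrate" and self.chemistry:
            raise ConfigurationError(
                "trap off-rate protocols use the hydrolysis-resistant substrate"
            )
        if self.dntps and self.substrate == "ssdna":
            raise ConfigurationError("the ssDNA scheme has no dNTP-activated steps")
        if self.signal == "primer-length-table" and not self.series:
            raise ConfigurationError("quench protocols must declare band series")

    def times(self):
        if self.kind == "titration":
            raise ConfigurationError("titration protocols have no time grid")
        if self.time_spacing == "linear":
            return np.linspace(0.0, self.time_max_s, self.n_times)
        if self.time_spacing == "log":
            return np.concatenate(
                [[0.0], np.geomspace(self.time_min_s, self.time_max_s, self.n_times - 1)]
            )
        raise ConfigurationError(f"unknown time spacing {self.time_spacing!r}")

    def to_json_dict(self):
        d = asdict(self)
        d["series"] = [[lab, list(ls)] for lab, ls in self.series]
        return d

    @classmethod
    def from_json_dict(cls, d):
        d = dict(d)
        if d.get("titration"):
            d["titration"] = TitrationSchedule(**d["titration"])
        d["series"] = tuple((lab, tuple(ls)) for lab, ls in d.get("series", ()))
        return cls(**d)


def load_protocol(name):
    """Load a bundled protocol by name (e.g. 'mm3_melting_mgstart')."""
    path = resources.files("proofkin.data.protocols").joinpath(f"{name}.json")
    try:
        with path.open() as fh:
            return ExperimentProtocol.from_json_dict(json.load(fh))
    except FileNotFoundError:
        raise ConfigurationError(f"no bundled protocol named {name!r}") from None


def list_protocols():
    return sorted(
        p.name.removesuffix(".json")
        for p in resources.files("proofkin.data.protocols").iterdir()
        if p.name.endswith(".json")
    )


def preincubation_initial_state(substrate, dna_uM, enzyme_uM):
    """Initial concentrations for "+Mg2+-start" protocols.

    Bound DNA is distributed over pol/intermediate/exo at the no-Mg
    occupancies reported for the substrate; any remainder is free DNA.
    """
    if substrate not in PREINCUBATION_FRACTIONS:
        raise ConfigurationError(
            f"no preincubation occupancies for substrate {substrate!r}"
        )
    if not enzyme_uM > dna_uM:
        raise ConfigurationError("preincubation requires excess enzyme")
    fr = PREINCUBATION_FRACTIONS[substrate]
    bound = {
        "P27": fr["pol"] * dna_uM,
        "I27": fr["intermediate"] * dna_uM,
        "X27": fr["exo"] * dna_uM,
    }
    total_bound = sum(bound.values())
    state = dict(bound)
    state["D27"] = max(dna_uM - total_bound, 0.0)
    state["E"] = enzyme_uM - total_bound
    return state


@dataclass
class Prediction:
    """Noiseless model output for one protocol.

    ``basis`` (traces, titrations) has one column per scaling coefficient
    so the measured signal is ``basis @ c``; ``table`` (quench) holds
    absolute concentrations per band series.
    """

    protocol: ExperimentProtocol
    x: np.ndarray  # time grid, or titrant concentration for titrations
    basis: np.ndarray | None = None
    basis_labels: tuple = ()
    table: pd.DataFrame | None = None
    dilution: np.ndarray | None = None

    def signal(self, scaling):
        """Apply an ObservableScaling to the basis (traces/titrations)."""
        if self.basis is None:
            raise ConfigurationError("quench predictions have no scalar signal")
        if self.protocol.signal == "anisotropy":
            c = np.array([scaling.r_free, scaling.r_bound])
        else:
            c = scaling.coefficients(self.basis_labels)
        return self.basis @ c


class ProtocolSimulator:
    """Simulate protocols against a mechanism variant cache."""

    def __init__(self, rtol=1e-8, atol=1e-12):
        self.rtol = rtol
        self.atol = atol
        self._mechs = {}

    def mechanism_for(self, protocol):
        key = (
            protocol.substrate,
            protocol.chemistry,
            protocol.dntps,
            protocol.trap_uM > 0,
        )
        if key not in self._mechs:
            self._mechs[key] = build_mechanism(
                protocol.substrate,
                chemistry=protocol.chemistry,
                dntps_present=protocol.dntps,
                trap=protocol.trap_uM > 0,
            )
        return self._mechs[key]

    def default_rates(self, protocol):
        return self.mechanism_for(protocol)[1]

    def initial_state(self, protocol, mechanism, rates):
        p = protocol
        if p.kind in ("mix-binding", "quench-mix"):
            state = {"D27": p.dna_uM, "E": p.enzyme_uM}
            if p.dcmp_uM:
                state["dCMP"] = p.dcmp_uM
            if p.trap_uM:
                state["T"] = p.trap_uM
            return state
        if p.kind == "trap-offrate":
            premix = {"D27": p.dna_uM, "E": p.enzyme_uM}
            x, _ = equilibrium_distribution(
                mechanism, rates, self._vector(mechanism, premix),
                rtol=min(self.rtol, 1e-8), atol=min(self.atol, 1e-11),
            )
            state = dict(zip(mechanism.species_names, x))
            state["T"] = p.trap_uM
            return state
        if p.kind in ("quench-preincubate-Mg", "stopped-preincubate-Mg",
                      "excision-extension"):
            state = preincubation_initial_state(p.substrate, p.dna_uM, p.enzyme_uM)
            if p.trap_uM:
                state["T"] = p.trap_uM
            return state
        raise ConfigurationError(f"no initial-state rule for kind {p.kind!r}")

    @staticmethod
    def _vector(mechanism, state):
        x0 = np.zeros(len(mechanism.species))
        for k, v in state.items():
            x0[mechanism.index(k)] = v
        return x0

    def predict(self, protocol, rates=None):
        """Noiseless :class:`Prediction` for a protocol under ``rates``."""
        mech, default = self.mechanism_for(protocol)
        if rates is None:
            rates = default
        if protocol.kind == "titration":
            return self._predict_titration(protocol, mech, rates)
        state = self.initial_state(protocol, mech, rates)
        times = protocol.times()
        traj = simulate(mech, rates, self._vector(mech, state), times,
                        rtol=self.rtol, atol=self.atol)
        if protocol.signal == "anisotropy":
            return Prediction(protocol, times, basis=anisotropy_basis(traj),
                              basis_labels=("r_free", "r_bound"))
        if protocol.signal == "fluorescence":
            return Prediction(protocol, times, basis=class_occupancies(traj),
                              basis_labels=FLUOR_BASIS_CLASSES)
        table = primer_length_table(traj)
        cols = {}
        for label, lengths in protocol.series:
            present = [n for n in lengths if n in table.columns]
            cols[label] = table[present].sum(axis=1) if present else pd.Series(
                0.0, index=table.index
            )
        return Prediction(protocol, times, table=pd.DataFrame(cols))

    def _predict_titration(self, protocol, mech, rates):
        if mech.has_irreversible_steps():
            raise ConfigurationError(
                "titration protocols require the hydrolysis-free mechanism variant"
            )
        titrant, dilution = protocol.titration.points()
        rows = []
        for e_tot, f in zip(titrant, dilution):
            state = {"D27": protocol.dna_uM * f, "E": e_tot}
            x, _ = equilibrium_distribution(
                mech, rates, self._vector(mech, state),
                rtol=min(self.rtol, 1e-8), atol=min(self.atol, 1e-11),
            )
            traj_like = _SingleState(mech, x)
            rows.append(class_occupancies(traj_like)[0])
        return Prediction(
            protocol,
            titrant,
            basis=np.array(rows),
            basis_labels=FLUOR_BASIS_CLASSES,
            dilution=dilution,
        )


class _SingleState:
    """Adapter exposing one state vector through the Trajectory interface."""

    def __init__(self, mechanism, x):
        self.mechanism = mechanism
        self.times = np.zeros(1)
        self.conc = np.asarray(x, dtype=float)[:, None]

    def sum_where(self, predicate, labeled_only=False):
        total = np.zeros(1)
        for i, s in enumerate(self.mechanism.species):
            if labeled_only and not s.labeled:
                continue
            if predicate(s):
                total = total + self.conc[i]
        return total
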