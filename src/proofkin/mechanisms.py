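"""The three T7 DNA polymerase proofreading mechanisms and their signals.

Builders return a :class:`~proofkin.core.Mechanism` plus a
:class:`~proofkin.core.RateConstantSet` defaulting to the published
best-fit parameter tables bundled as ``data/table{2,3,4}.json``:

* ``build_ssdna_mechanism`` — ssDNA binds the exonuclease (exo) site at the
  diffusion limit and is processively shortened; product (dNMP) release
  limits excision after the first base; dCMP acts as a weak competitive
  inhibitor of ssDNA binding.
* ``build_mm3_mechanism`` — duplex DNA with a 3'-terminal mismatch binds at
  three sites (pol, a partially melted intermediate, exo); the mismatch is
  excised in the exo site and the trimmed primer returns to the pol site.
* ``build_bmm_mechanism`` — duplex DNA with a buried mismatch; excision of
  the first (correct) base is followed by a rate-limiting dNMP release
  step, excision of the mismatched base, and return to the pol site.

Each builder accepts ``chemistry=False`` to produce the hydrolysis-free
variant used for phosphorothioate (hydrolysis-resistant) substrates, with
rate constants linked by symbol to the full scheme, and ``trap=True`` to
add an unlabeled competitor DNA that sequesters free enzyme.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    Mechanism,
    RateConstantSet,
    RateExpr,
    Reaction,
    Species,
)

SUBSTRATES = ("ssdna", "mm3", "bmm")


def load_rate_table(name):
    """Load a bundled parameter table ('table2'|'table3'|'table4')."""
    with resources.files("proofkin.data").joinpath(f"{name}.json").open() as fh:
        return RateConstantSet.from_json(json.load(fh))


@dataclass(frozen=True)
class SiteMap:
    """Association/dissociation symbol pair per DNA binding site."""

    pol: tuple[str, str]
    intermediate: tuple[str, str]
    exo: tuple[str, str]

    def as_dict(self):
        return {"pol": self.pol, "intermediate": self.intermediate, "exo": self.exo}


#: site-to-symbol mapping shared by both duplex schemes: k1 pairs with the
#: exo site, k2 with the intermediate, k3 with the pol site (this uniquely
#: reproduces the published 12/47/40% association-flux shares).
DUPLEX_SITE_MAP = SiteMap(
    pol=("k3", "km3"), intermediate=("k2", "km2"), exo=("k1", "km1")
)


@dataclass
class ObservableScaling:
    """Linear scaling from species occupancy to measured signal.

    ``a`` is the overall fluorescence scale; ``b`` maps a fluorescence
    class to its relative brightness (the fluorescent cytosine analog is
    brighter the more single-stranded its environment, so high > mid >
    low).  ``r_free``/``r_bound`` are anisotropy levels of free and
    enzyme-bound DNA (bound DNA tumbles slower, so r_bound > r_free).
    """

    a: float = 1.0
    b: dict = field(
        default_factory=lambda: {"free": 1.0, "low": 1.3, "mid": 1.8, "high": 2.6}
    )
    r_free: float = 0.05
    r_bound: float = 0.15

    def __post_init__(self):
        b = self.b
        if not (b["high"] > b["mid"] > b["low"]):
            raise ConfigurationError("brightness must satisfy high > mid > low")
        if not self.r_bound > self.r_free:
            raise ConfigurationError("anisotropy must satisfy r_bound > r_free")

    def coefficients(self, classes):
        return np.array([self.a * self.b[c] for c in classes])


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _trap_species_and_reactions(site_pairs, length=27):
    """Unlabeled competitor DNA binding free enzyme (binding only)."""
    sp = [
        Species("T", "free-DNA", primer_length=length, fluorescence_class="none",
                dna_units=1, nucleotide_units=length, labeled=False)
    ]
    rx = []
    for site, (kon, koff) in site_pairs.items():
        nm = f"ET_{site}"
        sp.append(
            Species(nm, "enzyme-bound-complex", primer_length=length, site=site,
                    fluorescence_class="none", enzyme_units=1, dna_units=1,
                    nucleotide_units=length, labeled=False)
        )
        rx.append(Reaction((("E", 1), ("T", 1)), ((nm, 1),), kon, koff))
    return sp, rx


def build_ssdna_mechanism(chemistry=True, trap=False, max_len=27, min_len=19):
    """ssDNA exo-site binding and processive excision (defaults: bundled table2).

    States: free ssDNA D{n} for n = max_len..min_len, exo-bound X{n}, and
    post-chemistry product complexes XD{n} that still hold the excised
    dNMP.  The first chemistry step is reversible (k2/km2); later steps
    are effectively irreversible.  dNMP release is k3 for the first base
    (a dCMP for this substrate), k3_2/k3_3 for the next two, and a common
    k3_late afterwards.  dCMP binds free enzyme as a weak competitive
    inhibitor with equilibrium constant KI (mM).
    """
    lengths = list(range(max_len, min_len - 1, -1))
    species = [Species("E", "enzyme", enzyme_units=1)]
    for n in lengths:
        species.append(
            Species(f"D{n}", "free-DNA", primer_length=n, fluorescence_class="free",
                    dna_units=1, nucleotide_units=n)
        )
        species.append(
            Species(f"X{n}", "enzyme-bound-complex", primer_length=n, site="exo",
                    fluorescence_class="high", enzyme_units=1, dna_units=1,
                    nucleotide_units=n)
        )
    species += [
        Species("dCMP", "small-molecule", nucleotide_units=1),
        Species("dNMP", "small-molecule", nucleotide_units=1),
        Species("EC", "enzyme-bound-complex", enzyme_units=1, nucleotide_units=1),
    ]
    reactions = []
    for n in lengths:
        reactions.append(
            Reaction((("E", 1), (f"D{n}", 1)), ((f"X{n}", 1),), "k1", "km1",
                     tag="assoc:exo" if n == max_len else "")
        )
    if chemistry:
        release_syms = {}
        for i, n in enumerate(lengths[:-1]):  # chemistry on n -> product n-1
            m = n - 1
            species.append(
                Species(f"XD{m}", "enzyme-bound-complex", primer_length=m, site="exo",
                        fluorescence_class="high", enzyme_units=1, dna_units=1,
                        nucleotide_units=m + 1)
            )
            reactions.append(
                Reaction(((f"X{n}", 1),), ((f"XD{m}", 1),), "k2",
                         "km2" if i == 0 else None)
            )
            release_syms[m] = ["k3", "k3_2", "k3_3"][i] if i < 3 else "k3_late"
        for i, (m, sym) in enumerate(sorted(release_syms.items(), reverse=True)):
            nuc = "dCMP" if i == 0 else "dNMP"
            reactions.append(
                Reaction(((f"XD{m}", 1),), ((f"X{m}", 1), (nuc, 1)), sym,
                         "km3" if i == 0 else None)
            )
    reactions.append(
        Reaction(
            (("E", 1), ("dCMP", 1)),
            (("EC", 1),),
            "kI_on",
            RateExpr(("kI_on", "KI"), lambda v: v["kI_on"] * v["KI"] * 1e3,
                     label="kI_on*KI"),
        )
    )
    if trap:
        sp, rx = _trap_species_and_reactions({"exo": ("k1", "km1")}, length=max_len)
        species += sp
        reactions += rx
    mech = Mechanism(
        name=f"ssdna{'_full' if chemistry else '_binding'}{'_trap' if trap else ''}",
        species=tuple(species),
        reactions=tuple(reactions),
        metadata={"substrate": "ssdna", "chemistry": chemistry, "trap": trap,
                  "start_length": max_len},
    )
    return mech, load_rate_table("table2")


def build_mm3_mechanism(dntps_present=False, chemistry=True, trap=False):
    """3'-terminal mismatch excision scheme (defaults: bundled table3).

    The 27-mer duplex binds the enzyme at three parallel sites (exo:
    k1/km1, intermediate: k2/km2, pol: k3/km3).  The intermediate
    exchanges with the exo site (k5/km5; forward replaced by k5act with
    dNTPs).  There is no pol-to-intermediate transfer without dNTPs; with
    dNTPs it proceeds at k4act.  Hydrolysis (k6, locked at its lower
    limit) releases the mismatched dNMP; the trimmed 26-mer returns to the
    pol site at k7 and, with dNTPs, is extended by two bases at kext per
    nucleotide.
    """
    k5f = "k5act" if dntps_present else "k5"
    species = [
        Species("E", "enzyme", enzyme_units=1),
        Species("D27", "free-DNA", primer_length=27, fluorescence_class="free",
                dna_units=1, nucleotide_units=27),
        Species("P27", "enzyme-bound-complex", primer_length=27, site="pol",
                fluorescence_class="low", enzyme_units=1, dna_units=1,
                nucleotide_units=27),
        Species("I27", "enzyme-bound-complex", primer_length=27, site="intermediate",
                fluorescence_class="mid", enzyme_units=1, dna_units=1,
                nucleotide_units=27),
        Species("X27", "enzyme-bound-complex", primer_length=27, site="exo",
                fluorescence_class="high", enzyme_units=1, dna_units=1,
                nucleotide_units=27),
    ]
    reactions = [
        Reaction((("E", 1), ("D27", 1)), (("X27", 1),), "k1", "km1", tag="assoc:exo"),
        Reaction((("E", 1), ("D27", 1)), (("I27", 1),), "k2", "km2",
                 tag="assoc:intermediate"),
        Reaction((("E", 1), ("D27", 1)), (("P27", 1),), "k3", "km3", tag="assoc:pol"),
        Reaction((("I27", 1),), (("X27", 1),), k5f, "km5"),
    ]
    if dntps_present:
        reactions.append(Reaction((("P27", 1),), (("I27", 1),), "k4act"))
    if chemistry:
        species += [
            Species("X26", "enzyme-bound-complex", primer_length=26, site="exo",
                    fluorescence_class="high", enzyme_units=1, dna_units=1,
                    nucleotide_units=26),
            Species("P26", "enzyme-bound-complex", primer_length=26, site="pol",
                    fluorescence_class="low", enzyme_units=1, dna_units=1,
                    nucleotide_units=26),
            Species("dNMP", "small-molecule", nucleotide_units=1),
        ]
        reactions += [
            Reaction((("X27", 1),), (("X26", 1), ("dNMP", 1)), "k6"),
            Reaction((("X26", 1),), (("P26", 1),), "k7"),
        ]
        if dntps_present:
            species += [
                Species("P27c", "enzyme-bound-complex", primer_length=27, site="pol",
                        fluorescence_class="low", enzyme_units=1, dna_units=1,
                        nucleotide_units=27),
                Species("P28", "enzyme-bound-complex", primer_length=28, site="pol",
                        fluorescence_class="low", enzyme_units=1, dna_units=1,
                        nucleotide_units=28),
            ]
            reactions += [
                Reaction((("P26", 1),), (("P27c", 1),), "kext",
                         exempt=("total_nucleotides",)),
                Reaction((("P27c", 1),), (("P28", 1),), "kext",
                         exempt=("total_nucleotides",)),
            ]
    if trap:
        sp, rx = _trap_species_and_reactions(DUPLEX_SITE_MAP.as_dict())
        species += sp
        reactions += rx
    mech = Mechanism(
        name=f"mm3{'_full' if chemistry else '_binding'}"
        f"{'_dntp' if dntps_present else ''}{'_trap' if trap else ''}",
        species=tuple(species),
        reactions=tuple(reactions),
        metadata={"substrate": "mm3", "chemistry": chemistry,
                  "dntps": dntps_present, "trap": trap, "start_length": 27},
    )
    return mech, load_rate_table("table3")


def build_bmm_mechanism(dntps_present=False, chemistry=True, trap=False):
    """Buried-mismatch excision scheme (defaults: bundled table4).

    Committed topology: three parallel binding steps for the 27-mer;
    pol<->intermediate transfer (k4/km4, forward k4act with dNTPs);
    intermediate<->exo (k5/km5, forward k5act with dNTPs).  Hydrolysis of
    the first (correct, terminal) base (k6) leaves a closed product
    complex C26 holding the dNMP; dNMP release is rate-limiting and
    modeled as a first-order opening C26 <-> O26 (k8/km8; forward k8act
    with dNTPs).  The open complex either re-closes (km8), hydrolyzes the
    now-terminal mismatched base (k6), returns the 26-mer primer to the
    pol site (k12), or dissociates (k9).  Dissociated 26-mer rebinds with
    the 3'-mismatch
    association rate constants (kon_*26, locked) and the locked
    dissociation values k9/k10/k14; I26 transfers to the exo site at k13
    and, with dNTPs, P26 transfers to I26 at k4act.  The second excision
    yields a 25-mer with fast dNMP release (k11, lower limit) and return
    to the pol site at k7; with dNTPs the 25-mer is extended to 30 nt at
    kext per base.
    """
    k4f = "k4act" if dntps_present else "k4"
    k5f = "k5act" if dntps_present else "k5"
    k8f = "k8act" if dntps_present else "k8"

    def bound(nm, n, site, cls):
        return Species(nm, "enzyme-bound-complex", primer_length=n, site=site,
                       fluorescence_class=cls, enzyme_units=1, dna_units=1,
                       nucleotide_units=n)

    species = [
        Species("E", "enzyme", enzyme_units=1),
        Species("D27", "free-DNA", primer_length=27, fluorescence_class="free",
                dna_units=1, nucleotide_units=27),
        bound("P27", 27, "pol", "low"),
        bound("I27", 27, "intermediate", "mid"),
        bound("X27", 27, "exo", "high"),
    ]
    reactions = [
        Reaction((("E", 1), ("D27", 1)), (("X27", 1),), "k1", "km1", tag="assoc:exo"),
        Reaction((("E", 1), ("D27", 1)), (("I27", 1),), "k2", "km2",
                 tag="assoc:intermediate"),
        Reaction((("E", 1), ("D27", 1)), (("P27", 1),), "k3", "km3", tag="assoc:pol"),
        Reaction((("P27", 1),), (("I27", 1),), k4f, "km4"),
        Reaction((("I27", 1),), (("X27", 1),), k5f, "km5"),
    ]
    if chemistry:
        # C26/O26 still count the excised dNMP in their composition
        species += [
            Species(
                "C26", "enzyme-bound-complex", primer_length=26, site="exo",
                fluorescence_class="high", enzyme_units=1, dna_units=1,
                nucleotide_units=27,
            ),
            Species(
                "O26", "enzyme-bound-complex", primer_length=26, site="exo",
                fluorescence_class="high", enzyme_units=1, dna_units=1,
                nucleotide_units=27,
            ),
            bound("X26", 26, "exo", "high"),
            bound("P26", 26, "pol", "low"),
            bound("I26", 26, "intermediate", "mid"),
            Species("D26", "free-DNA", primer_length=26, fluorescence_class="free",
                    dna_units=1, nucleotide_units=26),
            Species(
                "X25d", "enzyme-bound-complex", primer_length=25, site="exo",
                fluorescence_class="high", enzyme_units=1, dna_units=1,
                nucleotide_units=26,
            ),
            bound("X25", 25, "exo", "high"),
            bound("P25", 25, "pol", "low"),
            Species("dNMP", "small-molecule", nucleotide_units=1),
        ]
        reactions += [
            Reaction((("X27", 1),), (("C26", 1),), "k6"),
            Reaction((("C26", 1),), (("O26", 1),), k8f, "km8"),
            Reaction((("O26", 1),), (("P26", 1), ("dNMP", 1)), "k12"),
            Reaction((("O26", 1),), (("X25d", 1), ("dNMP", 1)), "k6"),
            Reaction((("O26", 1),), (("E", 1), ("D26", 1), ("dNMP", 1)), "k9"),
            Reaction((("X26", 1),), (("X25d", 1),), "k6"),
            Reaction((("X26", 1),), (("P26", 1),), "k12"),
            Reaction((("E", 1), ("D26", 1)), (("X26", 1),), "kon_x26", "k9"),
            Reaction((("E", 1), ("D26", 1)), (("I26", 1),), "kon_i26", "k10"),
            Reaction((("E", 1), ("D26", 1)), (("P26", 1),), "kon_p26", "k14"),
            Reaction((("I26", 1),), (("X26", 1),), "k13"),
            Reaction((("X25d", 1),), (("X25", 1), ("dNMP", 1)), "k11"),
            Reaction((("X25", 1),), (("P25", 1),), "k7"),
        ]
        if dntps_present:
            reactions.append(Reaction((("P26", 1),), (("I26", 1),), "k4act"))
            prev = "P25"
            for n in range(26, 31):
                nm = f"P{n}e" if n < 30 else "P30"
                species.append(bound(nm, n, "pol", "low"))
                reactions.append(
                    Reaction(((prev, 1),), ((nm, 1),), "kext",
                             exempt=("total_nucleotides",))
                )
                prev = nm
    if trap:
        sp, rx = _trap_species_and_reactions(DUPLEX_SITE_MAP.as_dict())
        species += sp
        reactions += rx
    mech = Mechanism(
        name=f"bmm{'_full' if chemistry else '_binding'}"
        f"{'_dntp' if dntps_present else ''}{'_trap' if trap else ''}",
        species=tuple(species),
        reactions=tuple(reactions),
        metadata={"substrate": "bmm", "chemistry": chemistry,
                  "dntps": dntps_present, "trap": trap, "start_length": 27},
    )
    return mech, load_rate_table("table4")


BUILDERS = {
    "ssdna": build_ssdna_mechanism,
    "mm3": build_mm3_mechanism,
    "bmm": build_bmm_mechanism,
}


def build_mechanism(substrate, chemistry=True, dntps_present=False, trap=False):
    """Dispatch to the named builder with the applicable flags."""
    if substrate not in BUILDERS:
        raise ConfigurationError(f"unknown substrate {substrate!r}")
    if substrate == "ssdna":
        if dntps_present:
            raise ConfigurationError("the ssDNA scheme has no dNTP-activated steps")
        return build_ssdna_mechanism(chemistry=chemistry, trap=trap)
    return BUILDERS[substrate](dntps_present=dntps_present, chemistry=chemistry,
                               trap=trap)


# ---------------------------------------------------------------------------
# trajectory -> measured signal
# ---------------------------------------------------------------------------

FLUOR_BASIS_CLASSES = ("free", "low", "mid", "high")


def class_occupancies(traj):
    """(n_times, 4) occupancy (uM) of labeled DNA per fluorescence class."""
    cols = [
        traj.sum_where(lambda s, c=c: s.fluorescence_class == c and s.dna_units > 0,
                       labeled_only=True)
        for c in FLUOR_BASIS_CLASSES
    ]
    return np.column_stack(cols)


def fluorescence_signal(traj, scaling):
    """signal(t) = a * sum_s b_class(s) * [s](t) over labeled DNA species."""
    for s in traj.mechanism.species:
        if s.dna_units and s.labeled and s.fluorescence_class == "none":
            raise ConfigurationError(f"species {s.name!r} lacks a fluorescence class")
    occ = class_occupancies(traj)
    return occ @ scaling.coefficients(FLUOR_BASIS_CLASSES)


def anisotropy_basis(traj):
    """(n_times, 2) fractions of labeled DNA that are free / enzyme-bound."""
    free = traj.sum_where(lambda s: s.dna_units > 0 and s.enzyme_units == 0,
                          labeled_only=True)
    bound = traj.sum_where(lambda s: s.dna_units > 0 and s.enzyme_units > 0,
                           labeled_only=True)
    total = free + bound
    total = np.where(total > 0, total, 1.0)
    return np.column_stack([free / total, bound / total])


def anisotropy_signal(traj, scaling):
    """Two-state anisotropy estimate, equal brightness of free and bound."""
    basis = anisotropy_basis(traj)
    return basis @ np.array([scaling.r_free, scaling.r_bound])


def high_state_occupancy(traj):
    """Occupancy (uM) of the melted, exo-site (high-fluorescence) states."""
    return traj.sum_where(
        lambda s: s.fluorescence_class == "high" and s.dna_units > 0,
        labeled_only=True,
    )


def primer_length_table(traj, lengths=None):
    """Concentration per primer length vs time (labeled DNA, free + bound).

    Returns a DataFrame indexed by time with one column per length; column
    sums equal total labeled DNA at every time.
    """
    if lengths is None:
        lengths = sorted(
            {s.primer_length for s in traj.mechanism.species
             if s.dna_units and s.labeled and s.primer_length is not None},
            reverse=True,
        )
    data = {}
    for n in lengths:
        data[n] = traj.sum_where(
            lambda s, n=n: s.dna_units > 0 and s.primer_length == n,
            labeled_only=True,
        )
    return pd.DataFrame(data, index=pd.Index(traj.times, name="time_s"))
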