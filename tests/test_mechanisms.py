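"""The three proofreading schemes, their parameter tables, and signals."""
import numpy as np
import pytest

from proofkin.core import simulate
from proofkin.mechanisms import (
    ObservableScaling,
    anisotropy_signal,
    build_bmm_mechanism,
    build_mechanism,
    build_mm3_mechanism,
    build_ssdna_mechanism,
    fluorescence_signal,
    load_rate_table,
    primer_length_table,
)
from proofkin.core import ConfigurationError


class TestParameterTables:
    def test_ssdna_net_kd_is_40_nM(self):
        r = load_rate_table("table2")
        kd_nM = r.value("km1") / r.value("k1") * 1e3
        assert kd_nM == pytest.approx(40.0, abs=1.5)

    def test_chemistry_equilibrium_constant_near_3(self):
        r = load_rate_table("table2")
        assert r.value("k2") / r.value("km2") == pytest.approx(3.0, abs=0.05)

    def test_lower_limit_chemistry_rates_are_locked(self):
        assert load_rate_table("table2")["k2"].status == "lower-limit"
        assert load_rate_table("table3")["k6"].status == "lower-limit"
        assert "k2" not in load_rate_table("table2").free_symbols()

    def test_bmm_pol_intermediate_equilibrium_near_2(self):
        r = load_rate_table("table4")
        assert r.value("k4") / r.value("km4") == pytest.approx(2.0, abs=0.06)

    def test_bmm_locked_dissociations_equal_mm3_values(self):
        t3, t4 = load_rate_table("table3"), load_rate_table("table4")
        assert t4.value("k9") == t3.value("km1") == 0.372
        assert t4.value("k10") == t3.value("km2") == 2.44
        assert t4["k9"].status == t4["k10"].status == "locked"

    def test_mm3_net_duplex_affinity_below_1_nM(self):
        """Three parallel site equilibria combine to sub-nanomolar Kd."""
        r = load_rate_table("table3")
        k_assoc = (
            r.value("k1") / r.value("km1")
            + r.value("k2") / r.value("km2")
            + r.value("k3") / r.value("km3")
        )
        assert 1e3 / k_assoc < 1.0  # nM

    def test_dntp_activated_transfer_values(self):
        r = load_rate_table("table3")
        assert r.value("k5act") == pytest.approx(7.83)
        mech, _ = build_mm3_mechanism(dntps_present=True)
        syms = {rx.k_forward for rx in mech.reactions if isinstance(rx.k_forward, str)}
        assert "k5act" in syms and "k4act" in syms and "k5" not in syms

    def test_no_pol_to_intermediate_transfer_without_dntps(self):
        mech, _ = build_mm3_mechanism(dntps_present=False)
        for rx in mech.reactions:
            assert not (
                rx.reactants == (("P27", 1),) and rx.products == (("I27", 1),)
            )


class TestMechanismStructure:
    @pytest.mark.parametrize("substrate", ["ssdna", "mm3", "bmm"])
    def test_conservation_along_full_digestion(self, substrate):
        mech, rates = build_mechanism(substrate)
        traj = simulate(mech, rates, {"E": 1.0, "D27": 0.15},
                        np.linspace(0, 2.0, 41))
        assert max(traj.conservation_error().values()) < 1e-6

    @pytest.mark.parametrize("substrate", ["mm3", "bmm"])
    def test_extension_variant_conserves_enzyme_and_dna(self, substrate):
        mech, rates = build_mechanism(substrate, dntps_present=True, trap=True)
        traj = simulate(mech, rates, {"E": 0.4, "D27": 0.075, "T": 1.0},
                        np.linspace(0, 2.0, 41))
        errs = traj.conservation_error()
        assert errs["total_enzyme"] < 1e-6 and errs["total_dna"] < 1e-6
        # nucleotide total is intentionally not conserved when dNTPs extend
        assert "total_nucleotides" not in errs

    def test_ssdna_monotone_loss_of_full_length_primer(self):
        mech, rates = build_mechanism("ssdna")
        traj = simulate(mech, rates, {"E": 1.25, "D27": 0.15},
                        np.linspace(0, 0.3, 61))
        full = traj.conc_of("D27") + traj.conc_of("X27")
        assert np.all(np.diff(full) <= 1e-12)

    def test_ssdna_excision_is_binding_limited(self):
        """10x faster chemistry changes the free 27-mer decay by < 1%.

        Free ssDNA is consumed at k1*[E] no matter how fast the committed
        chemistry runs; only the small km1 return flux carries any k2
        dependence.
        """
        mech, rates = build_mechanism("ssdna")
        t = np.linspace(0, 0.02, 41)
        base = simulate(mech, rates, {"E": 1.25, "D27": 0.15}, t)
        fast = simulate(
            mech, dict(rates.values_dict(), k2=50000.0),
            {"E": 1.25, "D27": 0.15}, t,
        )
        assert np.max(np.abs(base.conc_of("D27") - fast.conc_of("D27"))) / 0.15 < 0.01

    def test_association_flux_shares_equal_on_rate_ratios(self):
        """Gross binding shares are k_site/sum(k) in excess enzyme."""
        from proofkin.uncertainty import binding_flux_shares

        mech, rates = build_mechanism("mm3")
        rep = binding_flux_shares(mech, rates, dna_uM=0.15, enzyme_uM=1.0)
        k = {s: rates.value(s) for s in ("k1", "k2", "k3")}
        tot = sum(k.values())
        assert rep.fractions["exo"] == pytest.approx(k["k1"] / tot, rel=1e-3)
        assert rep.fractions["intermediate"] == pytest.approx(k["k2"] / tot, rel=1e-3)
        assert rep.fractions["pol"] == pytest.approx(k["k3"] / tot, rel=1e-3)

    def test_mm3_26mer_does_not_accumulate_with_dntps(self):
        """With dNTPs, the trimmed 26-mer converts on to the 28-mer."""
        mech, rates = build_mm3_mechanism(dntps_present=True)
        state = {"P27": 0.0255, "I27": 0.04275, "X27": 0.006, "D27": 0.00075,
                 "E": 0.4 - 0.07425}
        traj = simulate(mech, rates, state, np.linspace(0, 3, 121))
        tab = primer_length_table(traj)
        assert tab[26].max() < 0.25 * 0.075  # transient stays small
        assert tab[28].iloc[-1] > 0.6 * 0.075  # product accumulates

    def test_bmm_second_excision_faster_with_dntps(self):
        """With dNTPs the 26-mer is hydrolyzed on within a binding event.

        Single-turnover (trap present): the 25/30-mer yield at 0.5 s grows
        several-fold because dNTPs accelerate the rate-limiting dNMP
        release (k8 -> k8act).
        """
        from proofkin.protocols import preincubation_initial_state

        t = np.linspace(0, 0.5, 26)
        res = {}
        for dntps in (False, True):
            mech, rates = build_bmm_mechanism(dntps_present=dntps, trap=True)
            init = preincubation_initial_state("bmm", 0.075, 0.4)
            init["T"] = 1.0
            tab = primer_length_table(simulate(mech, rates, init, t))
            beyond = [c for c in tab.columns if c <= 25 or c >= 30]
            res[dntps] = tab[beyond].sum(axis=1).iloc[-1]
        assert res[True] > 1.5 * res[False]

    def test_extension_amplitude_exceeds_excision_only(self):
        """Single-turnover product amplitude grows when dNTPs are present."""
        t = np.linspace(0, 3, 61)
        mech0, rates0 = build_mm3_mechanism(dntps_present=False, trap=True)
        mech1, rates1 = build_mm3_mechanism(dntps_present=True, trap=True)
        init = {"P27": 0.0255, "I27": 0.04275, "X27": 0.006, "D27": 0.00075,
                "E": 0.4 - 0.07425, "T": 1.0}
        loss0 = 0.075 - primer_length_table(
            simulate(mech0, rates0, init, t))[27].iloc[-1]
        ext1 = primer_length_table(simulate(mech1, rates1, init, t))[28].iloc[-1]
        assert ext1 > loss0 * 0.9  # conversion, not just loss of 27-mer


class TestSignals:
    def _traj(self):
        mech, rates = build_mm3_mechanism()
        return simulate(mech, rates, {"E": 0.1, "D27": 0.04},
                        np.linspace(0, 1, 21))

    def test_uniform_brightness_makes_signal_constant(self):
        traj = self._traj()
        sc = ObservableScaling(b={"free": 1.0, "low": 1.0 - 1e-12,
                                  "mid": 1.0, "high": 1.0 + 1e-12})
        y = fluorescence_signal(traj, sc)
        assert np.allclose(y, y[0], rtol=1e-6)

    def test_signal_scales_linearly_with_a(self):
        traj = self._traj()
        y1 = fluorescence_signal(traj, ObservableScaling(a=1.0))
        y2 = fluorescence_signal(traj, ObservableScaling(a=2.0))
        assert np.allclose(y2, 2 * y1)

    def test_brightness_ordering_enforced(self):
        with pytest.raises(ConfigurationError, match="high > mid > low"):
            ObservableScaling(b={"free": 1.0, "low": 2.0, "mid": 1.5, "high": 2.5})

    def test_anisotropy_limits(self, two_state):
        mech, rates = two_state
        sc = ObservableScaling()
        no_enzyme = simulate(mech, rates, {"D": 0.05}, np.linspace(0, 0.01, 5))
        assert np.allclose(anisotropy_signal(no_enzyme, sc), sc.r_free)
        bound = simulate(mech, {"kon": 0.0, "koff": 0.0}, {"ED": 0.05},
                         np.linspace(0, 0.01, 5))
        assert np.allclose(anisotropy_signal(bound, sc), sc.r_bound)

    def test_primer_table_starts_full_length_and_conserves(self):
        mech, rates = build_ssdna_mechanism()
        traj = simulate(mech, rates, {"E": 1.25, "D27": 0.15},
                        np.linspace(0, 0.5, 31))
        tab = primer_length_table(traj)
        assert tab.iloc[0][27] == pytest.approx(0.15, rel=1e-9)
        assert np.allclose(tab.sum(axis=1), 0.15, rtol=1e-7)
        # irreversible cascade ends at the terminal length
        assert tab.iloc[-1][19] == pytest.approx(0.15, rel=1e-3)

    def test_trap_dna_is_invisible_to_signals(self):
        mech, rates = build_mm3_mechanism(chemistry=False, trap=True)
        traj = simulate(mech, rates, {"E": 0.05, "D27": 0.025, "T": 0.5},
                        np.linspace(0, 5, 11))
        tab = primer_length_table(traj)
        assert np.allclose(tab.sum(axis=1), 0.025, rtol=1e-7)
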