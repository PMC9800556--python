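"""Mass-action assembly, integration, and analytic oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proofkin.core import (
    ConfigurationError,
    Mechanism,
    RateConstant,
    RateConstantSet,
    Reaction,
    Species,
    analytic_two_state,
    assemble_odes,
    equilibrium_distribution,
    simulate,
)
from proofkin.mechanisms import build_ssdna_mechanism


class TestValidation:
    def test_duplicate_species_names_rejected(self):
        sp = Species("E", "enzyme", enzyme_units=1)
        with pytest.raises(ConfigurationError, match="unique"):
            Mechanism("bad", (sp, sp), ())

    def test_bound_complex_requires_site_and_length(self):
        with pytest.raises(ConfigurationError, match="site and primer_length"):
            Species("ED", "enzyme-bound-complex", enzyme_units=1, dna_units=1)

    def test_unknown_symbol_is_named_in_error(self, two_state):
        mech, _ = two_state
        bad = RateConstantSet([RateConstant("kon", 1.0, "uM-1 s-1")])
        with pytest.raises(ConfigurationError, match="koff"):
            assemble_odes(mech, bad)

    def test_units_molecularity_mismatch_rejected(self, two_state):
        mech, _ = two_state
        bad = RateConstantSet(
            [RateConstant("kon", 1.0, "s-1"), RateConstant("koff", 1.0, "s-1")]
        )
        with pytest.raises(ConfigurationError, match="inconsistent"):
            assemble_odes(mech, bad)

    def test_nonconserving_reaction_rejected(self):
        sp = (
            Species("A", "free-DNA", primer_length=5, fluorescence_class="free",
                    dna_units=1, nucleotide_units=5),
            Species("B", "free-DNA", primer_length=4, fluorescence_class="free",
                    dna_units=1, nucleotide_units=4),
        )
        with pytest.raises(ConfigurationError, match="conserve"):
            Mechanism("bad", sp, (Reaction((("A", 1),), (("B", 1),), "k"),))

    def test_locked_constants_cannot_be_perturbed(self):
        rs = RateConstantSet([RateConstant("k", 1.0, "s-1", status="locked")])
        with pytest.raises(ConfigurationError, match="locked"):
            rs.updated({"k": 2.0})


class TestAssembleOdes:
    def test_zero_rates_give_null_field(self, two_state):
        mech, _ = two_state
        rates = {"kon": 0.0, "koff": 0.0}
        rhs, _ = assemble_odes(mech, rates)
        x = np.array([0.3, 0.2, 0.1])
        assert np.all(rhs(0.0, x) == 0.0)

    def test_mass_action_definition(self, two_state):
        """d[ED]/dt = kon*[E][D] - koff*[ED] for the reversible pair."""
        mech, rates = two_state
        rhs, jac = assemble_odes(mech, rates)
        x = np.array([0.4, 0.05, 0.02])
        kon, koff = rates.value("kon"), rates.value("koff")
        expect = kon * x[0] * x[1] - koff * x[2]
        got = rhs(0.0, x)
        assert got[mech.index("ED")] == pytest.approx(expect, rel=1e-12)
        # Jacobian consistency with finite differences
        eps = 1e-7
        for j in range(3):
            dx = np.zeros(3)
            dx[j] = eps
            fd = (rhs(0, x + dx) - rhs(0, x - dx)) / (2 * eps)
            assert np.allclose(jac(0, x)[:, j], fd, rtol=1e-5, atol=1e-6)

    def test_dna_species_rates_sum_to_zero_in_ssdna_scheme(self):
        """Symbolic check: generated RHS moves no net DNA in or out."""
        mech, rates = build_ssdna_mechanism()
        rhs, _ = assemble_odes(mech, rates)
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, len(mech.species))
        dna = np.array([s.dna_units for s in mech.species], dtype=float)
        assert abs(dna @ rhs(0.0, x)) < 1e-9 * np.abs(rhs(0.0, x)).max()


class TestSimulate:
    def test_zero_rate_network_stays_at_initial_state(self, two_state):
        mech, _ = two_state
        zero = RateConstantSet(
            [RateConstant("kon", 0.0, "uM-1 s-1"), RateConstant("koff", 0.0, "s-1")]
        )
        traj = simulate(mech, zero, {"E": 0.4, "D": 0.05}, np.linspace(0, 1, 5))
        assert np.allclose(traj.conc_of("D"), 0.05)
        assert np.allclose(traj.conc_of("ED"), 0.0)

    def test_pseudo_first_order_relaxation_matches_oracle(self, two_state):
        """kobs = kon*E + koff = 484.1 /s at 0.4 uM enzyme, 50 nM DNA."""
        mech, rates = two_state
        t = np.linspace(0, 0.05, 201)
        traj = simulate(mech, rates, {"E": 0.4, "D": 0.05}, t)
        oracle = analytic_two_state(1100.0, 44.1, 0.4, 0.05, t)
        scale = oracle[-1]
        assert np.max(np.abs(traj.conc_of("ED") - oracle)) / scale < 1e-6

    def test_tolerance_self_convergence(self, two_state):
        mech, rates = two_state
        t = np.linspace(0, 0.05, 51)
        a = simulate(mech, rates, {"E": 0.4, "D": 0.05}, t, rtol=1e-8, atol=1e-12)
        b = simulate(mech, rates, {"E": 0.4, "D": 0.05}, t, rtol=0.5e-8, atol=0.5e-12)
        ref = np.abs(a.conc).max()
        assert np.max(np.abs(a.conc - b.conc)) / ref < 1e-6

    def test_time_shift_composition(self, two_state):
        """Simulating to t1 then restarting to t2 equals one run to t1+t2."""
        mech, rates = two_state
        t1, t2 = 0.004, 0.01
        a = simulate(mech, rates, {"E": 0.4, "D": 0.05}, np.linspace(0, t1, 11))
        mid = {s: a.conc_of(s)[-1] for s in mech.species_names}
        b = simulate(mech, rates, mid, np.linspace(0, t2, 11))
        c = simulate(mech, rates, {"E": 0.4, "D": 0.05},
                     np.linspace(0, t1 + t2, 23))
        assert b.conc_of("ED")[-1] == pytest.approx(c.conc_of("ED")[-1], rel=1e-7)

    def test_negative_initial_state_rejected(self, two_state):
        mech, rates = two_state
        with pytest.raises(ConfigurationError, match="nonnegative"):
            simulate(mech, rates, {"E": -0.1}, np.linspace(0, 1, 3))

    @settings(max_examples=15, deadline=None)
    @given(
        kon=st.floats(0.1, 2000.0),
        koff=st.floats(0.05, 5000.0),
        e0=st.floats(0.01, 2.0),
    )
    def test_conservation_holds_for_random_rates(self, two_state, kon, koff, e0):
        mech, _ = two_state
        rates = {"kon": kon, "koff": koff}
        traj = simulate(mech, rates, {"E": e0, "D": 0.05},
                        np.linspace(0, 0.1, 21))
        assert max(traj.conservation_error().values()) < 1e-6


class TestAnalyticTwoState:
    def test_zero_time_gives_zero_bound(self):
        assert analytic_two_state(1100, 44.1, 0.4, 0.05, 0.0) == 0.0

    def test_equilibrium_partition_ratio(self):
        """kon*E/koff = 10 puts 10/11 of the DNA in the complex."""
        ed = analytic_two_state(10.0, 1.0, 1.0, 0.001, 1e6)
        assert ed == pytest.approx(0.001 * 10 / 11, rel=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ConfigurationError):
            analytic_two_state(-1.0, 44.1, 0.4, 0.05, 0.1)


class TestEquilibriumDistribution:
    def test_single_site_half_saturation(self, two_state):
        """K_assoc * E = 1 leaves DNA half bound (enzyme in large excess)."""
        mech, _ = two_state
        rates = {"kon": 1.0, "koff": 10.0}  # Kd = 10 uM
        _, fractions = equilibrium_distribution(
            mech, rates, {"E": 10.0, "D": 0.001}
        )
        assert fractions["ED"] == pytest.approx(0.5, abs=1e-3)

    def test_two_site_fractions_follow_equilibrium_constants(self):
        mech = Mechanism(
            "two_site",
            species=(
                Species("E", "enzyme", enzyme_units=1),
                Species("D", "free-DNA", primer_length=1, fluorescence_class="free",
                        dna_units=1, nucleotide_units=1),
                Species("EDa", "enzyme-bound-complex", primer_length=1, site="pol",
                        fluorescence_class="low", enzyme_units=1, dna_units=1,
                        nucleotide_units=1),
                Species("EDb", "enzyme-bound-complex", primer_length=1, site="exo",
                        fluorescence_class="high", enzyme_units=1, dna_units=1,
                        nucleotide_units=1),
            ),
            reactions=(
                Reaction((("E", 1), ("D", 1)), (("EDa", 1),), "ka", "kma"),
                Reaction((("E", 1), ("D", 1)), (("EDb", 1),), "kb", "kmb"),
            ),
        )
        rates = {"ka": 30.0, "kma": 3.0, "kb": 5.0, "kmb": 1.0}
        _, fr = equilibrium_distribution(mech, rates, {"E": 2.0, "D": 0.001})
        # bound fractions proportional to K_assoc = kon/koff: 10 vs 5
        assert fr["EDa"] / fr["EDb"] == pytest.approx(2.0, rel=1e-3)

    def test_irreversible_step_rejected(self):
        mech, rates = build_ssdna_mechanism(chemistry=True)
        with pytest.raises(ConfigurationError, match="irreversible"):
            equilibrium_distribution(mech, rates, {"E": 0.1, "D27": 0.05})
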