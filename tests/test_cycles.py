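"""The four pKa schemes: worked examples, algebraic identities, invariants."""

import math

import numpy as np
import pytest

from pkacycles import (
    AcidBasePair,
    IsodesmicReference,
    ProtonParameters,
    SpeciesEnergy,
    ThermoContext,
    WaterPairParameters,
    direct_pka,
    isodesmic_pka,
    tc1_pka,
    tc2_pka,
)
from pkacycles.core_thermo import InvalidInputError
from pkacycles.cycles import ConsistencyError, InvalidPairError


def _pair(acid_g, acid_s, base_g, base_s, charge=1, tag="m", solvent="water"):
    return AcidBasePair(
        acid=SpeciesEnergy("a", charge, acid_g, acid_s, tag, solvent),
        base=SpeciesEnergy("b", charge - 1, base_g, base_s, tag, solvent),
    )


ZERO_PROTON = ProtonParameters(
    dg_solv_proton=0.0, g_gas_proton=0.0, preset_label="custom"
)


class TestTc1:
    def test_inverts_free_energy_relation(self, ctx):
        # Pair whose total deprotonation free energy is 11.70 pKa units.
        dg = 11.70 * ctx.log_conversion
        pair = _pair(0.0, 0.0, dg, 0.0)
        assert tc1_pka(pair, ZERO_PROTON, ctx) == pytest.approx(11.70, abs=1e-9)
        # The same ΔG in kcal/mol is ~15.963 at 298.15 K.
        assert dg == pytest.approx(15.963, abs=2e-3)

    def test_null_reaction_gives_zero(self, ctx):
        pair = _pair(3.0, -2.0, 3.0, -2.0)
        assert tc1_pka(pair, ZERO_PROTON, ctx) == pytest.approx(0.0, abs=1e-12)

    def test_preset_switch_shifts_by_analytic_amount(self, ctx, pair_factory):
        # Moving dg_solv(H+) from -265.9 to -270.3 changes ΔG_aq by -4.4,
        # hence pKa by -4.4/(ln10 RT) ~ -3.225, identically for any pair.
        expected = -4.4 / ctx.log_conversion
        rng = np.random.default_rng(5)
        for _ in range(25):
            pair = pair_factory(rng)
            shift = tc1_pka(pair, ProtonParameters.from_preset("minus_270_3"), ctx) - tc1_pka(
                pair, ProtonParameters.from_preset("minus_265_9"), ctx
            )
            assert shift == pytest.approx(expected, abs=1e-9)
            assert shift < 0  # pKa2 column always below pKa1

    def test_standard_state_correction_adds_once(self, pair_factory):
        rng = np.random.default_rng(6)
        pair = pair_factory(rng)
        off = ThermoContext(apply_standard_state=False)
        on = ThermoContext(apply_standard_state=True)
        gap = tc1_pka(pair, None, on) - tc1_pka(pair, None, off)
        assert gap == pytest.approx(on.standard_state_correction / on.log_conversion)

    def test_mixed_tags_rejected(self):
        acid = SpeciesEnergy("a", 1, 0.0, 0.0, "m1", "water")
        base = SpeciesEnergy("b", 0, 0.0, 0.0, "m2", "water")
        with pytest.raises(ConsistencyError):
            AcidBasePair(acid=acid, base=base)

    def test_charge_mismatch_rejected(self):
        acid = SpeciesEnergy("a", 0, 0.0, 0.0)
        base = SpeciesEnergy("b", 0, 0.0, 0.0)
        with pytest.raises(InvalidPairError):
            AcidBasePair(acid=acid, base=base)

    def test_preset_label_consistency_enforced(self):
        with pytest.raises(InvalidInputError):
            ProtonParameters(dg_solv_proton=-1.0, preset_label="minus_265_9")


def _reducing_water_pair(proton, tag="m", solvent="water", g0=-10.0, s0=-4.0):
    """H2O/H3O+ whose differences equal the bare-proton parameters."""
    water = SpeciesEnergy("h2o", 0, g0, s0, tag, solvent)
    hydronium = SpeciesEnergy(
        "h3o", 1, g0 + proton.g_gas_proton, s0 + proton.dg_solv_proton, tag, solvent
    )
    return WaterPairParameters(water=water, hydronium=hydronium)


class TestTc2:
    def test_reduces_to_tc1_under_reduction_condition(self, ctx, pair_factory):
        rng = np.random.default_rng(8)
        proton = ProtonParameters()
        for _ in range(50):
            pair = pair_factory(rng)
            wp = _reducing_water_pair(proton)
            assert tc2_pka(pair, wp, ctx) == pytest.approx(
                tc1_pka(pair, proton, ctx), abs=1e-9
            )

    def test_constructed_free_energy_inverts_to_reference_value(self, ctx):
        # The winning level of theory predicts 12.47 for the reference
        # molecule; build TC2 energies whose ΔG_aq encodes exactly that.
        target = 12.47
        water = SpeciesEnergy("h2o", 0, 0.0, 0.0, "m", "water")
        hydronium = SpeciesEnergy("h3o", 1, 0.0, 0.0, "m", "water")
        pair = _pair(0.0, 0.0, target * ctx.log_conversion, 0.0)
        wp = WaterPairParameters(water=water, hydronium=hydronium)
        assert tc2_pka(pair, wp, ctx) == pytest.approx(target, abs=1e-9)

    def test_null_reaction_zero_without_correction(self, ctx):
        pair = _pair(1.0, 2.0, 1.0, 2.0)
        wp = WaterPairParameters(
            water=SpeciesEnergy("h2o", 0, 5.0, -1.0, "m", "water"),
            hydronium=SpeciesEnergy("h3o", 1, 5.0, -1.0, "m", "water"),
        )
        assert tc2_pka(pair, wp, ctx) == pytest.approx(0.0, abs=1e-12)

    def test_water_concentration_correction_subtracts_log_molarity(self, ctx):
        pair = _pair(1.0, 2.0, 1.0, 2.0)
        wp = WaterPairParameters(
            water=SpeciesEnergy("h2o", 0, 5.0, -1.0, "m", "water"),
            hydronium=SpeciesEnergy("h3o", 1, 5.0, -1.0, "m", "water"),
            water_concentration_correction=True,
        )
        assert tc2_pka(pair, wp, ctx) == pytest.approx(-math.log10(55.34), abs=1e-12)


class TestDirect:
    def test_identity_with_tc1_when_proton_terms_match(self, ctx, pair_factory):
        rng = np.random.default_rng(9)
        proton = ProtonParameters()
        for _ in range(20):
            pair = pair_factory(rng)
            g_h = proton.g_gas_proton + proton.dg_solv_proton
            assert direct_pka(pair, g_h, ctx) == pytest.approx(
                tc1_pka(pair, proton, ctx), abs=1e-10
            )

    def test_matches_hand_summed_terms(self, ctx, pair_factory):
        rng = np.random.default_rng(10)
        for _ in range(20):
            pair = pair_factory(rng)
            g_h = rng.uniform(-280, -250)
            oracle = (
                pair.base.g_gas
                + pair.base.dg_solv
                + g_h
                - pair.acid.g_gas
                - pair.acid.dg_solv
            ) / ctx.log_conversion
            assert direct_pka(pair, g_h, ctx) == pytest.approx(oracle, abs=1e-10)

    def test_null_reaction(self, ctx):
        pair = _pair(0.0, 0.0, 0.0, 0.0)
        assert direct_pka(pair, 0.0, ctx) == pytest.approx(0.0, abs=1e-12)


class TestIsodesmic:
    def test_self_exchange_returns_reference_pka(self, ctx, pair_factory):
        rng = np.random.default_rng(12)
        pair = pair_factory(rng)
        ref = IsodesmicReference(ref_acid=pair.acid, ref_base=pair.base, ref_pka=19.41)
        assert isodesmic_pka(pair, ref, ctx) == 19.41

    def test_unit_free_energy_shift(self, ctx):
        # ΔG_soln of exactly one pKa unit on top of the MeCN anchor 19.41.
        query = _pair(0.0, 0.0, 10.0 + ctx.log_conversion, 0.0)
        ref = IsodesmicReference(
            ref_acid=SpeciesEnergy("hb", 1, 0.0, 0.0, "m", "water"),
            ref_base=SpeciesEnergy("b", 0, 10.0, 0.0, "m", "water"),
            ref_pka=19.41,
        )
        assert isodesmic_pka(query, ref, ctx) == pytest.approx(20.41, abs=1e-9)

    def test_round_trip_antisymmetry(self, ctx, pair_factory):
        rng = np.random.default_rng(13)
        for _ in range(20):
            query = pair_factory(rng, ident="q")
            other = pair_factory(rng, ident="r")
            ref = IsodesmicReference(other.acid, other.base, ref_pka=11.70)
            forward = isodesmic_pka(query, ref, ctx)
            back = isodesmic_pka(
                other, IsodesmicReference(query.acid, query.base, ref_pka=forward), ctx
            )
            assert back == pytest.approx(11.70, abs=1e-9)

    def test_tag_mismatch_rejected(self, ctx, pair_factory):
        rng = np.random.default_rng(14)
        query = pair_factory(rng, solvent_tag="water")
        other = pair_factory(rng, solvent_tag="mecn")
        ref = IsodesmicReference(other.acid, other.base, ref_pka=1.0)
        with pytest.raises(ConsistencyError):
            isodesmic_pka(query, ref, ctx)


class TestSchemeInvariants:
    def test_linearity_in_each_energy_term(self, ctx, pair_factory):
        # Finite differences: slope of pKa w.r.t. every input free energy
        # is +-1/(ln10 RT), sign by which side of the reaction it enters.
        rng = np.random.default_rng(15)
        pair = pair_factory(rng)
        proton = ProtonParameters()
        h = 0.5
        slope = 1.0 / ctx.log_conversion
        base_val = tc1_pka(pair, proton, ctx)

        def rebuild(d_acid_g=0.0, d_acid_s=0.0, d_base_g=0.0, d_base_s=0.0):
            return AcidBasePair(
                acid=SpeciesEnergy(
                    "a", 1, pair.acid.g_gas + d_acid_g, pair.acid.dg_solv + d_acid_s,
                    pair.acid.method_tag, pair.acid.solvent_tag,
                ),
                base=SpeciesEnergy(
                    "b", 0, pair.base.g_gas + d_base_g, pair.base.dg_solv + d_base_s,
                    pair.base.method_tag, pair.base.solvent_tag,
                ),
            )

        for kwargs, sign in [
            ({"d_acid_g": h}, -1),
            ({"d_acid_s": h}, -1),
            ({"d_base_g": h}, +1),
            ({"d_base_s": h}, +1),
        ]:
            diff = tc1_pka(rebuild(**kwargs), proton, ctx) - base_val
            assert diff / h == pytest.approx(sign * slope, abs=1e-9)

    def test_charged_species_shift_cancels_only_in_isodesmic(self, ctx, pair_factory):
        # A constant error c on every charged species' solvation energy
        # shifts TC1 but cancels between two cationic-acid pairs in the
        # isodesmic difference.
        rng = np.random.default_rng(16)
        c = 3.7

        def shifted(pair):
            def maybe(s):
                if s.charge_state == 0:
                    return s
                return SpeciesEnergy(
                    s.species_id, s.charge_state, s.g_gas, s.dg_solv + c,
                    s.method_tag, s.solvent_tag,
                )
            return AcidBasePair(acid=maybe(pair.acid), base=maybe(pair.base))

        for _ in range(10):
            query = pair_factory(rng, ident="q")
            refp = pair_factory(rng, ident="r")
            ref = IsodesmicReference(refp.acid, refp.base, ref_pka=10.0)
            ref_shifted = IsodesmicReference(
                shifted(refp).acid, shifted(refp).base, ref_pka=10.0
            )
            # cationic acid -> base is neutral; only the acid moves.
            tc1_shift = tc1_pka(shifted(query), None, ctx) - tc1_pka(query, None, ctx)
            assert tc1_shift == pytest.approx(-c / ctx.log_conversion, abs=1e-9)
            assert isodesmic_pka(shifted(query), ref_shifted, ctx) == pytest.approx(
                isodesmic_pka(query, ref, ctx), abs=1e-9
            )
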