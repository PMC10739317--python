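"""Forward curve mathematics: Hill, multi-ligand GRA, ECx and antagonist inversions."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from gramix import (LigandParams, ReferenceScale, UnreachableEffectError,
                    apparent_ec50_shift, ca_mixture_ecx, ecx_from_hill,
                    gra_response, hill_response, ic50_of_antagonist)
from gramix.types import MixtureSpec

from conftest import random_ligand

AG = LigandParams(a=1.0, c=1.0, n=1.0)
ANT = LigandParams(a=0.0, c=1.0, n=1.0)


class TestHillResponse:
    def test_zero_dose_returns_baseline(self, shifted_scale):
        p = LigandParams(a=1.3, c=2e-8, n=2.5)
        assert hill_response(p, shifted_scale, 0.0) == shifted_scale.y0

    def test_full_agonist_midpoint_is_half_max(self, scale):
        assert hill_response(LigandParams(1.0, 10e-9, 1.0), scale, 10e-9) == pytest.approx(50.0)

    def test_partial_agonist_saturates_at_its_efficacy(self, scale):
        # kaempferol-like 60% partial agonist approaches 60, never exceeds it
        p = LigandParams(a=0.6, c=2e-6, n=1.0)
        assert hill_response(p, scale, 1e6 * p.c) == pytest.approx(60.0, abs=1e-3)
        x = np.logspace(-9, 0, 50)
        assert np.all(hill_response(p, scale, x) <= 60.0 + 1e-12)

    def test_monotone_in_dose_for_agonist(self, scale):
        p = LigandParams(a=1.8, c=1e-7, n=0.7)
        y = hill_response(p, scale, np.logspace(-10, -4, 60))
        assert np.all(np.diff(y) > 0)

    @pytest.mark.parametrize("bad", [-1.0, np.nan, np.inf])
    def test_invalid_dose_rejected(self, scale, bad):
        with pytest.raises(ValueError):
            hill_response(AG, scale, bad)


class TestGraResponse:
    def test_single_ligand_reduces_to_hill_exactly(self, scale, rng):
        for _ in range(20):
            p = random_ligand(rng)
            x = float(10.0 ** rng.uniform(-11, -4))
            assert gra_response([(p, x)], scale) == hill_response(p, scale, x)

    def test_antagonist_occupies_without_activating(self, scale):
        # one agonist unit vs nine antagonist units: occupancy ratio 1/11
        y = gra_response([(AG, 1.0), (ANT, 9.0)], scale)
        assert y == pytest.approx(100.0 / 11.0, rel=1e-12)

    def test_adding_antagonist_strictly_decreases_response(self, scale):
        alone = gra_response([(AG, 1.0)], scale)
        assert alone == pytest.approx(50.0)
        with_ant = gra_response([(AG, 1.0), (ANT, 9.0)], scale)
        assert with_ant < alone

    def test_empty_mixture_rejected(self, scale):
        with pytest.raises(ValueError, match="at least one ligand"):
            gra_response([], scale)

    def test_response_bounded_by_largest_efficacy(self, shifted_scale, rng):
        for _ in range(20):
            ligands = [random_ligand(rng) for _ in range(3)]
            x = [float(10.0 ** rng.uniform(-10, -3)) for _ in ligands]
            y = gra_response(list(zip(ligands, x)), shifted_scale)
            a_max = max(p.a for p in ligands)
            assert shifted_scale.y0 - 1e-9 <= y
            assert y <= shifted_scale.y0 + shifted_scale.span * a_max + 1e-9

    def test_saturated_doses_recover_efficacy_weighted_limit(self, scale):
        p1 = LigandParams(1.0, 1e-9, 1.0)
        p2 = LigandParams(2.0, 1e-9, 1.0)
        y = gra_response([(p1, 1.0), (p2, 1.0)], scale)
        assert y == pytest.approx(150.0, rel=1e-6)


class TestEcxInversion:
    def test_ec50_of_full_agonist_is_potency(self, scale):
        assert ecx_from_hill(LigandParams(1.0, 10e-9, 1.0), scale, 50.0) == pytest.approx(10e-9)

    def test_partial_agonist_midlevel(self, scale):
        # a=0.6 at X=30: r/(a-r) = 1 so ECx equals c
        p = LigandParams(0.6, 2e-6, 1.0)
        x30 = ecx_from_hill(p, scale, 30.0)
        assert x30 == pytest.approx(2e-6, rel=1e-12)
        assert hill_response(p, scale, x30) == pytest.approx(30.0, rel=1e-9)

    def test_level_above_efficacy_is_unreachable(self, scale):
        with pytest.raises(UnreachableEffectError, match="0.6"):
            ecx_from_hill(LigandParams(0.6, 2e-6, 1.0), scale, 70.0)

    @given(
        a=st.floats(0.5, 2.0),
        logc=st.floats(-10, -5),
        n=st.floats(0.5, 5.0),
        rel=st.floats(0.05, 0.95),
    )
    def test_roundtrip_with_forward_response(self, a, logc, n, rel):
        scale = ReferenceScale()
        p = LigandParams(a=a, c=10.0 ** logc, n=n)
        X = rel * 100.0 * a
        x = ecx_from_hill(p, scale, X)
        assert hill_response(p, scale, x) == pytest.approx(X, rel=1e-9)
        assert ecx_from_hill(p, scale, hill_response(p, scale, x)) == pytest.approx(x, rel=1e-9)


class TestCaMixtureEcx:
    def test_single_component_returns_own_ecx(self, scale):
        p = LigandParams(1.0, 5e-8, 1.3)
        mix = MixtureSpec((("p", p),), (1.0,))
        assert ca_mixture_ecx(mix, scale, 40.0) == pytest.approx(
            ecx_from_hill(p, scale, 40.0), rel=1e-12)

    def test_harmonic_combination_of_two_components(self, scale):
        # ECx 1 uM and 3 uM at equal fractions: (0.5/1 + 0.5/3)^-1 = 1.5 uM
        mix = MixtureSpec(
            (("p", LigandParams(1.0, 1e-6, 1.0)), ("q", LigandParams(1.0, 3e-6, 1.0))),
            (0.5, 0.5))
        assert ca_mixture_ecx(mix, scale, 50.0) == pytest.approx(1.5e-6, rel=1e-12)

    def test_identical_components_leave_ecx_unchanged(self, scale):
        p = LigandParams(1.0, 2e-6, 1.0)
        mix = MixtureSpec((("p", p), ("q", p)), (0.5, 0.5))
        assert ca_mixture_ecx(mix, scale, 50.0) == pytest.approx(2e-6, rel=1e-12)

    def test_unreachable_level_names_offenders(self, scale):
        mix = MixtureSpec(
            (("full", LigandParams(1.0, 1e-6, 1.0)),
             ("partial", LigandParams(0.6, 1e-6, 1.0))),
            (0.5, 0.5))
        with pytest.raises(UnreachableEffectError, match="partial"):
            ca_mixture_ecx(mix, scale, 80.0)


class TestAntagonistInversions:
    def test_no_antagonist_leaves_potency_unshifted(self, scale):
        ag = LigandParams(1.0, 3e-8, 1.4)
        ant = LigandParams(0.0, 1e-7, 1.0)
        assert apparent_ec50_shift(ag, ant, 0.0, scale) == pytest.approx(ag.c, rel=1e-9)

    def test_schild_closed_form_for_unit_slopes(self, scale):
        # x_ant = 9 c_ant gives a tenfold right-shift
        ag = LigandParams(1.0, 2e-9, 1.0)
        ant = LigandParams(0.0, 5e-8, 1.0)
        shift = apparent_ec50_shift(ag, ant, 9.0 * ant.c, scale)
        assert shift == pytest.approx(10.0 * ag.c, rel=1e-6)

    def test_shift_grows_with_antagonist_dose(self, scale):
        ag = LigandParams(1.2, 2e-9, 1.7)
        ant = LigandParams(0.0, 5e-8, 0.8)
        doses = [1e-8, 2e-8, 4e-8, 8e-8]
        shifts = [apparent_ec50_shift(ag, ant, d, scale) for d in doses]
        assert np.all(np.diff(shifts) > 0)

    def test_shift_requires_pure_antagonist(self, scale):
        with pytest.raises(ValueError, match="a = 0"):
            apparent_ec50_shift(AG, LigandParams(0.1, 1.0, 1.0), 1.0, scale)

    def test_ic50_closed_form_for_unit_slopes(self, scale):
        # halving the response of an agonist at its EC50 needs v = 1 + u
        # antagonist occupancy units, i.e. IC50 = c_ant (1 + x_ag/c_ag) = 2 c_ant
        ag = LigandParams(1.0, 1e-9, 1.0)
        ant = LigandParams(0.0, 4e-8, 1.0)
        ic50 = ic50_of_antagonist(ag, ag.c, ant, scale)
        assert ic50 == pytest.approx(2.0 * ant.c, rel=1e-6)
        # and at x_ag = 3 c_ag: IC50 = 4 c_ant
        ic50b = ic50_of_antagonist(ag, 3.0 * ag.c, ant, scale)
        assert ic50b == pytest.approx(4.0 * ant.c, rel=1e-6)

    def test_doubling_antagonist_beyond_ic50_drops_below_half(self, scale):
        ag = LigandParams(1.0, 1e-9, 1.3)
        ant = LigandParams(0.0, 4e-8, 0.9)
        x_ag = 5e-10
        half = scale.y0 + (hill_response(ag, scale, x_ag) - scale.y0) / 2.0
        ic50 = ic50_of_antagonist(ag, x_ag, ant, scale)
        assert gra_response([(ag, x_ag), (ant, 2 * ic50)], scale) < half

    def test_ic50_invariant_to_reference_rescaling(self, shifted_scale, scale):
        ag = LigandParams(0.9, 1e-9, 1.6)
        ant = LigandParams(0.0, 4e-8, 1.2)
        v1 = ic50_of_antagonist(ag, 2e-9, ant, scale)
        v2 = ic50_of_antagonist(ag, 2e-9, ant, shifted_scale)
        assert v1 == pytest.approx(v2, rel=1e-9)
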