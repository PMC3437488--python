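"""Well-mixed-room material balance: forward model, inversion, normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioemit import (
    IMPACTOR_BINS,
    BinLossRates,
    ConcentrationProfile,
    EmissionProfile,
    InfiltrationFactors,
    RoomParams,
    SizeBinGrid,
    denormalize_dlogdp,
    infiltration_factors,
    invert_emission,
    normalize_dlogdp,
    occupied_vacant_ratio,
    steady_state_concentration,
)
from bioemit.mass_balance import FLAG_NEGATIVE_CLAMPED, FLAG_OK, FLAG_UNDEFINED

GRID = IMPACTOR_BINS
N = len(GRID)


def profile(conc, location="indoor", state="occupied", analyte="bacterial_genomes"):
    return ConcentrationProfile(
        analyte=analyte, location=location, state=state, bins=GRID, conc=np.asarray(conc, float)
    )


ROOM = RoomParams(volume_m3=90.0, aer_per_h=5.5, occupants=4.7)
K = BinLossRates(bins=GRID, k_per_h=(0.31, 0.79, 2.1, 4.4, 8.6, 9.6))


class TestInfiltrationFactors:
    def test_simple_ratio(self):
        f = infiltration_factors(
            profile(np.full(N, 0.5), state="vacant"),
            profile(np.ones(N), "outdoor", "vacant"),
        )
        assert np.allclose(f.f, 0.5)

    def test_identical_profiles_give_unity(self):
        c = np.linspace(1, 6, N)
        f = infiltration_factors(
            profile(c, state="vacant"), profile(c, "outdoor", "vacant")
        )
        assert np.allclose(f.f, 1.0)

    def test_zero_outdoor_bin_flagged_others_computed(self):
        out = np.ones(N)
        out[2] = 0.0
        f = infiltration_factors(
            profile(np.full(N, 0.5), state="vacant"), profile(out, "outdoor", "vacant")
        )
        assert f.flags[2] == FLAG_UNDEFINED
        assert np.isnan(f.f[2])
        kept = [i for i in range(N) if i != 2]
        assert np.allclose(f.f[kept], 0.5)

    def test_requires_vacant_state(self):
        with pytest.raises(ValueError, match="vacant"):
            infiltration_factors(
                profile(np.ones(N), state="occupied"), profile(np.ones(N), "outdoor", "vacant")
            )


class TestForwardModel:
    def test_hand_computed_steady_state(self):
        """V=90 m3, AER=5.5/h, N=4.7, k=4.4/h, f=0.8, C_out=1000, E=1e6
        gives C = 800 + 4.7e6/891 ~ 6075 copies/m3."""
        grid = SizeBinGrid.from_edges([3.3, 4.7])
        f = InfiltrationFactors(bins=grid, f=np.array([0.8]))
        out = ConcentrationProfile(
            analyte="bacterial_genomes", location="outdoor", state="occupied",
            bins=grid, conc=np.array([1000.0]),
        )
        e = EmissionProfile(bins=grid, e=np.array([1e6]))
        k = BinLossRates(bins=grid, k_per_h=(4.4,))
        c = steady_state_concentration(f, out, e, ROOM, k)
        assert c.conc[0] == pytest.approx(800 + 4.7e6 / 891, rel=1e-12)

    def test_no_source_limit(self):
        f = InfiltrationFactors(bins=GRID, f=np.full(N, 0.7))
        out = profile(np.linspace(1, 6, N), "outdoor")
        e = EmissionProfile(bins=GRID, e=np.zeros(N))
        c = steady_state_concentration(f, out, e, ROOM, K)
        assert np.allclose(c.conc, 0.7 * out.conc)

    def test_occupancy_scales_source_term_only(self):
        f = InfiltrationFactors(bins=GRID, f=np.full(N, 0.7))
        out = profile(np.ones(N), "outdoor")
        e = EmissionProfile(bins=GRID, e=np.full(N, 1e5))
        room2 = RoomParams(90.0, 5.5, 2 * ROOM.occupants)
        c1 = steady_state_concentration(f, out, e, ROOM, K).conc
        c2 = steady_state_concentration(f, out, e, room2, K).conc
        assert np.allclose(c2 - 0.7, 2 * (c1 - 0.7))


class TestInversion:
    def test_inverse_of_hand_computed_forward_case(self):
        grid = SizeBinGrid.from_edges([3.3, 4.7])
        f = InfiltrationFactors(bins=grid, f=np.array([0.8]))
        indoor = ConcentrationProfile(
            analyte="bacterial_genomes", location="indoor", state="occupied",
            bins=grid, conc=np.array([800 + 4.7e6 / 891]),
        )
        out = ConcentrationProfile(
            analyte="bacterial_genomes", location="outdoor", state="occupied",
            bins=grid, conc=np.array([1000.0]),
        )
        k = BinLossRates(bins=grid, k_per_h=(4.4,))
        e = invert_emission(indoor, out, f, ROOM, k)
        assert e.e[0] == pytest.approx(1e6, rel=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        e_scale=st.floats(1e2, 1e8),
        f_val=st.floats(0.05, 1.4),
        aer=st.floats(0.5, 12.0),
        occ=st.floats(0.5, 40.0),
    )
    def test_roundtrip_forward_then_invert(self, e_scale, f_val, aer, occ):
        room = RoomParams(90.0, aer, occ)
        f = InfiltrationFactors(bins=GRID, f=np.full(N, f_val))
        out = profile(np.linspace(10, 60, N), "outdoor")
        e_true = EmissionProfile(bins=GRID, e=e_scale * np.linspace(0.2, 2.0, N))
        c = steady_state_concentration(f, out, e_true, room, K)
        e_rec = invert_emission(c, out, f, room, K)
        assert np.allclose(e_rec.e, e_true.e, rtol=1e-12)

    def test_no_indoor_excess_gives_zero(self):
        f = InfiltrationFactors(bins=GRID, f=np.full(N, 0.6))
        out = profile(np.full(N, 100.0), "outdoor")
        indoor = profile(0.6 * out.conc)
        e = invert_emission(indoor, out, f, ROOM, K)
        assert np.allclose(e.e, 0.0)
        assert all(fl == FLAG_OK for fl in e.flags)

    def test_negative_excess_clamped_with_diagnostics(self):
        f = InfiltrationFactors(bins=GRID, f=np.ones(N))
        out = profile(np.full(N, 100.0), "outdoor")
        indoor_c = np.full(N, 100.0)
        indoor_c[3] = 50.0
        e = invert_emission(profile(indoor_c), out, f, ROOM, K)
        assert e.flags[3] == FLAG_NEGATIVE_CLAMPED
        assert e.e[3] == 0.0
        assert e.raw_e[3] < 0

    def test_zero_occupancy_raises_per_person_error(self):
        f = InfiltrationFactors(bins=GRID, f=np.ones(N))
        out = profile(np.ones(N), "outdoor")
        with pytest.raises(ValueError, match="per person"):
            invert_emission(profile(np.ones(N)), out, f, RoomParams(90, 5.5, 0.0), K)

    def test_emission_scales_inversely_with_occupancy(self):
        f = InfiltrationFactors(bins=GRID, f=np.full(N, 0.5))
        out = profile(np.full(N, 10.0), "outdoor")
        indoor = profile(np.full(N, 50.0))
        e1 = invert_emission(indoor, out, f, RoomParams(90, 5.5, 2.0), K)
        e2 = invert_emission(indoor, out, f, RoomParams(90, 5.5, 4.0), K)
        assert np.allclose(e1.e, 2 * e2.e)

    def test_emission_increases_with_removal_rate(self):
        f = InfiltrationFactors(bins=GRID, f=np.full(N, 0.5))
        out = profile(np.full(N, 10.0), "outdoor")
        indoor = profile(np.full(N, 50.0))
        e_lo = invert_emission(indoor, out, f, RoomParams(90, 3.0, 4.7), K)
        e_hi = invert_emission(indoor, out, f, RoomParams(90, 8.0, 4.7), K)
        assert np.all(e_hi.e > e_lo.e)


class TestNormalisation:
    def test_decade_bin_is_identity(self):
        grid = SizeBinGrid.from_edges([1.0, 10.0])
        assert normalize_dlogdp([5.0], grid)[0] == pytest.approx(5.0)

    def test_top_stage_density(self):
        grid = SizeBinGrid.from_edges([9.0, 20.0])
        got = normalize_dlogdp([3.47], grid)[0]
        assert got == pytest.approx(3.47 / np.log10(20 / 9), rel=1e-12)
        assert got == pytest.approx(10.0, abs=0.05)

    def test_roundtrip_identity(self):
        vals = np.array([1.0, 2.5, 0.0, 7.2, 3.3, 9.9])
        dens = normalize_dlogdp(vals, GRID)
        assert np.allclose(denormalize_dlogdp(dens, GRID), vals, rtol=1e-15, atol=0)


class TestOccupiedVacantRatio:
    def test_identity_profiles(self):
        c = profile(np.linspace(1, 6, N))
        res = occupied_vacant_ratio(c, profile(c.conc, state="vacant"))
        assert np.allclose(res["per_bin"], 1.0)
        assert res["mean_of_ratios"] == pytest.approx(1.0)
        assert res["ratio_of_sums"] == pytest.approx(1.0)

    def test_uniform_scaling_agrees_across_conventions(self):
        vac = profile(np.linspace(1, 6, N), state="vacant")
        occ = profile(3 * vac.conc)
        res = occupied_vacant_ratio(occ, vac)
        assert res["mean_of_ratios"] == pytest.approx(3.0)
        assert res["ratio_of_sums"] == pytest.approx(3.0)

    def test_conventions_differ_on_uneven_profiles(self):
        grid = SizeBinGrid.from_edges([1.0, 2.0, 4.0])
        occ = ConcentrationProfile("mass", "indoor", "occupied", grid, np.array([10.0, 2.0]))
        vac = ConcentrationProfile("mass", "indoor", "vacant", grid, np.array([1.0, 1.0]))
        res = occupied_vacant_ratio(occ, vac)
        assert res["mean_of_ratios"] == pytest.approx(6.0)
        assert res["ratio_of_sums"] == pytest.approx(6.0)
        # and a genuinely asymmetric case where they split
        vac2 = ConcentrationProfile("mass", "indoor", "vacant", grid, np.array([1.0, 2.0]))
        res2 = occupied_vacant_ratio(occ, vac2)
        assert res2["mean_of_ratios"] == pytest.approx((10 + 1) / 2)
        assert res2["ratio_of_sums"] == pytest.approx(12 / 3)
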