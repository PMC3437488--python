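"""Taxa apportionment: abundances, group fractions, emission splitting."""

import numpy as np
import pytest

from bioemit import (
    AbundanceTable,
    EmissionProfile,
    SizeBinGrid,
    TaxaGroup,
    apportion_emissions,
    default_groups,
    enrichment_factor,
    group_abundance,
    relative_abundances,
)
from bioemit.taxa import STATUS_FAILED_PCR, STATUS_OK

GRID2 = SizeBinGrid.from_edges([1.0, 2.0, 4.0])


def table2(counts, status=None):
    counts = np.asarray(counts)
    taxa = tuple(f"t{i}" for i in range(counts.shape[1]))
    return AbundanceTable(
        bins=GRID2, taxa=taxa, counts=counts, status=tuple(status) if status else ()
    )


class TestRelativeAbundances:
    def test_simple_proportions(self):
        t = table2([[3, 1], [5, 5]])
        props = relative_abundances(t)
        assert np.allclose(props, [[0.75, 0.25], [0.5, 0.5]])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        t = table2(rng.integers(1, 50, size=(2, 6)))
        assert np.allclose(relative_abundances(t).sum(axis=1), 1.0, atol=1e-12)

    def test_failed_bin_propagates_nan(self):
        t = table2([[3, 1], [0, 0]], status=[STATUS_OK, STATUS_FAILED_PCR])
        props = relative_abundances(t)
        assert np.all(np.isnan(props[1]))
        assert np.allclose(props[0], [0.75, 0.25])

    def test_zero_reads_in_ok_bin_is_error(self):
        with pytest.raises(ValueError, match="zero reads"):
            relative_abundances(table2([[3, 1], [0, 0]]))

    def test_multinomial_draw_within_three_sd(self):
        rng = np.random.default_rng(42)
        p = np.array([0.17, 0.03, 0.8])
        depth = 10_000
        counts = rng.multinomial(depth, p).reshape(1, 3)
        t = AbundanceTable(
            bins=SizeBinGrid.from_edges([1.0, 2.0]), taxa=("a", "b", "c"), counts=counts
        )
        props = relative_abundances(t)[0]
        sd = np.sqrt(p * (1 - p) / depth)
        assert np.all(np.abs(props - p) < 3 * sd + 1e-12)


class TestGroupAbundance:
    def test_all_taxa_group_is_one(self):
        t = table2([[3, 1], [5, 5]])
        g = TaxaGroup("all", t.taxa)
        res = group_abundance(t, g)
        assert np.allclose(res["per_bin"], 1.0)
        assert res["pooled"] == pytest.approx(1.0)

    def test_unmatched_members_warn_and_give_zero(self, caplog):
        t = table2([[3, 1], [5, 5]])
        g = TaxaGroup("ghost", ("nope", "nada"))
        with caplog.at_level("WARNING"):
            res = group_abundance(t, g)
        assert "ghost" in caplog.text
        assert np.allclose(res["per_bin"], 0.0)

    def test_pooled_vs_mean_convention(self):
        # member reads 3/10 and 1/10: pooled 4/20 = 0.2, mean (0.3+0.1)/2 = 0.2?
        # use uneven depths so the conventions genuinely split
        t = table2([[3, 7], [1, 29]])
        g = TaxaGroup("m", ("t0",))
        res = group_abundance(t, g)
        assert res["pooled"] == pytest.approx(4 / 40)
        assert res["mean_of_bins"] == pytest.approx((0.3 + 1 / 30) / 2)
        assert res["overall"] == res["pooled"]


class TestApportionment:
    def test_scaling_and_fraction_zero(self):
        e = EmissionProfile(bins=GRID2, e=np.array([1e6, 2e6]))
        g = TaxaGroup("g", ("x",))
        res = apportion_emissions(e, [0.5, 0.0], g)
        assert res.e_group[0] == pytest.approx(5e5)
        assert res.e_group[1] == 0.0
        assert res.total_e == pytest.approx(5e5)  # ND bin contributes nothing

    def test_implied_total_from_published_row(self):
        """A bin with group emissions 2.7e6 at 18% of total implies a total
        bin emission rate of 1.5e7 genomes/h/person."""
        frac = 0.18
        e_total_bin = 2.7e6 / frac
        assert e_total_bin == pytest.approx(1.5e7, rel=1e-9)
        e = EmissionProfile(bins=GRID2, e=np.array([e_total_bin, 0.0]))
        res = apportion_emissions(e, [frac, 0.0], TaxaGroup("skin", ("x",)))
        assert res.e_group[0] == pytest.approx(2.7e6, rel=1e-9)
        assert res.pct_of_total[0] == pytest.approx(18.0)

    def test_failed_bins_carried_not_summed(self):
        e = EmissionProfile(bins=GRID2, e=np.array([1e6, 2e6]))
        res = apportion_emissions(e, [0.5, np.nan], TaxaGroup("g", ("x",)))
        assert res.status[1] == STATUS_FAILED_PCR
        assert np.isnan(res.e_group[1])
        assert res.total_e == pytest.approx(5e5)

    def test_fraction_out_of_range_rejected(self):
        e = EmissionProfile(bins=GRID2, e=np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            apportion_emissions(e, [0.5, 1.2], TaxaGroup("g", ("x",)))

    def test_disjoint_groups_bounded_by_total(self):
        e = EmissionProfile(bins=GRID2, e=np.array([1e6, 2e6]))
        fr_a, fr_b = np.array([0.3, 0.1]), np.array([0.4, 0.2])
        res_a = apportion_emissions(e, fr_a, TaxaGroup("a", ("x",)))
        res_b = apportion_emissions(e, fr_b, TaxaGroup("b", ("y",)))
        assert np.all(res_a.e_group + res_b.e_group <= e.e + 1e-9)

    def test_commutes_with_emission_scaling(self):
        e = EmissionProfile(bins=GRID2, e=np.array([1e6, 2e6]))
        e2 = EmissionProfile(bins=GRID2, e=3 * e.e)
        g = TaxaGroup("g", ("x",))
        a = apportion_emissions(e, [0.2, 0.4], g)
        b = apportion_emissions(e2, [0.2, 0.4], g)
        assert np.allclose(b.e_group, 3 * a.e_group)


class TestTableReconstruction:
    """Reconstructing the published human-microflora emission table from
    its per-bin rows."""

    SKIN_E = np.array([0.06, 0.14, np.nan, 2.7, 2.0, 0.53]) * 1e6
    SKIN_PCT = np.array([13, 7.3, np.nan, 18, 15, 32])
    ORAL_E = np.array([0.0, 0.03, np.nan, 0.0, 0.5, 0.0]) * 1e6

    def _grid(self):
        from bioemit import IMPACTOR_BINS

        return IMPACTOR_BINS

    def test_skin_total(self):
        grid = self._grid()
        e_total = np.where(np.isnan(self.SKIN_E), np.nan, self.SKIN_E / (self.SKIN_PCT / 100))
        e = EmissionProfile(bins=grid, e=np.nan_to_num(e_total))
        res = apportion_emissions(
            e, np.where(np.isnan(self.SKIN_PCT), np.nan, self.SKIN_PCT / 100),
            TaxaGroup("skin", ("x",)),
        )
        assert res.total_e == pytest.approx(5.4e6, rel=0.02)

    def test_combined_total_and_ratio(self):
        skin = np.nansum(self.SKIN_E)
        oral = np.nansum(self.ORAL_E)
        assert skin + oral == pytest.approx(5.9e6, rel=0.02)
        assert skin / oral == pytest.approx(10.0, rel=0.05)


class TestEnrichment:
    def test_published_skin_enrichment(self):
        res = enrichment_factor(17.0, 4.9)
        assert float(f"{res['factor']:.2g}") == pytest.approx(3.5)

    def test_equal_fractions(self):
        assert enrichment_factor(5.0, 5.0)["factor"] == pytest.approx(1.0)

    def test_zero_indoor(self):
        assert enrichment_factor(0.0, 5.0)["factor"] == 0.0

    def test_zero_outdoor_undefined(self):
        res = enrichment_factor(5.0, 0.0)
        assert not res["defined"]
        assert res["indoor"] == 5.0


def test_default_groups_staph_assignment():
    groups = default_groups()
    assert "Staphylococcus" in groups["skin_hair_nostrils"].members
    assert "Staphylococcus" not in groups["oral_cavity"].members
    dual = default_groups(staph_in_oral=True)
    assert "Staphylococcus" in dual["oral_cavity"].members
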