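"""CSV/YAML readers and writers, pipeline configuration, and the
end-to-end emission-rate pipeline.

Table dialects: comma-separated by default, tab accepted, UTF-8.  Bin
edges are matched exactly across tables — a grid mismatch is an error,
never an interpolation.  Logs go to stderr via the ``bioemit`` logger;
results go only to files or returned objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bins import SizeBinGrid
from .deposition import (
    BinLossRates,
    CubicDepositionModel,
    SettlingModel,
    loss_rates_for_grid,
)
from .mass_balance import (
    ConcentrationProfile,
    EmissionProfile,
    RoomParams,
    infiltration_factors,
    invert_emission,
    occupied_vacant_ratio,
)
from .mass_fraction import MassFractionConfig, bacterial_mass_concentration, ppm_fraction
from .taxa import (
    AbundanceTable,
    TaxaGroup,
    apportion_emissions,
    default_groups,
    enrichment_factor,
    group_abundance,
)

__all__ = [
    "read_concentration_table",
    "write_concentration_table",
    "read_loss_rates",
    "write_loss_rates",
    "write_emission_profile",
    "read_abundance_table",
    "write_abundance_table",
    "read_tracer_series",
    "PipelineConfig",
    "run_pipeline",
    "write_observations",
]

log = logging.getLogger("bioemit")

CONC_COLUMNS = ["analyte", "location", "state", "d_lo_um", "d_hi_um", "concentration", "units"]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def _grid_from_rows(sub: pd.DataFrame, path, key) -> SizeBinGrid:
    sub = sub.sort_values("d_lo_um")
    lo = sub["d_lo_um"].to_numpy(dtype=float)
    hi = sub["d_hi_um"].to_numpy(dtype=float)
    for i in range(len(lo) - 1):
        if hi[i] > lo[i + 1]:
            rows = sub.index[[i, i + 1]].tolist()
            raise ValueError(f"{path}: overlapping bins for {key} at rows {rows}")
    from .bins import SizeBin

    return SizeBinGrid(tuple(SizeBin(a, b) for a, b in zip(lo, hi)))


def read_concentration_table(path) -> dict:
    """Read a concentration CSV into profiles keyed (analyte, location, state).

    Required columns: analyte, location, state, d_lo_um, d_hi_um,
    concentration; optional: units.  Errors name offending rows.
    """
    df = _read_table(path)
    _require_columns(df, CONC_COLUMNS[:-1], path)
    neg = df.index[df["concentration"] < 0].tolist()
    if neg:
        raise ValueError(f"{path}: negative concentrations at rows {neg}")
    profiles = {}
    for key, sub in df.groupby(["analyte", "location", "state"]):
        grid = _grid_from_rows(sub, path, key)
        sub = sub.sort_values("d_lo_um")
        units = str(sub["units"].iloc[0]) if "units" in sub.columns else None
        profiles[key] = ConcentrationProfile(
            analyte=key[0],
            location=key[1],
            state=key[2],
            bins=grid,
            conc=sub["concentration"].to_numpy(dtype=float),
            units=units,
        )
    return profiles


def write_concentration_table(profiles, path) -> None:
    """Write profiles (iterable or dict of ConcentrationProfile) to CSV."""
    if isinstance(profiles, dict):
        profiles = profiles.values()
    rows = []
    for p in profiles:
        for b, c in zip(p.bins, p.conc):
            rows.append(
                dict(
                    analyte=p.analyte,
                    location=p.location,
                    state=p.state,
                    d_lo_um=b.d_lo,
                    d_hi_um=b.d_hi,
                    concentration=c,
                    units=p.units,
                )
            )
    pd.DataFrame(rows, columns=CONC_COLUMNS).to_csv(path, index=False)


def read_loss_rates(path) -> BinLossRates:
    """Read a k table: columns d_lo_um, d_hi_um, k_per_h."""
    df = _read_table(path)
    _require_columns(df, ["d_lo_um", "d_hi_um", "k_per_h"], path)
    grid = _grid_from_rows(df, path, "loss rates")
    df = df.sort_values("d_lo_um")
    return BinLossRates(bins=grid, k_per_h=tuple(df["k_per_h"].astype(float)))


def write_loss_rates(k: BinLossRates, path) -> None:
    pd.DataFrame(
        {
            "d_lo_um": k.bins.d_lo,
            "d_hi_um": k.bins.d_hi,
            "k_per_h": k.k,
        }
    ).to_csv(path, index=False)


def write_emission_profile(profile: EmissionProfile, path) -> None:
    pd.DataFrame(
        {
            "d_lo_um": profile.bins.d_lo,
            "d_hi_um": profile.bins.d_hi,
            "E": profile.e,
            "E_dlogdp": profile.e_dlogdp,
            "flag": list(profile.flags),
        }
    ).to_csv(path, index=False)


def read_abundance_table(path) -> AbundanceTable:
    """Read taxa counts: columns d_lo_um, d_hi_um, taxon, reads, status."""
    df = _read_table(path)
    _require_columns(df, ["d_lo_um", "d_hi_um", "taxon", "reads"], path)
    if "status" not in df.columns:
        df = df.assign(status="ok")
    pivot = df.pivot_table(
        index=["d_lo_um", "d_hi_um"], columns="taxon", values="reads", fill_value=0
    ).sort_index()
    status = (
        df.groupby(["d_lo_um", "d_hi_um"])["status"].first().reindex(pivot.index)
    )
    from .bins import SizeBin

    grid = SizeBinGrid(tuple(SizeBin(lo, hi) for lo, hi in pivot.index))
    return AbundanceTable(
        bins=grid,
        taxa=tuple(pivot.columns),
        counts=pivot.to_numpy().astype(np.int64),
        status=tuple(status),
    )


def write_abundance_table(table: AbundanceTable, path) -> None:
    rows = []
    for i, b in enumerate(table.bins):
        for j, taxon in enumerate(table.taxa):
            rows.append(
                dict(
                    d_lo_um=b.d_lo,
                    d_hi_um=b.d_hi,
                    taxon=taxon,
                    reads=int(table.counts[i, j]),
                    status=table.status[i],
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracer_series(path, background: float = 0.0):
    """Read a tracer CSV (columns t_h, conc) into a TracerSeries."""
    from .aer import TracerSeries

    df = _read_table(path)
    _require_columns(df, ["t_h", "conc"], path)
    return TracerSeries(
        t_h=df["t_h"].to_numpy(dtype=float),
        conc=df["conc"].to_numpy(dtype=float),
        background=background,
    )


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs.

    ``concentrations`` is the path of a concentration CSV holding all four
    location × state combinations for each analyte.  ``k_source`` is
    "cubic", "settling", or the path of a k CSV.
    """

    concentrations: str
    room: RoomParams
    k_source: str = "cubic"
    taxa_counts: str | None = None
    taxa_counts_outdoor: str | None = None
    groups: dict | None = None
    outdir: str | None = None
    staph_in_oral: bool = False
    pooled_group_fractions: bool = True
    clamp_negative: bool = True
    cell_mass_fg: float = 655.0
    room_height_m: float = 3.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        room = RoomParams(**raw.pop("room"))
        groups = raw.pop("groups", None)
        if groups is not None:
            groups = {
                name: TaxaGroup(name=name, members=tuple(members))
                for name, members in groups.items()
            }
        return cls(room=room, groups=groups, **raw)


def _resolve_k(config: PipelineConfig, grid: SizeBinGrid) -> BinLossRates:
    if config.k_source == "cubic":
        return loss_rates_for_grid(grid, CubicDepositionModel())
    if config.k_source == "settling":
        return loss_rates_for_grid(grid, SettlingModel(room_height_m=config.room_height_m))
    k = read_loss_rates(config.k_source)
    return k


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full emission-rate analysis on one conforming dataset.

    Per analyte: infiltration factors from the vacant tables, inversion of
    the occupied tables for per-person emission rates, occupied/vacant
    ratios.  If taxa counts are supplied: group abundances, apportioned
    group emissions and indoor/outdoor enrichment.  Bacterial mass ppm
    fractions are computed when both mass and bacterial profiles exist.
    Writes CSVs under ``config.outdir`` when set; always returns the
    results as a dict.
    """
    profiles = read_concentration_table(config.concentrations)
    analytes = sorted({key[0] for key in profiles})
    report: dict = {"emissions": {}, "f": {}, "occ_vac_ratio": {}, "diagnostics": []}

    grid = None
    for analyte in analytes:
        needed = {
            (analyte, "indoor", "vacant"),
            (analyte, "outdoor", "vacant"),
            (analyte, "indoor", "occupied"),
            (analyte, "outdoor", "occupied"),
        }
        missing = needed - set(profiles)
        if missing:
            raise ValueError(
                f"cannot estimate emissions for {analyte!r}: missing tables "
                f"{sorted(missing)} (vacant tables are required to estimate "
                "infiltration factors f)"
            )
        grid = profiles[(analyte, "indoor", "occupied")].bins
        k = _resolve_k(config, grid)
        f = infiltration_factors(
            profiles[(analyte, "indoor", "vacant")], profiles[(analyte, "outdoor", "vacant")]
        )
        emission = invert_emission(
            profiles[(analyte, "indoor", "occupied")],
            profiles[(analyte, "outdoor", "occupied")],
            f,
            config.room,
            k,
            clamp_negative=config.clamp_negative,
        )
        report["f"][analyte] = f
        report["emissions"][analyte] = emission
        report["occ_vac_ratio"][analyte] = occupied_vacant_ratio(
            profiles[(analyte, "indoor", "occupied")], profiles[(analyte, "indoor", "vacant")]
        )
        report["diagnostics"].append(
            f"{analyte}: f={np.array2string(f.f, precision=3)} "
            f"k={np.array2string(k.k, precision=2)} flags={emission.flags}"
        )

    if (
        "mass" in report["emissions"]
        and "bacterial_genomes" in report["emissions"]
    ):
        mass_occ = profiles[("mass", "indoor", "occupied")].conc
        bact_occ = profiles[("bacterial_genomes", "indoor", "occupied")].conc
        bact_mass = bacterial_mass_concentration(
            bact_occ, MassFractionConfig(cell_mass_fg=config.cell_mass_fg)
        )
        report["mass_fraction"] = ppm_fraction(bact_mass, mass_occ)

    if config.taxa_counts is not None and "bacterial_genomes" in report["emissions"]:
        table = read_abundance_table(config.taxa_counts)
        groups = config.groups or default_groups(staph_in_oral=config.staph_in_oral)
        report["taxa"] = {}
        outdoor_table = (
            read_abundance_table(config.taxa_counts_outdoor)
            if config.taxa_counts_outdoor
            else None
        )
        for name, group in groups.items():
            ab = group_abundance(table, group, pooled=config.pooled_group_fractions)
            ge = apportion_emissions(
                report["emissions"]["bacterial_genomes"], ab["per_bin"], group
            )
            entry = {"abundance": ab, "emissions": ge}
            if outdoor_table is not None:
                ab_out = group_abundance(
                    outdoor_table, group, pooled=config.pooled_group_fractions
                )
                entry["outdoor_abundance"] = ab_out
                entry["enrichment"] = enrichment_factor(ab["overall"], ab_out["overall"])
            report["taxa"][name] = entry

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for analyte, emission in report["emissions"].items():
            write_emission_profile(emission, outdir / f"emissions_{analyte}.csv")
        if "taxa" in report:
            rows = []
            for name, entry in report["taxa"].items():
                ge = entry["emissions"]
                for b, e, pct, st in zip(
                    ge.bins, ge.e_group, ge.pct_of_total, ge.status
                ):
                    rows.append(
                        dict(
                            group=name,
                            d_lo_um=b.d_lo,
                            d_hi_um=b.d_hi,
                            E_group=e,
                            pct_of_total=pct,
                            status=st,
                        )
                    )
            pd.DataFrame(rows).to_csv(outdir / "taxa_group_emissions.csv", index=False)
        if "mass_fraction" in report:
            mf = report["mass_fraction"]
            pd.DataFrame(
                {
                    "d_lo_um": grid.d_lo,
                    "d_hi_um": grid.d_hi,
                    "ppm": mf["per_bin_ppm"],
                }
            ).to_csv(outdir / "bacterial_mass_ppm.csv", index=False)
        for line in report["diagnostics"]:
            log.info(line)
    return report


def write_observations(obs, outdir) -> dict:
    """Write a SimulatedObservations bundle as the CSVs the pipeline reads.

    Returns the mapping of logical names to file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    conc_path = outdir / "concentrations.csv"
    write_concentration_table(obs.concentrations, conc_path)
    paths["concentrations"] = str(conc_path)
    taxa_in = outdir / "taxa_indoor.csv"
    taxa_out = outdir / "taxa_outdoor.csv"
    write_abundance_table(obs.taxa_indoor, taxa_in)
    write_abundance_table(obs.taxa_outdoor, taxa_out)
    paths["taxa_counts"] = str(taxa_in)
    paths["taxa_counts_outdoor"] = str(taxa_out)
    for i, series in enumerate(obs.tracer_series):
        p = outdir / f"tracer_{i}.csv"
        pd.DataFrame({"t_h": series.t_h, "conc": series.conc}).to_csv(p, index=False)
        paths[f"tracer_{i}"] = str(p)
    return paths
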