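"""qPCR absolute quantification with rRNA-operon copy-number correction.

A qPCR assay against a multi-copy marker gene (bacterial 16S, fungal 18S)
counts *gene* copies, not organisms.  Calibration uses genomic DNA of a
calibrant species with a known operon count, so converting a cycle
threshold (Ct) to organism genomes takes two corrections:

1. the standard curve maps Ct → calibrant-genome equivalents; multiplying
   by the calibrant's operons/genome gives marker-gene copies;
2. dividing gene copies by the operons/genome assumed for the sampled
   community gives community genomes.

For bacteria the community average is taken as 4 operons/genome
(calibrant *B. atrophaeus*: 10).  Fungal 18S copy numbers are too variable
and too poorly catalogued for step 2, so fungal results stay expressed as
*calibrant-equivalent genomes* (calibrant *A. fumigatus*: 55
operons/genome) and are never converted to true genomes.

Also here: scaling genome counts from a filter aliquot to an airborne
concentration via the sampled air volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "OperonConfig",
    "StandardCurve",
    "FilterSample",
    "BACTERIAL_OPERONS",
    "FUNGAL_OPERONS",
    "fit_standard_curve",
    "quantify_genomes",
    "air_concentration",
    "BelowDetection",
]


class BelowDetection:
    """Sentinel result for samples with no reliable amplification.

    Deliberately not zero: absence of amplification bounds the quantity
    below the assay's detection limit, it does not measure it.
    """

    def __repr__(self) -> str:  # pragma: no cover
        return "<below detection>"


@dataclass(frozen=True)
class OperonConfig:
    """rRNA operons per genome for the calibrant and the sampled community."""

    calibrant_operons: int
    assumed_sample_operons: int

    def __post_init__(self) -> None:
        for name, v in (
            ("calibrant_operons", self.calibrant_operons),
            ("assumed_sample_operons", self.assumed_sample_operons),
        ):
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")


#: Bacterial assay: calibrated on B. atrophaeus (10 operons/genome),
#: community average assumed 4 operons/genome.
BACTERIAL_OPERONS = OperonConfig(calibrant_operons=10, assumed_sample_operons=4)
#: Fungal assay: calibrated on A. fumigatus (55 operons/genome); results
#: remain A. fumigatus-equivalent genomes, so sample operons = calibrant.
FUNGAL_OPERONS = OperonConfig(calibrant_operons=55, assumed_sample_operons=55)


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration Ct = slope·log10(calibrant genomes) + intercept."""

    slope: float
    intercept: float
    calibrant: str = ""
    log10_range: tuple[float, float] | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(
                f"standard-curve slope must be negative (more template, earlier Ct); got {self.slope}"
            )

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, 10^(−1/slope) − 1 (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def ct_to_log10_copies(self, ct: float) -> float:
        return (ct - self.intercept) / self.slope

    def log10_copies_to_ct(self, log10_copies: float) -> float:
        return self.slope * log10_copies + self.intercept


def fit_standard_curve(
    log10_copies, ct, calibrant: str = ""
) -> StandardCurve:
    """Least-squares standard curve from a dilution series.

    Requires ≥ 3 points spanning ≥ 2 decades of template quantity.
    """
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("log10_copies and ct must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 dilution points, got {len(x)}")
    if len(np.unique(x)) < 2 or x.max() - x.min() < 2.0:
        raise ValueError("dilution series must span at least 2 decades")
    res = stats.linregress(x, y)
    return StandardCurve(
        slope=res.slope,
        intercept=res.intercept,
        calibrant=calibrant,
        log10_range=(float(x.min()), float(x.max())),
        r_squared=res.rvalue**2,
    )


def quantify_genomes(
    ct_replicates,
    curve: StandardCurve,
    operons: OperonConfig,
    max_failed: int = 1,
):
    """Convert Ct replicates to organism genomes (or calibrant equivalents).

    Replicates are averaged (arithmetic mean of Ct) before conversion;
    NaN replicates count as failed amplification, and more than
    ``max_failed`` failures yields :class:`BelowDetection` rather than a
    number.  The chain is

        mean Ct → calibrant-genome equivalents (standard curve)
                → gene copies (× calibrant operons)
                → genomes (÷ assumed sample operons).

    With ``operons.assumed_sample_operons == operons.calibrant_operons``
    (the fungal configuration) the result is calibrant-equivalent genomes.
    """
    cts = np.asarray(ct_replicates, dtype=float)
    failed = np.isnan(cts)
    if failed.sum() > max_failed:
        return BelowDetection()
    mean_ct = float(cts[~failed].mean())
    log10_equiv = curve.ct_to_log10_copies(mean_ct)
    if curve.log10_range is not None and not (
        curve.log10_range[0] - 0.5 <= log10_equiv <= curve.log10_range[1] + 0.5
    ):
        import logging

        logging.getLogger(__name__).warning(
            "Ct %.2f maps to 10^%.2f calibrant genomes, outside the calibrated "
            "range 10^%.1f-10^%.1f; extrapolating",
            mean_ct, log10_equiv, *curve.log10_range,
        )
    calibrant_equivalents = 10.0 ** log10_equiv
    gene_copies = calibrant_equivalents * operons.calibrant_operons
    return gene_copies / operons.assumed_sample_operons


def gene_copies_to_genomes(gene_copies: float, operons: OperonConfig) -> float:
    """Marker-gene copies → organism genomes via the assumed operon count."""
    return gene_copies / operons.assumed_sample_operons


@dataclass(frozen=True)
class FilterSample:
    """Air-filter sample geometry: aliquot analysed, flow and duration."""

    aliquot_fraction: float = 0.25
    flow_lpm: float = 28.3
    duration_h: float = 22.2

    def __post_init__(self) -> None:
        if not 0 < self.aliquot_fraction <= 1:
            raise ValueError("aliquot fraction must be in (0, 1]")
        if self.flow_lpm <= 0:
            raise ValueError("sampling flow must be positive")
        if self.duration_h <= 0:
            raise ValueError("sampling duration must be positive")

    @property
    def air_volume_m3(self) -> float:
        """Total air volume drawn through the filter (m³)."""
        return self.flow_lpm * self.duration_h * 60.0 / 1000.0


def air_concentration(genomes_in_aliquot: float, sample: FilterSample):
    """Airborne concentration (copies/m³) from an aliquot's genome count.

    Scales the aliquot up to the whole filter, then divides by the sampled
    air volume.  A :class:`BelowDetection` input propagates unchanged.
    """
    if isinstance(genomes_in_aliquot, BelowDetection):
        return genomes_in_aliquot
    copies_on_filter = genomes_in_aliquot / sample.aliquot_fraction
    return copies_on_filter / sample.air_volume_m3
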