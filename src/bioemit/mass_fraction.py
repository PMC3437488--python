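"""Bacterial contribution to airborne particulate mass, per size bin.

Genome concentrations convert to bacterial mass concentrations via an
assumed per-cell mass (default 655 fg per bacterium, a literature average
for airborne bacteria); dividing by the co-measured particulate-matter mass
gives the bacterial mass fraction in parts per million.  The overall
fraction pools mass across bins (Σ bacterial / Σ PM), so bins with more
aerosol mass weigh more, as they should for a mass fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MassFractionConfig", "bacterial_mass_concentration", "ppm_fraction"]

FG_PER_UG = 1e9


@dataclass(frozen=True)
class MassFractionConfig:
    """Per-cell bacterial mass in femtograms."""

    cell_mass_fg: float = 655.0

    def __post_init__(self) -> None:
        if self.cell_mass_fg <= 0:
            raise ValueError("cell mass must be positive")


def bacterial_mass_concentration(
    genome_conc_per_m3, cfg: MassFractionConfig | None = None
):
    """Genome copies/m³ → bacterial mass μg/m³ (one genome ≡ one cell)."""
    if cfg is None:
        cfg = MassFractionConfig()
    conc = np.asarray(genome_conc_per_m3, dtype=float)
    if np.any(conc < 0):
        raise ValueError("genome concentrations must be non-negative")
    mass = conc * cfg.cell_mass_fg / FG_PER_UG
    return float(mass) if np.isscalar(genome_conc_per_m3) else mass


def ppm_fraction(bacterial_mass_ug_m3, pm_mass_ug_m3) -> dict:
    """Bacterial share of particulate mass, per bin and pooled, in ppm.

    Bins with zero PM mass are flagged and excluded from the pooled
    overall value (which is Σ bacterial / Σ PM over reporting bins, not a
    mean of per-bin ratios).
    """
    bact = np.atleast_1d(np.asarray(bacterial_mass_ug_m3, dtype=float))
    pm = np.atleast_1d(np.asarray(pm_mass_ug_m3, dtype=float))
    if bact.shape != pm.shape:
        raise ValueError("bacterial and PM mass arrays must have equal shape")
    ok = pm > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        per_bin = np.where(ok, 1e6 * bact / np.where(ok, pm, 1.0), np.nan)
    overall = 1e6 * bact[ok].sum() / pm[ok].sum() if ok.any() else np.nan
    return {
        "per_bin_ppm": per_bin,
        "overall_ppm": float(overall),
        "excluded_bins": tuple(np.nonzero(~ok)[0].tolist()),
    }
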