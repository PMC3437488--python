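"""Steady-state well-mixed-room material balance and its inversion.

The model: a single well-mixed room of volume V (m³) ventilated at Q = AER·V
(m³/h), holding N occupants.  At steady state the time-averaged indoor
concentration of an airborne analyte in one size bin is the sum of an
infiltrated outdoor contribution and an indoor occupant-emission
contribution:

    C = f · C_out + N · E / (Q + k · V)

where f is the indoor/outdoor ratio without indoor sources (the
infiltration factor, measured during vacant periods), E the per-person
emission rate, and k the size-specific deposition loss-rate coefficient
(1/h).  Ventilation and surface deposition are the only removal pathways.

Solving for E bin by bin,

    E = (C − f · C_out) · (Q + k · V) / N

is an exact algebraic inverse; a negative indoor excess (C < f·C_out,
possible under measurement noise) is clamped to zero and flagged, with the
raw value kept for diagnostics.

Assumptions: well-mixed air, steady state over the averaging period, f
unchanged between vacant and occupied periods, and no coagulation or
size-shifting between bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .bins import SizeBinGrid
from .deposition import BinLossRates

__all__ = [
    "Analyte",
    "RoomParams",
    "ConcentrationProfile",
    "InfiltrationFactors",
    "EmissionProfile",
    "infiltration_factors",
    "steady_state_concentration",
    "invert_emission",
    "normalize_dlogdp",
    "denormalize_dlogdp",
    "occupied_vacant_ratio",
]

Analyte = Literal["mass", "bacterial_genomes", "fungal_equiv_genomes"]

#: concentration units per analyte; emissions are these per hour per person
ANALYTE_UNITS = {
    "mass": "ug/m3",
    "bacterial_genomes": "copies/m3",
    "fungal_equiv_genomes": "equivalent copies/m3",
}

FLAG_OK = "ok"
FLAG_NEGATIVE_CLAMPED = "negative_clamped"
FLAG_BELOW_DETECTION = "below_detection"
FLAG_UNDEFINED = "undefined"


@dataclass(frozen=True)
class RoomParams:
    """Room volume (m³), air-exchange rate (1/h) and mean occupancy."""

    volume_m3: float
    aer_per_h: float
    occupants: float

    def __post_init__(self) -> None:
        if self.volume_m3 <= 0:
            raise ValueError("room volume must be positive")
        if self.aer_per_h < 0:
            raise ValueError("air-exchange rate must be non-negative")
        if self.occupants < 0:
            raise ValueError("occupancy must be non-negative")

    @property
    def ventilation_m3_h(self) -> float:
        """Volumetric ventilation rate Q = AER·V (m³/h)."""
        return self.aer_per_h * self.volume_m3


def _as_bin_array(values, n: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have one value per bin ({n}), got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class ConcentrationProfile:
    """Per-bin time-averaged concentration for one analyte/location/state."""

    analyte: str
    location: Literal["indoor", "outdoor"]
    state: Literal["occupied", "vacant"]
    bins: SizeBinGrid
    conc: np.ndarray
    units: str | None = None

    def __post_init__(self) -> None:
        arr = _as_bin_array(self.conc, len(self.bins), "conc")
        if np.any(arr < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "conc", arr)
        if self.units is None:
            object.__setattr__(self, "units", ANALYTE_UNITS.get(self.analyte, ""))

    def scaled(self, factor: float) -> "ConcentrationProfile":
        return replace(self, conc=self.conc * factor)


@dataclass(frozen=True)
class InfiltrationFactors:
    """Per-bin indoor/outdoor ratio in the absence of indoor sources."""

    bins: SizeBinGrid
    f: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = _as_bin_array(self.f, len(self.bins), "f")
        object.__setattr__(self, "f", arr)
        if not self.flags:
            object.__setattr__(self, "flags", tuple(FLAG_OK for _ in range(len(self.bins))))
        valid = arr[np.array(self.flags) == FLAG_OK]
        if np.any(valid < 0):
            raise ValueError("infiltration factors must be non-negative")

    @property
    def ok(self) -> np.ndarray:
        return np.array(self.flags) == FLAG_OK


@dataclass(frozen=True)
class EmissionProfile:
    """Per-bin per-person emission rates with size-density normalisation.

    ``e`` is the emission rate per bin (units/h/person); ``e_dlogdp`` its
    ΔE/Δlog dₚ density form; ``raw_e`` keeps pre-clamp values for
    diagnostics when the inversion produced a negative excess.
    """

    bins: SizeBinGrid
    e: np.ndarray
    flags: tuple[str, ...] = ()
    raw_e: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        arr = _as_bin_array(self.e, len(self.bins), "e")
        object.__setattr__(self, "e", arr)
        if not self.flags:
            object.__setattr__(self, "flags", tuple(FLAG_OK for _ in range(len(self.bins))))
        if len(self.flags) != len(self.bins):
            raise ValueError("one flag per bin required")
        if self.raw_e is not None:
            object.__setattr__(self, "raw_e", _as_bin_array(self.raw_e, len(self.bins), "raw_e"))

    @property
    def e_dlogdp(self) -> np.ndarray:
        """ΔE/Δlog10 dₚ; multiplying back by the bin log-widths is exact."""
        return normalize_dlogdp(self.e, self.bins)

    @property
    def ok(self) -> np.ndarray:
        return np.isin(np.array(self.flags), [FLAG_OK, FLAG_NEGATIVE_CLAMPED])

    def total(self) -> float:
        """Sum of E over bins with data (ok or clamped)."""
        return float(self.e[self.ok].sum())


def _check_same_grid(a, b, what: str) -> None:
    if len(a.bins) != len(b.bins) or any(
        x.d_lo != y.d_lo or x.d_hi != y.d_hi for x, y in zip(a.bins, b.bins)
    ):
        raise ValueError(f"{what}: size-bin grids do not match")


def infiltration_factors(
    indoor_vacant: ConcentrationProfile, outdoor_vacant: ConcentrationProfile
) -> InfiltrationFactors:
    """Per-bin f = C_in/C_out from vacant-period measurements.

    Bins with zero outdoor concentration get flag ``undefined`` and are
    excluded downstream.
    """
    _check_same_grid(indoor_vacant, outdoor_vacant, "infiltration_factors")
    if indoor_vacant.analyte != outdoor_vacant.analyte:
        raise ValueError("infiltration_factors: analytes differ")
    for p, loc in ((indoor_vacant, "indoor"), (outdoor_vacant, "outdoor")):
        if p.state != "vacant":
            raise ValueError(f"{loc} profile must be from the vacant state, got {p.state!r}")
    out = outdoor_vacant.conc
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(out > 0, indoor_vacant.conc / np.where(out > 0, out, 1.0), np.nan)
    flags = tuple(FLAG_OK if o > 0 else FLAG_UNDEFINED for o in out)
    return InfiltrationFactors(bins=indoor_vacant.bins, f=f, flags=flags)


def steady_state_concentration(
    f: InfiltrationFactors,
    outdoor: ConcentrationProfile,
    emission: EmissionProfile,
    room: RoomParams,
    k: BinLossRates,
) -> ConcentrationProfile:
    """Forward model: C = f·C_out + N·E/(Q + k·V) per bin."""
    _check_same_grid(f, outdoor, "steady_state_concentration")
    _check_same_grid(f, emission, "steady_state_concentration")
    _check_same_grid(f, k, "steady_state_concentration")
    removal = room.ventilation_m3_h + k.k * room.volume_m3  # m3/h
    if np.any((removal == 0) & (emission.e > 0)):
        raise ZeroDivisionError(
            "total removal rate Q + k·V is zero with nonzero emissions: "
            "steady state does not exist"
        )
    source = np.divide(
        room.occupants * emission.e,
        removal,
        out=np.zeros_like(emission.e),
        where=removal > 0,
    )
    conc = f.f * outdoor.conc + source
    return ConcentrationProfile(
        analyte=outdoor.analyte,
        location="indoor",
        state="occupied",
        bins=outdoor.bins,
        conc=conc,
        units=outdoor.units,
    )


def invert_emission(
    indoor_occupied: ConcentrationProfile,
    outdoor_occupied: ConcentrationProfile,
    f: InfiltrationFactors,
    room: RoomParams,
    k: BinLossRates,
    clamp_negative: bool = True,
) -> EmissionProfile:
    """Solve the material balance for per-person emission rates.

    E = (C − f·C_out)·(Q + k·V)/N per bin.  Bins with undefined f propagate
    as undefined; a negative indoor excess is clamped to zero with flag
    ``negative_clamped`` (raw value retained) unless ``clamp_negative`` is
    False.
    """
    _check_same_grid(indoor_occupied, outdoor_occupied, "invert_emission")
    _check_same_grid(indoor_occupied, f, "invert_emission")
    _check_same_grid(indoor_occupied, k, "invert_emission")
    if room.occupants <= 0:
        raise ValueError(
            "emission rates are per person: occupancy N must be positive to invert"
        )
    removal = room.ventilation_m3_h + k.k * room.volume_m3
    excess = indoor_occupied.conc - f.f * outdoor_occupied.conc
    raw = excess * removal / room.occupants
    flags = []
    e = raw.copy()
    for i in range(len(raw)):
        if f.flags[i] != FLAG_OK:
            flags.append(FLAG_UNDEFINED)
            e[i] = np.nan
        elif raw[i] < 0 and clamp_negative:
            flags.append(FLAG_NEGATIVE_CLAMPED)
            e[i] = 0.0
        else:
            flags.append(FLAG_OK)
    units = (indoor_occupied.units or "").replace("/m3", "") + "/h/person"
    return EmissionProfile(
        bins=indoor_occupied.bins, e=e, flags=tuple(flags), raw_e=raw, units=units
    )


def normalize_dlogdp(values, bins: SizeBinGrid) -> np.ndarray:
    """Per-bin value divided by the decadal-log bin width, Δvalue/Δlog10 dₚ."""
    vals = _as_bin_array(values, len(bins), "values")
    widths = bins.dlog10
    if np.any(widths <= 0):
        raise ValueError("zero-width bin in normalisation")
    return vals / widths


def denormalize_dlogdp(density, bins: SizeBinGrid) -> np.ndarray:
    """Inverse of :func:`normalize_dlogdp`; exact reconstruction."""
    vals = _as_bin_array(density, len(bins), "density")
    return vals * bins.dlog10


def occupied_vacant_ratio(
    occupied: ConcentrationProfile, vacant: ConcentrationProfile
) -> dict:
    """Occupancy-associated concentration increase, per bin and summarised.

    Returns per-bin ratios plus two across-bin summaries — the mean of
    per-bin ratios and the ratio of bin sums — since either convention is a
    defensible single-number summary of size-resolved data.
    """
    _check_same_grid(occupied, vacant, "occupied_vacant_ratio")
    if occupied.analyte != vacant.analyte:
        raise ValueError("occupied_vacant_ratio: analytes differ")
    v = vacant.conc
    with np.errstate(divide="ignore", invalid="ignore"):
        per_bin = np.where(v > 0, occupied.conc / np.where(v > 0, v, 1.0), np.nan)
    ok = v > 0
    return {
        "per_bin": per_bin,
        "flags": tuple(FLAG_OK if b else FLAG_UNDEFINED for b in ok),
        "mean_of_ratios": float(np.nanmean(per_bin[ok])) if ok.any() else np.nan,
        "ratio_of_sums": float(occupied.conc[ok].sum() / v[ok].sum()) if ok.any() else np.nan,
    }
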