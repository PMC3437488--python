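"""Synthetic classroom scenarios with known ground truth.

Generates everything the analysis pipeline consumes — size-binned
indoor/outdoor × occupied/vacant concentration tables for three analytes,
per-bin taxa read counts, qPCR Ct triplicates with a standard curve, and
tracer-decay series — from a fully specified :class:`RoomScenario`, so that
recovery of the known emission rates, infiltration factors, compositions
and air-exchange rate can be tested end to end.

Default parameters emulate a mechanically ventilated university classroom:
90 m³ volume, air-exchange rate 5.5/h, mean occupancy 4.7 persons, the
six-stage impactor grid capped at 20 μm, deposition coefficients from the
cubic loss model, pyrosequencing-scale read depth (~60 reads per bin), and
one indoor size stage whose sequencing library fails.  Measurement noise is
multiplicative lognormal (concentrations are strictly positive and span
decades), taxa counts are multinomial, and Ct noise is additive Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .aer import TracerSeries
from .bins import IMPACTOR_BINS, SizeBinGrid
from .deposition import BinLossRates, CubicDepositionModel, loss_rates_for_grid
from .mass_balance import (
    ConcentrationProfile,
    EmissionProfile,
    InfiltrationFactors,
    RoomParams,
    steady_state_concentration,
)
from .qpcr import BACTERIAL_OPERONS, FilterSample, OperonConfig, StandardCurve
from .taxa import STATUS_FAILED_PCR, STATUS_OK, AbundanceTable

__all__ = [
    "RoomScenario",
    "NoiseModel",
    "SimulatedObservations",
    "generate_scenario",
    "simulate_observations",
    "DEFAULT_TAXA",
]

ANALYTES = ("mass", "bacterial_genomes", "fungal_equiv_genomes")

#: Taxon namespace of the generator: four skin/hair/nostril taxa, three
#: oral-cavity taxa, and common environmental bioaerosol taxa.
DEFAULT_TAXA = (
    "Propionibacterineae",
    "Staphylococcus",
    "Enterobacteriaceae",
    "Corynebacterineae",
    "Pasteurellaceae",
    "Fusobacterium",
    "Veillionella",
    "Sphingomonas",
    "Rhodobacteria",
    "Streptophyta",
    "Acidobacteria",
    "Other",
)

# Indoor occupied per-bin compositions over DEFAULT_TAXA.  Skin-group bin
# fractions follow the observed size dependence of human-microflora
# enrichment (low in submicron bins, ~1/3 in the >9 um stage, pooling to
# ~17%); oral taxa are sparse; the remainder is environmental.
_SKIN_FRAC_INDOOR = np.array([0.13, 0.073, 0.12, 0.18, 0.15, 0.32])
_ORAL_FRAC_INDOOR = np.array([0.0, 0.018, 0.01, 0.0, 0.04, 0.0])
# Outdoor composition: skin taxa at ~4.9% overall, essentially all
# Propionibacterineae; trace oral Veillionella.
_SKIN_FRAC_OUTDOOR = 0.049
_ORAL_FRAC_OUTDOOR = 0.004


def _composition_matrix(skin_frac, oral_frac) -> np.ndarray:
    """Build per-bin probability vectors over DEFAULT_TAXA."""
    skin_frac = np.atleast_1d(np.asarray(skin_frac, dtype=float))
    oral_frac = np.broadcast_to(
        np.atleast_1d(np.asarray(oral_frac, dtype=float)), skin_frac.shape
    )
    n_bins = len(skin_frac)
    comp = np.zeros((n_bins, len(DEFAULT_TAXA)))
    # split skin mass: Propionibacterineae carries half, the rest shared
    comp[:, 0] = skin_frac * 0.5
    comp[:, 1] = skin_frac * 0.25
    comp[:, 2] = skin_frac * 0.10
    comp[:, 3] = skin_frac * 0.15
    comp[:, 4] = oral_frac * 0.4
    comp[:, 5] = oral_frac * 0.2
    comp[:, 6] = oral_frac * 0.4
    env = 1.0 - skin_frac - oral_frac
    comp[:, 7] = env * 0.25
    comp[:, 8] = env * 0.20
    comp[:, 9] = env * 0.20
    comp[:, 10] = env * 0.10
    comp[:, 11] = env * 0.25
    return comp


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes for simulated observations.

    concentration_cv
        coefficient of variation of the multiplicative lognormal noise on
        every measured concentration (default 0.10).
    ct_sd
        additive s.d. of qPCR Ct replicates (default 0.15 cycles).
    read_depth
        sequence reads drawn per size bin (default 60, pyrosequencing
        scale: ~621 reads over 11 size-fractionated libraries).
    tracer_cv
        multiplicative CV on the tracer excess over background (default 0.02).
    """

    concentration_cv: float = 0.10
    ct_sd: float = 0.15
    read_depth: int = 60
    tracer_cv: float = 0.02

    def __post_init__(self) -> None:
        if min(self.concentration_cv, self.ct_sd, self.tracer_cv) < 0 or self.read_depth < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass(frozen=True)
class RoomScenario:
    """Ground truth for one simulated study."""

    room: RoomParams
    bins: SizeBinGrid
    k: BinLossRates
    f_true: InfiltrationFactors
    e_true: dict  # analyte -> EmissionProfile
    outdoor_true: dict  # analyte -> ConcentrationProfile (state "vacant")
    taxa: tuple[str, ...]
    indoor_composition: np.ndarray  # (n_bins, n_taxa) probability rows
    outdoor_composition: np.ndarray
    aer_true_per_h: float
    tracer_background: float
    tracer_initial_excess: float
    failed_indoor_taxa_bins: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        for comp in (self.indoor_composition, self.outdoor_composition):
            if comp.shape != (len(self.bins), len(self.taxa)):
                raise ValueError("composition must be (n_bins, n_taxa)")
            if not np.allclose(comp.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("composition rows must sum to 1")
            if np.any(comp < 0):
                raise ValueError("composition probabilities must be non-negative")

    def expected_indoor_occupied(self, analyte: str) -> ConcentrationProfile:
        """Noise-free steady-state indoor occupied concentration."""
        return steady_state_concentration(
            self.f_true, self.outdoor_true[analyte], self.e_true[analyte], self.room, self.k
        )


# Default outdoor concentrations and per-person emission rates.  Jointly
# they reproduce the study conditions the pipeline is meant to face: mean
# occupied/vacant indoor ratios of ~15 (mass), ~170 (bacterial genomes) and
# ~2.3 (fungal equivalents), a ~12x bacterial increase in the largest stage,
# mass emissions majority >9 um, bacterial emissions peaking at 3-5 um, and
# per-bin bacterial E back-calculated from the published human-microflora
# rows (group E divided by its percent of total).
def _default_outdoor() -> dict[str, np.ndarray]:
    return {
        # outdoor PM mass, ug/m3 per bin (vegetated urban site, modest levels)
        "mass": np.array([2.0, 2.5, 2.0, 1.5, 2.0, 3.0]),
        # outdoor airborne bacterial genomes/m3; low enough that occupancy
        # dominates indoor levels by the observed two orders of magnitude
        "bacterial_genomes": np.array([95.0, 130.0, 210.0, 400.0, 950.0, 2700.0]),
        # outdoor fungal calibrant-equivalent genomes/m3 (spore-size peaks)
        "fungal_equiv_genomes": np.array([2e3, 3e3, 6e3, 5e3, 3e3, 5e3]),
    }


def _default_emissions() -> dict[str, np.ndarray]:
    return {
        # per-person PM mass emissions, ug/h/person, majority >9 um
        "mass": np.array([300.0, 480.0, 760.0, 990.0, 3900.0, 8500.0]),
        # per-person bacterial genome emissions, genomes/h/person, peaking
        # in the 3-5 um range; consistent with a human-microflora subtotal
        # of ~5.4e6 at ~17% of the total
        "bacterial_genomes": np.array([0.46e6, 1.9e6, 5.0e6, 15.0e6, 13.3e6, 1.7e6]),
        # per-person fungal equivalent-genome emissions, largest stage dominant
        "fungal_equiv_genomes": np.array([1.0e5, 1.7e5, 5.7e5, 7.1e5, 4.2e5, 7.8e5]),
    }


def generate_scenario(config: dict | None = None, seed: int = 0) -> RoomScenario:
    """Build a ground-truth scenario; deterministic for a given seed/config.

    ``config`` overrides any of: volume_m3, aer_per_h, occupants, bins
    (edge list), f (per-bin), k (per-bin), outdoor (analyte -> per-bin),
    emissions (analyte -> per-bin), skin_frac_indoor, oral_frac_indoor,
    skin_frac_outdoor, oral_frac_outdoor, tracer_background,
    tracer_initial_excess, failed_indoor_taxa_bins.
    """
    cfg = dict(config or {})

    def pop(name, default):
        return cfg.pop(name, default)

    bins = pop("bins", None)
    grid = SizeBinGrid.from_edges(bins) if bins is not None else IMPACTOR_BINS
    n = len(grid)
    room = RoomParams(
        volume_m3=float(pop("volume_m3", 90.0)),
        aer_per_h=float(pop("aer_per_h", 5.5)),
        occupants=float(pop("occupants", 4.7)),
    )
    k_vals = pop("k", None)
    k = (
        BinLossRates(bins=grid, k_per_h=tuple(float(x) for x in k_vals))
        if k_vals is not None
        else loss_rates_for_grid(grid, CubicDepositionModel())
    )
    f_vals = pop("f", None)
    if f_vals is None:
        # infiltration declines with size: penetration and deposition losses
        # grow with aerodynamic diameter
        f_vals = np.interp(np.arange(n), [0, n - 1], [0.9, 0.2]) if n != 6 else np.array(
            [0.90, 0.80, 0.65, 0.50, 0.35, 0.20]
        )
    f_true = InfiltrationFactors(bins=grid, f=np.asarray(f_vals, dtype=float))

    outdoor_defaults = _default_outdoor()
    emission_defaults = _default_emissions()
    outdoor_cfg = pop("outdoor", {})
    emission_cfg = pop("emissions", {})
    outdoor_true = {}
    e_true = {}
    for analyte in ANALYTES:
        out_vals = np.asarray(
            outdoor_cfg.get(analyte, outdoor_defaults[analyte][:n]), dtype=float
        )
        e_vals = np.asarray(
            emission_cfg.get(analyte, emission_defaults[analyte][:n]), dtype=float
        )
        outdoor_true[analyte] = ConcentrationProfile(
            analyte=analyte, location="outdoor", state="vacant", bins=grid, conc=out_vals
        )
        e_true[analyte] = EmissionProfile(bins=grid, e=e_vals)

    skin_in = pop("skin_frac_indoor", _SKIN_FRAC_INDOOR[:n])
    oral_in = pop("oral_frac_indoor", _ORAL_FRAC_INDOOR[:n])
    skin_out = pop("skin_frac_outdoor", _SKIN_FRAC_OUTDOOR)
    oral_out = pop("oral_frac_outdoor", _ORAL_FRAC_OUTDOOR)
    indoor_comp = _composition_matrix(skin_in, oral_in)
    outdoor_comp = _composition_matrix(np.full(n, skin_out), np.full(n, oral_out))

    scenario = RoomScenario(
        room=room,
        bins=grid,
        k=k,
        f_true=f_true,
        e_true=e_true,
        outdoor_true=outdoor_true,
        taxa=DEFAULT_TAXA,
        indoor_composition=indoor_comp,
        outdoor_composition=outdoor_comp,
        aer_true_per_h=float(pop("aer_true_per_h", room.aer_per_h)),
        tracer_background=float(pop("tracer_background", 400.0)),
        tracer_initial_excess=float(pop("tracer_initial_excess", 1600.0)),
        failed_indoor_taxa_bins=tuple(pop("failed_indoor_taxa_bins", (2,) if n == 6 else ())),
        seed=int(seed),
    )
    if cfg:
        raise ValueError(f"unknown scenario config fields: {sorted(cfg)}")
    return scenario


@dataclass(frozen=True)
class SimulatedObservations:
    """Observed (noisy) tables produced from one scenario realisation."""

    concentrations: dict  # (analyte, location, state) -> ConcentrationProfile
    taxa_indoor: AbundanceTable
    taxa_outdoor: AbundanceTable
    standard_curve: StandardCurve
    ct_triplicates: dict  # (analyte, location, state) -> (n_bins, 3) Ct array
    tracer_series: list  # of TracerSeries
    filter_sample: FilterSample


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-one multiplicative lognormal factors with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def simulate_observations(
    scenario: RoomScenario,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    n_tracer_releases: int = 6,
    operons: OperonConfig = BACTERIAL_OPERONS,
) -> SimulatedObservations:
    """Draw one noisy realisation of all study observations.

    Occupied indoor concentrations are drawn around the steady-state
    forward model; vacant indoor around f × outdoor; outdoor profiles are
    shared between states up to noise.  All randomness flows from ``seed``
    (default: the scenario's own seed), so realisations are reproducible.
    """
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    grid = scenario.bins
    n = len(grid)

    concentrations = {}
    for analyte in ANALYTES:
        outdoor = scenario.outdoor_true[analyte].conc
        truth = {
            ("outdoor", "occupied"): outdoor,
            ("outdoor", "vacant"): outdoor,
            ("indoor", "vacant"): scenario.f_true.f * outdoor,
            ("indoor", "occupied"): scenario.expected_indoor_occupied(analyte).conc,
        }
        for (location, state), mu in truth.items():
            obs = mu * _lognormal_noise(rng, noise.concentration_cv, n)
            concentrations[(analyte, location, state)] = ConcentrationProfile(
                analyte=analyte, location=location, state=state, bins=grid, conc=obs
            )

    def draw_counts(comp: np.ndarray, failed: tuple[int, ...]) -> AbundanceTable:
        counts = np.zeros((n, len(scenario.taxa)), dtype=np.int64)
        status = []
        for i in range(n):
            if i in failed:
                status.append(STATUS_FAILED_PCR)
                continue
            counts[i] = rng.multinomial(noise.read_depth, comp[i])
            status.append(STATUS_OK)
        return AbundanceTable(
            bins=grid, taxa=scenario.taxa, counts=counts, status=tuple(status)
        )

    taxa_indoor = draw_counts(scenario.indoor_composition, scenario.failed_indoor_taxa_bins)
    taxa_outdoor = draw_counts(scenario.outdoor_composition, ())

    # qPCR: an ideal (perfect-efficiency) standard curve; Ct triplicates for
    # the bacterial-genome concentration observations
    # perfect doubling: slope = -1/log10(2) ~ -3.32 cycles per decade
    curve = StandardCurve(
        slope=-1.0 / np.log10(2.0),
        intercept=40.0,
        calibrant="synthetic",
        log10_range=(1.0, 6.0),
    )
    filter_sample = FilterSample()
    ct_triplicates = {}
    for (analyte, location, state), profile in concentrations.items():
        if analyte != "bacterial_genomes":
            continue
        genomes_aliquot = (
            profile.conc * filter_sample.air_volume_m3 * filter_sample.aliquot_fraction
        )
        calibrant_equiv = (
            genomes_aliquot * operons.assumed_sample_operons / operons.calibrant_operons
        )
        with np.errstate(divide="ignore"):
            ideal_ct = curve.log10_copies_to_ct(np.log10(calibrant_equiv))
        cts = ideal_ct[:, None] + rng.normal(0.0, noise.ct_sd, size=(n, 3))
        ct_triplicates[(analyte, location, state)] = cts

    # tracer releases: exponential decay to background, 20 samples / 0.5 h
    t = np.linspace(0.0, 0.5, 20)
    tracer_series = []
    for _ in range(n_tracer_releases):
        excess = scenario.tracer_initial_excess * np.exp(-scenario.aer_true_per_h * t)
        excess = excess * _lognormal_noise(rng, noise.tracer_cv, t.shape)
        tracer_series.append(
            TracerSeries(
                t_h=t,
                conc=scenario.tracer_background + excess,
                background=scenario.tracer_background,
            )
        )

    return SimulatedObservations(
        concentrations=concentrations,
        taxa_indoor=taxa_indoor,
        taxa_outdoor=taxa_outdoor,
        standard_curve=curve,
        ct_triplicates=ct_triplicates,
        tracer_series=tracer_series,
        filter_sample=filter_sample,
    )
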