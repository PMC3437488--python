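"""Taxa apportionment of size-resolved emission rates.

Amplicon sequencing of the same size-fractionated samples that yielded
total genome emission rates gives, per size bin, relative abundances of
bacterial taxa.  Multiplying the total bacterial emission rate in a bin by
a taxa group's relative abundance in that bin apportions the emissions to
that group — e.g. the human skin/hair/nostril microflora or the oral-cavity
microflora — and comparing a group's indoor share to its outdoor share
gives an enrichment factor for occupancy-associated taxa.

Bins where PCR failed or no member taxon was detected carry explicit
status flags and are excluded from totals rather than treated as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from .bins import SizeBinGrid
from .mass_balance import EmissionProfile

__all__ = [
    "AbundanceTable",
    "TaxaGroup",
    "GroupEmissionProfile",
    "SKIN_GROUP",
    "ORAL_GROUP",
    "default_groups",
    "relative_abundances",
    "group_abundance",
    "apportion_emissions",
    "enrichment_factor",
]

log = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_FAILED_PCR = "failed_pcr"
STATUS_NOT_DETECTED = "not_detected"


@dataclass(frozen=True)
class AbundanceTable:
    """Per-bin, per-taxon sequence read counts.

    ``counts`` has shape (n_bins, n_taxa); ``status`` marks bins whose
    library failed (no data, as opposed to zero reads for one taxon).
    """

    bins: SizeBinGrid
    taxa: tuple[str, ...]
    counts: np.ndarray
    status: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (len(self.bins), len(self.taxa)):
            raise ValueError(
                f"counts must be (n_bins={len(self.bins)}, n_taxa={len(self.taxa)}), got {arr.shape}"
            )
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            if np.any(arr != np.round(arr)) or np.any(arr < 0):
                raise ValueError("read counts must be non-negative integers")
            arr = arr.astype(np.int64)
        object.__setattr__(self, "counts", arr)
        if not self.status:
            object.__setattr__(
                self, "status", tuple(STATUS_OK for _ in range(len(self.bins)))
            )
        if len(self.status) != len(self.bins):
            raise ValueError("one status per bin required")

    @property
    def ok(self) -> np.ndarray:
        return np.array(self.status) == STATUS_OK

    def bin_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class TaxaGroup:
    """A named set of taxon labels, e.g. the skin-associated microflora."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"taxa group {self.name!r} has no members")

    def indices(self, taxa: tuple[str, ...]) -> np.ndarray:
        present = [t for t in self.members if t in taxa]
        missing = [t for t in self.members if t not in taxa]
        if missing:
            log.warning(
                "group %r members not in table: %s", self.name, ", ".join(missing)
            )
        return np.array([taxa.index(t) for t in present], dtype=int)


#: Taxa uniquely associated with human skin, hair and nostrils.
SKIN_GROUP = TaxaGroup(
    name="skin_hair_nostrils",
    members=(
        "Propionibacterineae",
        "Staphylococcus",
        "Enterobacteriaceae",
        "Corynebacterineae",
    ),
)

#: Taxa characteristic of the human oral cavity.  Staphylococcus has both
#: skin and oral sources; by default it sits in the skin group only (see
#: :func:`default_groups`).
ORAL_GROUP = TaxaGroup(
    name="oral_cavity",
    members=("Pasteurellaceae", "Fusobacterium", "Veillionella"),
)


def default_groups(staph_in_oral: bool = False) -> dict[str, TaxaGroup]:
    """Default human-microflora group definitions.

    ``staph_in_oral=True`` duplicates Staphylococcus into the oral group,
    reflecting its dual skin/oral-cavity provenance.
    """
    oral = ORAL_GROUP
    if staph_in_oral:
        oral = TaxaGroup(name=oral.name, members=oral.members + ("Staphylococcus",))
    return {SKIN_GROUP.name: SKIN_GROUP, oral.name: oral}


def relative_abundances(table: AbundanceTable) -> np.ndarray:
    """Per-bin proportions (rows sum to 1 for ok bins; NaN for failed bins)."""
    totals = table.bin_totals().astype(float)
    ok = table.ok
    if np.any(ok & (totals == 0)):
        bad = [str(b) for b, o, t in zip(table.bins, ok, totals) if o and t == 0]
        raise ValueError(f"bins marked ok but with zero reads: {', '.join(bad)}")
    props = np.full(table.counts.shape, np.nan)
    props[ok] = table.counts[ok] / totals[ok, None]
    return props


def group_abundance(table: AbundanceTable, group: TaxaGroup, pooled: bool = True) -> dict:
    """Group relative abundance per bin and overall.

    Per-bin: sum of member proportions within the bin.  The overall summary
    is read-pooled by default (member reads over total reads across ok
    bins), appropriate when per-bin read depth is low and uneven; the
    unweighted mean of per-bin fractions is also returned.
    """
    idx = group.indices(table.taxa)
    props = relative_abundances(table)
    per_bin = (
        props[:, idx].sum(axis=1) if len(idx) else np.where(table.ok, 0.0, np.nan)
    )
    ok = table.ok
    member_reads = table.counts[:, idx].sum() if len(idx) else 0
    total_reads = table.counts[ok].sum()
    pooled_frac = float(member_reads) / total_reads if total_reads else np.nan
    mean_frac = float(np.nanmean(per_bin[ok])) if ok.any() else np.nan
    return {
        "per_bin": per_bin,
        "pooled": pooled_frac,
        "mean_of_bins": mean_frac,
        "overall": pooled_frac if pooled else mean_frac,
    }


@dataclass(frozen=True)
class GroupEmissionProfile:
    """Per-bin emission rates apportioned to one taxa group."""

    group: TaxaGroup
    bins: SizeBinGrid
    e_group: np.ndarray
    pct_of_total: np.ndarray
    status: tuple[str, ...]

    @property
    def total_e(self) -> float:
        """Sum over bins with data; ND/failed bins contribute nothing."""
        ok = np.array(self.status) == STATUS_OK
        return float(np.nansum(self.e_group[ok]))


def apportion_emissions(
    e_total: EmissionProfile, group_fraction_per_bin, group: TaxaGroup
) -> GroupEmissionProfile:
    """E_group,i = E_total,i × fraction_i, with missing-bin propagation.

    ``group_fraction_per_bin`` may contain NaN for bins without sequence
    data (failed PCR); those bins are carried with status ``failed_pcr``
    and excluded from the group total.
    """
    frac = np.asarray(group_fraction_per_bin, dtype=float)
    if frac.shape != (len(e_total.bins),):
        raise ValueError("one group fraction per bin required")
    finite = np.isfinite(frac)
    if np.any((frac[finite] < 0) | (frac[finite] > 1)):
        raise ValueError("group fractions must lie in [0, 1]")
    e = np.where(finite, e_total.e * frac, np.nan)
    status = tuple(
        STATUS_FAILED_PCR if not fin else (STATUS_NOT_DETECTED if fr == 0 else STATUS_OK)
        for fin, fr in zip(finite, frac)
    )
    return GroupEmissionProfile(
        group=group,
        bins=e_total.bins,
        e_group=e,
        pct_of_total=100.0 * frac,
        status=status,
    )


def enrichment_factor(indoor_fraction: float, outdoor_fraction: float) -> dict:
    """Indoor/outdoor ratio of a group's relative abundance.

    Fractions may be given as proportions or percentages, consistently.
    Zero outdoor abundance makes the ratio undefined; the indoor value is
    still reported.
    """
    if indoor_fraction < 0 or outdoor_fraction < 0:
        raise ValueError("abundance fractions must be non-negative")
    if outdoor_fraction == 0:
        return {"factor": np.nan, "defined": False, "indoor": indoor_fraction}
    return {
        "factor": indoor_fraction / outdoor_fraction,
        "defined": True,
        "indoor": indoor_fraction,
    }
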