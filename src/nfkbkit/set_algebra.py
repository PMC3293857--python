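"""Three-way Venn decomposition and overlap percentages for protein sets."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UndefinedMetricError
from .ppi_io import ProteinSet

# membership patterns in (a, b, c) order: '110' = in a and b, not in c
REGIONS = ("100", "010", "001", "110", "101", "011", "111")


@dataclass(frozen=True)
class VennSummary:
    """Counts (and members) of the 7 regions of a three-set Venn diagram."""

    set_names: tuple[str, str, str]
    region_counts: dict[str, int]
    region_members: dict[str, frozenset[str]]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def set_size(self, index: int) -> int:
        """Size of input set ``index`` (0, 1 or 2) from its four regions."""
        return sum(
            c for patt, c in self.region_counts.items() if patt[index] == "1"
        )


def venn3(a: ProteinSet, b: ProteinSet, c: ProteinSet) -> VennSummary:
    """Partition the union of three sets into the 7 Venn regions."""
    union = a.members | b.members | c.members
    members: dict[str, set[str]] = {patt: set() for patt in REGIONS}
    for x in union:
        patt = f"{int(x in a.members)}{int(x in b.members)}{int(x in c.members)}"
        members[patt].add(x)
    return VennSummary(
        set_names=(a.name, b.name, c.name),
        region_counts={patt: len(m) for patt, m in members.items()},
        region_members={patt: frozenset(m) for patt, m in members.items()},
    )


def overlap_percent(
    a: ProteinSet,
    b: ProteinSet,
    denominator: str = "grand_union",
    grand: ProteinSet | None = None,
    ndigits: int = 1,
) -> float:
    """Percentage of shared elements between two sets.

    ``denominator`` selects the reference size: ``grand_union`` (the union of
    all sets under study, passed as ``grand``), ``pair_union`` (|a or b|) or
    ``smaller_set`` (min(|a|, |b|)). Result is rounded to ``ndigits``
    (default one decimal, matching the reporting convention).
    """
    inter = len(a.members & b.members)
    if denominator == "grand_union":
        if grand is None:
            raise ValueError("grand_union denominator requires the grand set")
        denom = len(grand.members)
    elif denominator == "pair_union":
        denom = len(a.members | b.members)
    elif denominator == "smaller_set":
        denom = min(len(a.members), len(b.members))
    else:
        raise ValueError(f"unknown denominator policy {denominator!r}")
    if denom == 0:
        raise UndefinedMetricError("overlap percentage undefined: zero denominator")
    return round(100.0 * inter / denom, ndigits)
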