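"""Pathway over-representation analysis.

The test is the one-sided hypergeometric upper tail (equivalently Fisher's
exact test for over-representation): given a study set of size ``N`` drawn
from a background of size ``M`` containing ``K`` pathway members, the
p-value is ``P(X >= hits)`` for ``X ~ Hypergeometric(M, K, N)``. Computation
is exact via :func:`scipy.stats.hypergeom.sf`; no normal approximation.

Alongside the p-value, two coverage percentages are reported:

- ``pct_of_set``: 100 * hits / |study set| — how much of the study set the
  pathway explains;
- ``pct_of_pathway``: 100 * hits / |pathway| — how much of the pathway the
  study set covers.

Raw p < alpha is the default significance filter; Benjamini-Hochberg
q-values are always computed and reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ContingencyError, EmptyInputError
from .ppi_io import PathwayAnnotation, ProteinSet

SORT_KEYS = ("p_value", "pct_of_set", "pct_of_pathway")


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested pathway's contingency, coverage and significance."""

    pathway_id: str
    description: str
    pathway_size: int
    hits: int
    set_size: int
    background_size: int
    pct_of_set: float
    pct_of_pathway: float
    p_value: float
    q_value: float | None = None


def test_pathway(
    set_size: int,
    background_size: int,
    pathway_size: int,
    hits: int,
    pathway_id: str = "",
    description: str = "",
) -> EnrichmentRow:
    """Exact one-sided over-representation test from the four counts."""
    if not (0 <= hits <= min(pathway_size, set_size)):
        raise ContingencyError(
            f"hits={hits} inconsistent with set_size={set_size}, "
            f"pathway_size={pathway_size}"
        )
    if pathway_size > background_size or set_size > background_size:
        raise ContingencyError(
            f"pathway_size={pathway_size} / set_size={set_size} exceed "
            f"background_size={background_size}"
        )
    if pathway_size < 1 or set_size < 1:
        raise ContingencyError("pathway_size and set_size must be positive")
    p = float(hypergeom.sf(hits - 1, background_size, pathway_size, set_size))
    return EnrichmentRow(
        pathway_id=pathway_id,
        description=description,
        pathway_size=pathway_size,
        hits=hits,
        set_size=set_size,
        background_size=background_size,
        pct_of_set=100.0 * hits / set_size,
        pct_of_pathway=100.0 * hits / pathway_size,
        p_value=min(p, 1.0),
    )


def profile(
    study_set: ProteinSet,
    annotation: list[PathwayAnnotation],
    background: ProteinSet,
    alpha: float = 0.05,
    sort_key: str = "p_value",
    top: int | None = None,
) -> list[EnrichmentRow]:
    """Over-representation profile of a protein set against a GMT collection.

    Hits are computed on the intersection with the background; study-set
    members outside the background are dropped from the contingency (the
    usual ORA convention). q-values are BH-adjusted over *all* tested
    pathways before the ``p < alpha`` filter is applied. ``sort_key``
    selects the ranking column (descending for coverage percentages,
    ascending for p); ties break by pathway id.
    """
    if not annotation:
        raise EmptyInputError("empty pathway annotation")
    if sort_key not in SORT_KEYS:
        raise ValueError(f"sort_key must be one of {SORT_KEYS}")
    bg = background.members
    eff_set = study_set.members & bg
    if not eff_set:
        raise EmptyInputError(
            f"study set '{study_set.name}' has no member in the background"
        )
    rows = []
    for pw in annotation:
        pw_bg = pw.members & bg
        if not pw_bg:
            continue
        rows.append(
            test_pathway(
                set_size=len(eff_set),
                background_size=len(bg),
                pathway_size=len(pw_bg),
                hits=len(eff_set & pw_bg),
                pathway_id=pw.pathway_id,
                description=pw.description,
            )
        )
    if not rows:
        return []
    _, qvals, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
    rows = [
        EnrichmentRow(**{**r.__dict__, "q_value": float(q)})
        for r, q in zip(rows, qvals)
    ]
    rows = [r for r in rows if r.p_value < alpha]
    if sort_key == "p_value":
        rows.sort(key=lambda r: (r.p_value, r.pathway_id))
    else:
        rows.sort(key=lambda r: (-getattr(r, sort_key), r.pathway_id))
    if top is not None:
        rows = rows[:top]
    return rows


def default_background(annotation: list[PathwayAnnotation]) -> ProteinSet:
    """Union of all pathway members — the fallback ORA background."""
    members: set[str] = set()
    for pw in annotation:
        members |= pw.members
    return ProteinSet(name="gmt_background", members=frozenset(members))


def format_percent(value: float, decimal_comma: bool = False) -> str:
    """Render a coverage percentage to 2 d.p., optionally comma-style."""
    s = f"{value:.2f}"
    return s.replace(".", ",") if decimal_comma else s
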