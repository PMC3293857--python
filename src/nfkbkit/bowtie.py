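"""Bow-tie decomposition and feedback-loop detection.

A transcription-factor signaling system often has a bow-tie shape: many
upstream signals (*fan-in*) converge on a small core of transcription-factor
subunits (the *knob*), which fans out to many transcriptional targets
(*fan-out*). *Feedback* proteins are the targets that also sit inside the
upstream interactome — their genes are regulated by the factor whose
activation they themselves help control.

Classification rules:

- knob membership takes precedence: a knob member that is also a downstream
  target stays in the knob and is listed in ``knob_feedback``;
- ``feedback`` = (upstream nodes ∩ downstream set) minus the knob;
- ``fan_in`` = upstream-only proteins; ``fan_out`` = downstream-only.

The four classes partition the universe (upstream ∪ knob ∪ downstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import EmptyInputError
from .interactome import InteractionNetwork
from .ppi_io import ProteinSet

logger = logging.getLogger(__name__)

DENOMINATOR_POLICIES = ("downstream_checked", "downstream_mapped", "downstream_all")


@dataclass(frozen=True)
class FeedbackReport:
    """Proteins shared by the upstream interactome and the downstream set."""

    feedback_members: tuple[str, ...]
    fraction: float  # percentage of the chosen denominator
    denominator: int
    denominator_policy: str

    @property
    def feedback_count(self) -> int:
        return len(self.feedback_members)


@dataclass(frozen=True)
class BowTieDecomposition:
    knob: frozenset[str]
    fan_in: frozenset[str]
    fan_out: frozenset[str]
    feedback: frozenset[str]
    knob_feedback: frozenset[str]  # knob members that are also downstream
    knob_missing_from_upstream: frozenset[str]

    @property
    def universe(self) -> frozenset[str]:
        return self.knob | self.fan_in | self.fan_out | self.feedback


def feedback_set(
    upstream: InteractionNetwork,
    downstream: ProteinSet,
    denominator_policy: str = "downstream_checked",
    denominators: dict[str, int] | None = None,
) -> FeedbackReport:
    """Intersect the upstream interactome's nodes with the downstream set.

    The feedback *fraction* is reported against an explicit, labeled
    denominator. By default (``downstream_checked``) the denominator is the
    size of the downstream set actually handed in — i.e. the targets that
    were checked against the PPI source. Alternative totals (e.g. all mapped
    protein IDs before PPI filtering) may be supplied via ``denominators``,
    keyed by policy name.
    """
    if not downstream.members:
        raise EmptyInputError("downstream set is empty")
    if denominator_policy not in DENOMINATOR_POLICIES:
        raise ValueError(
            f"denominator_policy must be one of {DENOMINATOR_POLICIES}"
        )
    members = tuple(sorted(upstream.nodes & downstream.members))
    denom = (denominators or {}).get(denominator_policy, len(downstream.members))
    fraction = round(100.0 * len(members) / denom, 1)
    logger.info(
        "feedback: %d members, %.1f%% of %d (%s)",
        len(members),
        fraction,
        denom,
        denominator_policy,
    )
    return FeedbackReport(
        feedback_members=members,
        fraction=fraction,
        denominator=denom,
        denominator_policy=denominator_policy,
    )


def bowtie_classify(
    upstream: InteractionNetwork,
    knob: ProteinSet,
    downstream: ProteinSet,
) -> BowTieDecomposition:
    """Partition upstream/knob/downstream proteins into bow-tie classes."""
    if not knob.members:
        raise EmptyInputError("knob set is empty")
    if not downstream.members:
        raise EmptyInputError("downstream set is empty")
    up = upstream.nodes
    k = knob.members
    down = downstream.members
    missing = k - up
    if missing:
        logger.warning(
            "knob members absent from the upstream interactome: %s",
            ", ".join(sorted(missing)),
        )
    feedback = (up & down) - k
    fan_in = up - down - k
    fan_out = down - up - k
    return BowTieDecomposition(
        knob=frozenset(k),
        fan_in=frozenset(fan_in),
        fan_out=frozenset(fan_out),
        feedback=frozenset(feedback),
        knob_feedback=frozenset(k & down),
        knob_missing_from_upstream=frozenset(missing),
    )
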