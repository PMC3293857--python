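"""Synthetic study generator with exactly-known planted structure.

Every stage of the pipeline can be exercised offline against data whose
ground truth is known by construction:

- a hub-structured (preferential-attachment) PPI graph with independent
  self-loops, emulating the heavy-tailed degree distribution of protein
  interaction databases;
- three seed sets planted region-by-region so a three-way Venn decomposition
  returns requested counts exactly, with a small core (the "knob", standing
  in for the transcription-factor family) placed inside the triple
  intersection;
- a pathway annotation in which designated pathways are enriched in a target
  set at a requested odds ratio (membership odds inside vs outside the
  target), the rest sampled uniformly — a null calibration resource;
- a downstream target set with an exactly planted feedback overlap with the
  upstream interactome, the remaining targets being fresh identifiers.

Default dimensions mirror the NF-kB study the toolkit was built around:
seed sets of 377/210/141 proteins whose union is 622 with a 16-member
triple intersection containing a 5-member knob, and a 384-protein
downstream set sharing 49 proteins with the upstream union.

All sampling is driven by one :class:`numpy.random.Generator` seeded from
``rng_seed``; identical seeds give identical studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .errors import SyntheticSpecError
from .ppi_io import (
    InteractionRecord,
    PathwayAnnotation,
    ProteinSet,
    write_gmt,
    write_protein_set,
)
from .set_algebra import REGIONS

_FRESH_FMT = "SYN{:05d}"  # reserved namespace; never collides with real accessions


@dataclass
class SyntheticSpec:
    """Parameters of a planted synthetic study."""

    n_proteins: int = 2000
    attachment_m: int = 3
    self_loop_rate: float = 0.08
    set_names: tuple[str, str, str] = ("DI", "U", "MC")
    # Venn region counts in REGIONS order (100,010,001,110,101,011,111):
    # sets of 377/210/141, union 622, triple intersection 16.
    region_counts: tuple[int, ...] = (307, 140, 85, 34, 20, 20, 16)
    knob_size: int = 5
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (40, 300)
    planted_odds: dict = field(default_factory=lambda: {"SYNPATH_PLANTED": 8.0})
    downstream_size: int = 384
    planted_feedback: int = 49
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 10:
            raise SyntheticSpecError("n_proteins must be >= 10")
        if not (0.0 <= self.self_loop_rate <= 1.0):
            raise SyntheticSpecError("self_loop_rate must be in [0, 1]")
        if len(self.region_counts) != 7 or any(c < 0 for c in self.region_counts):
            raise SyntheticSpecError("region_counts needs 7 non-negative values")
        if sum(self.region_counts) > self.n_proteins:
            raise SyntheticSpecError(
                f"union of seed sets ({sum(self.region_counts)}) exceeds "
                f"n_proteins ({self.n_proteins})"
            )
        if self.knob_size > self.region_counts[REGIONS.index("111")]:
            raise SyntheticSpecError(
                "knob must fit inside the triple-intersection region"
            )
        if self.planted_feedback > min(
            self.downstream_size, sum(self.region_counts)
        ):
            raise SyntheticSpecError(
                "planted_feedback exceeds downstream size or upstream union"
            )
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_proteins):
            raise SyntheticSpecError("invalid pathway_size_range")
        for pid, odds in self.planted_odds.items():
            if odds <= 0:
                raise SyntheticSpecError(f"odds for {pid!r} must be positive")


@dataclass
class SyntheticStudy:
    """A generated study plus its complete ground truth."""

    spec: SyntheticSpec
    ppi: list[InteractionRecord]
    seed_sets: dict[str, ProteinSet]
    knob: ProteinSet
    pathways: list[PathwayAnnotation]
    planted_pathway_ids: list[str]
    downstream: ProteinSet
    planted_feedback_members: tuple[str, ...]
    truth: dict


def _node_name(i: int) -> str:
    return _FRESH_FMT.format(i)


def generate_ppi(spec: SyntheticSpec, rng: np.random.Generator) -> list[InteractionRecord]:
    """Preferential-attachment PPI edge table with independent self-loops."""
    spec.validate()
    g = nx.barabasi_albert_graph(
        spec.n_proteins, spec.attachment_m, seed=int(rng.integers(2**31))
    )
    records = [
        InteractionRecord.make(_node_name(a), _node_name(b)) for a, b in g.edges
    ]
    loops = rng.random(spec.n_proteins) < spec.self_loop_rate
    for i in np.flatnonzero(loops):
        records.append(InteractionRecord.make(_node_name(int(i)), _node_name(int(i))))
    return sorted(records, key=lambda r: r.pair)


def plant_sets(
    spec: SyntheticSpec, universe: list[str], rng: np.random.Generator
) -> tuple[dict[str, ProteinSet], ProteinSet, dict[str, tuple[str, ...]]]:
    """Construct three seed sets realizing the requested Venn regions.

    Returns the sets, the knob (drawn from the triple intersection), and the
    per-region ground-truth membership.
    """
    spec.validate()
    total = sum(spec.region_counts)
    if total > len(universe):
        raise SyntheticSpecError("universe smaller than requested union")
    chosen = rng.choice(np.array(sorted(universe)), size=total, replace=False)
    region_members: dict[str, tuple[str, ...]] = {}
    pos = 0
    for patt, count in zip(REGIONS, spec.region_counts):
        region_members[patt] = tuple(sorted(map(str, chosen[pos : pos + count])))
        pos += count
    sets: dict[str, set[str]] = {name: set() for name in spec.set_names}
    for patt, members in region_members.items():
        for idx, name in enumerate(spec.set_names):
            if patt[idx] == "1":
                sets[name].update(members)
    knob_members = region_members["111"][: spec.knob_size]
    out = {
        name: ProteinSet(name=name, members=frozenset(m)) for name, m in sets.items()
    }
    knob = ProteinSet(name="knob", members=frozenset(knob_members))
    return out, knob, region_members


def _planted_probs(odds: float, target_n: int, outside_n: int, size: float):
    """Membership probabilities inside/outside the target for a planted pathway.

    Chooses ``p0`` (outside) so that the inside odds are ``odds`` times the
    outside odds and the expected pathway size equals ``size``.
    """

    def p1(p0: float) -> float:
        return odds * p0 / (1.0 + (odds - 1.0) * p0)

    def excess(p0: float) -> float:
        return p1(p0) * target_n + p0 * outside_n - size

    p0 = brentq(excess, 1e-12, 1.0)
    return p1(p0), p0


def plant_annotation(
    spec: SyntheticSpec,
    universe: list[str],
    target: ProteinSet,
    rng: np.random.Generator,
) -> tuple[list[PathwayAnnotation], list[str]]:
    """GMT-style annotation with planted over-represented pathways.

    Null pathways are uniform draws from the universe; planted pathways are
    Bernoulli-sampled with inside-target membership odds equal to the
    requested odds ratio (expected size matching the drawn size).
    """
    spec.validate()
    uni = np.array(sorted(universe))
    target_arr = np.isin(uni, np.array(sorted(target.members)))
    t_n = int(target_arr.sum())
    lo, hi = spec.pathway_size_range
    pathways: list[PathwayAnnotation] = []
    planted_ids = list(spec.planted_odds)
    n_null = max(spec.n_pathways - len(planted_ids), 0)
    for i in range(n_null):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(uni, size=size, replace=False)
        pathways.append(
            PathwayAnnotation(
                f"SYNPATH{i:03d}", "null pathway", frozenset(map(str, members))
            )
        )
    for pid in planted_ids:
        odds = float(spec.planted_odds[pid])
        size = int(rng.integers(lo, hi + 1))
        p_in, p_out = _planted_probs(odds, t_n, len(uni) - t_n, size)
        draw = rng.random(len(uni))
        keep = np.where(target_arr, draw < p_in, draw < p_out)
        members = uni[keep]
        if len(members) == 0:  # pragma: no cover - vanishingly rare
            members = rng.choice(uni, size=max(lo, 1), replace=False)
        pathways.append(
            PathwayAnnotation(
                pid,
                f"planted pathway (odds {odds:g})",
                frozenset(map(str, members)),
            )
        )
    return pathways, planted_ids


def plant_downstream(
    spec: SyntheticSpec, upstream_nodes: frozenset[str], rng: np.random.Generator
) -> tuple[ProteinSet, tuple[str, ...]]:
    """Downstream target set with an exactly planted feedback overlap."""
    spec.validate()
    if spec.planted_feedback > len(upstream_nodes):
        raise SyntheticSpecError("planted_feedback exceeds upstream node count")
    planted = rng.choice(
        np.array(sorted(upstream_nodes)), size=spec.planted_feedback, replace=False
    )
    planted = tuple(sorted(map(str, planted)))
    fresh = [
        _node_name(spec.n_proteins + i)
        for i in range(spec.downstream_size - spec.planted_feedback)
    ]
    members = frozenset(planted) | frozenset(fresh)
    return ProteinSet(name="DG", members=members), planted


def simulate_study(spec: SyntheticSpec | None = None) -> SyntheticStudy:
    """Generate a full planted study: PPI, seed sets, annotation, downstream."""
    spec = spec or SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    ppi = generate_ppi(spec, rng)
    universe = sorted({n for r in ppi for n in r.pair})
    seed_sets, knob, region_members = plant_sets(spec, universe, rng)
    upstream_union = frozenset().union(*(s.members for s in seed_sets.values()))
    target = ProteinSet(name="upstream_union", members=upstream_union)
    pathways, planted_ids = plant_annotation(spec, universe, target, rng)
    downstream, planted_fb = plant_downstream(spec, upstream_union, rng)
    truth = {
        "region_counts": dict(zip(REGIONS, spec.region_counts)),
        "region_members": {k: list(v) for k, v in region_members.items()},
        "knob": sorted(knob.members),
        "planted_pathways": planted_ids,
        "planted_feedback": list(planted_fb),
        "rng_seed": spec.rng_seed,
    }
    return SyntheticStudy(
        spec=spec,
        ppi=ppi,
        seed_sets=seed_sets,
        knob=knob,
        pathways=pathways,
        planted_pathway_ids=planted_ids,
        downstream=downstream,
        planted_feedback_members=planted_fb,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write a study to disk in the pipeline's plain-text input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    edges = outdir / "edges.tsv"
    with open(edges, "w", encoding="utf-8", newline="\n") as fh:
        for rec in study.ppi:
            fh.write(f"{rec.a}\t{rec.b}\n")
    paths["edges"] = edges
    for name, pset in study.seed_sets.items():
        p = outdir / f"set_{name}.txt"
        write_protein_set(pset, p)
        paths[f"set_{name}"] = p
    write_protein_set(study.knob, outdir / "knob.txt")
    paths["knob"] = outdir / "knob.txt"
    write_gmt(study.pathways, outdir / "pathways.gmt")
    paths["gmt"] = outdir / "pathways.gmt"
    write_protein_set(study.downstream, outdir / "downstream.txt")
    paths["downstream"] = outdir / "downstream.txt"
    truth_path = outdir / "truth.json"
    with open(truth_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(study.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["truth"] = truth_path
    return paths
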