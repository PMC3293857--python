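"""Full-study orchestration: one config file in, one report directory out.

``run_study`` rebuilds every interactome named in the config, computes the
topology and centrality tables, the three-way Venn decomposition, the
per-set over-representation profiles, the feedback set and the bow-tie
classification, and writes everything as deterministic plain-text TSV/SIF
files plus a provenance log (input checksums, policy flags, package
version). Re-running on identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .bowtie import bowtie_classify, feedback_set
from .enrichment import default_background, format_percent, profile
from .errors import NfkbKitError, StageError
from .interactome import (
    InteractionNetwork,
    build_direct_interactome,
    build_induced_interactome,
    component_summary,
    core_network,
    union_networks,
)
from .ppi_io import read_edge_table, read_gmt, read_protein_set, write_network
from .set_algebra import REGIONS, overlap_percent, venn3
from .topology import rank_centrality, summarize

logger = logging.getLogger(__name__)


@dataclass
class SeedSpec:
    name: str
    path: str
    rule: str = "induced"  # induced | direct


@dataclass
class StudyConfig:
    """Declarative description of one full study run."""

    ppi: str
    seed_sets: list[SeedSpec]
    output_dir: str
    dialect: str = "sniff"
    knob: str | None = None
    gmt: str | None = None
    downstream: str | None = None
    edge_rule: str = "induced"  # edge policy for direct-rule networks
    overlap_denominator: str = "grand_union"
    alpha: float = 0.05
    sort_key: str = "p_value"
    top: int = 20
    top_central: int = 25
    fraction_denominator: str = "downstream_checked"
    decimal_comma: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        seeds = [SeedSpec(**s) for s in raw.pop("seed_sets")]
        return cls(seed_sets=seeds, **raw)

    def validate(self) -> None:
        missing = [p for p in self._input_paths().values() if not Path(p).exists()]
        if missing:
            raise NfkbKitError(f"missing input files: {missing}")

    def _input_paths(self) -> dict[str, str]:
        paths = {"ppi": self.ppi}
        for s in self.seed_sets:
            paths[f"seed:{s.name}"] = s.path
        for key in ("knob", "gmt", "downstream"):
            val = getattr(self, key)
            if val:
                paths[key] = val
        return paths


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def run_study(config: StudyConfig) -> Path:
    """Execute every stage of a study; returns the report directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "version": __version__,
        "inputs": {k: _sha256(v) for k, v in config._input_paths().items()},
        "flags": {
            "dialect": config.dialect,
            "edge_rule": config.edge_rule,
            "overlap_denominator": config.overlap_denominator,
            "alpha": config.alpha,
            "sort_key": config.sort_key,
            "top": config.top,
            "top_central": config.top_central,
            "fraction_denominator": config.fraction_denominator,
        },
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                result = fn()
                provenance["stages"].setdefault(name, "ok")
                return result
            except (NfkbKitError, ValueError, OSError) as exc:
                raise StageError(name, exc) from exc

        return deco

    @stage("read_inputs")
    def inputs():
        ppi = read_edge_table(config.ppi, dialect=config.dialect)
        seeds = {s.name: read_protein_set(s.path, s.name) for s in config.seed_sets}
        knob = read_protein_set(config.knob, "knob") if config.knob else None
        downstream = (
            read_protein_set(config.downstream, "DG") if config.downstream else None
        )
        return ppi, seeds, knob, downstream

    ppi, seeds, knob, downstream = inputs

    @stage("build_networks")
    def networks():
        nets: dict[str, InteractionNetwork] = {}
        for s in config.seed_sets:
            if s.rule == "direct":
                if knob is None:
                    raise NfkbKitError(
                        f"seed set {s.name}: direct rule needs a knob/core file"
                    )
                nets[s.name] = build_direct_interactome(
                    ppi, knob, name=s.name, edges=config.edge_rule
                )
            else:
                nets[s.name] = build_induced_interactome(ppi, seeds[s.name], name=s.name)
        union = union_networks(list(nets.values()), name="UNION")
        core = core_network(list(nets.values()), name="core")
        return nets, union, core

    nets, union, core = networks
    all_nets = {**nets, "UNION": union, "core": core}
    for name, net in all_nets.items():
        write_network(net, outdir / f"net_{name}.sif", dialect="sif")

    @stage("topology")
    def topo():
        rows = []
        for name, net in all_nets.items():
            if net.n_nodes < 3:
                logger.warning("skipping topology summary for tiny network %s", name)
                continue
            t = summarize(net)
            cs = component_summary(net)
            rows.append(
                [
                    t.name,
                    str(t.n_nodes),
                    str(t.n_interactions),
                    f"{t.avg_neighbors:.1f}",
                    f"{t.density:.3f}",
                    f"{t.centralization:.3f}",
                    str(cs.main_cluster_size),
                    str(cs.main_cluster_edges),
                    str(cs.isolated_count),
                ]
            )
        _write_tsv(
            outdir / "topology_summary.tsv",
            [
                "network",
                "n_proteins",
                "n_interactions",
                "avg_neighbors",
                "density",
                "centralization",
                "main_cluster_size",
                "main_cluster_edges",
                "isolated",
            ],
            rows,
        )
        cent = rank_centrality(union, k=config.top_central)
        _write_tsv(
            outdir / "centrality_UNION.tsv",
            ["rank", "id", "degree", "betweenness"],
            [
                [str(r.rank), r.protein, str(r.degree), f"{r.betweenness:.8f}"]
                for r in cent
            ],
        )

    topo

    @stage("venn")
    def venn():
        names = [s.name for s in config.seed_sets[:3]]
        if len(names) < 3:
            logger.warning("venn stage needs 3 seed sets; skipping")
            provenance["stages"]["venn"] = "skipped: needs 3 seed sets"
            return
        a, b, c = (seeds[n] for n in names)
        summary = venn3(a, b, c)
        _write_tsv(
            outdir / "venn.tsv",
            ["region", "count", "members"],
            [
                [
                    patt,
                    str(summary.region_counts[patt]),
                    ",".join(sorted(summary.region_members[patt])),
                ]
                for patt in REGIONS
            ],
        )

    venn

    @stage("enrichment")
    def enrich():
        if not config.gmt:
            logger.warning("no GMT annotation configured; enrichment skipped")
            provenance["stages"]["enrichment"] = "skipped: no GMT configured"
            return
        annotation = read_gmt(config.gmt)
        background = default_background(annotation)
        targets = dict(seeds)
        if downstream is not None:
            targets["DG"] = downstream
        for name, pset in targets.items():
            rows = profile(
                pset,
                annotation,
                background,
                alpha=config.alpha,
                sort_key=config.sort_key,
                top=config.top,
            )
            _write_tsv(
                outdir / f"enrichment_{name}.tsv",
                [
                    "pathway_id",
                    "description",
                    "total_terms_in_pathway",
                    "terms_in_set_and_pathway",
                    "pct_of_set",
                    "pct_of_pathway",
                    "p_value",
                    "q_value",
                ],
                [
                    [
                        r.pathway_id,
                        r.description,
                        str(r.pathway_size),
                        str(r.hits),
                        format_percent(r.pct_of_set, config.decimal_comma),
                        format_percent(r.pct_of_pathway, config.decimal_comma),
                        f"{r.p_value:.3e}",
                        f"{r.q_value:.3e}",
                    ]
                    for r in rows
                ],
            )

    enrich

    @stage("bowtie")
    def bowtie():
        if downstream is None:
            logger.warning("no downstream set configured; bow-tie stage skipped")
            provenance["stages"]["bowtie"] = "skipped: no downstream set"
            return
        fb = feedback_set(
            union, downstream, denominator_policy=config.fraction_denominator
        )
        _write_tsv(
            outdir / "feedback.tsv",
            ["id"],
            [[m] for m in fb.feedback_members],
        )
        provenance["feedback"] = {
            "count": fb.feedback_count,
            "fraction_pct": fb.fraction,
            "denominator": fb.denominator,
            "denominator_policy": fb.denominator_policy,
        }
        if knob is not None:
            bt = bowtie_classify(union, knob, downstream)
            rows = []
            for cls_name, members in (
                ("knob", bt.knob),
                ("fan_in", bt.fan_in),
                ("feedback", bt.feedback),
                ("fan_out", bt.fan_out),
            ):
                for m in sorted(members):
                    rows.append(
                        [m, cls_name, "1" if m in bt.knob_feedback else "0"]
                    )
            rows.sort(key=lambda r: r[0])
            _write_tsv(outdir / "bowtie.tsv", ["id", "class", "knob_feedback"], rows)

    bowtie

    with open(outdir / "provenance.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
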