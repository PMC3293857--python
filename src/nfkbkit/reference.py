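"""Bundled reference protein lists and published enrichment count tables.

Small plain-text resources shipped with the package:

- the five NF-kB family members (the bow-tie knob);
- the published 49-member feedback protein set (upstream-interactome
  proteins whose genes NF-kB itself regulates);
- the published downstream-gene over-representation counts
  (pathway id, pathway size, hits; study set of 410 identifiers),
  usable to recompute coverage percentages without any database access.
"""

from __future__ import annotations

from importlib import resources

from .ppi_io import ProteinSet, canonical

#: size of the downstream study set behind the bundled pathway counts
DG_SET_SIZE = 410


def _read_list(filename: str) -> list[str]:
    text = (resources.files("nfkbkit") / "data" / filename).read_text("utf-8")
    return [
        canonical(line)
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]


def nfkb_family() -> ProteinSet:
    """The five NF-kB family members (TF65, NFKB1, NFKB2, REL, RELB)."""
    return ProteinSet(name="NFKB_family", members=frozenset(_read_list("nfkb_family.txt")))


def feedback_proteins() -> ProteinSet:
    """The published 49-member feedback protein set."""
    return ProteinSet(
        name="feedback", members=frozenset(_read_list("nfkb_feedback_proteins.txt"))
    )


def dg_pathway_counts() -> list[dict]:
    """Published downstream-set pathway counts as a list of row dicts."""
    text = (resources.files("nfkbkit") / "data" / "dg_pathway_counts.tsv").read_text(
        "utf-8"
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    rows = []
    for ln in lines[1:]:
        vals = ln.split("\t")
        row = dict(zip(header, vals))
        row["pathway_size"] = int(row["pathway_size"])
        row["hits"] = int(row["hits"])
        rows.append(row)
    return rows
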