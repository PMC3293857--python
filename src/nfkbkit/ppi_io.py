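"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats
-----------------
- ``tsv-pairs``: two tab-separated identifier columns, optional third column
  with an evidence-source label; a single-column line denotes an isolated node.
- ``sif``: simple interaction format, ``source relation target [target ...]``;
  a bare line with one token is an isolated node.
- ``mitab-subset``: the first two columns of PSI-MITAB, ``uniprotkb:``
  prefixes stripped; any further columns are ignored.
- GMT for pathway collections, one pathway per line
  (``id<TAB>description<TAB>member...``).
- plain identifier lists (one per line, ``#`` comments) for protein sets.

All identifiers are canonicalized (stripped, uppercased) at every ingestion
point; duplicate edge lines collapse into one record with merged evidence
sources. Self-interactions (a protein paired with itself) are legitimate
records and are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import EmptyInputError, MalformedIdentifierError, ParseError

logger = logging.getLogger(__name__)

DIALECTS = ("tsv-pairs", "sif", "mitab-subset")


@dataclass(frozen=True)
class ProteinId:
    """A canonical protein identifier plus an optional NCBI gene symbol."""

    accession: str
    gene_name: str | None = None

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.accession


def canonical(raw: str) -> str:
    """Canonical form of a raw identifier: stripped and uppercased.

    Idempotent by construction. Raises
    :class:`~nfkbkit.errors.MalformedIdentifierError` on blank input.
    """
    token = raw.strip()
    if not token:
        raise MalformedIdentifierError(f"blank protein identifier: {raw!r}")
    return token.upper()


def normalize_id(raw: str, gene_names: Mapping[str, str] | None = None) -> ProteinId:
    """Normalize ``raw`` into a :class:`ProteinId`.

    ``gene_names`` is an optional accession -> gene-symbol mapping table
    (keys are matched after canonicalization).
    """
    acc = canonical(raw)
    gene = None
    if gene_names:
        gene = gene_names.get(acc)
    return ProteinId(acc, gene)


@dataclass(frozen=True)
class InteractionRecord:
    """One undirected evidence-based interaction between two proteins.

    The pair is stored sorted so that ``(a, b)`` and ``(b, a)`` compare equal;
    ``a == b`` encodes a self-interaction.
    """

    a: str
    b: str
    sources: frozenset[str] = frozenset()

    @classmethod
    def make(cls, a: str, b: str, sources: Iterable[str] = ()) -> "InteractionRecord":
        a, b = canonical(a), canonical(b)
        if b < a:
            a, b = b, a
        return cls(a, b, frozenset(sources))

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)

    @property
    def is_self(self) -> bool:
        return self.a == self.b


@dataclass(frozen=True)
class ProteinSet:
    """A named set of canonical protein identifiers."""

    name: str
    members: frozenset[str]
    duplicates_removed: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.members

    def sorted(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class PathwayAnnotation:
    """One pathway: identifier, free-text description and member proteins."""

    pathway_id: str
    description: str
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# edge tables


def sniff_dialect(path: str | Path) -> str:
    """Guess the edge-table dialect from the first non-blank line."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if any(f.lower().startswith("uniprotkb:") for f in fields[:2]):
                return "mitab-subset"
            if len(fields) >= 3 and "\t" not in line:
                return "sif"
            if len(fields) >= 3 and fields[1].lower() in ("pp", "pd"):
                # tab-delimited SIF: middle column is a relation type
                return "sif"
            return "tsv-pairs"
    raise EmptyInputError(f"{path}: no records found")


def _split(line: str) -> list[str]:
    return line.split("\t") if "\t" in line else line.split()


def _parse_edge_lines(path: str | Path, dialect: str):
    """Yield ``(line_no, endpoints, sources, isolated)`` tuples."""
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = _split(line)
            if dialect == "tsv-pairs":
                if len(fields) == 1:
                    yield line_no, None, (), canonical(fields[0])
                elif len(fields) in (2, 3):
                    src = (fields[2],) if len(fields) == 3 and fields[2].strip() else ()
                    yield line_no, [(fields[0], fields[1])], src, None
                else:
                    raise ParseError(
                        f"expected 1-3 columns, got {len(fields)}", path, line_no
                    )
            elif dialect == "sif":
                if len(fields) == 1:
                    yield line_no, None, (), canonical(fields[0])
                elif len(fields) >= 3:
                    src_node, _relation = fields[0], fields[1]
                    yield line_no, [(src_node, t) for t in fields[2:]], (), None
                else:
                    raise ParseError(
                        "SIF line needs 1 token (isolated node) or >=3 "
                        f"(source relation targets...), got {len(fields)}",
                        path,
                        line_no,
                    )
            elif dialect == "mitab-subset":
                if len(fields) < 2:
                    raise ParseError(
                        f"MITAB line needs >=2 columns, got {len(fields)}",
                        path,
                        line_no,
                    )
                ends = []
                for f in fields[:2]:
                    f = f.strip()
                    if f.lower().startswith("uniprotkb:"):
                        f = f.split(":", 1)[1]
                    ends.append(f)
                yield line_no, [tuple(ends)], (), None
            else:
                raise ValueError(f"unknown dialect {dialect!r}; use one of {DIALECTS}")


def read_edge_table(
    path: str | Path, dialect: str = "sniff"
) -> list[InteractionRecord]:
    """Read an edge table into deduplicated interaction records.

    Duplicate pairs (in either orientation) collapse into one record with
    merged evidence sources. Raises
    :class:`~nfkbkit.errors.EmptyInputError` when no interaction record
    survives parsing.
    """
    records, _isolated = read_edges_and_isolated(path, dialect)
    if not records:
        raise EmptyInputError(f"{path}: no interaction records found")
    return records


def read_edges_and_isolated(
    path: str | Path, dialect: str = "sniff"
) -> tuple[list[InteractionRecord], set[str]]:
    """Like :func:`read_edge_table` but also return bare isolated-node lines."""
    if dialect == "sniff":
        dialect = sniff_dialect(path)
    merged: dict[tuple[str, str], set[str]] = {}
    isolated: set[str] = set()
    n_lines = 0
    for line_no, pairs, sources, lone in _parse_edge_lines(path, dialect):
        n_lines += 1
        if lone is not None:
            isolated.add(lone)
            continue
        for a, b in pairs:
            try:
                rec = InteractionRecord.make(a, b, sources)
            except MalformedIdentifierError as exc:
                raise ParseError(str(exc), path, line_no) from exc
            merged.setdefault(rec.pair, set()).update(rec.sources)
    records = [
        InteractionRecord(a, b, frozenset(srcs))
        for (a, b), srcs in sorted(merged.items())
    ]
    logger.info(
        "%s: %d data lines -> %d distinct pairs, %d isolated nodes",
        path,
        n_lines,
        len(records),
        len(isolated),
    )
    return records, isolated


# ---------------------------------------------------------------------------
# protein sets


def read_protein_set(path: str | Path, name: str) -> ProteinSet:
    """Read a one-identifier-per-line protein list.

    Lines starting with ``#`` are comments; blanks are skipped. Duplicates
    (after canonicalization) are removed and their count recorded on the
    returned set's ``duplicates_removed`` field.
    """
    members: set[str] = set()
    n_ids = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            n_ids += 1
            members.add(canonical(token))
    if not members:
        raise EmptyInputError(f"{path}: protein set '{name}' is empty")
    dupes = n_ids - len(members)
    if dupes:
        logger.info("%s: removed %d duplicate identifiers", path, dupes)
    return ProteinSet(name=name, members=frozenset(members), duplicates_removed=dupes)


def write_protein_set(pset: ProteinSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in pset.sorted():
            fh.write(m + "\n")


# ---------------------------------------------------------------------------
# GMT pathway collections


def read_gmt(path: str | Path) -> list[PathwayAnnotation]:
    """Read a GMT file (id, description, members...) into annotations."""
    out: list[PathwayAnnotation] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line needs >=3 tab-separated fields, got {len(fields)}",
                    path,
                    line_no,
                )
            pid = fields[0].strip()
            if pid in seen:
                raise ParseError(f"duplicate pathway id {pid!r}", path, line_no)
            seen.add(pid)
            members = frozenset(canonical(m) for m in fields[2:] if m.strip())
            if not members:
                raise ParseError(f"pathway {pid!r} has no members", path, line_no)
            out.append(PathwayAnnotation(pid, fields[1].strip(), members))
    if not out:
        raise EmptyInputError(f"{path}: no pathways found")
    return out


def write_gmt(pathways: Iterable[PathwayAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pw in pathways:
            fh.write(
                "\t".join([pw.pathway_id, pw.description, *sorted(pw.members)]) + "\n"
            )


# ---------------------------------------------------------------------------
# network output (the InteractionNetwork type lives in interactome.py; these
# writers only need its node/edge accessors)


def write_network(network, path: str | Path, dialect: str = "sif") -> None:
    """Write a network as SIF or tsv-pairs.

    Isolated nodes are emitted as bare single-token lines in both dialects so
    the write -> read round trip preserves the node set exactly.
    """
    if dialect not in ("sif", "tsv-pairs"):
        raise ValueError(f"unknown output dialect {dialect!r}")
    edges = sorted(
        (tuple(sorted((a, b))) for a, b in network.edge_pairs()),
    )
    touched = {n for e in edges for n in e}
    lone = sorted(set(network.nodes) - touched)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in edges:
            if dialect == "sif":
                fh.write(f"{a}\tpp\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")
        for n in lone:
            fh.write(n + "\n")


def write_node_attributes(table, path: str | Path) -> None:
    """Write a per-node attribute table as TSV with an ``id`` first column.

    ``table`` is a mapping ``node -> {attr: value}`` or a pandas DataFrame
    indexed by node id.
    """
    import pandas as pd

    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame.from_dict(table, orient="index")
    table = table.sort_index()
    table.index.name = "id"
    table.to_csv(path, sep="\t", lineterminator="\n")
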