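"""Readers and writers for the external formats the pipeline touches.

All tabular files are TSV (header row, UTF-8, '.' decimal). Sequences come in
as FASTA and are canonicalized to RNA uppercase. Gene sets are GMT. Networks
go out as SIF, GraphML, or an edge TSV for Cytoscape import.

Feature classes (circRNA / miRNA / mRNA) are carried by file role — which
argument a file is passed as — never parsed out of identifier strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

LAYERS = ("counts", "log_intensity", "log_norm")
GROUPS = ("case", "control")
MOLTYPES = ("miRNA", "mRNA_target", "circRNA_target")

_RNA_ALPHABET = set("ACGU")
_CANON = str.maketrans("acgtuT", "ACGUUU")


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A features x samples numeric matrix with a layer tag and sample design.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, one column per sample id.
    layer
        One of ``counts``, ``log_intensity``, ``log_norm``.
    design
        Mapping sample id -> group, groups being ``case`` / ``control``.
    """

    values: pd.DataFrame
    layer: str
    design: dict[str, str]

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise FormatError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        dup_f = self.values.index[self.values.index.duplicated()].unique().tolist()
        if dup_f:
            raise FormatError(f"duplicate feature id(s): {', '.join(map(str, dup_f))}")
        dup_s = self.values.columns[self.values.columns.duplicated()].unique().tolist()
        if dup_s:
            raise FormatError(f"duplicate sample id(s): {', '.join(map(str, dup_s))}")
        missing = [s for s in self.values.columns if s not in self.design]
        if missing:
            raise FormatError(f"sample(s) missing from design: {', '.join(missing)}")
        bad_group = {s: g for s, g in self.design.items() if g not in GROUPS}
        if bad_group:
            raise FormatError(f"design group(s) outside {GROUPS}: {bad_group}")
        if self.layer == "counts":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                i, j = np.argwhere(arr < 0)[0]
                raise FormatError(
                    "negative value in counts layer at feature "
                    f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.design[s] == group]

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to the given features, preserving matrix order."""
        keep = set(feature_ids)
        sub = self.values.loc[[f for f in self.feature_ids if f in keep]]
        return ExpressionMatrix(sub, self.layer, dict(self.design))


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column design TSV (sample_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"design file {path} lacks column {col!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise FormatError(f"duplicate sample id(s) in design: {', '.join(dup)}")
    return dict(zip(df["sample_id"], df["group"]))


def read_expression(path: str | Path, layer: str,
                    design_path: str | Path | None = None,
                    design: Mapping[str, str] | None = None) -> ExpressionMatrix:
    """Read a features x samples TSV plus its sample design.

    The first column holds feature ids, the header row holds sample ids.
    Row and column order are preserved. Either ``design_path`` or an
    in-memory ``design`` mapping must be supplied.
    """
    if design is None:
        if design_path is None:
            raise ValueError("either design_path or design is required")
        design = read_design(design_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), layer, dict(design))


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    em.values.to_csv(path, sep="\t", index_label="feature_id")


def write_design(design: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(design), "group": list(design.values())}
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeqRecord:
    """A canonicalized RNA sequence: uppercase over {A,C,G,U}, T mapped to U."""

    id: str
    seq: str
    moltype: str = "mRNA_target"

    def __post_init__(self) -> None:
        if self.moltype not in MOLTYPES:
            raise FormatError(f"unknown moltype {self.moltype!r}")
        if not self.seq:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - _RNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains letters outside ACGU(T): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


def canonicalize(seq: str) -> str:
    """Map T->U and lowercase->uppercase. Idempotent."""
    return seq.translate(_CANON).upper()


def read_fasta(path: str | Path, moltype: str = "mRNA_target") -> list[SeqRecord]:
    """Read FASTA; ids are the first whitespace token of each header."""
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, canonicalize(str(rec.seq)), moltype))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe used for enrichment."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {term!r} is empty")
        self.restrict(self.universe)

    def restrict(self, universe: Iterable[str]) -> None:
        """Clip every set to ``universe`` (sets falling empty are dropped)."""
        uni = frozenset(universe)
        clipped = {}
        for term, (desc, members) in self.sets.items():
            kept = members & uni
            if kept:
                clipped[term] = (desc, kept)
            else:
                log.warning("gene set %s has no member in the universe; dropped", term)
        self.sets = clipped
        self.universe = uni


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Parse GMT (term TAB description TAB gene...).

    The universe defaults to the union of all members unless supplied.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    union: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term!r}")
            sets[term] = (desc, frozenset(genes))
            union |= set(genes)
    if not sets:
        log.warning("GMT file %s is empty", path)
    uni = frozenset(universe) if universe is not None else frozenset(union)
    return GeneSetCollection(sets, uni)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection.sets):
            desc, members = collection.sets[term]
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("SIF", "GraphML", "edge_TSV")


def write_network(triplets, fmt: str, path: str | Path) -> None:
    """Export ceRNA triplets for Cytoscape.

    SIF uses the relation labels ``sponges`` (circRNA -> miRNA) and
    ``targets`` (miRNA -> mRNA); duplicated edges are written once. GraphML
    carries ``cls`` and ``de_direction`` node attributes. Output is
    deterministic given identical input order.
    """
    triplets = list(triplets)
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; expected one of {NETWORK_FORMATS}")
    if not triplets:
        log.warning("writing empty network to %s", path)

    edges: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    nodes: dict[str, tuple[str, str]] = {}
    for t in triplets:
        nodes.setdefault(t.circ_id, ("circRNA", t.circ_direction))
        nodes.setdefault(t.mirna_id, ("miRNA", t.mirna_direction))
        nodes.setdefault(t.mrna_id, ("mRNA", t.mrna_direction))
        for edge in ((t.circ_id, "sponges", t.mirna_id),
                     (t.mirna_id, "targets", t.mrna_id)):
            if edge not in seen:
                seen.add(edge)
                edges.append(edge)

    if fmt == "SIF":
        with open(path, "w") as fh:
            for a, rel, b in edges:
                fh.write(f"{a}\t{rel}\t{b}\n")
    elif fmt == "edge_TSV":
        with open(path, "w") as fh:
            fh.write("source\trelation\ttarget\n")
            for a, rel, b in edges:
                fh.write(f"{a}\t{rel}\t{b}\n")
    else:  # GraphML
        g = nx.DiGraph()
        for node, (cls, direction) in nodes.items():
            g.add_node(node, cls=cls, de_direction=direction)
        for a, rel, b in edges:
            g.add_edge(a, b, relation=rel)
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Generic tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
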