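"""Readers and writers for the three input formats.

The pipeline consumes (a) circRNA nucleotide sequences in FASTA,
(b) a two-column circRNA-disease association table (TSV with header
``circRNA<TAB>disease``), and (c) a disease ontology giving each term's
parents, either as an OBO 1.2 file (only ``id``/``name``/``is_a``/
``is_obsolete`` are honoured) or as a child->parent edge-list TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """An input file violates its expected format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A circRNA identifier and its normalized DNA sequence (A/C/G/T)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )


def normalize_sequence(raw: str) -> str:
    """Uppercase and map RNA U to DNA T (circBase-style sequences are DNA,
    but inputs may arrive in the RNA alphabet)."""
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Raises :class:`FormatError` naming the offending record on an empty
    sequence or invalid residue.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, seq=normalize_sequence(str(rec.seq))))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


@dataclass
class AssociationTable:
    """Known circRNA-disease pairs plus deterministic entity orderings.

    ``circ_ids``/``dis_ids`` fix the row/column order of the binary
    association matrix A (nc x nd); by default they are first-appearance
    order over ``pairs``, but explicit lists may carry entities with no
    associations (useful for synthetic data).
    """

    pairs: list[tuple[str, str]]
    circ_ids: list[str] = field(default_factory=list)
    dis_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.circ_ids:
            self.circ_ids = list(dict.fromkeys(c for c, _ in self.pairs))
        if not self.dis_ids:
            self.dis_ids = list(dict.fromkeys(d for _, d in self.pairs))
        cset, dset = set(self.circ_ids), set(self.dis_ids)
        for c, d in self.pairs:
            if c not in cset or d not in dset:
                raise ValueError(f"pair ({c}, {d}) references unknown id")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in AssociationTable")

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)

    @property
    def n_dis(self) -> int:
        return len(self.dis_ids)


def read_associations(path: str | Path) -> AssociationTable:
    """Read a two-column TSV of (circRNA id, disease id) pairs.

    A leading ``circRNA<TAB>disease`` header row is skipped if present.
    Duplicate rows are dropped with a logged warning; rows with missing
    columns raise :class:`FormatError`.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            c, d = cols[0].strip(), cols[1].strip()
            if lineno == 1 and (c, d) == ("circRNA", "disease"):
                continue
            if (c, d) in seen:
                n_dup += 1
                continue
            seen.add((c, d))
            pairs.append((c, d))
    if n_dup:
        logger.warning("%s: dropped %d duplicate association rows", path, n_dup)
    if not pairs:
        raise FormatError(f"{path}: no associations")
    return AssociationTable(pairs=pairs)


def write_associations(assoc: AssociationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("circRNA\tdisease\n")
        for c, d in assoc.pairs:
            fh.write(f"{c}\t{d}\n")


@dataclass
class DiseaseDAG:
    """A rooted DAG of disease ontology terms with child->parent edges."""

    terms: set[str]
    parents: dict[str, set[str]]

    def __post_init__(self) -> None:
        for t, ps in self.parents.items():
            if t not in self.terms:
                raise ValueError(f"parent map references unknown term {t!r}")
            missing = ps - self.terms
            if missing:
                raise ValueError(f"term {t!r} has unknown parents {sorted(missing)}")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        if not self.roots():
            raise ValueError("ontology has no root term")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        return g

    def roots(self) -> set[str]:
        return {t for t in self.terms if not self.parents.get(t)}

    def ancestors(self, term: str) -> set[str]:
        """Proper ancestors of ``term`` (transitive closure of parents)."""
        if term not in self.terms:
            raise KeyError(term)
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return out


def _dag_from_edges(edges: Iterable[tuple[str, str]]) -> DiseaseDAG:
    terms: set[str] = set()
    parents: dict[str, set[str]] = {}
    for child, parent in edges:
        terms.update((child, parent))
        parents.setdefault(child, set()).add(parent)
    for t in terms:
        parents.setdefault(t, set())
    return DiseaseDAG(terms=terms, parents=parents)


def read_ontology(path: str | Path) -> DiseaseDAG:
    """Read a disease ontology from ``.obo`` or child->parent ``.tsv``.

    The dialect is auto-detected by extension; anything else is rejected
    rather than guessed. Obsolete OBO terms are excluded. A cycle raises
    :class:`ValueError` listing one offending cycle.
    """
    path = Path(path)
    if path.suffix == ".obo":
        # obonet drops obsolete stanzas by default and stores is_a as
        # child -> parent edges.
        graph = obonet.read_obo(str(path))
        edges = [(c, p) for c, p, key in graph.edges(keys=True) if key == "is_a"]
        terms = set(graph.nodes)
        parents: dict[str, set[str]] = {t: set() for t in terms}
        for c, p in edges:
            parents[c].add(p)
        return DiseaseDAG(terms=terms, parents=parents)
    if path.suffix == ".tsv":
        edges = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                cols = line.split("\t")
                if len(cols) < 2:
                    raise FormatError(f"{path}:{lineno}: expected child<TAB>parent")
                if lineno == 1 and cols[:2] == ["child", "parent"]:
                    continue
                edges.append((cols[0].strip(), cols[1].strip()))
        if not edges:
            raise FormatError(f"{path}: no ontology edges")
        return _dag_from_edges(edges)
    raise FormatError(f"{path}: unrecognized ontology extension (want .obo or .tsv)")


def write_ontology_obo(dag: DiseaseDAG, path: str | Path) -> None:
    """Write the DAG as a minimal OBO 1.2 file (id + is_a only)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            for p in sorted(dag.parents.get(term, ())):
                fh.write(f"is_a: {p}\n")


def to_matrix(assoc: AssociationTable) -> np.ndarray:
    """Binary association matrix A (nc x nd): A[i, j] = 1 iff the pair
    (circ_ids[i], dis_ids[j]) is a known association."""
    c_index = {c: i for i, c in enumerate(assoc.circ_ids)}
    d_index = {d: j for j, d in enumerate(assoc.dis_ids)}
    A = np.zeros((assoc.n_circ, assoc.n_dis), dtype=np.int8)
    for c, d in assoc.pairs:
        A[c_index[c], d_index[d]] = 1
    return A
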