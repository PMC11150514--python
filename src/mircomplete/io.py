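"""Readers, writers and core typed containers.

All on-disk artifacts are plain text: association pairs as two-column
TSV/CSV, similarity/score matrices as TSV with a header row and a header
column of labels, ontology DAGs as child->parent edge lists plus a
disease->term roots table, and ranked predictions as a four-column TSV.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Role",
    "AssociationTable",
    "AssociationMatrix",
    "LabeledMatrix",
    "DiseaseDAG",
    "ParseError",
    "LabelError",
    "ValidationError",
    "OntologyError",
    "read_association_pairs",
    "build_association_matrix",
    "read_labeled_matrix",
    "write_labeled_matrix",
    "read_dag_edges",
    "write_predictions",
]


class ParseError(ValueError):
    """A text input could not be parsed; the message names the line."""


class LabelError(ValueError):
    """Row/column labels are inconsistent between objects."""


class ValidationError(ValueError):
    """A matrix violates the invariants its role declares."""


class OntologyError(ValueError):
    """The ontology edge list is not a DAG or references unknown terms."""


class Role(str, Enum):
    """Semantic role of a labeled matrix.

    Similarity roles demand a square symmetric matrix in [0, 1] with unit
    diagonal; ``H`` is the heterogeneous target block matrix and ``SCORES``
    the completed association block.
    """

    MF = "MF"          # miRNA functional similarity (external input)
    DS1 = "DS1"        # DAG semantic similarity, contribution scheme 1
    DS2 = "DS2"        # DAG semantic similarity, information-content scheme
    DS = "DS"          # weighted average of DS1 and DS2
    MGKS = "MGKS"      # Gaussian interaction-profile kernel, miRNA side
    DGKS = "DGKS"      # Gaussian interaction-profile kernel, disease side
    MM = "MM"          # fused miRNA similarity
    DD = "DD"          # fused disease similarity
    H = "H"            # heterogeneous target matrix
    SCORES = "scores"  # predicted association probabilities


SIMILARITY_ROLES = frozenset(
    {Role.MF, Role.DS1, Role.DS2, Role.DS, Role.MGKS, Role.DGKS, Role.MM, Role.DD}
)

# Asymmetries up to this tolerance are repaired by averaging; anything worse
# is rejected as a genuine data error.
SYMMETRY_TOL = 1e-6
ENTRY_TOL = 1e-9


@dataclass(frozen=True)
class AssociationTable:
    """Ordered, deduplicated list of (miRNA id, disease id) pairs."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for m, d in self.pairs:
            if not m or not d:
                raise ValueError("association ids must be non-empty strings")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("association table contains duplicate pairs")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease association matrix with row/column labels."""

    mirna_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray  # shape (nm, nd), entries in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        nm, nd = self.values.shape
        if nm != len(self.mirna_ids) or nd != len(self.disease_ids):
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.mirna_ids)) != nm or len(set(self.disease_ids)) != nd:
            raise LabelError("duplicate row or column labels")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValidationError("association matrix entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_associations(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(list(self.mirna_ids), list(self.disease_ids), self.values.copy())


@dataclass
class LabeledMatrix:
    """Real matrix with row/column labels and an optional semantic role.

    Construction does not validate role invariants (intermediate objects such
    as an all-zero placeholder similarity are legitimate in memory); call
    :meth:`validate` or go through the file reader/writer to enforce them.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    role: Role | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("label lengths do not match matrix shape")

    def validate(self) -> "LabeledMatrix":
        """Check (and repair within tolerance) the invariants of the role."""
        if self.role in SIMILARITY_ROLES:
            n, m = self.values.shape
            if n != m or self.row_ids != self.col_ids:
                raise ValidationError(f"role {self.role.value} requires a square labeled matrix")
            asym = np.abs(self.values - self.values.T).max() if n else 0.0
            if asym > SYMMETRY_TOL:
                raise ValidationError(
                    f"matrix asymmetric beyond tolerance ({asym:.3g} > {SYMMETRY_TOL:g})"
                )
            self.values = (self.values + self.values.T) / 2.0
            if self.values.size:
                lo, hi = self.values.min(), self.values.max()
                if lo < -ENTRY_TOL or hi > 1 + ENTRY_TOL:
                    raise ValidationError(
                        f"similarity entries outside [0, 1]: range [{lo:.6g}, {hi:.6g}]"
                    )
                np.clip(self.values, 0.0, 1.0, out=self.values)
                diag = np.diag(self.values)
                if np.abs(diag - 1.0).max() > SYMMETRY_TOL:
                    raise ValidationError("similarity diagonal must equal 1")
                np.fill_diagonal(self.values, 1.0)
        return self

    def copy(self) -> "LabeledMatrix":
        return LabeledMatrix(list(self.row_ids), list(self.col_ids), self.values.copy(), self.role)


@dataclass
class DiseaseDAG:
    """Ancestor DAGs of diseases over ontology terms.

    ``graph`` stores child->parent edges, so ontology ancestors of a term are
    its graph descendants.  ``phi`` is the unitless semantic contribution
    decay applied per edge when walking away from a disease's own term.
    """

    graph: nx.DiGraph
    disease_roots: dict[str, str]
    phi: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (0, 1)")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(f"ontology edges contain a cycle: {cycle}")
        missing = [t for t in self.disease_roots.values() if t not in self.graph]
        if missing:
            raise OntologyError(f"disease root terms absent from ontology: {missing}")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def diseases(self) -> list[str]:
        return sorted(self.disease_roots)

    def term_set(self, disease_id: str) -> set[str]:
        """T(d): the disease's own term plus all of its ontology ancestors."""
        try:
            root = self.disease_roots[disease_id]
        except KeyError:
            raise KeyError(f"unknown disease id: {disease_id!r}") from None
        return {root} | nx.descendants(self.graph, root)

    def children_in(self, term: str, universe: set[str]) -> list[str]:
        """DAG children of ``term`` (edge sources) restricted to ``universe``."""
        return [c for c in self.graph.predecessors(term) if c in universe]


# ---------------------------------------------------------------------------
# association pairs


def _split_line(line: str) -> list[str]:
    if "\t" in line:
        parts = line.split("\t")
    elif "," in line:
        parts = line.split(",")
    else:
        parts = line.split()
    return [p.strip() for p in parts if p.strip()]


def read_association_pairs(path: str | Path) -> AssociationTable:
    """Read a two-column (miRNA id, disease id) table, deduplicating pairs.

    Tab is the preferred delimiter with comma and whitespace fallbacks;
    lines starting with ``#`` and blank lines are skipped.  Duplicate pairs
    are dropped (first occurrence kept) and counted in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seen: dict[tuple[str, str], None] = {}
    duplicates = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            if len(fields) > 2:
                logger.debug("%s:%d: ignoring %d extra columns", path, lineno, len(fields) - 2)
            pair = (fields[0], fields[1])
            if pair in seen:
                duplicates += 1
            else:
                seen[pair] = None
    if duplicates:
        logger.info("dropped %d duplicate association pairs from %s", duplicates, path)
    if not seen:
        logger.warning("association file %s contains no pairs", path)
    return AssociationTable(tuple(seen))


def build_association_matrix(
    table: AssociationTable,
    mirna_ids: Sequence[str] | None = None,
    disease_ids: Sequence[str] | None = None,
) -> AssociationMatrix:
    """Build the binary association matrix A from a pair table.

    Entry (i, j) is 1 iff the pair (miRNA i, disease j) is present.  When
    label universes are not supplied they are taken from the table and
    sorted lexicographically for a reproducible layout.
    """
    if mirna_ids is None:
        mirna_ids = sorted({m for m, _ in table.pairs})
    if disease_ids is None:
        disease_ids = sorted({d for _, d in table.pairs})
    mirna_ids, disease_ids = list(mirna_ids), list(disease_ids)
    mi = {m: i for i, m in enumerate(mirna_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    values = np.zeros((len(mirna_ids), len(disease_ids)))
    for m, d in table.pairs:
        if m not in mi:
            raise LabelError(f"miRNA id {m!r} not in supplied universe")
        if d not in di:
            raise LabelError(f"disease id {d!r} not in supplied universe")
        values[mi[m], di[d]] = 1.0
    return AssociationMatrix(mirna_ids, disease_ids, values)


# ---------------------------------------------------------------------------
# labeled matrices


def read_labeled_matrix(path: str | Path, role: Role | None = None) -> LabeledMatrix:
    """Read a TSV matrix with a header row and header column of labels."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error wrapping
        raise ParseError(f"could not parse matrix file {path}: {exc}") from exc
    m = LabeledMatrix(
        [str(r) for r in frame.index],
        [str(c) for c in frame.columns],
        frame.to_numpy(dtype=float),
        role,
    )
    return m.validate()


def write_labeled_matrix(m: LabeledMatrix, path: str | Path) -> Path:
    """Write a labeled matrix as TSV; round trips are lossless to 1e-12."""
    m.validate()
    path = Path(path)
    frame = pd.DataFrame(m.values, index=m.row_ids, columns=m.col_ids)
    frame.to_csv(path, sep="\t")
    return path


# ---------------------------------------------------------------------------
# ontology DAGs


def read_dag_edges(path: str | Path, roots_path: str | Path, phi: float = 0.5) -> DiseaseDAG:
    """Read child->parent ontology edges and a disease->term roots table.

    Acyclicity is verified; terms unreachable from every disease root are
    permitted but reported in the log.
    """
    graph = nx.DiGraph()
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected (child, parent), got {len(fields)} columns")
            graph.add_edge(fields[0], fields[1])
    roots: dict[str, str] = {}
    roots_path = Path(roots_path)
    with open(roots_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line)
            if len(fields) < 2:
                raise ParseError(f"{roots_path}:{lineno}: expected (disease, term)")
            roots[fields[0]] = fields[1]
            graph.add_node(fields[1])  # roots may be isolated terms
    dag = DiseaseDAG(graph, roots, phi)
    reachable: set[str] = set()
    for d in roots:
        reachable |= dag.term_set(d)
    stray = dag.terms - reachable
    if stray:
        logger.warning("%d ontology terms unreachable from any disease root", len(stray))
    return dag


# ---------------------------------------------------------------------------
# ranked predictions


def write_predictions(
    scores: LabeledMatrix,
    known: AssociationMatrix,
    path: str | Path,
    top_k: int = 50,
) -> Path:
    """Write the top-k novel candidates per disease, ranked by score.

    Known (training) pairs are excluded; ties are broken by miRNA id
    ascending so output is a deterministic function of its inputs.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if scores.row_ids != known.mirna_ids or scores.col_ids != known.disease_ids:
        raise LabelError("scores and known association matrix must share labels")
    rows = []
    for j, disease in enumerate(scores.col_ids):
        candidates = [
            (-scores.values[i, j], mirna, scores.values[i, j])
            for i, mirna in enumerate(scores.row_ids)
            if known.values[i, j] == 0
        ]
        candidates.sort()
        for rank, (_, mirna, score) in enumerate(candidates[:top_k], start=1):
            rows.append((disease, rank, mirna, score))
    frame = pd.DataFrame(rows, columns=["disease_id", "rank", "miRNA_id", "score"])
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path
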