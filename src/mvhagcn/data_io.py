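"""Reading, validating and writing the input and output file formats.

Canonical on-disk dialect: tab-separated matrices with a header row of
column ids and a first column of row ids; FASTA for miRNA sequences; a
three-column TSV edge list for the per-disease MeSH-style DAGs; CSV for
ranked predictions and metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IngestError",
    "FormatError",
    "ContractError",
    "EntityIndex",
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseDAGSet",
    "read_association_table",
    "write_association_table",
    "read_matrix",
    "write_matrix",
    "read_similarity_table",
    "read_fasta",
    "write_fasta",
    "read_family_table",
    "write_family_table",
    "read_dag_edges",
    "write_dag_edges",
    "write_predictions",
    "read_predictions",
]


class IngestError(ValueError):
    """Raised when an input file violates a structural invariant."""


class FormatError(IngestError):
    """Raised when a cell or record cannot be parsed as its declared type."""


class ContractError(ValueError):
    """Raised when an in-memory value violates an operation precondition."""


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen = set()
    for i in ids:
        if i in seen:
            raise IngestError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


@dataclass(frozen=True)
class EntityIndex:
    """Ordered miRNA and disease id lists; the coordinate system for every
    matrix in the pipeline (miRNAs first in the heterogeneous node order)."""

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "mirna_ids", tuple(_check_unique(self.mirna_ids, "miRNA")))
        object.__setattr__(self, "disease_ids", tuple(_check_unique(self.disease_ids, "disease")))
        if len(self.mirna_ids) < 2 or len(self.disease_ids) < 2:
            raise IngestError("need at least 2 miRNAs and 2 diseases")

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease association matrix."""

    values: np.ndarray
    index: EntityIndex

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (self.index.n_mirna, self.index.n_disease):
            raise IngestError(
                f"association matrix shape {self.values.shape} does not match "
                f"index ({self.index.n_mirna}, {self.index.n_disease})"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise FormatError("association matrix entries must be 0 or 1")
        if self.values.sum() < 1:
            raise IngestError("association matrix has no positive entries")
        self.values = self.values.astype(np.float64)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.values.copy(), self.index)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix for one view, entries in [0, 1]."""

    values: np.ndarray
    ids: tuple[str, ...]
    view_name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.ids = tuple(str(i) for i in self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise IngestError(
                f"similarity matrix {self.view_name!r} shape {self.values.shape} "
                f"does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise IngestError(f"similarity matrix {self.view_name!r} is not symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise IngestError(f"similarity matrix {self.view_name!r} outside [0, 1]")
        # enforce exact symmetry / bounds after the tolerance checks
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, 1.0)

    @classmethod
    def from_loaded(cls, values, ids, view_name: str = "") -> "SimilarityMatrix":
        """Ingest an externally computed matrix: symmetrize and clip to [0, 1]."""
        values = np.asarray(values, dtype=np.float64)
        values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        return cls(values, ids, view_name)


@dataclass
class DiseaseDAGSet:
    """Per-disease ancestor DAGs (child -> parent edges, the disease term is
    the most specific node) with term document frequencies across diseases."""

    graphs: dict[str, nx.DiGraph]
    term_frequency: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.term_frequency:
            freq: dict[str, int] = {}
            for g in self.graphs.values():
                for t in g.nodes:
                    freq[t] = freq.get(t, 0) + 1
            self.term_frequency = freq

    def ancestors(self, disease: str) -> set[str]:
        """A(D): the disease term plus every term reachable via parent edges."""
        g = self.graphs[disease]
        if disease not in g:
            return set()
        return {disease} | nx.descendants(g, disease)


# ---------------------------------------------------------------------------
# matrix tables


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_association_table(path) -> AssociationMatrix:
    """Read a binary miRNA x disease TSV (disease ids in the header, miRNA
    ids in the first column, cells 0/1)."""
    df = _read_table(path)
    mirnas = _check_unique(df.index, "miRNA")
    diseases = _check_unique(df.columns, "disease")
    values = np.empty(df.shape, dtype=np.float64)
    for i, m in enumerate(mirnas):
        for j, d in enumerate(diseases):
            cell = df.iat[i, j]
            if str(cell).strip() not in ("0", "1"):
                raise FormatError(
                    f"non-binary cell {cell!r} at miRNA {m!r}, disease {d!r}"
                )
            values[i, j] = float(cell)
    return AssociationMatrix(values, EntityIndex(tuple(mirnas), tuple(diseases)))


def write_association_table(assoc: AssociationMatrix, path) -> None:
    df = pd.DataFrame(
        assoc.values.astype(int),
        index=list(assoc.index.mirna_ids),
        columns=list(assoc.index.disease_ids),
    )
    df.to_csv(path, sep="\t")


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a generic real-valued TSV matrix with id header/column."""
    df = _read_table(path)
    rows = _check_unique(df.index, "row")
    cols = _check_unique(df.columns, "column")
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    return values, rows, cols


def write_matrix(values: np.ndarray, row_ids, col_ids, path) -> None:
    pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t"
    )


def read_similarity_table(path, view_name: str = "", expected_ids=None) -> SimilarityMatrix:
    """Read a square similarity TSV; loaded matrices are symmetrized and
    clipped to [0, 1] on ingest."""
    values, rows, cols = read_matrix(path)
    if rows != cols:
        raise IngestError(f"similarity table {path} row/column ids differ")
    if expected_ids is not None and rows != [str(i) for i in expected_ids]:
        raise IngestError(f"similarity table {path} ids do not match the entity index")
    return SimilarityMatrix.from_loaded(values, rows, view_name or str(path))


# ---------------------------------------------------------------------------
# sequences and families

_RNA = set("ACGU")


def read_fasta(path) -> dict[str, str]:
    """Read miRNA sequences; DNA-style T is normalized to U, case folded up."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise IngestError(f"duplicate FASTA record id {rec.id!r}")
        seq = str(rec.seq).upper().replace("T", "U")
        if not seq:
            raise IngestError(f"empty sequence for record {rec.id!r}")
        bad = set(seq) - _RNA
        if bad:
            raise IngestError(
                f"illegal character(s) {sorted(bad)} in record {rec.id!r}"
            )
        sequences[rec.id] = seq
    return sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=m, description="") for m, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_family_table(path) -> dict[str, str]:
    """Two-column TSV (miRNA id, family id); miRNAs absent from the file are
    simply unannotated."""
    df = pd.read_csv(path, sep="\t", header=None, names=["mirna", "family"], dtype=str)
    families: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.mirna in families:
            raise IngestError(f"duplicate family annotation for {row.mirna!r}")
        families[str(row.mirna)] = str(row.family)
    return families


def write_family_table(families: dict[str, str], path) -> None:
    pd.DataFrame(sorted(families.items())).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# disease DAGs


def read_dag_edges(path, disease_ids) -> DiseaseDAGSet:
    """Read (disease_id, child_term, parent_term) rows into per-disease DAGs.

    Diseases listed in `disease_ids` but absent from the file get an empty
    DAG (their semantic similarity to every other disease is 0).
    """
    disease_ids = [str(d) for d in disease_ids]
    known = set(disease_ids)
    graphs: dict[str, nx.DiGraph] = {d: nx.DiGraph() for d in disease_ids}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["disease", "child", "parent"], dtype=str
    )
    for row in df.itertuples(index=False):
        d = str(row.disease)
        if d not in known:
            raise IngestError(f"DAG edge references unknown disease {d!r}")
        graphs[d].add_edge(str(row.child), str(row.parent))
    for d, g in graphs.items():
        if g.number_of_nodes() and not nx.is_directed_acyclic_graph(g):
            raise IngestError(f"cycle detected in the DAG of disease {d!r}")
        if g.number_of_nodes():
            g.add_node(d)  # ensure the disease's own term is present
    return DiseaseDAGSet(graphs)


def write_dag_edges(dag_set: DiseaseDAGSet, path) -> None:
    rows = []
    for d in dag_set.graphs:
        for child, parent in sorted(dag_set.graphs[d].edges):
            rows.append((d, child, parent))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# predictions


def write_predictions(scores: np.ndarray, index: EntityIndex, path) -> None:
    """Write per-disease descending rankings of all miRNAs.

    Ties are broken by lexicographically smaller miRNA id.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (index.n_mirna, index.n_disease):
        raise ContractError(
            f"score matrix shape {scores.shape} does not match the index"
        )
    if scores.min() < 0 or scores.max() > 1:
        raise ContractError("prediction scores must lie in [0, 1]")
    rows = []
    for j, d in enumerate(index.disease_ids):
        order = sorted(
            range(index.n_mirna),
            key=lambda i: (-scores[i, j], index.mirna_ids[i]),
        )
        for rank, i in enumerate(order, start=1):
            rows.append((index.mirna_ids[i], d, scores[i, j], rank))
    pd.DataFrame(rows, columns=["mirna", "disease", "score", "rank"]).to_csv(
        path, index=False
    )


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"mirna": str, "disease": str})


# ---------------------------------------------------------------------------
# input bundles


@dataclass
class InputBundle:
    """Everything the pipeline consumes, in memory: the association matrix,
    miRNA sequences/families, disease DAGs, the loaded functional-similarity
    matrix, and the two lncRNA interaction matrices."""

    index: EntityIndex
    associations: AssociationMatrix
    sequences: dict[str, str]
    families: dict[str, str]
    dag_set: DiseaseDAGSet
    functional: SimilarityMatrix
    mirna_lnc: np.ndarray
    disease_lnc: np.ndarray
    lnc_ids: tuple[str, ...]


_BUNDLE_FILES = {
    "associations": "associations.tsv",
    "sequences": "sequences.fasta",
    "families": "families.tsv",
    "dags": "disease_dags.tsv",
    "functional": "functional_similarity.tsv",
    "mirna_lnc": "mirna_lncrna.tsv",
    "disease_lnc": "disease_lncrna.tsv",
}


def save_bundle(bundle: InputBundle, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_association_table(bundle.associations, d / _BUNDLE_FILES["associations"])
    write_fasta(bundle.sequences, d / _BUNDLE_FILES["sequences"])
    write_family_table(bundle.families, d / _BUNDLE_FILES["families"])
    write_dag_edges(bundle.dag_set, d / _BUNDLE_FILES["dags"])
    write_matrix(
        bundle.functional.values,
        bundle.index.mirna_ids,
        bundle.index.mirna_ids,
        d / _BUNDLE_FILES["functional"],
    )
    write_matrix(
        bundle.mirna_lnc.astype(int),
        bundle.index.mirna_ids,
        bundle.lnc_ids,
        d / _BUNDLE_FILES["mirna_lnc"],
    )
    write_matrix(
        bundle.disease_lnc.astype(int),
        bundle.index.disease_ids,
        bundle.lnc_ids,
        d / _BUNDLE_FILES["disease_lnc"],
    )


def load_bundle(directory) -> InputBundle:
    d = Path(directory)
    assoc = read_association_table(d / _BUNDLE_FILES["associations"])
    index = assoc.index
    sequences = read_fasta(d / _BUNDLE_FILES["sequences"])
    families = read_family_table(d / _BUNDLE_FILES["families"])
    dag_set = read_dag_edges(d / _BUNDLE_FILES["dags"], index.disease_ids)
    functional = read_similarity_table(
        d / _BUNDLE_FILES["functional"], "functional", expected_ids=index.mirna_ids
    )
    m_lnc, m_rows, lnc_ids = read_matrix(d / _BUNDLE_FILES["mirna_lnc"])
    d_lnc, d_rows, lnc_ids2 = read_matrix(d / _BUNDLE_FILES["disease_lnc"])
    if tuple(m_rows) != index.mirna_ids or tuple(d_rows) != index.disease_ids:
        raise IngestError("lncRNA matrix row ids do not match the entity index")
    if lnc_ids != lnc_ids2:
        raise IngestError("lncRNA column ids differ between the two matrices")
    return InputBundle(
        index=index,
        associations=assoc,
        sequences=sequences,
        families=families,
        dag_set=dag_set,
        functional=functional,
        mirna_lnc=m_lnc,
        disease_lnc=d_lnc,
        lnc_ids=tuple(lnc_ids),
    )
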