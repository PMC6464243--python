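"""Readers, writers and the typed containers every other module consumes.

The external artifacts are deliberately plain text: association tables as
TSV/CSV, miRNA sequences as FASTA, the disease hierarchy as (name, dotted
tree number) rows or MeSH ASCII descriptor records, and similarity
matrices as labelled CSV. Everything is validated on the way in so that
downstream code can assume clean registries and well-formed matrices.

Conventions shared by all containers:

* registries (disease and miRNA name lists) are sorted lexicographically
  by their case-folded form, so matrix layouts are reproducible;
* name matching trims whitespace and case-folds, with no fuzzy matching;
* the association matrix is oriented rows = diseases, columns = miRNAs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, DataError, UnknownEntityError

logger = logging.getLogger(__name__)

_TREE_NUMBER_RE = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+)*$")
_RNA_ALPHABET = frozenset("ACGU")


def _norm(name: str) -> str:
    return name.strip().casefold()


def _sorted_registry(names) -> list[str]:
    """Unique names sorted by case-folded form (stable, reproducible)."""
    seen: dict[str, str] = {}
    for raw in names:
        stripped = str(raw).strip()
        key = stripped.casefold()
        if key and key not in seen:
            seen[key] = stripped
    return [seen[k] for k in sorted(seen)]


@dataclass
class AssociationSet:
    """Binary disease x miRNA adjacency matrix with name registries.

    ``ad[i, j] == 1`` iff disease ``diseases[i]`` is associated with miRNA
    ``mirnas[j]``. Rows are interaction profiles of diseases, columns are
    interaction profiles of miRNAs.
    """

    diseases: list[str]
    mirnas: list[str]
    ad: np.ndarray

    def __post_init__(self) -> None:
        self.ad = np.asarray(self.ad)
        if self.ad.shape != (len(self.diseases), len(self.mirnas)):
            raise DataError(
                f"adjacency shape {self.ad.shape} does not match registries "
                f"({len(self.diseases)} diseases, {len(self.mirnas)} miRNAs)"
            )
        if not np.isin(self.ad, (0, 1)).all():
            raise DataError("adjacency entries must be 0 or 1")
        self._d_index = {_norm(d): i for i, d in enumerate(self.diseases)}
        self._m_index = {_norm(m): j for j, m in enumerate(self.mirnas)}
        if len(self._d_index) != len(self.diseases):
            raise DataError("duplicate disease names after normalization")
        if len(self._m_index) != len(self.mirnas):
            raise DataError("duplicate miRNA names after normalization")

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    def disease_index(self, name: str) -> int:
        try:
            return self._d_index[_norm(name)]
        except KeyError:
            raise UnknownEntityError(f"unknown disease: {name!r}") from None

    def mirna_index(self, name: str) -> int:
        try:
            return self._m_index[_norm(name)]
        except KeyError:
            raise UnknownEntityError(f"unknown miRNA: {name!r}") from None

    def positive_pairs(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.ad)
        return [(self.diseases[i], self.mirnas[j]) for i, j in zip(rows, cols)]


@dataclass
class SequenceSet:
    """miRNA name -> RNA sequence (uppercase, alphabet ACGU)."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.records.items():
            if not seq:
                raise DataError(f"empty sequence for record {name!r}")
            bad = set(seq) - _RNA_ALPHABET
            if bad:
                raise DataError(
                    f"record {name!r} contains non-ACGU letters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def names(self) -> list[str]:
        return list(self.records)


@dataclass
class DiseaseOntology:
    """Disease name -> set of dotted tree numbers, plus corpus-level terms.

    ``dag_counts`` (how many per-disease ancestor graphs contain a node) and
    ``ic_values`` (information-content contribution of a node) start unset
    and are filled in by the semantic-similarity computation.
    """

    tree_numbers: dict[str, set[str]]
    num_diseases: int | None = None
    dag_counts: dict[str, int] = field(default_factory=dict)
    ic_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._lookup = {_norm(name): name for name in self.tree_numbers}
        owners: dict[str, str] = {}
        for name, numbers in self.tree_numbers.items():
            for tn in numbers:
                if not _TREE_NUMBER_RE.match(tn):
                    raise DataError(f"malformed tree number {tn!r} for {name!r}")
                if tn in owners and owners[tn] != name:
                    logger.warning(
                        "tree number %s claimed by both %r and %r; keeping %r",
                        tn, owners[tn], name, owners[tn],
                    )
                else:
                    owners[tn] = name
        self._owner_of = owners

    def __contains__(self, name: str) -> bool:
        return _norm(name) in self._lookup

    def numbers_for(self, name: str) -> set[str]:
        try:
            return self.tree_numbers[self._lookup[_norm(name)]]
        except KeyError:
            raise UnknownEntityError(f"disease {name!r} not in ontology") from None

    def owner_of(self, tree_number: str) -> str | None:
        """Disease name owning a tree number, or None if unclaimed."""
        return self._owner_of.get(tree_number)


@dataclass
class NamedMatrix:
    """Real matrix with ordered row/column label registries."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match labels "
                f"({len(self.row_labels)} x {len(self.col_labels)})"
            )
        self._r = {_norm(x): i for i, x in enumerate(self.row_labels)}
        self._c = {_norm(x): j for j, x in enumerate(self.col_labels)}

    @property
    def is_square(self) -> bool:
        return self.values.shape[0] == self.values.shape[1]

    def row_index(self, label: str) -> int:
        try:
            return self._r[_norm(label)]
        except KeyError:
            raise UnknownEntityError(f"unknown row label: {label!r}") from None

    def col_index(self, label: str) -> int:
        try:
            return self._c[_norm(label)]
        except KeyError:
            raise UnknownEntityError(f"unknown column label: {label!r}") from None

    def has_row(self, label: str) -> bool:
        return _norm(label) in self._r

    def loc(self, row: str, col: str) -> float:
        return float(self.values[self.row_index(row), self.col_index(col)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.row_labels,
                     columns=self.col_labels).to_csv(path)


def read_association_table(path, disease_col: str, mirna_col: str) -> AssociationSet:
    """Load a one-pair-per-row association table into an AssociationSet.

    The matrix entry is 1 iff the pair appears at least once; duplicated
    rows are collapsed with a logged warning. Registries come out sorted
    lexicographically regardless of input row order.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError:
        raise DataError(f"association table {path} is empty") from None
    for col in (disease_col, mirna_col):
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path}; available: {list(df.columns)}"
            )
    if df.empty:
        raise DataError(f"association table {path} has no data rows")
    pairs = {( _norm(d), _norm(m)): (str(d).strip(), str(m).strip())
             for d, m in zip(df[disease_col], df[mirna_col])}
    if len(pairs) < len(df):
        logger.warning("%d duplicated association rows collapsed in %s",
                       len(df) - len(pairs), path)
    diseases = _sorted_registry(d for d, _ in pairs.values())
    mirnas = _sorted_registry(m for _, m in pairs.values())
    d_idx = {_norm(d): i for i, d in enumerate(diseases)}
    m_idx = {_norm(m): j for j, m in enumerate(mirnas)}
    ad = np.zeros((len(diseases), len(mirnas)), dtype=np.int8)
    for dk, mk in pairs:
        ad[d_idx[dk], m_idx[mk]] = 1
    return AssociationSet(diseases, mirnas, ad)


def read_fasta(path) -> SequenceSet:
    """Read miRNA sequences from FASTA; T is transliterated to U.

    Record names are the header token up to the first whitespace. Sequences
    are upper-cased; anything outside {A,C,G,U} after T->U is rejected.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if _norm(name) in {_norm(n) for n in records}:
            raise DataError(f"duplicate FASTA record name {name!r}")
        seq = str(rec.seq).upper().replace("T", "U")
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise DataError(
                f"FASTA record {name!r} contains invalid letters {sorted(bad)}"
            )
        records[name.strip()] = seq
    return SequenceSet(records)


def read_ontology(path, dialect: str = "tsv") -> DiseaseOntology:
    """Read a disease hierarchy as name <-> dotted tree-number pairs.

    ``tsv``: two tab-separated columns (name, tree number), no header, one
    row per pair. ``mesh_ascii``: MeSH ASCII descriptor records where MH
    lines carry the name and MN lines the tree numbers.
    """
    tree_numbers: dict[str, set[str]] = {}

    def add(name: str, tn: str, lineno: int) -> None:
        tn = tn.strip()
        if not _TREE_NUMBER_RE.match(tn):
            raise DataError(f"{path}:{lineno}: malformed tree number {tn!r}")
        tree_numbers.setdefault(name.strip(), set()).add(tn)

    with open(path, encoding="utf-8") as fh:
        if dialect == "tsv":
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise DataError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, "
                        f"got {len(parts)}"
                    )
                add(parts[0], parts[1], lineno)
        elif dialect == "mesh_ascii":
            current: str | None = None
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if line.startswith("MH = "):
                    current = line[5:].strip()
                elif line.startswith("MN = "):
                    if current is None:
                        raise DataError(f"{path}:{lineno}: MN line before MH")
                    add(current, line[5:], lineno)
                elif line.strip() == "*NEWRECORD":
                    current = None
        else:
            raise ConfigurationError(f"unknown ontology dialect {dialect!r}")
    return DiseaseOntology(tree_numbers)


def read_named_matrix(path) -> NamedMatrix:
    """Read a labelled CSV matrix (header = column labels, col 0 = row labels).

    Square matrices are checked for symmetry; violations beyond 1e-9 are
    kept but flagged with a warning, matching the contract that producers
    document their own diagonal/symmetry guarantees.
    """
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError:
        raise DataError(f"matrix file {path} is empty") from None
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise DataError(
                        f"{path}: non-numeric cell at row {i + 1}, column "
                        f"{j + 1}: {cell!r}"
                    ) from None
        raise
    mat = NamedMatrix([str(x) for x in df.index],
                      [str(x) for x in df.columns], values)
    if mat.is_square and not np.allclose(values, values.T, atol=1e-9):
        logger.warning("matrix %s is not symmetric within 1e-9", path)
    return mat


def write_predictions(path, rows: list[tuple[str, str, float]]) -> None:
    """Write (disease, miRNA, score) rows as TSV, six-decimal scores.

    Rows are sorted by descending score, ties broken by (disease, miRNA)
    name so the output is deterministic.
    """
    for d, m, s in rows:
        if not 0.0 <= s <= 1.0:
            raise DataError(f"score {s} for ({d}, {m}) outside [0, 1]")
    ordered = sorted(rows, key=lambda r: (-round(r[2], 6), r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease\tmirna\tscore\n")
        for d, m, s in ordered:
            fh.write(f"{d}\t{m}\t{s:.6f}\n")


def read_predictions(path) -> list[tuple[str, str, float]]:
    """Inverse of write_predictions (used for round-trip checks)."""
    df = pd.read_csv(path, sep="\t")
    return [(str(d), str(m), float(s))
            for d, m, s in zip(df["disease"], df["mirna"], df["score"])]
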