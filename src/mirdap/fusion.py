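"""Fusion of similarity sources into per-pair feature descriptors.

Disease similarity (DSim) averages the two semantic models when both
diseases have ontology coverage and otherwise falls back to the
interaction-profile kernel. miRNA similarity (RSim) uses the precomputed
functional-similarity matrix when both miRNAs are covered by it,
otherwise the kernel. The descriptor of a (disease, miRNA) pair is the
concatenation [DSim row of the disease | RSim column of the miRNA |
pooled sequence embedding of the miRNA], giving width
n_diseases + n_mirnas + embedding_size; two ablations drop the sequence
block ("DescSim") or the miRNA-similarity block ("DescSeq").

Negative pairs are sampled uniformly without replacement from the zero
cells of the adjacency matrix, disjoint from the positives by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError
from .io_formats import AssociationSet, NamedMatrix

ABLATION_MODES = ("full", "DescSeq", "DescSim")


@dataclass
class FusedSimilarity:
    """DSim/RSim matrices plus per-entry provenance flags."""

    dsim: NamedMatrix
    rsim: NamedMatrix
    dsim_provenance: np.ndarray  # "semantic" | "gip"
    rsim_provenance: np.ndarray  # "functional" | "gip"


def fuse_disease_similarity(
    sv1: NamedMatrix,
    sv2: NamedMatrix,
    gd: NamedMatrix,
    has_semantic: dict[str, bool],
) -> tuple[NamedMatrix, np.ndarray]:
    """DSim over the full disease registry of the kernel matrix.

    Entry = (SV1 + SV2) / 2 when both diseases are ontology-covered, else
    the kernel entry; the provenance array records which branch fired.
    """
    diseases = gd.row_labels
    unknown = [d for d in has_semantic if not gd.has_row(d)]
    if unknown:
        raise ConfigurationError(
            f"coverage flags name diseases outside the kernel registry: {unknown}"
        )
    n = len(diseases)
    out = np.array(gd.values, dtype=float)
    prov = np.full((n, n), "gip", dtype=object)
    covered_idx = [(i, d) for i, d in enumerate(diseases) if has_semantic.get(d, False)]
    for i, di in covered_idx:
        a = sv1.row_index(di)
        for j, dj in covered_idx:
            b = sv1.col_index(dj)
            out[i, j] = (sv1.values[a, b] + sv2.values[a, b]) / 2.0
            prov[i, j] = "semantic"
    return NamedMatrix(list(diseases), list(diseases), out), prov


def fuse_mirna_similarity(
    rf: NamedMatrix | None,
    gr: NamedMatrix,
    covered: set[str] | None = None,
) -> tuple[NamedMatrix, np.ndarray]:
    """RSim over the full miRNA registry of the kernel matrix.

    Entry = functional similarity when both miRNAs are present in the
    functional matrix (and flagged covered), else the kernel entry.
    """
    mirnas = gr.row_labels
    n = len(mirnas)
    out = np.array(gr.values, dtype=float)
    prov = np.full((n, n), "gip", dtype=object)
    if rf is not None:
        in_rf = [
            (i, m) for i, m in enumerate(mirnas)
            if rf.has_row(m) and (covered is None or m in covered)
        ]
        for i, mi in in_rf:
            a = rf.row_index(mi)
            for j, mj in in_rf:
                b = rf.col_index(mj)
                out[i, j] = rf.values[a, b]
                prov[i, j] = "functional"
    return NamedMatrix(list(mirnas), list(mirnas), out), prov


def fuse(sv1, sv2, gd, has_semantic, rf, gr, covered=None) -> FusedSimilarity:
    dsim, dprov = fuse_disease_similarity(sv1, sv2, gd, has_semantic)
    rsim, rprov = fuse_mirna_similarity(rf, gr, covered)
    return FusedSimilarity(dsim=dsim, rsim=rsim,
                           dsim_provenance=dprov, rsim_provenance=rprov)


def _feature_blocks(mode: str, d_row, r_col, r_seq) -> np.ndarray:
    if mode == "full":
        return np.concatenate([d_row, r_col, r_seq])
    if mode == "DescSeq":  # disease similarity + sequence only
        return np.concatenate([d_row, r_seq])
    if mode == "DescSim":  # disease similarity + miRNA similarity only
        return np.concatenate([d_row, r_col])
    raise ConfigurationError(f"unknown ablation mode {mode!r}; "
                             f"expected one of {ABLATION_MODES}")


def build_feature_vector(
    disease: str,
    mirna: str,
    dsim: NamedMatrix,
    rsim: NamedMatrix,
    rseq: NamedMatrix,
    mode: str = "full",
) -> np.ndarray:
    """Descriptor of one pair: [DSim row | RSim column | RSeq row]."""
    i = dsim.row_index(disease)
    j = rsim.col_index(mirna)
    k = rseq.row_index(mirna)
    return _feature_blocks(mode, dsim.values[i, :], rsim.values[:, j],
                           rseq.values[k, :])


def feature_width(mode: str, n_diseases: int, n_mirnas: int, size: int) -> int:
    return {"full": n_diseases + n_mirnas + size,
            "DescSeq": n_diseases + size,
            "DescSim": n_diseases + n_mirnas}[mode]


def sample_negatives(
    assoc: AssociationSet, count: int, seed: int
) -> list[tuple[str, str]]:
    """Uniform sample, without replacement, of unassociated pairs.

    Seeded and reproducible; never overlaps the positive cells.
    """
    zeros_flat = np.flatnonzero(assoc.ad == 0)
    if count > zeros_flat.size:
        raise ConfigurationError(
            f"requested {count} negatives but only {zeros_flat.size} "
            "unassociated pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zeros_flat, size=count, replace=False)
    n = assoc.n_mirnas
    return [(assoc.diseases[idx // n], assoc.mirnas[idx % n]) for idx in chosen]


@dataclass
class FeatureTable:
    """Labelled per-pair descriptors ready for a classifier."""

    pairs: list[tuple[str, str]]
    labels: np.ndarray
    features: np.ndarray
    mode: str = "full"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features.shape[0] != len(self.pairs) or \
                self.labels.shape[0] != len(self.pairs):
            raise DataError("rows, labels and pairs must align")
        if len(set(self.pairs)) != len(self.pairs):
            raise DataError("duplicate (disease, miRNA) pair in feature table")

    @property
    def feature_width(self) -> int:
        return self.features.shape[1]


def assemble_dataset(
    positives: list[tuple[str, str]],
    negatives: list[tuple[str, str]],
    dsim: NamedMatrix,
    rsim: NamedMatrix,
    rseq: NamedMatrix,
    mode: str = "full",
    seed: int | None = None,
    reduce_to: int | None = None,
) -> FeatureTable:
    """Stack positive and negative pairs into one shuffled feature table.

    ``reduce_to`` optionally appends a principal-component reduction of
    the descriptor block (off by default; the classifier consumes the raw
    fused descriptor).
    """
    overlap = set(positives) & set(negatives)
    if overlap:
        raise DataError(f"positive/negative lists overlap: {sorted(overlap)[:3]}")
    pairs = list(positives) + list(negatives)
    labels = np.concatenate([np.ones(len(positives), dtype=int),
                             np.zeros(len(negatives), dtype=int)])

    d_idx = np.array([dsim.row_index(d) for d, _ in pairs])
    m_idx = np.array([rsim.col_index(m) for _, m in pairs])
    s_idx = np.array([rseq.row_index(m) for _, m in pairs])
    blocks = []
    if mode in ("full", "DescSeq", "DescSim"):
        blocks.append(dsim.values[d_idx, :])
    else:
        raise ConfigurationError(f"unknown ablation mode {mode!r}")
    if mode in ("full", "DescSim"):
        blocks.append(rsim.values[:, m_idx].T)
    if mode in ("full", "DescSeq"):
        blocks.append(rseq.values[s_idx, :])
    features = np.hstack(blocks)

    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(pairs))
        pairs = [pairs[i] for i in order]
        labels = labels[order]
        features = features[order]

    meta = {"mode": mode, "seed": seed, "n_positives": len(positives),
            "n_negatives": len(negatives)}
    if reduce_to is not None:
        from sklearn.decomposition import PCA

        keep = min(reduce_to, features.shape[1], features.shape[0])
        pca = PCA(n_components=keep, random_state=seed or 0)
        features = pca.fit_transform(features)
        meta["reduced_to"] = keep
    return FeatureTable(pairs=pairs, labels=labels, features=features,
                        mode=mode, metadata=meta)
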