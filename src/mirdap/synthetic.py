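"""Synthetic inputs with planted cluster structure.

The generator emulates the statistical shape of the real inputs of the
pipeline — a disease hierarchy, mature-miRNA-scale sequences, a sparse
binary association matrix and a partially covering functional-similarity
matrix — with one shared cluster structure so that every feature block
independently carries signal:

* diseases in the same cluster share a deep common ancestor in the
  generated tree-number hierarchy, diseases in different clusters share
  only the root;
* miRNAs in the same cluster carry the cluster's planted sequence motif
  at a random offset inside otherwise uniform random RNA;
* associations follow a block model, Bernoulli(p_in) inside matched
  clusters and Bernoulli(p_out) elsewhere;
* functional similarity is drawn high within clusters and low between,
  for the covered fraction of miRNAs only.

Everything is driven by one seed, so identical configs reproduce
identical artifacts byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .io_formats import AssociationSet, DiseaseOntology, NamedMatrix, SequenceSet

RNA = "ACGU"


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic benchmark.

    Defaults give 5 aligned clusters over 40 diseases x 60 miRNAs, a
    within-block association rate of 0.6 against a 0.05 background,
    20-25 nt sequences with an 8 nt planted motif, functional-similarity
    coverage of 60% of miRNAs, and a 4-level hierarchy.
    """

    n_diseases: int = 40
    n_mirnas: int = 60
    n_clusters: int = 5
    p_in: float = 0.6
    p_out: float = 0.05
    seq_len_range: tuple[int, int] = (20, 25)
    motif_len: int = 8
    functional_coverage: float = 0.6
    ontology_depth: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ConfigurationError("need 0 <= p_out < p_in <= 1")
        if self.n_clusters > min(self.n_diseases, self.n_mirnas):
            raise ConfigurationError("more clusters than entities")
        if self.motif_len >= self.seq_len_range[0]:
            raise ConfigurationError("motif must be shorter than any sequence")


def _cluster_assignment(n: int, k: int) -> np.ndarray:
    """Contiguous, near-equal cluster labels for n entities."""
    return np.array([i * k // n for i in range(n)])


def disease_names(config: SyntheticConfig) -> list[str]:
    return [f"disease_{i:03d}" for i in range(config.n_diseases)]


def mirna_names(config: SyntheticConfig) -> list[str]:
    return [f"mir-{i:03d}" for i in range(config.n_mirnas)]


def disease_clusters(config: SyntheticConfig) -> dict[str, int]:
    labels = _cluster_assignment(config.n_diseases, config.n_clusters)
    return dict(zip(disease_names(config), labels.tolist()))


def mirna_clusters(config: SyntheticConfig) -> dict[str, int]:
    labels = _cluster_assignment(config.n_mirnas, config.n_clusters)
    return dict(zip(mirna_names(config), labels.tolist()))


def generate_ontology(config: SyntheticConfig) -> DiseaseOntology:
    """Rooted tree-number hierarchy aligned with the disease clusters.

    Leaf tree numbers have ``ontology_depth`` dotted segments. With depth
    1 every disease is its own root (no shared ancestors at all);
    otherwise all diseases share the root segment, and cluster members
    additionally share every intermediate segment, giving them a common
    ancestor at depth ``ontology_depth - 1``.
    """
    depth = config.ontology_depth
    clusters = disease_clusters(config)
    tree_numbers: dict[str, set[str]] = {}
    if depth == 1:
        for i, name in enumerate(disease_names(config)):
            tree_numbers[name] = {f"C{i + 1:03d}"}
        return DiseaseOntology(tree_numbers)
    tree_numbers["root_disease"] = {"C01"}
    if depth == 2:  # shared root only; clusters are invisible to the hierarchy
        for i, name in enumerate(disease_names(config)):
            tree_numbers[name] = {f"C01.{i + 1:03d}"}
        return DiseaseOntology(tree_numbers)
    for c in range(config.n_clusters):
        prefix = f"C01.{c + 1:02d}"
        tree_numbers[f"branch_{c:02d}"] = {prefix}
        for level in range(3, depth):  # chain of per-cluster mid levels
            prefix = prefix + ".S"
            tree_numbers[f"branch_{c:02d}_l{level}"] = {prefix}
    for i, name in enumerate(disease_names(config)):
        c = clusters[name]
        prefix = f"C01.{c + 1:02d}" + ".S" * (depth - 3)
        tree_numbers[name] = {f"{prefix}.{i + 1:03d}"}
    return DiseaseOntology(tree_numbers)


def cluster_motifs(config: SyntheticConfig) -> list[str]:
    """One planted motif per cluster, drawn from the bundle seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    return ["".join(rng.choice(list(RNA), size=config.motif_len))
            for _ in range(config.n_clusters)]


def generate_sequences(config: SyntheticConfig) -> SequenceSet:
    """Uniform random RNA with each cluster's motif planted in all members."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 102]))
    motifs = cluster_motifs(config)
    clusters = mirna_clusters(config)
    lo, hi = config.seq_len_range
    records = {}
    for name in mirna_names(config):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list(RNA), size=length))
        motif = motifs[clusters[name]]
        offset = int(rng.integers(0, length - len(motif) + 1))
        seq[offset:offset + len(motif)] = list(motif)
        records[name] = "".join(seq)
    return SequenceSet(records)


def generate_associations(
    config: SyntheticConfig,
    d_clusters: dict[str, int] | None = None,
    m_clusters: dict[str, int] | None = None,
) -> AssociationSet:
    """Block-model binary adjacency: Bernoulli(p_in) within matched clusters."""
    d_clusters = d_clusters or disease_clusters(config)
    m_clusters = m_clusters or mirna_clusters(config)
    diseases = sorted(d_clusters)
    mirnas = sorted(m_clusters)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 103]))
    d_lab = np.array([d_clusters[d] for d in diseases])
    m_lab = np.array([m_clusters[m] for m in mirnas])
    same = d_lab[:, None] == m_lab[None, :]
    p = np.where(same, config.p_in, config.p_out)
    ad = (rng.random(p.shape) < p).astype(np.int8)
    return AssociationSet(diseases, mirnas, ad)


def generate_functional_similarity(
    config: SyntheticConfig,
    m_clusters: dict[str, int] | None = None,
) -> tuple[NamedMatrix, set[str]]:
    """Noisy within/between-cluster similarity over a covered miRNA subset.

    Within-cluster entries centre on 0.8, between-cluster on 0.2 (sd 0.1,
    clipped to [0, 1]); the matrix is symmetrized with unit diagonal and
    covers only a ``functional_coverage`` fraction of miRNAs, emulating a
    precomputed similarity resource that misses part of the registry.
    """
    m_clusters = m_clusters or mirna_clusters(config)
    mirnas = sorted(m_clusters)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104]))
    n_cov = int(round(config.functional_coverage * len(mirnas)))
    covered = sorted(rng.choice(mirnas, size=n_cov, replace=False).tolist())
    lab = np.array([m_clusters[m] for m in covered])
    same = lab[:, None] == lab[None, :]
    mean = np.where(same, 0.8, 0.2)
    vals = np.clip(rng.normal(mean, 0.1), 0.0, 1.0)
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return NamedMatrix(covered, covered, vals), set(covered)


@dataclass
class SyntheticBundle:
    """All four generated inputs plus the shared cluster assignments."""

    config: SyntheticConfig
    ontology: DiseaseOntology
    sequences: SequenceSet
    associations: AssociationSet
    functional: NamedMatrix
    functional_covered: set[str]
    disease_clusters: dict[str, int] = field(default_factory=dict)
    mirna_clusters: dict[str, int] = field(default_factory=dict)


def generate_bundle(config: SyntheticConfig | None = None) -> SyntheticBundle:
    config = config or SyntheticConfig()
    d_cl = disease_clusters(config)
    m_cl = mirna_clusters(config)
    functional, covered = generate_functional_similarity(config, m_cl)
    return SyntheticBundle(
        config=config,
        ontology=generate_ontology(config),
        sequences=generate_sequences(config),
        associations=generate_associations(config, d_cl, m_cl),
        functional=functional,
        functional_covered=covered,
        disease_clusters=d_cl,
        mirna_clusters=m_cl,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Write the four artifacts in the exact dialects the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": str(outdir / "associations.tsv"),
        "sequences": str(outdir / "sequences.fasta"),
        "ontology": str(outdir / "ontology.tsv"),
        "functional": str(outdir / "functional_similarity.csv"),
    }
    with open(paths["associations"], "w", encoding="utf-8") as fh:
        fh.write("disease\tmirna\n")
        for d, m in bundle.associations.positive_pairs():
            fh.write(f"{d}\t{m}\n")
    with open(paths["sequences"], "w", encoding="utf-8") as fh:
        for name in bundle.sequences.names():
            fh.write(f">{name}\n{bundle.sequences.records[name]}\n")
    with open(paths["ontology"], "w", encoding="utf-8") as fh:
        for name in sorted(bundle.ontology.tree_numbers):
            for tn in sorted(bundle.ontology.tree_numbers[name]):
                fh.write(f"{name}\t{tn}\n")
    bundle.functional.to_csv(paths["functional"])
    return paths


def make_xor_blobs(n: int = 400, seed: int = 0, std: float = 0.25
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Four Gaussian blobs at (+-1, +-1) with XOR labels.

    Not linearly separable: a benchmark where a single logistic model is
    at chance while an axis-split tree with node models succeeds.
    """
    rng = np.random.default_rng(seed)
    centers = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
    labels = np.array([0, 0, 1, 1])
    idx = rng.integers(0, 4, size=n)
    X = centers[idx] + rng.normal(scale=std, size=(n, 2))
    return X, labels[idx]
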