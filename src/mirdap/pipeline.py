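"""End-to-end orchestration: inputs -> features -> CV / ranking.

This module wires the stages together behind two entry points used by
the command-line tool, the test-suite and the reproduction script:
``build_features`` turns the four inputs into a labelled feature table,
``run_cv`` cross-validates a classifier on it, and ``run_rank`` trains
on everything and ranks candidate miRNAs for one disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .disease_semantics import SemanticConfig, semantic_similarity_matrices
from .embedding import SkipgramConfig, build_corpus, build_rseq, train_skipgram
from .evaluation import MetricsReport, cross_validate, rank_candidates
from .fusion import FeatureTable, assemble_dataset, fuse, sample_negatives
from .gip import disease_gip, mirna_gip
from .io_formats import AssociationSet, DiseaseOntology, NamedMatrix, SequenceSet
from .lmt import LMTConfig, make_classifier
from .synthetic import SyntheticBundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    """The four external artifacts, already parsed."""

    associations: AssociationSet
    sequences: SequenceSet
    ontology: DiseaseOntology
    functional: NamedMatrix | None = None
    functional_covered: set[str] | None = None

    @classmethod
    def from_bundle(cls, bundle: SyntheticBundle) -> "PipelineInputs":
        return cls(associations=bundle.associations,
                   sequences=bundle.sequences,
                   ontology=bundle.ontology,
                   functional=bundle.functional,
                   functional_covered=bundle.functional_covered)


@dataclass
class FeatureArtifacts:
    """Feature table plus the intermediate matrices that produced it."""

    table: FeatureTable
    dsim: NamedMatrix
    rsim: NamedMatrix
    rseq: NamedMatrix
    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]
    metadata: dict = field(default_factory=dict)


def build_features(
    inputs: PipelineInputs,
    mode: str = "full",
    k: int = 6,
    semantic_config: SemanticConfig | None = None,
    skipgram_config: SkipgramConfig | None = None,
    negatives_seed: int = 0,
    shuffle_seed: int | None = None,
    n_negatives: int | None = None,
) -> FeatureArtifacts:
    """Run similarities, embedding and fusion; assemble a balanced dataset.

    The number of negatives defaults to the number of known positives
    (balanced design); the skip-gram trains on the supplied FASTA.
    """
    assoc = inputs.associations
    semantic_config = semantic_config or SemanticConfig()
    skipgram_config = skipgram_config or SkipgramConfig()

    sem = semantic_similarity_matrices(inputs.ontology, assoc.diseases,
                                       semantic_config)
    gd = disease_gip(assoc)
    gr = mirna_gip(assoc)
    fused = fuse(sem.sv1, sem.sv2, gd.matrix, sem.has_semantic,
                 inputs.functional, gr.matrix, inputs.functional_covered)

    corpus = build_corpus(inputs.sequences, k=k)
    embedding = train_skipgram(corpus, skipgram_config)
    rseq_all = build_rseq(inputs.sequences, embedding, k=k)
    # align sequence rows to the association registry
    rows = np.stack([
        rseq_all.values[rseq_all.row_index(m)] if rseq_all.has_row(m)
        else np.zeros(embedding.size)
        for m in assoc.mirnas
    ])
    rseq = NamedMatrix(list(assoc.mirnas), list(rseq_all.col_labels), rows)

    positives = assoc.positive_pairs()
    count = len(positives) if n_negatives is None else n_negatives
    negatives = sample_negatives(assoc, count, seed=negatives_seed)
    table = assemble_dataset(positives, negatives, fused.dsim, fused.rsim,
                             rseq, mode=mode,
                             seed=shuffle_seed if shuffle_seed is not None
                             else negatives_seed)
    meta = {
        "mode": mode, "k": k,
        "n_positives": len(positives), "n_negatives": len(negatives),
        "total_samples": 2 * len(positives) if count == len(positives)
        else len(positives) + count,
        "feature_width": table.feature_width,
        "theta_disease": gd.theta, "theta_mirna": gr.theta,
        "embedding_vocabulary": embedding.metadata.get("vocabulary_size"),
        "negatives_seed": negatives_seed,
    }
    return FeatureArtifacts(table=table, dsim=fused.dsim, rsim=fused.rsim,
                            rseq=rseq, positives=positives,
                            negatives=negatives, metadata=meta)


def run_cv(
    inputs: PipelineInputs,
    classifier: str = "lmt",
    mode: str = "full",
    k_folds: int = 5,
    seed: int = 0,
    lmt_config: LMTConfig | None = None,
    permute_labels: bool = False,
    **feature_kwargs,
) -> tuple[MetricsReport, FeatureArtifacts]:
    """Full stage chain ending in stratified k-fold cross-validation.

    ``permute_labels`` shuffles the labels (seeded) before CV, giving the
    null benchmark a signal-free dataset of identical geometry.
    """
    feature_kwargs.setdefault("negatives_seed", seed)
    feature_kwargs.setdefault("skipgram_config", SkipgramConfig(seed=seed))
    artifacts = build_features(inputs, mode=mode, **feature_kwargs)
    table = artifacts.table
    if permute_labels:
        rng = np.random.default_rng(seed + 7919)
        table = FeatureTable(pairs=table.pairs,
                             labels=rng.permutation(table.labels),
                             features=table.features, mode=table.mode,
                             metadata={**table.metadata, "permuted": True})
    clf = make_classifier(classifier, seed=seed, config=lmt_config)
    report = cross_validate(table, clf, k=k_folds, seed=seed)
    return report, artifacts


def run_rank(
    inputs: PipelineInputs,
    disease: str,
    n: int = 30,
    classifier: str = "lmt",
    mode: str = "full",
    seed: int = 0,
    lmt_config: LMTConfig | None = None,
    include_known: bool = True,
    **feature_kwargs,
):
    """Train on all labelled pairs, then rank candidates for one disease."""
    feature_kwargs.setdefault("negatives_seed", seed)
    feature_kwargs.setdefault("skipgram_config", SkipgramConfig(seed=seed))
    artifacts = build_features(inputs, mode=mode, **feature_kwargs)
    clf = make_classifier(classifier, seed=seed, config=lmt_config)
    clf.fit(artifacts.table.features, artifacts.table.labels)
    ranking = rank_candidates(clf, disease, inputs.associations,
                              artifacts.dsim, artifacts.rsim, artifacts.rseq,
                              n=n, mode=mode, include_known=include_known)
    return ranking, artifacts
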