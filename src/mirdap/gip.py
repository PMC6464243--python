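"""Gaussian interaction-profile kernel similarity.

The interaction profile of a disease is its row of the binary adjacency
matrix; that of a miRNA is its column. Two entities are similar when
their profiles are close: ``exp(-theta * ||V_i - V_j||^2)``.

The width parameter is normalised by the mean squared profile norm,
``theta = theta' / ((1/m) * sum ||V_i||^2)`` with ``theta' = 1``, so the
kernel scale adapts to the density of the association matrix. A literal
variant ``theta = (1/m) * sum ||V_i||^2`` (no reciprocal) is available as
a switch since both conventions appear in the literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .io_formats import AssociationSet, NamedMatrix

logger = logging.getLogger(__name__)


@dataclass
class GIPResult:
    """Kernel matrix for one side of the bipartite network."""

    kind: str  # "disease" or "mirna"
    theta: float
    matrix: NamedMatrix


def gip_width(profiles: np.ndarray, literal: bool = False) -> float:
    """Kernel width from a stack of binary profiles (one per row).

    Default: reciprocal of the mean squared norm (normalised convention).
    ``literal=True``: the mean squared norm itself. An all-zero profile
    set degenerates to width 0 (similarity 1 everywhere) with a warning.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 1:
        raise ConfigurationError("profiles must be a non-empty 2-D array")
    mean_sq_norm = float((profiles ** 2).sum() / profiles.shape[0])
    if mean_sq_norm == 0.0:
        logger.warning("all-zero interaction profiles: width set to 0, "
                       "similarity degenerates to 1 everywhere")
        return 0.0
    return mean_sq_norm if literal else 1.0 / mean_sq_norm


def gip_similarity(profiles: np.ndarray, theta: float,
                   labels: list[str], kind: str) -> GIPResult:
    """Kernel matrix ``exp(-theta * ||V_i - V_j||^2)`` with exact unit diagonal."""
    if theta < 0:
        raise ConfigurationError(f"theta must be >= 0, got {theta}")
    profiles = np.asarray(profiles, dtype=float)
    gram = profiles @ profiles.T
    sq = np.diag(gram)
    d2 = sq[:, None] + sq[None, :] - 2.0 * gram
    np.maximum(d2, 0.0, out=d2)  # guard tiny negative rounding
    sim = np.exp(-theta * d2)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return GIPResult(kind=kind, theta=theta,
                     matrix=NamedMatrix(list(labels), list(labels), sim))


def disease_gip(assoc: AssociationSet, literal: bool = False) -> GIPResult:
    """Kernel over diseases (adjacency rows as profiles)."""
    theta = gip_width(assoc.ad, literal=literal)
    return gip_similarity(assoc.ad, theta, assoc.diseases, "disease")


def mirna_gip(assoc: AssociationSet, literal: bool = False) -> GIPResult:
    """Kernel over miRNAs (adjacency columns as profiles)."""
    theta = gip_width(assoc.ad.T, literal=literal)
    return gip_similarity(assoc.ad.T, theta, assoc.mirnas, "mirna")
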