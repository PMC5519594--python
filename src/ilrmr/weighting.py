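"""Confidence weight matrix for the sparse-error penalty.

W(i,j) averages two projections of the training network onto the
integrated similarities:

    W_mir(i,j) = <Sim_mir[i, :], X[:, j]> / ||X[:, j]||
    W_dd(i,j)  = <X[i, :], Sim_dd[:, j]> / ||X[i, :]||
    W(i,j)     = (W_mir(i,j) + W_dd(i,j)) / 2

W_mir is large when miRNA i is similar to the miRNAs already known to
interact with disease j; W_dd is large when disease j is similar to the
diseases miRNA i already interacts with.  The denominators are Euclidean
norms of the corresponding association-profile vectors; a profile with
no known interactions gives weight 0 by convention, which keeps W finite
for isolated rows and columns.  No rescaling to [0, 1] is applied — the
solver's sparsity parameter absorbs the global scale.
"""

from __future__ import annotations

import numpy as np

from .datatypes import AssociationMatrix, SimilarityMatrix, WeightMatrix

__all__ = [
    "mirna_weight",
    "disease_weight",
    "combine_weights",
    "build_weights",
    "penalty_weights",
]


def mirna_weight(sim_mir: SimilarityMatrix, assoc: AssociationMatrix) -> WeightMatrix:
    """miRNA-based weight: similarity of miRNA i to disease j's known interactors."""
    if sim_mir.ids != assoc.mirna_ids:
        raise ValueError("miRNA similarity ids do not match association miRNA ids")
    X = assoc.values
    col_norms = np.linalg.norm(X, axis=0)
    safe = np.where(col_norms > 0, col_norms, 1.0)
    w = (sim_mir.values @ X) / safe[None, :]
    w[:, col_norms == 0] = 0.0
    return WeightMatrix(w, list(assoc.mirna_ids), list(assoc.disease_ids))


def disease_weight(sim_dd: SimilarityMatrix, assoc: AssociationMatrix) -> WeightMatrix:
    """Disease-based weight: similarity of disease j to miRNA i's known interactors."""
    if sim_dd.ids != assoc.disease_ids:
        raise ValueError("disease similarity ids do not match association disease ids")
    X = assoc.values
    row_norms = np.linalg.norm(X, axis=1)
    safe = np.where(row_norms > 0, row_norms, 1.0)
    w = (X @ sim_dd.values) / safe[:, None]
    w[row_norms == 0, :] = 0.0
    return WeightMatrix(w, list(assoc.mirna_ids), list(assoc.disease_ids))


def combine_weights(w_mir: WeightMatrix, w_dd: WeightMatrix) -> WeightMatrix:
    """Elementwise average of the miRNA- and disease-based weights."""
    if w_mir.values.shape != w_dd.values.shape:
        raise ValueError("weight matrices must have the same shape")
    if w_mir.mirna_ids != w_dd.mirna_ids or w_mir.disease_ids != w_dd.disease_ids:
        raise ValueError("weight matrices must share labels")
    return WeightMatrix(
        (w_mir.values + w_dd.values) / 2.0, list(w_mir.mirna_ids), list(w_mir.disease_ids)
    )


def build_weights(
    sim_mir: SimilarityMatrix, sim_dd: SimilarityMatrix, assoc: AssociationMatrix
) -> WeightMatrix:
    """Full weight construction from integrated similarities and training matrix."""
    return combine_weights(mirna_weight(sim_mir, assoc), disease_weight(sim_dd, assoc))


def penalty_weights(W: WeightMatrix, assoc: AssociationMatrix) -> np.ndarray:
    """Turn association confidence into the l1 penalty weight for the solver.

    The sparse-error penalty should price how much we trust the
    *observed* entry, not how likely an association is: an observed 1
    backed by high confidence W must be expensive to explain away as
    error, while an observed 0 at a high-confidence position is suspect
    and should be cheap to overwrite with a completed score.  Hence

        penalty(i,j) = (1 + W(i,j))^(2 X(i,j) - 1)

    i.e. (1 + W) on known associations and 1 / (1 + W) on unknown
    pairs.  With W identically zero this is the all-ones weight of
    plain robust PCA.  Passing W directly as the penalty would invert
    the ranking: high-confidence unknown pairs — precisely the ones the
    method exists to surface — would be pinned at their observed 0.
    """
    if W.values.shape != assoc.shape:
        raise ValueError("weight and association shapes differ")
    X = assoc.values
    return (1.0 + W.values) ** (2.0 * X - 1.0)
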