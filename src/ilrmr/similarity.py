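"""Cosine similarities from the association network and their integration.

Each miRNA is represented by its row of the binary association matrix
(its disease-interaction profile) and each disease by its column.  The
cosine of two profiles measures how much of their interaction pattern
they share; an all-zero profile has an undefined angle and is assigned
similarity 0 by convention, which keeps isolated diseases and miRNAs
usable downstream.

The integrated similarities multiply the externally supplied functional
(miRNA) or semantic (disease) similarity by boost factors:

    Sim_mir(i,j) = Sim_fun(i,j) * (1 + Sim_cos(i,j)) * (1 + FAM(i,j))
    Sim_dd(i,j)  = Sim_phe(i,j) * (1 + Sim_cos(i,j))

so the base similarity is amplified (up to 4x / 2x) when the two items
also share interaction partners or a miRBase family.  No rescaling is
applied afterwards: the downstream weight formulas are scale-sensitive.
"""

from __future__ import annotations

import numpy as np

from .datatypes import NO_FAMILY, AssociationMatrix, FamilyAssignment, SimilarityMatrix

__all__ = [
    "mirna_cosine_similarity",
    "disease_cosine_similarity",
    "family_matrix",
    "integrate_mirna_similarity",
    "integrate_disease_similarity",
]


def _cosine_rows(rows: np.ndarray) -> np.ndarray:
    """Pairwise cosine of the rows of `rows`; zero rows yield 0 everywhere."""
    norms = np.linalg.norm(rows, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = rows / safe[:, None]
    sim = unit @ unit.T
    sim = (sim + sim.T) / 2.0
    np.clip(sim, 0.0, 1.0, out=sim)
    # exact diagonal: 1 for nonzero profiles, 0 for the degenerate all-zero ones
    np.fill_diagonal(sim, np.where(norms > 0, 1.0, 0.0))
    return sim


def mirna_cosine_similarity(assoc: AssociationMatrix) -> SimilarityMatrix:
    """Cosine similarity between miRNA interaction profiles (matrix rows)."""
    return SimilarityMatrix(_cosine_rows(assoc.values), list(assoc.mirna_ids), "mirna_cosine")


def disease_cosine_similarity(assoc: AssociationMatrix) -> SimilarityMatrix:
    """Cosine similarity between disease interaction profiles (matrix columns)."""
    return SimilarityMatrix(_cosine_rows(assoc.values.T), list(assoc.disease_ids), "disease_cosine")


def family_matrix(fams: FamilyAssignment, mirna_ids: list[str]) -> SimilarityMatrix:
    """Binary same-family indicator FAM(i,j).

    1 iff both miRNAs carry the same known family; an unassigned miRNA
    ("none") never matches anything, including another "none".  The
    diagonal is 1.
    """
    labels = [fams.family_of(m) for m in mirna_ids]
    k = len(mirna_ids)
    fam = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if labels[i] != NO_FAMILY and labels[i] == labels[j]:
                fam[i, j] = 1.0
    np.fill_diagonal(fam, 1.0)
    return SimilarityMatrix(fam, list(mirna_ids), "family")


def _require_same_ids(*sims: SimilarityMatrix) -> None:
    ids0 = sims[0].ids
    for s in sims[1:]:
        if s.ids != ids0:
            raise ValueError("similarity matrices must share the same id order")


def integrate_mirna_similarity(
    fun: SimilarityMatrix, cos: SimilarityMatrix, fam: SimilarityMatrix
) -> SimilarityMatrix:
    """Functional similarity boosted by cosine and family agreement; in [0, 4]."""
    _require_same_ids(fun, cos, fam)
    values = fun.values * (1.0 + cos.values) * (1.0 + fam.values)
    return SimilarityMatrix(values, list(fun.ids), "mirna_integrated")


def integrate_disease_similarity(
    phe: SimilarityMatrix, cos: SimilarityMatrix
) -> SimilarityMatrix:
    """Semantic similarity boosted by cosine agreement; in [0, 2]."""
    _require_same_ids(phe, cos)
    values = phe.values * (1.0 + cos.values)
    return SimilarityMatrix(values, list(phe.ids), "disease_integrated")
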