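"""Core data containers shared across the ILRMR pipeline.

The conventions are fixed throughout the package: rows of the association
matrix are miRNAs, columns are diseases.  Similarity matrices are square,
symmetric and nonnegative; the admissible upper bound depends on the kind
(plain cosine / functional / semantic / family similarities live in [0, 1],
while the multiplicatively integrated miRNA and disease similarities are
bounded by 4 and 2 respectively).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "FamilyAssignment",
    "WeightMatrix",
    "RecoveryResult",
    "EvaluationReport",
    "SIMILARITY_BOUNDS",
    "NO_FAMILY",
]

#: distinguished family label for miRNAs with no known family
NO_FAMILY = "none"

#: admissible upper bound of each similarity kind
SIMILARITY_BOUNDS = {
    "mirna_functional": 1.0,
    "mirna_cosine": 1.0,
    "mirna_integrated": 4.0,
    "disease_semantic": 1.0,
    "disease_cosine": 1.0,
    "disease_integrated": 2.0,
    "family": 1.0,
}

_SYM_TOL = 1e-12


def _check_unique(labels: list[str], axis: str) -> None:
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for lab in labels:
            if lab in seen:
                dups.append(lab)
            seen.add(lab)
        raise ValueError(f"duplicate {axis} labels: {sorted(set(dups))}")


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease adjacency (1 = verified association)."""

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mirna_ids = list(self.mirna_ids)
        self.disease_ids = list(self.disease_ids)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("association matrix must be at least 1x1")
        if m != len(self.mirna_ids) or n != len(self.disease_ids):
            raise ValueError("label counts do not match matrix shape")
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.disease_ids, "disease")
        if not np.isin(self.values, (0.0, 1.0)).all():
            bad = self.values[~np.isin(self.values, (0.0, 1.0))]
            raise ValueError(f"association entries must be 0 or 1, got {bad[:5]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_known(self) -> int:
        """Number of known (1) associations."""
        return int(self.values.sum())

    def known_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i, j) of the known associations, row-major order."""
        ii, jj = np.nonzero(self.values)
        return list(zip(ii.tolist(), jj.tolist()))

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.values.copy(), list(self.mirna_ids), list(self.disease_ids))


@dataclass
class SimilarityMatrix:
    """Square symmetric nonnegative similarity with labelled axes."""

    values: np.ndarray
    ids: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = list(self.ids)
        if self.kind not in SIMILARITY_BOUNDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("label count does not match matrix size")
        _check_unique(self.ids, "similarity")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity matrix contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("similarity matrix must be nonnegative")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > _SYM_TOL:
            raise ValueError(f"similarity matrix not symmetric (max asymmetry {asym:g})")
        bound = SIMILARITY_BOUNDS[self.kind]
        # small numeric headroom over the formal bound
        if (self.values > bound + 1e-9).any():
            raise ValueError(f"kind {self.kind!r} entries must not exceed {bound}")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def reordered(self, ids: list[str]) -> "SimilarityMatrix":
        """Return a copy with rows/columns permuted into the order of `ids`."""
        missing = [x for x in ids if x not in set(self.ids)]
        if missing:
            raise ValueError(f"labels missing from similarity matrix: {missing}")
        if len(ids) != len(self.ids):
            raise ValueError("reordering must use the same label set")
        pos = {lab: k for k, lab in enumerate(self.ids)}
        perm = [pos[lab] for lab in ids]
        return SimilarityMatrix(self.values[np.ix_(perm, perm)], list(ids), self.kind)


@dataclass
class FamilyAssignment:
    """miRNA -> miRBase family mapping; unassigned miRNAs map to "none"."""

    mapping: dict[str, str] = field(default_factory=dict)

    def family_of(self, mirna: str) -> str:
        return self.mapping.get(mirna, NO_FAMILY)

    @classmethod
    def empty(cls) -> "FamilyAssignment":
        return cls({})


@dataclass
class WeightMatrix:
    """Nonnegative m x n confidence weights for the sparse-error penalty."""

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("weight matrix must be 2-dimensional")
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError("label counts do not match weight matrix shape")
        if not np.isfinite(self.values).all():
            raise ValueError("weight matrix contains NaN/Inf")
        if (self.values < 0).any():
            raise ValueError("weight matrix must be nonnegative")


@dataclass
class RecoveryResult:
    """Output of the weighted low-rank recovery.

    `scores` is the recovered low-rank matrix (the association scores),
    `residual` the sparse error term; at convergence their sum reproduces
    the input to within the solver's feasibility tolerance.
    """

    scores: np.ndarray
    residual: np.ndarray
    converged: bool
    iterations: int
    objective_trace: list[float]
    lambda_used: float
    mirna_ids: list[str] | None = None
    disease_ids: list[str] | None = None


@dataclass
class EvaluationReport:
    """Summary of a cross-validation or masking experiment."""

    per_item_records: list[tuple[str, float, int, int]]
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    auc: float
    aupr: float
    n_repeats: int = 1
    seed: int | None = None
    per_repeat_auc: list[float] = field(default_factory=list)
    extras: dict = field(default_factory=dict)
    # pooled (score, label) pairs behind auc/aupr; kept for baselines/plots
    pooled_scores: np.ndarray | None = None
    pooled_labels: np.ndarray | None = None

    def summary(self) -> dict:
        out = {
            "auc": self.auc,
            "aupr": self.aupr,
            "n_folds": len(self.per_item_records),
            "n_repeats": self.n_repeats,
            "seed": self.seed,
        }
        out.update(self.extras)
        return out
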