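"""Cross-validation and masking protocols with ROC/PR summaries.

Three protocols are implemented:

* leave-one-out cross validation — each known association is zeroed in
  turn, the pipeline is rerun on the training matrix (cosine terms and
  weights rebuilt from it, so the held-out edge never leaks into its own
  score), and the held-out pair is ranked against the unknown pairs;
* mask-ratio experiments — a fixed fraction of known associations is
  hidden per repeat and the hidden entries are scored against the true
  unknowns, averaged over repeats;
* isolated-disease evaluation — an entire disease column is removed and
  its true interactors must be recovered from similarity structure alone.

AUC uses the rank (Mann-Whitney) formulation with ties counting 1/2;
AUPR uses step-wise interpolation over descending score thresholds with
tied scores processed as a block.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .datatypes import (
    AssociationMatrix,
    EvaluationReport,
    FamilyAssignment,
    SimilarityMatrix,
)
from .recovery import SolverConfig, predict_scores

__all__ = [
    "auc_from_scores",
    "aupr_from_scores",
    "loocv",
    "mask_experiment",
    "isolated_disease_eval",
]


def auc_from_scores(scores, labels) -> float:
    """Area under the ROC curve by the rank / Mann-Whitney formulation.

    Equals the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def aupr_from_scores(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise, block ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if (labels == 1).sum() == 0:
        raise ValueError("AUPR undefined: no positive labels")
    return float(average_precision_score(labels, scores))


def _curves(scores: np.ndarray, labels: np.ndarray):
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    precision, recall, _ = precision_recall_curve(labels, scores)
    pr_points = list(zip(recall.tolist(), precision.tolist()))
    return roc_points, pr_points


def _default_scorer(
    sim_mir_fun: SimilarityMatrix,
    sim_dd_phe: SimilarityMatrix,
    fams: FamilyAssignment | None,
    config: SolverConfig | None,
    use_weights: bool,
    use_family_and_cosine: bool,
) -> Callable[[AssociationMatrix], np.ndarray]:
    def score(train: AssociationMatrix) -> np.ndarray:
        return predict_scores(
            train,
            sim_mir_fun,
            sim_dd_phe,
            fams,
            config,
            use_weights=use_weights,
            use_family_and_cosine=use_family_and_cosine,
        ).scores

    return score


def loocv(
    assoc: AssociationMatrix,
    sim_mir_fun: SimilarityMatrix,
    sim_dd_phe: SimilarityMatrix,
    fams: FamilyAssignment | None = None,
    config: SolverConfig | None = None,
    use_weights: bool = True,
    use_family_and_cosine: bool = True,
    per_disease: bool = False,
    scorer: Callable[[AssociationMatrix], np.ndarray] | None = None,
) -> EvaluationReport:
    """Leave-one-out cross validation over the known associations.

    Each fold zeroes one known entry, re-scores from the training matrix
    and ranks the held-out pair among the candidate pairs (the held-out
    entry plus every other 0-entry; restricted to the held-out disease's
    column when `per_disease`).  The pooled (score, label) pairs of all
    folds give the global AUC/AUPR.

    `use_weights=False` drops the confidence weights (plain robust PCA);
    `use_family_and_cosine=False` keeps only the functional/semantic
    similarities in the weight construction.  `scorer` replaces the
    recovery pipeline (testing hook).
    """
    knowns = assoc.known_pairs()
    if len(knowns) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    if scorer is None:
        scorer = _default_scorer(
            sim_mir_fun, sim_dd_phe, fams, config, use_weights, use_family_and_cosine
        )
    zeros_mask = assoc.values == 0

    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    records: list[tuple[str, float, int, int]] = []
    for i, j in knowns:
        train = assoc.copy()
        train.values[i, j] = 0.0
        S = scorer(train)
        held_score = float(S[i, j])
        if per_disease:
            neg_scores = S[zeros_mask[:, j], j]
        else:
            neg_scores = S[zeros_mask]
        fold_scores = np.concatenate(([held_score], neg_scores))
        fold_labels = np.concatenate(([1], np.zeros(neg_scores.size, dtype=int)))
        pooled_scores.append(fold_scores)
        pooled_labels.append(fold_labels)
        # rank of the held-out pair among the fold's candidates (ties -> mean rank)
        rank = int(round(rankdata(-fold_scores)[0]))
        records.append(
            (f"{assoc.mirna_ids[i]}|{assoc.disease_ids[j]}", held_score, rank, fold_scores.size)
        )

    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    roc_points, pr_points = _curves(scores, labels)
    return EvaluationReport(
        per_item_records=records,
        roc_points=roc_points,
        pr_points=pr_points,
        auc=auc_from_scores(scores, labels),
        aupr=aupr_from_scores(scores, labels),
        n_repeats=1,
        pooled_scores=scores,
        pooled_labels=labels,
        extras={
            "protocol": "loocv",
            "use_weights": use_weights,
            "use_family_and_cosine": use_family_and_cosine,
            "per_disease": per_disease,
        },
    )


def mask_experiment(
    assoc: AssociationMatrix,
    sim_mir_fun: SimilarityMatrix,
    sim_dd_phe: SimilarityMatrix,
    fams: FamilyAssignment | None = None,
    config: SolverConfig | None = None,
    mask_ratio: float = 0.1,
    n_repeats: int = 20,
    seed: int = 0,
    use_weights: bool = True,
    use_family_and_cosine: bool = True,
) -> EvaluationReport:
    """Hide a fraction of known associations and score their recovery.

    Per repeat, floor(mask_ratio * #knowns) known entries are sampled
    uniformly without replacement and zeroed; the pipeline recovers the
    masked matrix and the hidden entries (positives) are ranked against
    the true unknown pairs (negatives).  Reported AUC/AUPR are means
    over repeats; the ROC/PR point sets pool all repeats.
    """
    if not 0 < mask_ratio < 1:
        raise ValueError("mask_ratio must lie in (0, 1)")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    knowns = assoc.known_pairs()
    n_mask = int(np.floor(mask_ratio * len(knowns)))
    if n_mask == 0:
        raise ValueError("mask_ratio too small: would mask 0 associations")
    if n_mask >= len(knowns):
        raise ValueError("masking would remove every known association")
    if not (assoc.values == 0).any():
        raise ValueError("association matrix has no unknown pairs to rank against")
    scorer = _default_scorer(
        sim_mir_fun, sim_dd_phe, fams, config, use_weights, use_family_and_cosine
    )
    zeros_mask = assoc.values == 0

    per_auc, per_aupr = [], []
    pooled_scores, pooled_labels = [], []
    records: list[tuple[str, float, int, int]] = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        picked = rng.choice(len(knowns), size=n_mask, replace=False)
        train = assoc.copy()
        for k in picked:
            i, j = knowns[k]
            train.values[i, j] = 0.0
        S = scorer(train)
        pos_scores = np.array([S[knowns[k]] for k in picked])
        neg_scores = S[zeros_mask]
        scores = np.concatenate([pos_scores, neg_scores])
        labels = np.concatenate([np.ones(n_mask, dtype=int), np.zeros(neg_scores.size, dtype=int)])
        per_auc.append(auc_from_scores(scores, labels))
        per_aupr.append(aupr_from_scores(scores, labels))
        pooled_scores.append(scores)
        pooled_labels.append(labels)
        ranks = rankdata(-scores)
        for t, k in enumerate(picked):
            i, j = knowns[k]
            records.append(
                (
                    f"{assoc.mirna_ids[i]}|{assoc.disease_ids[j]}",
                    float(pos_scores[t]),
                    int(round(ranks[t])),
                    scores.size,
                )
            )

    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    roc_points, pr_points = _curves(scores, labels)
    return EvaluationReport(
        per_item_records=records,
        roc_points=roc_points,
        pr_points=pr_points,
        auc=float(np.mean(per_auc)),
        aupr=float(np.mean(per_aupr)),
        n_repeats=n_repeats,
        seed=seed,
        per_repeat_auc=[float(a) for a in per_auc],
        pooled_scores=scores,
        pooled_labels=labels,
        extras={
            "protocol": "mask",
            "mask_ratio": mask_ratio,
            "n_masked_per_repeat": n_mask,
            "use_weights": use_weights,
            "use_family_and_cosine": use_family_and_cosine,
        },
    )


def isolated_disease_eval(
    assoc: AssociationMatrix,
    sim_mir_fun: SimilarityMatrix,
    sim_dd_phe: SimilarityMatrix,
    fams: FamilyAssignment | None = None,
    config: SolverConfig | None = None,
    disease_id: str = "",
    use_weights: bool = True,
    use_family_and_cosine: bool = True,
) -> EvaluationReport:
    """Score a disease as if it had no known miRNA associations.

    The disease's entire column is zeroed before recovery, so all signal
    must come from its semantic similarity to other diseases; its true
    interactors are then ranked among all miRNAs.

    A fully unobserved column always completes to zero under the
    nuclear norm (appending a nonzero column can only increase it), so
    the recovered scores alone cannot discriminate within the column.
    The candidates are therefore ranked by the recovered score plus the
    similarity-derived confidence W — exactly the "similar information
    and known associations of other diseases" this mode is meant to
    exploit.
    """
    # delayed import to avoid a cycle at module load
    from .recovery import integrated_similarities, ilrmr_recover
    from .weighting import build_weights, penalty_weights

    if disease_id not in assoc.disease_ids:
        raise ValueError(f"unknown disease label {disease_id!r}")
    j = assoc.disease_ids.index(disease_id)
    truth = assoc.values[:, j].astype(int)
    if truth.sum() < 1:
        raise ValueError(f"disease {disease_id!r} has no known associations")
    train = assoc.copy()
    train.values[:, j] = 0.0
    sim_mir, sim_dd = integrated_similarities(
        train, sim_mir_fun, sim_dd_phe, fams, use_family_and_cosine
    )
    W = build_weights(sim_mir, sim_dd, train)
    penalty = penalty_weights(W, train) if use_weights else None
    result = ilrmr_recover(train, penalty, config)
    col_scores = result.scores[:, j] + W.values[:, j]
    ranks = rankdata(-col_scores)
    records = [
        (f"{assoc.mirna_ids[i]}|{disease_id}", float(col_scores[i]), int(round(ranks[i])), len(col_scores))
        for i in np.nonzero(truth)[0]
    ]
    if truth.sum() == truth.size:
        raise ValueError("disease is associated with every miRNA; AUC undefined")
    roc_points, pr_points = _curves(col_scores, truth)
    return EvaluationReport(
        per_item_records=records,
        roc_points=roc_points,
        pr_points=pr_points,
        auc=auc_from_scores(col_scores, truth),
        aupr=aupr_from_scores(col_scores, truth),
        n_repeats=1,
        extras={"protocol": "isolated_disease", "disease": disease_id},
    )
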