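"""Readers and writers for the plain TSV formats the tool exchanges.

All files are tab-delimited UTF-8; lines starting with '#' are comments.
Edge lists carry two columns (miRNA, disease) and no header.  Dense
matrices carry a header row of column labels and a first column of row
labels.  Prediction output is a four-column table with a header.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    NO_FAMILY,
    AssociationMatrix,
    FamilyAssignment,
    RecoveryResult,
    SimilarityMatrix,
)

__all__ = [
    "read_associations",
    "write_associations",
    "read_similarity",
    "write_similarity",
    "read_family",
    "write_family",
    "write_predictions",
]

_READ_SYM_TOL = 1e-8


def _strip_comments(path: str | Path) -> _io.StringIO:
    lines = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.lstrip().startswith("#"):
                lines.append(line)
    return _io.StringIO("".join(lines))


def read_associations(path: str | Path, format: str = "edge_list") -> AssociationMatrix:
    """Read a binary association matrix from an edge list or dense TSV.

    Edge-list label order is first appearance; dense order is file order.
    Duplicate edges collapse to a single 1.
    """
    if format == "edge_list":
        mirnas: list[str] = []
        diseases: list[str] = []
        mpos: dict[str, int] = {}
        dpos: dict[str, int] = {}
        edges: list[tuple[int, int]] = []
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                    raise ValueError(
                        f"{path}: line {lineno}: expected 'miRNA<TAB>disease', got {line!r}"
                    )
                mi, di = parts[0].strip(), parts[1].strip()
                if mi not in mpos:
                    mpos[mi] = len(mirnas)
                    mirnas.append(mi)
                if di not in dpos:
                    dpos[di] = len(diseases)
                    diseases.append(di)
                edges.append((mpos[mi], dpos[di]))
        if not edges:
            raise ValueError(f"{path}: no associations")
        values = np.zeros((len(mirnas), len(diseases)))
        for i, j in edges:
            values[i, j] = 1.0
        return AssociationMatrix(values, mirnas, diseases)

    if format == "dense":
        df = pd.read_csv(_strip_comments(path), sep="\t", index_col=0)
        if df.empty:
            raise ValueError(f"{path}: no associations")
        values = df.to_numpy(dtype=float)
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError(f"{path}: dense association cells must be 0 or 1")
        return AssociationMatrix(values, [str(x) for x in df.index], [str(x) for x in df.columns])

    raise ValueError(f"unknown association format {format!r}")


def write_associations(assoc: AssociationMatrix, path: str | Path, format: str = "dense") -> None:
    if format == "dense":
        df = pd.DataFrame(assoc.values.astype(int), index=assoc.mirna_ids, columns=assoc.disease_ids)
        df.to_csv(path, sep="\t")
    elif format == "edge_list":
        with open(path, "w", encoding="utf-8") as fh:
            for i, j in assoc.known_pairs():
                fh.write(f"{assoc.mirna_ids[i]}\t{assoc.disease_ids[j]}\n")
    else:
        raise ValueError(f"unknown association format {format!r}")


def read_similarity(
    path: str | Path,
    expected_ids: list[str] | None = None,
    kind: str = "mirna_functional",
) -> SimilarityMatrix:
    """Read a dense square similarity TSV.

    Small asymmetries (<= 1e-8) are symmetrized by averaging; larger ones
    are errors.  The diagonal is forced to 1 (self-similarity).  If
    `expected_ids` is given the matrix is reordered to that label order.
    """
    df = pd.read_csv(_strip_comments(path), sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: similarity matrix must be square")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row and column labels must match")
    asym = np.abs(values - values.T).max(initial=0.0)
    if asym > _READ_SYM_TOL:
        raise ValueError(f"{path}: similarity asymmetry {asym:g} exceeds {_READ_SYM_TOL:g}")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    sim = SimilarityMatrix(values, rows, kind)
    if expected_ids is not None:
        sim = sim.reordered(list(expected_ids))
    return sim


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_family(path: str | Path) -> FamilyAssignment:
    """Read a two-column miRNA<TAB>family table; later rows must not conflict."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 'miRNA<TAB>family'")
            mirna, fam = parts[0].strip(), parts[1].strip()
            if mirna in mapping and mapping[mirna] != fam:
                raise ValueError(f"{path}: line {lineno}: conflicting family for {mirna!r}")
            mapping[mirna] = fam if fam else NO_FAMILY
    return FamilyAssignment(mapping)


def write_family(fams: FamilyAssignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mirna, fam in fams.mapping.items():
            fh.write(f"{mirna}\t{fam}\n")


def write_predictions(
    result: RecoveryResult,
    assoc: AssociationMatrix,
    path: str | Path,
    top_k: int = 50,
) -> pd.DataFrame:
    """Write the top-k unknown-pair predictions per disease.

    Only pairs unknown in `assoc` (entry 0) are ranked, by descending
    score; ties break on the lexicographically smaller miRNA label.  A
    disease with fewer than `top_k` unknown pairs emits all it has.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    scores = result.scores
    if scores.shape != assoc.shape:
        raise ValueError("score and association shapes differ")
    rows = []
    for j, disease in enumerate(assoc.disease_ids):
        unknown = np.nonzero(assoc.values[:, j] == 0)[0]
        ranked = sorted(unknown, key=lambda i: (-scores[i, j], assoc.mirna_ids[i]))
        for rank, i in enumerate(ranked[:top_k], start=1):
            rows.append((disease, rank, assoc.mirna_ids[i], scores[i, j]))
    df = pd.DataFrame(rows, columns=["disease", "rank", "miRNA", "score"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df
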