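"""Indicator-matrix construction, code filtering, and cohort splitting.

Diagnostic-code lists become a persons x codes binary sparse matrix (one
column per distinct code, duplicates within a person collapse to a single
1).  Codes too rare to estimate in either the training or validation set
(count <= 1) and codes occurring in only one sex in either set are
removed before screening; the surviving vocabulary is common to both
sets so that downstream per-code models are estimable everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import EmptyInputError

SPLIT_LABELS = ("train", "valid", "test")


@dataclass
class CodeIndicatorMatrix:
    vocabulary: list[str]
    matrix: sparse.csr_matrix  # persons x codes, {0,1}
    person_index: pd.Index  # person_id per row

    def column_counts(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def sex_counts(self, sex: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-code carrier counts among (males, females)."""
        sex = np.asarray(sex)
        n_female = np.asarray(sex @ self.matrix).ravel()
        n_male = np.asarray((1 - sex) @ self.matrix).ravel()
        return n_male, n_female

    def subset_codes(self, codes: list[str]) -> "CodeIndicatorMatrix":
        pos = {c: j for j, c in enumerate(self.vocabulary)}
        idx = [pos[c] for c in codes]
        return CodeIndicatorMatrix(
            vocabulary=list(codes),
            matrix=self.matrix[:, idx].tocsr(),
            person_index=self.person_index,
        )

    def dense(self, codes: list[str] | None = None) -> np.ndarray:
        """Dense float array; codes absent from the vocabulary are zero
        columns (a scored person simply lacks them)."""
        if codes is None:
            return self.matrix.toarray().astype(float)
        pos = {c: j for j, c in enumerate(self.vocabulary)}
        out = np.zeros((self.matrix.shape[0], len(codes)))
        present = [(i, pos[c]) for i, c in enumerate(codes) if c in pos]
        if present:
            cols = self.matrix[:, [j for _, j in present]].toarray()
            for k, (i, _) in enumerate(present):
                out[:, i] = cols[:, k]
        return out


def tokenize_codes(cell: str, delimiter: str = "|") -> list[str]:
    """Split one codes cell into normalized (upper-case, stripped) tokens."""
    if not isinstance(cell, str) or not cell:
        return []
    return [t.strip().upper() for t in cell.split(delimiter) if t.strip()]


def build_indicator_matrix(
    cohort: pd.DataFrame, delimiter: str = "|"
) -> CodeIndicatorMatrix:
    """One column per distinct observed code; entries are presence flags."""
    if len(cohort) == 0:
        raise EmptyInputError("cannot build an indicator matrix from an empty cohort")
    token_lists = [tokenize_codes(c, delimiter) for c in cohort["codes"]]
    vocabulary = sorted({t for toks in token_lists for t in toks})
    pos = {c: j for j, c in enumerate(vocabulary)}
    rows, cols = [], []
    for i, toks in enumerate(token_lists):
        for c in set(toks):
            rows.append(i)
            cols.append(pos[c])
    matrix = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(cohort), len(vocabulary)),
    )
    return CodeIndicatorMatrix(
        vocabulary=vocabulary,
        matrix=matrix,
        person_index=pd.Index(cohort["person_id"]),
    )


def filter_codes(
    train: CodeIndicatorMatrix,
    train_sex: np.ndarray,
    valid: CodeIndicatorMatrix,
    valid_sex: np.ndarray,
) -> list[str]:
    """Vocabulary retained for screening, common to both sets.

    A code is kept only if, in the training set AND in the validation
    set, it occurs in at least two people and in both sexes.
    """
    common = sorted(set(train.vocabulary) & set(valid.vocabulary))
    keep = []
    for name, mat, sex in (("train", train, train_sex), ("valid", valid, valid_sex)):
        sub = mat.subset_codes([c for c in common if c in set(mat.vocabulary)])
        n_male, n_female = sub.sex_counts(np.asarray(sex))
        ok = (n_male + n_female >= 2) & (n_male >= 1) & (n_female >= 1)
        keep.append({c for c, flag in zip(sub.vocabulary, ok) if flag})
    return sorted(keep[0] & keep[1])


def split_cohort(
    cohort: pd.DataFrame,
    seed: int,
    proportions: tuple[float, float, float] = (0.50, 0.25, 0.25),
) -> pd.Series:
    """Random train/valid/test partition with largest-remainder rounding.

    Returns a Series of fold labels indexed like the cohort; the same
    seed always yields the same assignment.
    """
    n = len(cohort)
    if n < 4:
        raise EmptyInputError("need at least 4 people to split 50/25/25")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("split proportions must sum to 1")
    sizes = largest_remainder_sizes(n, proportions)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    start = 0
    for label, size in zip(SPLIT_LABELS, sizes):
        labels[perm[start : start + size]] = label
        start += size
    return pd.Series(labels, index=cohort.index, name="fold")


def largest_remainder_sizes(n: int, proportions: tuple[float, ...]) -> list[int]:
    quotas = [n * p for p in proportions]
    sizes = [int(q) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    short = n - sum(sizes)
    # Ties broken by fold order (train first) for determinism.
    order = sorted(range(len(proportions)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        sizes[i] += 1
    return sizes
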