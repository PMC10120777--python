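"""Design-matrix construction shared by the outcome models.

Categorical covariates are expanded to treatment-coded indicator columns
named ``var[level]``; the reference level gets no column.  Column order is
deterministic: intercept first, then terms in the order requested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError

CATEGORICAL_TERMS = {
    "mechanism": ("falls", "struck", "mvc", "cyclist", "other"),
}


def build_design(
    data: pd.DataFrame,
    terms: list[str],
    categorical_refs: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build an intercept-plus-terms design matrix from cohort columns."""
    refs = {"mechanism": "falls"}
    if categorical_refs:
        refs.update(categorical_refs)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(data))}
    for term in terms:
        if term not in data.columns:
            raise SchemaError(f"design term '{term}' not found in data")
        if term in CATEGORICAL_TERMS:
            levels = CATEGORICAL_TERMS[term]
            ref = refs.get(term, levels[0])
            observed = set(data[term].unique())
            unknown = observed - set(levels)
            if unknown:
                raise SchemaError(f"unknown {term} levels: {sorted(unknown)}")
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{term}[{lev}]"] = (data[term] == lev).to_numpy(dtype=float)
        else:
            cols[term] = data[term].to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=data.index)
    if design.isna().any().any():
        bad = design.columns[design.isna().any()].tolist()
        raise SchemaError(f"design matrix has missing values in {bad}")
    return design
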