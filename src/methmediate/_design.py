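"""Covariate design-matrix construction shared by the EWAS, meQTL and CIT stages.

The standard adjustment set mirrors the study design: sex, age, smoking
history (total pack-years), smoking status (dummy-coded against "never"),
alcohol consumption, and blood cell-subset proportions.  One cell-type
column is dropped because estimated fractions sum to ~1 and would be
collinear with the intercept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import SampleTable

DEFAULT_COVARIATES = ("sex", "age", "pack_years", "smoking_status", "alcohol", "cells")


def build_covariate_matrix(
    samples: SampleTable,
    covariate_set: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Numeric covariate matrix (no intercept column) indexed by sample id.

    ``covariate_set`` entries are sample-table columns, plus the expanders
    ``smoking_status`` (-> former/current dummies) and ``cells`` (-> all
    cell_<type> columns except the first).
    """
    df = samples.data
    cols: dict[str, np.ndarray] = {}
    for name in covariate_set:
        if name == "smoking_status":
            s = df["smoking_status"]
            cols["smoking_former"] = (s == "former").astype(float).to_numpy()
            cols["smoking_current"] = (s == "current").astype(float).to_numpy()
        elif name == "cells":
            cell_cols = samples.cell_columns
            for c in cell_cols[1:]:  # drop one to break the sum-to-one collinearity
                cols[c] = df[c].to_numpy(dtype=float)
        else:
            if name not in df.columns:
                raise KeyError(f"covariate {name!r} not in sample table")
            cols[name] = df[name].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def check_collinearity(X: np.ndarray, names: list[str]) -> None:
    """Raise naming a collinear column pair when the design is rank-deficient."""
    if X.shape[1] < 2:
        return
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X.T)
    for a in range(X.shape[1]):
        for b in range(a + 1, X.shape[1]):
            if sd[a] > 0 and sd[b] > 0 and abs(C[a, b]) > 1 - 1e-8:
                raise ValueError(
                    f"collinear covariates: {names[a]!r} and {names[b]!r}"
                )
    raise ValueError("design matrix is rank-deficient")
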