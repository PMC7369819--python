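"""Reference-based blood cell-type deconvolution from methylation.

Each sample's beta values at a panel of discriminating CpGs are projected
onto per-cell-type reference methylomes under the physical constraints
w >= 0 and sum(w) <= 1, so the fitted weights are directly interpretable
as leukocyte-subset fractions and can enter downstream regressions as
covariates.  The constrained least-squares problem is solved exactly by
non-negative least squares after adding a slack fraction s >= 0 with
w_1 + ... + w_K + s = 1 (the equality is enforced by a heavily weighted
augmentation row, accurate to ~1e-10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .io_formats import BetaMatrix, SampleTable, TableFormatError, _write_matrix

MIN_OVERLAP = 10
_SUM_WEIGHT = 1e5  # sqrt of the penalty enforcing sum(w) + slack = 1


@dataclass
class ReferenceProfiles:
    """Expected beta per (discriminating probe, cell type)."""

    data: pd.DataFrame  # index = probe ids, columns = cell type names

    def __post_init__(self):
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 cell types")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("reference betas must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class CellProportions:
    """Estimated per-sample cell-type fractions and fit residual norms."""

    data: pd.DataFrame       # index = sample ids, columns = cell types
    residual_norm: pd.Series  # index = sample ids


def default_reference_panel(n_probes_per_type: int = 50, seed: int = 20200701) -> ReferenceProfiles:
    """Deterministic synthetic reference: for each of six leukocyte subsets,
    a block of probes unmethylated in that subset and methylated elsewhere,
    mimicking the discriminating-CpG structure of published blood panels.

    This is a synthetic stand-in panel (no measured methylomes enter it);
    the packaged ``deconv_reference_synthetic.tsv`` is this function's
    output at default arguments.
    """
    cell_types = ["Neu", "CD4T", "CD8T", "Bcell", "NK", "Mono"]
    rng = np.random.default_rng(seed)
    K = len(cell_types)
    rows, ids = [], []
    for k in range(K):
        for j in range(n_probes_per_type):
            lo = rng.uniform(0.03, 0.15)
            hi = rng.uniform(0.75, 0.95)
            row = np.full(K, np.nan)
            for t in range(K):
                row[t] = lo if t == k else np.clip(hi + rng.normal(0, 0.04), 0, 1)
            rows.append(row)
            ids.append(f"ref_{cell_types[k]}_{j:03d}")
    df = pd.DataFrame(np.round(np.array(rows), 4), index=ids, columns=cell_types)
    return ReferenceProfiles(df)


def read_reference_profiles(path) -> ReferenceProfiles:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ReferenceProfiles(df)


def write_reference_profiles(ref: ReferenceProfiles, path) -> None:
    _write_matrix(ref.data, "probe_id", path)


def load_packaged_reference() -> ReferenceProfiles:
    from .io_formats import _resource_bytes
    import io

    df = pd.read_csv(io.BytesIO(_resource_bytes("deconv_reference_synthetic.tsv")),
                     sep="\t", index_col=0)
    return ReferenceProfiles(df)


def _check_rank(R: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(R)
    if rank < R.shape[1]:
        C = np.corrcoef(R.T)
        K = len(names)
        for a in range(K):
            for b in range(a + 1, K):
                if abs(C[a, b]) > 1 - 1e-10:
                    raise ValueError(
                        f"reference is rank-deficient: cell types {names[a]!r} "
                        f"and {names[b]!r} are collinear"
                    )
        raise ValueError("reference is rank-deficient")


def estimate_cell_proportions(betas: BetaMatrix, ref: ReferenceProfiles | None = None) -> CellProportions:
    """Estimate leukocyte fractions per sample by constrained projection.

    Solves, per sample, min_w ||R w - y||^2 subject to w >= 0 and
    sum(w) <= 1 over the probes shared between the cohort and the
    reference (>= 10 required).  Missing betas are dropped per sample.
    """
    if ref is None:
        ref = load_packaged_reference()
    overlap = [p for p in ref.probe_ids if p in set(betas.probe_ids)]
    if len(overlap) < MIN_OVERLAP:
        raise ValueError(
            f"only {len(overlap)} probes overlap between cohort and reference "
            f"(need >= {MIN_OVERLAP})"
        )
    R_full = ref.data.loc[overlap].to_numpy(dtype=float)
    _check_rank(R_full, ref.cell_types)
    Y = betas.values[overlap].to_numpy(dtype=float)
    K = R_full.shape[1]
    sum_row = np.full(K + 1, _SUM_WEIGHT)  # slack column included
    W = np.empty((Y.shape[0], K))
    resid = np.empty(Y.shape[0])
    for i in range(Y.shape[0]):
        y = Y[i]
        ok = ~np.isnan(y)
        if ok.sum() < MIN_OVERLAP:
            raise ValueError(
                f"sample {betas.sample_ids[i]!r} has fewer than {MIN_OVERLAP} "
                "non-missing reference probes"
            )
        R = R_full[ok]
        A = np.vstack([np.hstack([R, np.zeros((R.shape[0], 1))]), sum_row])
        b = np.concatenate([y[ok], [_SUM_WEIGHT]])
        w_aug, _ = nnls(A, b)
        w = w_aug[:K]
        W[i] = w
        resid[i] = float(np.linalg.norm(R @ w - y[ok]))
    data = pd.DataFrame(W, index=betas.sample_ids, columns=ref.cell_types)
    return CellProportions(data, pd.Series(resid, index=betas.sample_ids, name="residual_norm"))


def compare_proportions(props: CellProportions, samples: SampleTable) -> pd.DataFrame:
    """Rank-based two-group (gout vs non-gout) location test per cell type.

    Returns a table with the case/control median fractions and the
    two-sided Mann-Whitney p-value for each cell type.
    """
    gout = samples.data.loc[props.data.index, "gout"].to_numpy(dtype=float)
    if (gout == 1).sum() == 0 or (gout == 0).sum() == 0:
        raise ValueError("both gout and non-gout samples are required")
    rows = []
    for ct in props.data.columns:
        w = props.data[ct].to_numpy(dtype=float)
        a, b = w[gout == 1], w[gout == 0]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            stat, p = len(a) * len(b) / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"cell_type": ct, "median_gout": float(np.median(a)),
                     "median_non_gout": float(np.median(b)),
                     "statistic": stat, "p": min(p, 1.0)})
    return pd.DataFrame(rows).set_index("cell_type")
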