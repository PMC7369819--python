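"""Per-CpG association of methylation with gout and other phenotypes.

Regression is on the beta scale, so for the binary gout outcome the outcome
coefficient is directly the adjusted case-minus-control methylation
difference (delta-beta, tabulated x100 as percent).  The stages here are:
promoter-restricted EWAS with Benjamini-Hochberg FDR, metabolic-trait
specificity screens, three-group (normouricemia / hyperuricemia / gout)
contrasts, and co-methylation of neighboring promoter probes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._design import DEFAULT_COVARIATES, build_covariate_matrix, check_collinearity
from .io_formats import BetaMatrix, CpGAnnotation, SampleTable, PROMOTER_FEATURES

logger = logging.getLogger(__name__)

TRAITS = ("bmi", "hba1c", "total_cholesterol")


@dataclass
class EwasResult:
    """One probe's adjusted association with the outcome."""

    probe_id: str
    delta_beta: float  # outcome coefficient on the beta scale (fraction)
    se: float
    p: float
    q: float = float("nan")  # BH-adjusted p, set by promoter_ewas
    n_used: int = 0
    outcome: str = "gout"


@dataclass
class GroupContrastResult:
    probe_id: str
    contrast: str  # normo_vs_hyper | hyper_vs_gout
    difference: float
    se: float
    p: float
    n_used: int


@dataclass
class ComethylationResult:
    target_probe: str
    neighbor_probe: str
    r: float
    neighbor_gout_p: float
    comethylated: bool


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _assemble_design(
    betas: BetaMatrix,
    samples: SampleTable,
    probe_id: str,
    outcome: str,
    covariate_set: tuple[str, ...],
):
    if probe_id not in betas.values.columns:
        raise KeyError(f"probe {probe_id!r} not in beta matrix")
    common = betas.values.index.intersection(samples.data.index)
    y = betas.values.loc[common, probe_id].to_numpy(dtype=float)
    if outcome not in samples.data.columns:
        raise KeyError(f"outcome column {outcome!r} missing from sample table")
    x = samples.data.loc[common, outcome].to_numpy(dtype=float)
    cov = build_covariate_matrix(SampleTable(samples.data.loc[common]), covariate_set) \
        if covariate_set else pd.DataFrame(index=common)
    C = cov.to_numpy(dtype=float) if cov.shape[1] else np.empty((len(common), 0))
    ok = ~np.isnan(y) & ~np.isnan(x)
    if C.shape[1]:
        ok &= ~np.isnan(C).any(axis=1)
    return y[ok], x[ok], C[ok], list(cov.columns)


def fit_cpg_association(
    betas: BetaMatrix,
    samples: SampleTable,
    probe_id: str,
    outcome: str = "gout",
    covariate_set: tuple[str, ...] = DEFAULT_COVARIATES,
) -> EwasResult:
    """OLS of methylation on outcome + covariates; the outcome coefficient is
    the adjusted delta-beta (binary outcome coded 0/1) with a two-sided t test.
    Complete-case per probe."""
    y, x, C, cov_names = _assemble_design(betas, samples, probe_id, outcome, covariate_set)
    n, p_par = len(y), 2 + C.shape[1]
    if n < 10 + p_par:
        raise ValueError(
            f"probe {probe_id!r}: {n} complete cases < required {10 + p_par}"
        )
    if np.ptp(y) == 0:
        raise ValueError(f"degenerate probe {probe_id!r}: constant methylation")
    if np.ptp(x) == 0:
        raise ValueError(f"constant outcome {outcome!r}")
    X = np.column_stack([np.ones(n), x, C])
    check_collinearity(X[:, 1:], [outcome] + cov_names)
    fit = sm.OLS(y, X).fit()
    return EwasResult(
        probe_id=probe_id,
        delta_beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        n_used=n,
        outcome=outcome,
    )


def _ols_outcome_column(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of every column of Y on shared X; returns the
    (coefficient, se, two-sided p) of X's column 1 (the outcome)."""
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    coef = np.linalg.solve(R, Q.T @ Y)  # (p, m)
    resid = Y - X @ coef
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    Rinv = np.linalg.inv(R)
    unit = (Rinv @ Rinv.T)[1, 1]
    se = np.sqrt(unit * sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef[1] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return coef[1], se, pvals


def promoter_ewas(
    betas: BetaMatrix,
    samples: SampleTable,
    annotation: CpGAnnotation,
    covariate_set: tuple[str, ...] = DEFAULT_COVARIATES,
    outcome: str = "gout",
) -> list[EwasResult]:
    """Association of every promoter probe (TSS1500/TSS200/5'UTR) with gout,
    with BH FDR computed across exactly the tested promoter probes."""
    promoters = [p for p in annotation.promoter_probes() if p in set(betas.probe_ids)]
    if not promoters:
        raise ValueError("no promoter (TSS1500/TSS200/5UTR) probes to test")
    # fast path: shared complete-case design across probes
    common = betas.values.index.intersection(samples.data.index)
    sub = SampleTable(samples.data.loc[common])
    cov = build_covariate_matrix(sub, covariate_set) if covariate_set else \
        pd.DataFrame(index=common)
    x = sub.data[outcome].to_numpy(dtype=float)
    C = cov.to_numpy(dtype=float) if cov.shape[1] else np.empty((len(common), 0))
    Y = betas.values.loc[common, promoters].to_numpy(dtype=float)
    ok = ~np.isnan(x)
    if C.shape[1]:
        ok &= ~np.isnan(C).any(axis=1)
    if not np.isnan(Y[ok]).any():
        Yc, xc, Cc = Y[ok], x[ok], C[ok]
        if np.ptp(xc) == 0:
            raise ValueError(f"constant outcome {outcome!r}")
        X = np.column_stack([np.ones(ok.sum()), xc, Cc])
        check_collinearity(X[:, 1:], [outcome] + list(cov.columns))
        if np.any(np.ptp(Yc, axis=0) == 0):
            j = int(np.argmin(np.ptp(Yc, axis=0)))
            raise ValueError(f"degenerate probe {promoters[j]!r}: constant methylation")
        coefs, ses, ps = _ols_outcome_column(X, Yc)
        results = [
            EwasResult(pid, float(c), float(s), float(pv), n_used=int(ok.sum()),
                       outcome=outcome)
            for pid, c, s, pv in zip(promoters, coefs, ses, ps)
        ]
    else:  # per-probe complete-case fallback
        results = [
            fit_cpg_association(betas, samples, pid, outcome, covariate_set)
            for pid in promoters
        ]
    q = bh_qvalues(np.array([r.p for r in results]))
    for r, qv in zip(results, q):
        r.q = float(qv)
    return results


def manhattan_table(results: list[EwasResult], annotation: CpGAnnotation) -> pd.DataFrame:
    """Sortable (chromosome, position, -log10 p) table for plotting."""
    rows = []
    for r in results:
        a = annotation.data.loc[r.probe_id]
        rows.append({"probe_id": r.probe_id, "chromosome": a["chromosome"],
                     "position": int(a["position"]),
                     "neg_log10_p": float(-np.log10(max(r.p, 1e-300))),
                     "delta_beta": r.delta_beta, "p": r.p, "q": r.q})
    return (pd.DataFrame(rows)
            .sort_values(["chromosome", "position"], kind="mergesort")
            .reset_index(drop=True))


def trait_specificity(
    betas: BetaMatrix,
    samples: SampleTable,
    probes: list[str],
    traits: tuple[str, ...] = TRAITS,
    covariate_set: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> tuple[list[EwasResult], dict[str, bool]]:
    """Continuous-trait regressions per probe; a probe is gout-specific when
    none of the metabolic traits associates with its methylation at alpha."""
    for t in traits:
        if t not in samples.data.columns:
            raise KeyError(f"trait column {t!r} missing from sample table")
    results = []
    for pid in probes:
        for t in traits:
            results.append(fit_cpg_association(betas, samples, pid, t, covariate_set))
    flags = {
        pid: all(r.p >= alpha for r in results if r.probe_id == pid)
        for pid in probes
    }
    return results, flags


def three_group_contrasts(
    betas: BetaMatrix,
    samples: SampleTable,
    probes: list[str],
    covariate_set: tuple[str, ...] = DEFAULT_COVARIATES,
    min_group: int = 5,
) -> list[GroupContrastResult]:
    """Adjusted pairwise contrasts along the normouricemia -> hyperuricemia ->
    gout axis.  A probe shows the gouty-inflammation pattern when methylation
    is flat across the urate transition (normo vs hyper p >= 0.05) but shifts
    at the inflammation step (hyper vs gout p < 0.05)."""
    grp = samples.data["urate_group"]
    counts = grp.value_counts()
    results: list[GroupContrastResult] = []
    pairs = [("normo_vs_hyper", "normouricemia", "hyperuricemia"),
             ("hyper_vs_gout", "hyperuricemia", "gout")]
    for pid in probes:
        skip = False
        for _, a, b in pairs:
            if counts.get(a, 0) < min_group or counts.get(b, 0) < min_group:
                warnings.warn(
                    f"probe {pid!r}: group {a if counts.get(a,0) < min_group else b!r} "
                    f"has fewer than {min_group} samples; probe skipped",
                    stacklevel=2,
                )
                skip = True
                break
        if skip:
            continue
        for name, a, b in pairs:
            mask = grp.isin([a, b])
            sub = SampleTable(samples.data.loc[mask].assign(
                _contrast=(grp.loc[mask] == b).astype(float)))
            r = fit_cpg_association(betas, sub, pid, "_contrast", covariate_set)
            results.append(GroupContrastResult(pid, name, r.delta_beta, r.se, r.p, r.n_used))
    return results


def inflammation_pattern_flags(
    contrasts: list[GroupContrastResult], alpha: float = 0.05
) -> dict[str, bool]:
    by_probe: dict[str, dict[str, float]] = {}
    for c in contrasts:
        by_probe.setdefault(c.probe_id, {})[c.contrast] = c.p
    return {
        pid: ps.get("normo_vs_hyper", 0.0) >= alpha and ps.get("hyper_vs_gout", 1.0) < alpha
        for pid, ps in by_probe.items()
    }


def comethylation_neighbors(
    betas: BetaMatrix,
    annotation: CpGAnnotation,
    target_probe: str,
    window_bp: int = 5000,
    samples: SampleTable | None = None,
    covariate_set: tuple[str, ...] = DEFAULT_COVARIATES,
    r_threshold: float = 0.8,
) -> list[ComethylationResult]:
    """Pearson correlation between the target CpG and neighboring promoter /
    5'UTR probes (same gene, or within window_bp on the same chromosome),
    plus each neighbor's own adjusted gout association."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if target_probe not in annotation.data.index:
        raise KeyError(f"target probe {target_probe!r} not annotated")
    ann = annotation.data
    t = ann.loc[target_probe]
    promoter = ann["genomic_feature"].isin(PROMOTER_FEATURES)
    same_gene = (ann["gene"] == t["gene"]) & (ann["gene"] != "")
    near = (ann["chromosome"] == t["chromosome"]) & \
        (np.abs(ann["position"] - t["position"]) <= window_bp)
    neighbors = ann.index[promoter & (same_gene | near)].difference([target_probe])
    neighbors = [p for p in neighbors if p in set(betas.probe_ids)]
    if not neighbors:
        logger.info("no promoter neighbors for %s within %d bp", target_probe, window_bp)
        return []
    y0 = betas.values[target_probe].to_numpy(dtype=float)
    out = []
    for pid in neighbors:
        y1 = betas.values[pid].to_numpy(dtype=float)
        ok = ~np.isnan(y0) & ~np.isnan(y1)
        r = float(np.corrcoef(y0[ok], y1[ok])[0, 1]) if ok.sum() > 2 else float("nan")
        gout_p = float("nan")
        if samples is not None:
            gout_p = fit_cpg_association(betas, samples, pid, "gout", covariate_set).p
        out.append(ComethylationResult(target_probe, pid, r, gout_p,
                                       bool(abs(r) >= r_threshold)))
    return out
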