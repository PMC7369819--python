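"""Cis-window scans: variant -> methylation (meQTL) and variant -> gout.

For a candidate CpG the window is anchored at the probe position plus/minus
a flank (default 500 kb).  Methylation associations are covariate-adjusted
linear regressions; disease associations are covariate-adjusted logistic
regressions with a Firth bias-reduced refit when the likelihood separates.
Variants associated with both targets at the nominal threshold are the
"shared" set forwarded to the causal inference test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._design import DEFAULT_COVARIATES, build_covariate_matrix, check_collinearity
from ._glm import fit_logistic, fit_logistic_firth
from .io_formats import (
    BetaMatrix,
    CpGAnnotation,
    GenotypeMatrix,
    SampleTable,
    VariantAnnotation,
)

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 500_000


@dataclass(frozen=True)
class CisWindow:
    chromosome: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("window start > end")

    @classmethod
    def around(cls, annotation: CpGAnnotation, probe_id: str,
               flank_bp: int = DEFAULT_FLANK_BP) -> "CisWindow":
        row = annotation.data.loc[probe_id]
        pos = int(row["position"])
        return cls(str(row["chromosome"]), max(1, pos - flank_bp), pos + flank_bp)

    def contains(self, chromosome: str, position: int) -> bool:
        return str(chromosome) == self.chromosome and self.start <= position <= self.end


@dataclass
class AssociationRecord:
    variant_id: str
    target: str  # probe id or "gout"
    effect: float
    statistic: float
    p: float
    n_used: int
    position: int = -1
    firth: bool = False


@dataclass
class ScanResult:
    window: CisWindow
    target: str
    records: list[AssociationRecord] = field(default_factory=list)

    @property
    def p_by_variant(self) -> dict[str, float]:
        return {r.variant_id: r.p for r in self.records}


def _window_variants(variants: VariantAnnotation, window: CisWindow) -> pd.DataFrame:
    d = variants.data
    mask = (d["chromosome"].astype(str) == window.chromosome) & \
        (d["position"] >= window.start) & (d["position"] <= window.end)
    return d.loc[mask].sort_values("position", kind="mergesort")


def _aligned(genotypes: GenotypeMatrix, samples: SampleTable,
             covariate_set: tuple[str, ...]):
    common = genotypes.values.index.intersection(samples.data.index)
    sub = SampleTable(samples.data.loc[common])
    cov = build_covariate_matrix(sub, covariate_set) if covariate_set else \
        pd.DataFrame(index=common)
    return common, sub, cov


def scan_meqtl(
    betas: BetaMatrix,
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    probe_id: str,
    window: CisWindow,
    variants: VariantAnnotation,
    covariate_set: tuple[str, ...] = DEFAULT_COVARIATES,
) -> ScanResult:
    """Linear regression methylation ~ dosage + covariates per window variant.
    Monomorphic variants are skipped with a log entry."""
    in_win = _window_variants(variants, window)
    present = [v for v in in_win.index if v in set(genotypes.variant_ids)]
    if not present:
        raise ValueError(f"no variants in window {window} for probe {probe_id!r}")
    common, sub, cov = _aligned(genotypes, samples, covariate_set)
    common = common.intersection(betas.values.index)
    y_all = betas.values.loc[common, probe_id].to_numpy(dtype=float)
    C_all = cov.loc[common].to_numpy(dtype=float) if cov.shape[1] else \
        np.empty((len(common), 0))
    result = ScanResult(window, probe_id)
    for vid in present:
        g = genotypes.values.loc[common, vid].to_numpy(dtype=float)
        ok = ~np.isnan(g) & ~np.isnan(y_all)
        if C_all.shape[1]:
            ok &= ~np.isnan(C_all).any(axis=1)
        if np.ptp(g[ok]) == 0:
            logger.info("variant %s monomorphic for probe %s; skipped", vid, probe_id)
            continue
        X = np.column_stack([np.ones(ok.sum()), g[ok], C_all[ok]])
        check_collinearity(X[:, 1:], [vid] + list(cov.columns))
        fit = sm.OLS(y_all[ok], X).fit()
        result.records.append(AssociationRecord(
            vid, probe_id, float(fit.params[1]), float(fit.tvalues[1]),
            float(fit.pvalues[1]), int(ok.sum()),
            position=int(in_win.loc[vid, "position"])))
    return result


def scan_disease(
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    window: CisWindow,
    variants: VariantAnnotation,
    covariate_set: tuple[str, ...] = DEFAULT_COVARIATES,
) -> ScanResult:
    """Logistic regression gout ~ dosage + covariates per window variant;
    Wald p for the dosage term.  Separation or non-convergence triggers a
    Firth-penalized refit, flagged on the record."""
    in_win = _window_variants(variants, window)
    present = [v for v in in_win.index if v in set(genotypes.variant_ids)]
    if not present:
        raise ValueError(f"no variants in window {window}")
    common, sub, cov = _aligned(genotypes, samples, covariate_set)
    y_all = sub.data["gout"].to_numpy(dtype=float)
    if len(np.unique(y_all[~np.isnan(y_all)])) < 2:
        raise ValueError("gout outcome has a single class")
    C_all = cov.to_numpy(dtype=float) if cov.shape[1] else np.empty((len(common), 0))
    result = ScanResult(window, "gout")
    for vid in present:
        g = genotypes.values.loc[common, vid].to_numpy(dtype=float)
        ok = ~np.isnan(g) & ~np.isnan(y_all)
        if C_all.shape[1]:
            ok &= ~np.isnan(C_all).any(axis=1)
        if np.ptp(g[ok]) == 0:
            logger.info("variant %s monomorphic; skipped", vid)
            continue
        X = np.column_stack([np.ones(ok.sum()), g[ok], C_all[ok]])
        fit = fit_logistic(X, y_all[ok])
        firth = fit.separated
        if firth:
            ffit = fit_logistic_firth(X, y_all[ok])
            effect, p = float(ffit.coef[1]), ffit.wald_p(1)
            statistic = float(ffit.coef[1] / np.sqrt(ffit.cov[1, 1]))
        else:
            effect, p = float(fit.coef[1]), fit.wald_p(1)
            statistic = float(fit.coef[1] / np.sqrt(fit.cov[1, 1]))
        result.records.append(AssociationRecord(
            vid, "gout", effect, statistic, p, int(ok.sum()),
            position=int(in_win.loc[vid, "position"]), firth=firth))
    return result


def find_shared_variants(
    meqtl: ScanResult,
    disease: ScanResult,
    alpha: float = 0.05,
) -> list[str]:
    """Variants with meQTL p < alpha AND disease p < alpha, ordered by
    genomic position.  Both scans must cover the same window."""
    if meqtl.window != disease.window:
        raise ValueError(
            f"mismatched windows: {meqtl.window} vs {disease.window}"
        )
    pm = meqtl.p_by_variant
    pd_ = disease.p_by_variant
    pos = {r.variant_id: r.position for r in meqtl.records}
    shared = [v for v in pm if v in pd_ and pm[v] < alpha and pd_[v] < alpha]
    return sorted(shared, key=lambda v: (pos[v], v))


def regional_table(meqtl: ScanResult, disease: ScanResult,
                   shared: list[str]) -> pd.DataFrame:
    """Per-variant regional results (position, p_meqtl, p_gout, shared flag)."""
    pm, pg = meqtl.p_by_variant, disease.p_by_variant
    pos = {r.variant_id: r.position for r in meqtl.records}
    rows = [{"variant_id": v, "position": pos[v],
             "p_meqtl": pm[v], "p_gout": pg.get(v, float("nan")),
             "shared": v in set(shared)}
            for v in sorted(pm, key=lambda v: (pos[v], v)) if v in pg]
    return pd.DataFrame(rows)
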