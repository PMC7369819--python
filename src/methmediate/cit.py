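"""Causal inference test: does the chain variant L -> methylation G -> gout T hold?

Four component tests, each covariate-adjusted, with the omnibus p-value
equal to the largest component p (an intersection-union test: every link
must hold for mediation to be declared):

* p1 — T is associated with L (likelihood-ratio test in a logistic model);
* p2 — G is associated with L given T (t test in a linear model);
* p3 — T is associated with G given L (likelihood-ratio test);
* p4 — L is independent of T given G, tested in the equivalence direction:
  the observed likelihood-ratio statistic S_obs for L in T ~ L + G + cov is
  compared with a parametric-replicate null built under "no mediation"
  (outcomes re-drawn from a logistic model that retains L's marginal
  coefficient alongside the fitted G and covariate terms); p4 is the
  fraction of replicate statistics at or below S_obs, so the absence of
  residual L -> T signal yields a small p4.

p_omnibus < 0.05 is read as "methylation mediates the variant-gout
relationship"; otherwise the variant is a genetic confounder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from ._design import DEFAULT_COVARIATES, build_covariate_matrix
from ._glm import (
    _sigmoid,
    fit_logistic,
    fit_logistic_batch,
    fit_logistic_firth,
    logistic_lrt,
)
from .io_formats import BetaMatrix, GenotypeMatrix, SampleTable

MIN_COMPLETE_CASES = 50
MIN_B = 100
MEDIATION_ALPHA = 0.05


@dataclass
class CITResult:
    variant_id: str
    probe_id: str
    p1: float
    p2: float
    p3: float
    p4: float
    p_omnibus: float
    s1: float  # chi-square, L in T ~ L + cov
    s2: float  # t statistic, L in G ~ L + T + cov
    s3: float  # chi-square, G in T ~ G + L + cov
    s4: float  # observed chi-square compared against the replicate null
    n_used: int
    B: int
    seed: int

    @property
    def significant(self) -> bool:
        return self.p_omnibus < MEDIATION_ALPHA


def _component_fit(X, y, drop, component: str):
    stat, p, full = logistic_lrt(X, y, drop)
    if full.separated:
        ffit = fit_logistic_firth(X, y)
        if not ffit.converged:
            raise RuntimeError(
                f"CIT component {component}: penalized refit did not converge"
            )
    return stat, p


def cit_test(
    genotypes: GenotypeMatrix,
    betas: BetaMatrix,
    samples: SampleTable,
    variant_id: str,
    probe_id: str,
    covariate_set: tuple[str, ...] = DEFAULT_COVARIATES,
    B: int = 500,
    seed: int = 0,
) -> CITResult:
    """Run the four-component causal inference test for one (L, G, T) triple."""
    if B < MIN_B:
        raise ValueError(f"B must be >= {MIN_B}, got {B}")
    common = (genotypes.values.index
              .intersection(betas.values.index)
              .intersection(samples.data.index))
    L = genotypes.values.loc[common, variant_id].to_numpy(dtype=float)
    G = betas.values.loc[common, probe_id].to_numpy(dtype=float)
    T = samples.data.loc[common, "gout"].to_numpy(dtype=float)
    sub = SampleTable(samples.data.loc[common])
    cov = build_covariate_matrix(sub, covariate_set) if covariate_set else None
    C = cov.to_numpy(dtype=float) if cov is not None and cov.shape[1] else \
        np.empty((len(common), 0))
    ok = ~np.isnan(L) & ~np.isnan(G) & ~np.isnan(T)
    if C.shape[1]:
        ok &= ~np.isnan(C).any(axis=1)
    L, G, T, C = L[ok], G[ok], T[ok], C[ok]
    n = len(T)
    if n < MIN_COMPLETE_CASES:
        raise ValueError(f"{n} complete cases < required {MIN_COMPLETE_CASES}")
    if len(np.unique(T)) < 2:
        raise ValueError("gout outcome has a single class")
    if np.ptp(L) == 0:
        raise ValueError(f"variant {variant_id!r} has constant dosage")
    one = np.ones(n)

    # p1: T ~ L + cov, LRT for L
    X1 = np.column_stack([one, L, C])
    s1, p1 = _component_fit(X1, T, 1, "1 (T~L)")

    # p2: G ~ L + T + cov, t test for L
    X2 = np.column_stack([one, L, T, C])
    fit2 = sm.OLS(G, X2).fit()
    s2, p2 = float(fit2.tvalues[1]), float(fit2.pvalues[1])

    # p3: T ~ G + L + cov, LRT for G
    X3 = np.column_stack([one, G, L, C])
    s3, p3 = _component_fit(X3, T, 1, "3 (T~G|L)")

    # p4: equivalence test of L independent of T given G
    X_full = np.column_stack([one, L, G, C])
    X_red = np.column_stack([one, G, C])
    s_obs, _, full_fit = logistic_lrt(X_full, T, 1)
    marg = fit_logistic(X1, T)
    if marg.separated:
        marg = fit_logistic_firth(X1, T)
        if not marg.converged:
            raise RuntimeError("CIT component 4: penalized refit did not converge")
    gamma_L = float(marg.coef[1])
    red_fit = fit_logistic(X_red, T)
    if red_fit.separated:
        red_fit = fit_logistic_firth(X_red, T)
        if not red_fit.converged:
            raise RuntimeError("CIT component 4: penalized refit did not converge")
    eta0 = X_red @ red_fit.coef + gamma_L * (L - L.mean())
    rng = np.random.default_rng(seed)
    Tstar = (rng.random((n, B)) < _sigmoid(eta0)[:, None]).astype(float)
    warm_red = red_fit.coef if not getattr(red_fit, "separated", False) else None
    ll_red, beta_red = fit_logistic_batch(X_red, Tstar, beta0=warm_red)
    # warm-start the full model at each replicate's reduced optimum (zero for
    # the L column) so the nested likelihood ordering holds by construction
    warm_full = np.insert(beta_red, 1, 0.0, axis=0)
    ll_full, _ = fit_logistic_batch(X_full, Tstar, beta0=warm_full)
    s_star = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    p4 = float((1 + np.sum(s_star <= s_obs)) / (B + 1))

    ps = [p1, p2, p3, p4]
    return CITResult(
        variant_id=variant_id, probe_id=probe_id,
        p1=p1, p2=p2, p3=p3, p4=p4, p_omnibus=float(max(ps)),
        s1=s1, s2=s2, s3=s3, s4=float(s_obs),
        n_used=n, B=B, seed=seed,
    )


def per_variant_seed(seed: int, index: int) -> int:
    """Deterministic child seed for the index-th variant of a batch."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def cit_batch(
    shared_variants: list[str],
    probe_id: str,
    genotypes: GenotypeMatrix,
    betas: BetaMatrix,
    samples: SampleTable,
    covariate_set: tuple[str, ...] = DEFAULT_COVARIATES,
    B: int = 500,
    seed: int = 0,
) -> list[CITResult]:
    """One causal inference test per shared variant, with deterministic
    per-variant seeds derived from a common stream.  Empty input gives an
    empty result."""
    return [
        cit_test(genotypes, betas, samples, vid, probe_id,
                 covariate_set=covariate_set, B=B,
                 seed=per_variant_seed(seed, i))
        for i, vid in enumerate(shared_variants)
    ]
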