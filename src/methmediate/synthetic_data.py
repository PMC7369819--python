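"""Seeded synthetic cohorts with the causal structures the pipeline classifies.

The generator emulates a case/control blood-methylation cohort: leukocyte
proportions drawn from a Dirichlet, per-cell-type reference methylomes mixed
on the beta scale, cis genetic effects and covariate effects added on the
logit scale, and gout drawn from a logistic model whose intercept is
calibrated by bisection to a target prevalence.  Each target CpG carries one
of four causal structures:

* ``independent``  — methylation differs between cases and controls with no
  genetic driver (cases receive a logit shift calibrated to a target
  beta-scale difference);
* ``mediation``    — a cis variant shifts methylation, and gout risk depends
  on methylation only (variant -> CpG -> gout);
* ``confounding``  — a cis variant shifts both methylation and gout risk
  directly, with no methylation -> gout effect;
* ``null``         — no association with gout at all.

Decoy variants with no effect populate every target CpG's cis window so the
regional scan has a landscape to traverse.  Random streams are split per
component and per CpG, so enlarging the cohort's probe set does not perturb
earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .deconvolution import ReferenceProfiles, load_packaged_reference
from .io_formats import (
    BetaMatrix,
    CpGAnnotation,
    GenotypeMatrix,
    SampleTable,
    VariantAnnotation,
)

SCENARIOS = ("independent", "mediation", "confounding", "null")

#: scenario -> classification the pipeline should recover
EXPECTED_CLASSIFICATION = {
    "independent": "no_shared_variant",
    "mediation": "mediated",
    "confounding": "confounded",
    "null": "not_candidate",
}


def _logit(p):
    return np.log(p / (1.0 - p))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x)))


@dataclass
class CovariateEffects:
    """Coefficients of the shared covariates on gout log-odds and on
    logit-beta of every study CpG (age is centered at 50 years)."""

    gout_sex: float = 1.2
    gout_age: float = 0.03
    gout_pack_years: float = 0.01
    gout_alcohol: float = 0.3
    meth_sex: float = 0.05
    meth_age: float = 0.004
    meth_pack_years: float = 0.003
    meth_smoking_former: float = 0.03
    meth_smoking_current: float = 0.08
    meth_alcohol: float = 0.02

    def scaled(self, factor: float) -> "CovariateEffects":
        return CovariateEffects(**{k: v * factor for k, v in self.__dict__.items()})


@dataclass
class SimulationConfig:
    """Generative settings; defaults emulate the study cohort (1524 samples,
    4.5% gout prevalence) with effect sizes in the published range."""

    n_samples: int = 1524
    n_cpgs: int = 12
    n_cell_types: int = 6
    dirichlet_alpha: tuple = (35.0, 9.0, 5.0, 3.0, 2.0, 4.0)
    maf: float = 0.3
    scenarios: tuple = ("independent", "mediation", "confounding")
    meqtl_effect: float = 0.8            # per-allele shift on logit-beta
    disease_effect_methylation: float = 3.0  # gout log-odds per unit beta
    disease_effect_variant: float = 0.7      # gout log-odds per allele (confounding)
    delta_beta_target: float = 0.01          # case-control beta difference (independent)
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    noise_sd: float = 0.55               # logit-normal residual noise (beta-scale sd ~0.12 mid-range)
    gout_prevalence: float = 0.045
    hyperuricemia_fraction: float = 0.30
    n_decoy_variants: int = 9
    flank_bp: int = 100_000              # causal/decoy variants placed within this window
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")
        if len(self.scenarios) > self.n_cpgs:
            raise ValueError("more scenarios than CpGs")
        bad = set(self.scenarios) - set(SCENARIOS)
        if bad:
            raise ValueError(f"unknown scenarios {sorted(bad)}")
        if len(self.dirichlet_alpha) != self.n_cell_types:
            raise ValueError("dirichlet_alpha length must equal n_cell_types")
        if min(self.dirichlet_alpha) <= 0:
            raise ValueError("dirichlet_alpha entries must be positive")
        if not 0 < self.gout_prevalence < 1:
            raise ValueError("gout_prevalence must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SimulatedCohort:
    betas: BetaMatrix
    genotypes: GenotypeMatrix
    samples: SampleTable
    cpg_annotation: CpGAnnotation
    variant_annotation: VariantAnnotation
    truth: pd.DataFrame               # per-CpG scenario, true delta-beta, causal variant
    reference: ReferenceProfiles
    true_cell_proportions: pd.DataFrame
    config: SimulationConfig


def _calibrate_intercept(lp: np.ndarray, prevalence: float) -> float:
    """Bisection for the logistic intercept achieving the target mean risk."""
    lo, hi = -25.0, 25.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _invlogit(mid + lp).mean() > prevalence:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    config.validate()
    n = config.n_samples
    ce = config.covariate_effects
    root = np.random.SeedSequence(config.seed)
    (ss_prop, ss_ref, ss_geno, ss_cov, ss_noise, ss_pheno,
     ss_pos, ss_urate) = root.spawn(8)
    rng_prop = np.random.default_rng(ss_prop)
    rng_ref = np.random.default_rng(ss_ref)
    rng_cov = np.random.default_rng(ss_cov)
    rng_pheno = np.random.default_rng(ss_pheno)
    rng_pos = np.random.default_rng(ss_pos)
    rng_urate = np.random.default_rng(ss_urate)

    sample_ids = [f"S{i:05d}" for i in range(n)]

    # --- covariates -------------------------------------------------------
    sex = rng_cov.binomial(1, 0.5, n).astype(float)
    age = np.clip(rng_cov.normal(49.0, 11.0, n), 25.0, 80.0)
    smoking = rng_cov.choice(np.array(["never", "former", "current"]), size=n,
                             p=[0.60, 0.15, 0.25])
    pack_years = np.where(smoking == "never", 0.0,
                          rng_cov.gamma(2.0, 8.0, n))
    alcohol = rng_cov.binomial(1, 0.3, n).astype(float)
    bmi = 24.5 + 1.2 * sex + rng_cov.normal(0.0, 3.3, n)
    hba1c = 5.7 + 0.015 * (age - 50.0) + rng_cov.normal(0.0, 0.65, n)
    chol = 190.0 + 0.3 * (age - 50.0) + rng_cov.normal(0.0, 33.0, n)

    meth_cov = (
        ce.meth_sex * sex
        + ce.meth_age * (age - 50.0)
        + ce.meth_pack_years * pack_years
        + ce.meth_smoking_former * (smoking == "former")
        + ce.meth_smoking_current * (smoking == "current")
        + ce.meth_alcohol * alcohol
    )
    gout_cov = (
        ce.gout_sex * sex
        + ce.gout_age * (age - 50.0)
        + ce.gout_pack_years * pack_years
        + ce.gout_alcohol * alcohol
    )

    # --- cell mixture ------------------------------------------------------
    props = rng_prop.dirichlet(np.asarray(config.dirichlet_alpha, dtype=float), size=n)
    if config.n_cell_types == 6:
        reference = load_packaged_reference()
    else:
        reference = _draw_reference(config.n_cell_types, rng_ref)
    R = reference.data.to_numpy(dtype=float)  # panel probes x cell types
    panel_base = props @ R.T  # n x panel probes, beta scale

    # --- study CpGs --------------------------------------------------------
    scen = list(config.scenarios) + ["null"] * (config.n_cpgs - len(config.scenarios))
    probe_ids = [f"cgsim{j:04d}" for j in range(config.n_cpgs)]
    genes = [f"GENE{j + 1}" for j in range(config.n_cpgs)]
    features = [("TSS200", "5UTR", "TSS1500")[j % 3] for j in range(config.n_cpgs)]
    chroms = [str(j + 1) for j in range(config.n_cpgs)]
    cpg_pos = [1_000_000] * config.n_cpgs

    noise_children = ss_noise.spawn(config.n_cpgs)
    geno_children = ss_geno.spawn(config.n_cpgs)
    ref_children = ss_ref.spawn(config.n_cpgs)

    study_logit = np.empty((n, config.n_cpgs))
    dosage_cols: dict[str, np.ndarray] = {}
    var_rows: list[dict] = []
    causal_variant: list[str | None] = []

    for j, sc in enumerate(scen):
        rj = np.random.default_rng(ref_children[j])
        # target CpGs sit mid-range, where differential methylation is detectable
        base_logit = rj.uniform(-0.5, 0.5) if sc != "null" else rj.normal(0.0, 1.5)
        dev = rj.normal(0.0, 0.3, config.n_cell_types)
        cell_betas = _invlogit(base_logit + dev)
        mix = props @ cell_betas  # beta scale mixture baseline
        eta = _logit(np.clip(mix, 1e-6, 1 - 1e-6)) + meth_cov
        nj = np.random.default_rng(noise_children[j])
        if config.noise_sd > 0:
            eta = eta + nj.normal(0.0, config.noise_sd, n)

        cj = None
        ids_here: list[str] = []
        if sc in ("mediation", "confounding"):
            gj = np.random.default_rng(geno_children[j])
            L = gj.binomial(2, config.maf, n).astype(float)
            cj = f"rs{10_000 + j * 100}"
            dosage_cols[cj] = L
            ids_here.append(cj)
            eta = eta + config.meqtl_effect * L
        if sc != "null":
            gj_decoy = np.random.default_rng(geno_children[j].spawn(1)[0])
            n_decoys = config.n_decoy_variants + (0 if cj else 1)
            for k in range(n_decoys):
                vid = f"rs{10_000 + j * 100 + k + 1}"
                dosage_cols[vid] = gj_decoy.binomial(2, config.maf, n).astype(float)
                ids_here.append(vid)
            # positions for all window variants, unique and sorted
            positions = rng_pos.choice(
                np.arange(cpg_pos[j] - config.flank_bp, cpg_pos[j] + config.flank_bp),
                size=len(ids_here), replace=False)
            for vid, pos in zip(ids_here, np.sort(positions)):
                var_rows.append({"variant_id": vid, "chromosome": chroms[j],
                                 "position": int(pos), "ref": "A", "alt": "G"})
        causal_variant.append(cj)
        study_logit[:, j] = eta

    study_beta = _invlogit(study_logit)

    # --- disease model -----------------------------------------------------
    lp = gout_cov.copy()
    for j, sc in enumerate(scen):
        if sc == "mediation":
            b = study_beta[:, j]
            lp = lp + config.disease_effect_methylation * (b - b.mean())
        elif sc == "confounding":
            L = dosage_cols[causal_variant[j]]
            lp = lp + config.disease_effect_variant * (L - L.mean())
    intercept = _calibrate_intercept(lp, config.gout_prevalence)
    gout = rng_pheno.binomial(1, _invlogit(intercept + lp)).astype(float)

    # --- independent CpGs: case shift calibrated to delta_beta_target ------
    true_delta = []
    for j, sc in enumerate(scen):
        if sc == "independent":
            m = study_beta[:, j].mean()
            d = config.delta_beta_target / max(m * (1.0 - m), 0.05)
            shifted = _invlogit(study_logit[:, j] + d)
            study_beta[:, j] = np.where(gout == 1, shifted, study_beta[:, j])
            true_delta.append(config.delta_beta_target)
        elif sc == "null":
            true_delta.append(0.0)
        else:
            true_delta.append(np.nan)  # marginal difference is implied, not targeted

    # --- assemble ----------------------------------------------------------
    urate = np.where(
        gout == 1, "gout",
        np.where(rng_urate.random(n) < config.hyperuricemia_fraction,
                 "hyperuricemia", "normouricemia"))

    beta_df = pd.DataFrame(
        np.hstack([study_beta, np.clip(panel_base, 0.0, 1.0)]),
        index=sample_ids, columns=probe_ids + reference.probe_ids)
    betas = BetaMatrix(beta_df)

    geno_df = pd.DataFrame(dosage_cols, index=sample_ids)
    genotypes = GenotypeMatrix(geno_df)

    samples = SampleTable(pd.DataFrame({
        "sex": sex, "age": age, "pack_years": pack_years,
        "smoking_status": smoking, "alcohol": alcohol, "gout": gout,
        "urate_group": urate, "bmi": bmi, "hba1c": hba1c,
        "total_cholesterol": chol,
    }, index=pd.Index(sample_ids, name="sample_id")))

    ann_rows = {
        "chromosome": chroms + ["0"] * len(reference.probe_ids),
        "position": cpg_pos + list(range(1, len(reference.probe_ids) + 1)),
        "gene": genes + [""] * len(reference.probe_ids),
        "genomic_feature": features + ["Body"] * len(reference.probe_ids),
        "cpg_island": [s != "null" for s in scen] + [False] * len(reference.probe_ids),
    }
    annotation = CpGAnnotation(pd.DataFrame(
        ann_rows, index=pd.Index(probe_ids + reference.probe_ids, name="probe_id")))

    var_ann = VariantAnnotation(
        pd.DataFrame(var_rows).set_index("variant_id")
        if var_rows else
        pd.DataFrame(columns=["chromosome", "position", "ref", "alt"],
                     index=pd.Index([], name="variant_id")))

    truth = pd.DataFrame({
        "scenario": scen,
        "true_delta_beta": true_delta,
        "causal_variant": causal_variant,
        "gene": genes,
        "expected_classification": [EXPECTED_CLASSIFICATION[s] for s in scen],
    }, index=pd.Index(probe_ids, name="probe_id"))

    true_props = pd.DataFrame(props, index=sample_ids, columns=reference.cell_types)

    return SimulatedCohort(betas, genotypes, samples, annotation, var_ann,
                           truth, reference, true_props, config)


def strong_effects_config(**overrides) -> SimulationConfig:
    """Validation regime with clearly detectable effects at every stage:
    a 1.2 logit/allele meQTL, gout odds rising e^0.8-fold per 10% methylation,
    a 1.0 log-odds/allele direct variant effect, and an 8% case-control
    methylation difference for genetically independent CpGs.  Used for
    end-to-end recovery checks, where each causal structure should be
    recovered nearly every time."""
    base = dict(meqtl_effect=1.2, disease_effect_methylation=8.0,
                disease_effect_variant=1.0, delta_beta_target=0.08)
    base.update(overrides)
    return SimulationConfig(**base)


def _draw_reference(n_cell_types: int, rng: np.random.Generator) -> ReferenceProfiles:
    """Random discriminating panel for non-default cell-type counts."""
    names = [f"CT{k}" for k in range(n_cell_types)]
    rows, ids = [], []
    for k in range(n_cell_types):
        for j in range(50):
            row = np.clip(rng.uniform(0.75, 0.95, n_cell_types)
                          + rng.normal(0, 0.04, n_cell_types), 0, 1)
            row[k] = rng.uniform(0.03, 0.15)
            rows.append(row)
            ids.append(f"ref_{names[k]}_{j:03d}")
    return ReferenceProfiles(pd.DataFrame(rows, index=ids, columns=names))


def scenario_truth_table(cohort: SimulatedCohort) -> pd.DataFrame:
    """One row per simulated CpG: generative scenario and the classification
    the pipeline is expected to assign."""
    return cohort.truth[["scenario", "expected_classification",
                         "true_delta_beta", "causal_variant"]].copy()
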