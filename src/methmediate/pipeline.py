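"""End-to-end decision procedure and reporting.

Stages: cell-type deconvolution -> promoter EWAS (BH FDR) -> candidate
filter (FDR < 0.05 and gene on the curated IL-1-beta / gouty-inflammation
list) -> metabolic-trait specificity and urate-group contrasts (annotations)
-> cis meQTL + disease scans -> causal inference tests for shared variants
-> per-CpG classification -> co-methylation of survivors' neighbors.

Classification rule per candidate CpG:

* no variant associated with both its methylation and gout -> the epigenetic
  association is genetically independent (``no_shared_variant``, survives);
* shared variants exist and every one passes the causal inference test ->
  methylation mediates the variant-gout relationship (``mediated``, survives);
* any shared variant fails -> the variant confounds the association
  (``confounded``, dropped).

A fixture mode replays the packaged worked example (the published nine-row
candidate table) through the same classification and summary code without
any cohort data.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._design import DEFAULT_COVARIATES
from .cit import CITResult, cit_batch
from .deconvolution import estimate_cell_proportions, load_packaged_reference, read_reference_profiles
from .ewas import (
    EwasResult,
    comethylation_neighbors,
    inflammation_pattern_flags,
    promoter_ewas,
    three_group_contrasts,
    trait_specificity,
)
from .io_formats import (
    BetaMatrix,
    CandidateTable,
    load_candidate_fixture,
    load_curated_gene_config,
    read_beta_matrix,
    read_cpg_annotation,
    read_genotypes,
    read_sample_table,
    read_variant_annotation,
    write_results_table,
)
from .qtl_scan import CisWindow, find_shared_variants, regional_table, scan_disease, scan_meqtl
from .synthetic_data import SimulationConfig, simulate_cohort

STATUSES = ("no_shared_variant", "mediated", "confounded", "not_candidate")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending entity."""


@dataclass
class ClassificationRecord:
    probe_id: str
    gene: str
    delta_beta_percent: float
    p: float
    q: float
    candidate: bool
    shared_variants: list
    cit_results: list  # CITResult per shared variant
    status: str
    survives: bool
    inflammation_pattern: bool
    gout_specific: bool
    category: str = ""
    chromosome: str = ""
    position: int = -1

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class PipelineReport:
    records: list
    counts: dict
    provenance: dict

    def to_json(self) -> str:
        recs = []
        for r in self.records:
            d = asdict(r)
            d["cit_results"] = [
                {"variant_id": c.variant_id, "p_omnibus": c.p_omnibus}
                for c in r.cit_results
            ]
            recs.append(d)
        return json.dumps(
            {"records": recs, "counts": self.counts, "provenance": self.provenance},
            sort_keys=True, indent=1, allow_nan=True,
        )


def classify_cpg(
    ewas_row,
    shared_variants: list,
    cit_results: list,
    *,
    candidate: bool = True,
    alpha_cit: float = 0.05,
    gene: str = "",
    category: str = "",
    chromosome: str = "",
    position: int = -1,
    inflammation_pattern: bool = False,
    gout_specific: bool = False,
) -> ClassificationRecord:
    """Classify one CpG from its association row, shared-variant set and
    causal inference test results."""
    by_variant = {c.variant_id: c for c in cit_results}
    missing = [v for v in shared_variants if v not in by_variant]
    if missing:
        raise ValueError(f"missing CIT result for shared variant(s) {missing}")
    if not candidate:
        status = "not_candidate"
    elif not shared_variants:
        status = "no_shared_variant"
    elif all(by_variant[v].p_omnibus < alpha_cit for v in shared_variants):
        status = "mediated"
    else:
        status = "confounded"
    survives = status in ("no_shared_variant", "mediated")
    delta_pct = float(ewas_row.delta_beta) * 100.0 if isinstance(ewas_row, EwasResult) \
        else float(ewas_row["delta_beta_percent"])
    p = float(ewas_row.p if isinstance(ewas_row, EwasResult) else ewas_row["p"])
    q = float(ewas_row.q) if isinstance(ewas_row, EwasResult) else float("nan")
    return ClassificationRecord(
        probe_id=ewas_row.probe_id if isinstance(ewas_row, EwasResult) else str(ewas_row.name),
        gene=gene, delta_beta_percent=delta_pct, p=p, q=q,
        candidate=candidate,
        shared_variants=list(shared_variants),
        cit_results=list(cit_results),
        status=status, survives=survives,
        inflammation_pattern=inflammation_pattern, gout_specific=gout_specific,
        category=category, chromosome=str(chromosome), position=int(position),
    )


def summarize_report(report: PipelineReport) -> dict:
    """Headline counts: candidates, survivors by mechanism and by category,
    and the |delta-beta| range (percent) among survivors."""
    recs = [r for r in report.records]
    cands = [r for r in recs if r.candidate]
    survivors = [r for r in recs if r.survives]
    il1b = [r for r in survivors
            if r.category in ("il1b_production", "expressed_macrophage_il1b")]
    gi = [r for r in survivors if r.category == "gouty_inflammation"]
    abs_db = [abs(r.delta_beta_percent) for r in survivors]
    return {
        "n_candidates": len(cands),
        "n_survivors": len(survivors),
        "n_no_shared_variant": sum(r.status == "no_shared_variant" for r in recs),
        "n_mediated": sum(r.status == "mediated" for r in recs),
        "n_confounded": sum(r.status == "confounded" for r in recs),
        "n_survivors_il1b": len(il1b),
        "n_survivors_gouty_inflammation": len(gi),
        "min_abs_delta_beta_percent": float(min(abs_db)) if abs_db else float("nan"),
        "max_abs_delta_beta_percent": float(max(abs_db)) if abs_db else float("nan"),
    }


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | files | fixture
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    beta_path: str = ""
    genotype_path: str = ""
    sample_path: str = ""
    cpg_annotation_path: str = ""
    variant_annotation_path: str = ""
    reference_path: str = ""   # deconvolution reference ("" -> packaged panel)
    candidate_genes: dict | None = None  # gene -> {category, il1b_direction}
    covariate_set: tuple = DEFAULT_COVARIATES
    alpha_fdr: float = 0.05
    alpha_shared: float = 0.05
    alpha_cit: float = 0.05
    flank_bp: int = 500_000
    comethylation_window_bp: int = 5000
    r_threshold: float = 0.8
    cit_B: int = 500
    contrast_gate: bool = False  # gate candidates on the inflammation pattern
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "covariate_set"},
                  **({"covariate_set": tuple(raw["covariate_set"])}
                     if "covariate_set" in raw else {}))
        if sim:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def content_hash(self) -> str:
        d = asdict(self)
        d["covariate_set"] = list(self.covariate_set)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage {name!r} failed: {e}") from e


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineReport:
    t_start = time.perf_counter()
    timings: list[tuple[str, float]] = []

    def clock(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = _stage(name, fn, *args, **kwargs)
        timings.append((name, time.perf_counter() - t0))
        return out

    if config.mode == "fixture":
        report = _run_fixture(config)
        _write_outputs(report, [], {}, [], config, out_dir, timings)
        return report

    # --- load or simulate the cohort --------------------------------------
    if config.mode == "synthetic":
        sim = SimulationConfig(**{**asdict(config.simulation), "seed": config.seed})
        sim.covariate_effects = config.simulation.covariate_effects
        cohort = clock("simulate", simulate_cohort, sim)
        betas, genotypes = cohort.betas, cohort.genotypes
        samples, annotation = cohort.samples, cohort.cpg_annotation
        variants = cohort.variant_annotation
        if config.candidate_genes is None:
            tr = cohort.truth
            curated = {row.gene: {"category": "il1b_production", "il1b_direction": "unknown"}
                       for row in tr.itertuples() if row.scenario != "null"}
        else:
            curated = config.candidate_genes
        reference = cohort.reference
    elif config.mode == "files":
        betas = clock("read_betas", read_beta_matrix, config.beta_path)
        genotypes = clock("read_genotypes", read_genotypes, config.genotype_path)
        samples = clock("read_samples", read_sample_table, config.sample_path)
        annotation = clock("read_annotation", read_cpg_annotation, config.cpg_annotation_path)
        variants = clock("read_variants", read_variant_annotation, config.variant_annotation_path)
        if config.candidate_genes is None:
            curated = {g: meta for g, meta in load_curated_gene_config()["genes"].items()}
        else:
            curated = config.candidate_genes
        reference = (read_reference_profiles(config.reference_path)
                     if config.reference_path else load_packaged_reference())
    else:
        raise PipelineError(f"stage 'config' failed: unknown mode {config.mode!r}")

    # --- deconvolution -----------------------------------------------------
    props = clock("deconvolution", estimate_cell_proportions, betas, reference)
    samples = samples.with_cell_proportions(props.data)

    # --- promoter EWAS + FDR ----------------------------------------------
    ewas_results = clock("promoter_ewas", promoter_ewas, betas, samples,
                         annotation, config.covariate_set)
    by_probe = {r.probe_id: r for r in ewas_results}

    gene_of = annotation.data["gene"].to_dict()
    candidates = [r.probe_id for r in ewas_results
                  if r.q < config.alpha_fdr and gene_of.get(r.probe_id, "") in curated]

    # --- annotations: trait specificity, urate-group contrasts -------------
    gout_specific: dict[str, bool] = {}
    pattern: dict[str, bool] = {}
    if candidates:
        _, gout_specific = clock("trait_specificity", trait_specificity,
                                 betas, samples, candidates,
                                 covariate_set=config.covariate_set)
        contrasts = clock("three_group_contrasts", three_group_contrasts,
                          betas, samples, candidates, config.covariate_set)
        pattern = inflammation_pattern_flags(contrasts)
    if config.contrast_gate:
        candidates = [p for p in candidates if pattern.get(p, False)]

    # --- genetic/meQTL scans + CIT + classification -------------------------
    records: list[ClassificationRecord] = []
    scan_tables: dict[str, pd.DataFrame] = {}
    all_cits: list[CITResult] = []
    tested = set(annotation.data.index[
        annotation.data["genomic_feature"].isin(("TSS1500", "TSS200", "5UTR"))])
    for pid in sorted(by_probe, key=lambda p: (str(gene_of.get(p, "")), p)):
        if pid not in tested:
            continue
        r = by_probe[pid]
        ann = annotation.data.loc[pid]
        is_cand = pid in candidates
        shared: list[str] = []
        cits: list[CITResult] = []
        if is_cand:
            window = CisWindow.around(annotation, pid, config.flank_bp)
            has_vars = not variants.data.loc[
                (variants.data["chromosome"].astype(str) == window.chromosome)
                & (variants.data["position"] >= window.start)
                & (variants.data["position"] <= window.end)].empty
            if has_vars:
                meqtl = clock(f"scan_meqtl[{pid}]", scan_meqtl, betas, genotypes,
                              samples, pid, window, variants, config.covariate_set)
                disease = clock(f"scan_disease[{pid}]", scan_disease, genotypes,
                                samples, window, variants, config.covariate_set)
                shared = find_shared_variants(meqtl, disease, config.alpha_shared)
                scan_tables[pid] = regional_table(meqtl, disease, shared)
                if shared:
                    cits = clock(f"cit[{pid}]", cit_batch, shared, pid, genotypes,
                                 betas, samples, config.covariate_set,
                                 config.cit_B, config.seed)
                    all_cits.extend(cits)
        records.append(classify_cpg(
            r, shared, cits, candidate=is_cand, alpha_cit=config.alpha_cit,
            gene=str(gene_of.get(pid, "")), category="",
            chromosome=str(ann["chromosome"]), position=int(ann["position"]),
            inflammation_pattern=bool(pattern.get(pid, False)),
            gout_specific=bool(gout_specific.get(pid, False)),
        ))

    # --- co-methylation of survivors ---------------------------------------
    cometh = []
    for rec in records:
        if rec.survives:
            cometh.extend(clock(f"comethylation[{rec.probe_id}]",
                                comethylation_neighbors, betas, annotation,
                                rec.probe_id, config.comethylation_window_bp,
                                samples, config.covariate_set, config.r_threshold))

    counts = None
    report = PipelineReport(records, {}, {
        "tool": "methmediate", "version": __version__,
        "config_hash": config.content_hash(), "seed": config.seed,
        "mode": config.mode,
    })
    report.counts = summarize_report(report)
    _check_report(report)
    timings.append(("total", time.perf_counter() - t_start))
    _write_outputs(report, ewas_results, scan_tables, cometh, config, out_dir, timings)
    return report


def _check_report(report: PipelineReport) -> None:
    # structural invariants, asserted on every run
    for r in report.records:
        assert r.survives == (r.status in ("no_shared_variant", "mediated"))
        if r.survives and r.shared_variants:
            assert all(c.p_omnibus < 0.05 for c in r.cit_results)
    tallies = summarize_report(report)
    assert set(report.counts) == set(tallies)
    for k, v in tallies.items():
        w = report.counts[k]
        assert (v == w) or (isinstance(v, float) and np.isnan(v) and np.isnan(w))


def _run_fixture(config: PipelineConfig) -> PipelineReport:
    """Replay the packaged candidate table through classification/summary.

    Shared-variant sets come from the packaged replay map; each mapped
    variant's test outcome is encoded as a replayed omnibus p (0.01 for a
    significant causal inference test, 0.5 otherwise) so the classifier
    applies the same rule as in cohort mode."""
    table = _stage("load_fixture", load_candidate_fixture)
    replay = _stage("load_gene_config", load_curated_gene_config)
    shared_map = replay.get("shared_variants", {})
    records = []
    for pid, row in table.data.iterrows():
        entry = shared_map.get(pid, {"variants": [], "cit_significant": True})
        shared = list(entry["variants"])
        p_enc = 0.01 if entry["cit_significant"] else 0.5
        cits = [CITResult(v, pid, p_enc, p_enc, p_enc, p_enc, p_enc,
                          float("nan"), float("nan"), float("nan"), float("nan"),
                          0, 0, config.seed)
                for v in shared]
        records.append(classify_cpg(
            row, shared, cits, candidate=True, alpha_cit=config.alpha_cit,
            gene=row["gene"], category=row["category"],
            chromosome=row["chromosome"], position=int(row["position"]),
            inflammation_pattern=True, gout_specific=True,
        ))
    records.sort(key=lambda r: (int(r.chromosome), r.position))
    report = PipelineReport(records, {}, {
        "tool": "methmediate", "version": __version__,
        "config_hash": config.content_hash(), "seed": config.seed,
        "mode": "fixture",
    })
    report.counts = summarize_report(report)
    _check_report(report)
    return report


def classification_table(records: list) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "probe_id": r.probe_id, "gene": r.gene, "chromosome": r.chromosome,
            "position": r.position, "delta_beta_percent": r.delta_beta_percent,
            "p": r.p, "q": r.q, "candidate": r.candidate,
            "shared_variants": ",".join(r.shared_variants),
            "cit_p_omnibus": ",".join(repr(c.p_omnibus) for c in r.cit_results),
            "status": r.status, "survives": r.survives,
            "inflammation_pattern": r.inflammation_pattern,
            "gout_specific": r.gout_specific, "category": r.category,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["chromosome", "position"],
                            key=lambda s: s.map(_chrom_key) if s.name == "chromosome" else s,
                            kind="mergesort").reset_index(drop=True)
    return df


def _chrom_key(c):
    try:
        return int(c)
    except (TypeError, ValueError):
        return 10_000


def _write_outputs(report, ewas_results, scan_tables, cometh, config, out_dir, timings):
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json() + "\n")
    write_results_table(classification_table(report.records), out / "classification.tsv")
    if ewas_results:
        write_results_table(ewas_results, out / "ewas_results.tsv")
    for pid, tbl in scan_tables.items():
        write_results_table(tbl, out / f"qtl_{pid}.tsv")
    if cometh:
        write_results_table(cometh, out / "comethylation.tsv")
    with open(out / "run.log", "w") as fh:
        fh.write(f"methmediate {__version__} seed={config.seed} "
                 f"config={config.content_hash()}\n")
        for name, dt in timings:
            fh.write(f"{name}\t{dt:.3f}s\n")
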