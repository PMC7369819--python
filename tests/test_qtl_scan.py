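"""Cis-window scans: exactness, calibration hooks, separation handling."""

import numpy as np
import pandas as pd
import pytest

from methmediate.io_formats import (
    BetaMatrix,
    CpGAnnotation,
    GenotypeMatrix,
    SampleTable,
    VariantAnnotation,
)
from methmediate.qtl_scan import (
    AssociationRecord,
    CisWindow,
    ScanResult,
    find_shared_variants,
    scan_disease,
    scan_meqtl,
)


def _samples(gout):
    n = len(gout)
    return SampleTable(pd.DataFrame({
        "sex": 0.0, "age": 50.0, "pack_years": 0.0, "smoking_status": "never",
        "alcohol": 0.0, "gout": np.asarray(gout, dtype=float),
        "urate_group": ["gout" if g else "normouricemia" for g in gout],
        "bmi": 24.0, "hba1c": 5.5, "total_cholesterol": 190.0,
    }, index=[f"s{i}" for i in range(n)]))


def _variants(ids, positions, chrom="1"):
    return VariantAnnotation(pd.DataFrame({
        "chromosome": chrom, "position": positions, "ref": "A", "alt": "G",
    }, index=pd.Index(ids, name="variant_id")))


def _annotation(probe, pos=1000, chrom="1"):
    return CpGAnnotation(pd.DataFrame({
        "chromosome": [chrom], "position": [pos], "gene": ["G1"],
        "genomic_feature": ["TSS200"], "cpg_island": [True],
    }, index=pd.Index([probe], name="probe_id")))


class TestWindow:
    def test_anchoring_and_containment(self):
        ann = _annotation("cgA", pos=100_000)
        w = CisWindow.around(ann, "cgA", flank_bp=50_000)
        assert (w.start, w.end) == (50_000, 150_000)
        assert w.contains("1", 100_000) and not w.contains("2", 100_000)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            CisWindow("1", 10, 5)


class TestScanMeqtl:
    def test_exact_linear_relation(self, rng):
        n = 200
        g = rng.binomial(2, 0.4, n).astype(float)
        bm = BetaMatrix(pd.DataFrame({"cgA": 0.4 + 0.05 * g},
                                     index=[f"s{i}" for i in range(n)]))
        gm = GenotypeMatrix(pd.DataFrame({"rs1": g}, index=bm.sample_ids))
        res = scan_meqtl(bm, gm, _samples(rng.binomial(1, 0.2, n)), "cgA",
                         CisWindow("1", 1, 2000), _variants(["rs1"], [500]),
                         covariate_set=())
        rec = res.records[0]
        assert np.isclose(rec.effect, 0.05, atol=1e-12)
        assert rec.p < 1e-200

    def test_monomorphic_skipped(self, rng, caplog):
        n = 100
        bm = BetaMatrix(pd.DataFrame({"cgA": rng.uniform(0.3, 0.7, n)},
                                     index=[f"s{i}" for i in range(n)]))
        gm = GenotypeMatrix(pd.DataFrame(
            {"rs1": np.zeros(n), "rs2": rng.binomial(2, 0.3, n).astype(float)},
            index=bm.sample_ids))
        import logging
        with caplog.at_level(logging.INFO, logger="methmediate.qtl_scan"):
            res = scan_meqtl(bm, gm, _samples(rng.binomial(1, 0.2, n)), "cgA",
                             CisWindow("1", 1, 2000), _variants(["rs1", "rs2"], [100, 200]),
                             covariate_set=())
        assert [r.variant_id for r in res.records] == ["rs2"]
        assert any("monomorphic" in m for m in caplog.messages)

    def test_causal_variant_attains_window_minimum(self, strong_cohort, strong_samples):
        tr = strong_cohort.truth
        probe = tr.index[tr.scenario == "mediation"][0]
        causal = tr.loc[probe, "causal_variant"]
        ann = strong_cohort.cpg_annotation
        w = CisWindow.around(ann, probe, 200_000)
        res = scan_meqtl(strong_cohort.betas, strong_cohort.genotypes,
                         strong_samples, probe, w, strong_cohort.variant_annotation)
        best = min(res.records, key=lambda r: r.p)
        assert best.variant_id == causal

    def test_allele_flip_preserves_p(self, rng):
        n = 300
        g = rng.binomial(2, 0.3, n).astype(float)
        y = np.clip(0.5 + 0.02 * g + rng.normal(0, 0.05, n), 0, 1)
        bm = BetaMatrix(pd.DataFrame({"cgA": y}, index=[f"s{i}" for i in range(n)]))
        st = _samples(rng.binomial(1, 0.2, n))
        win, var = CisWindow("1", 1, 2000), _variants(["rs1"], [500])
        a = scan_meqtl(bm, GenotypeMatrix(pd.DataFrame({"rs1": g}, index=bm.sample_ids)),
                       st, "cgA", win, var, covariate_set=()).records[0]
        b = scan_meqtl(bm, GenotypeMatrix(pd.DataFrame({"rs1": 2 - g}, index=bm.sample_ids)),
                       st, "cgA", win, var, covariate_set=()).records[0]
        assert np.isclose(a.p, b.p, atol=1e-10)
        assert np.isclose(a.effect, -b.effect, atol=1e-12)


class TestScanDisease:
    def test_confounding_causal_variant_detected(self, strong_cohort, strong_samples):
        tr = strong_cohort.truth
        probe = tr.index[tr.scenario == "confounding"][0]
        causal = tr.loc[probe, "causal_variant"]
        w = CisWindow.around(strong_cohort.cpg_annotation, probe, 200_000)
        res = scan_disease(strong_cohort.genotypes, strong_samples, w,
                           strong_cohort.variant_annotation)
        rec = {r.variant_id: r for r in res.records}[causal]
        assert rec.p < 0.01 and rec.effect > 0

    def test_single_class_outcome_raises(self, rng):
        n = 60
        gm = GenotypeMatrix(pd.DataFrame(
            {"rs1": rng.binomial(2, 0.3, n).astype(float)},
            index=[f"s{i}" for i in range(n)]))
        with pytest.raises(ValueError, match="single class"):
            scan_disease(gm, _samples(np.zeros(n)), CisWindow("1", 1, 2000),
                         _variants(["rs1"], [500]), covariate_set=())

    def test_perfect_separation_takes_firth_path(self):
        n = 40
        gout = np.r_[np.ones(20), np.zeros(20)]
        g = np.r_[np.full(20, 2.0), np.zeros(20)]
        gm = GenotypeMatrix(pd.DataFrame({"rs1": g}, index=[f"s{i}" for i in range(n)]))
        res = scan_disease(gm, _samples(gout), CisWindow("1", 1, 2000),
                           _variants(["rs1"], [500]), covariate_set=())
        rec = res.records[0]
        assert rec.firth
        assert np.isfinite(rec.effect) and abs(rec.effect) < 15

    def test_null_variants_type_one_error(self, rng):
        """Dosage independent of gout: rejection at 0.05 within 3 binomial se
        (400 simulated variants)."""
        n, m = 500, 400
        gout = rng.binomial(1, 0.1, n).astype(float)
        ids = [f"rs{j}" for j in range(m)]
        gm = GenotypeMatrix(pd.DataFrame(
            {v: rng.binomial(2, 0.3, n).astype(float) for v in ids},
            index=[f"s{i}" for i in range(n)]))
        res = scan_disease(gm, _samples(gout), CisWindow("1", 1, m + 10),
                           _variants(ids, list(range(1, m + 1))), covariate_set=())
        rate = np.mean([r.p < 0.05 for r in res.records])
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / m)


class TestSharedVariants:
    @staticmethod
    def _scan(target, pvals, window=None):
        w = window or CisWindow("1", 1, 1000)
        recs = [AssociationRecord(v, target, 0.1, 1.0, p, 100, position=i + 1)
                for i, (v, p) in enumerate(pvals.items())]
        return ScanResult(w, target, recs)

    def test_one_sided_failure_not_shared(self):
        m = self._scan("cgA", {"rs1": 0.04})
        d = self._scan("gout", {"rs1": 0.2})
        assert find_shared_variants(m, d) == []

    def test_alpha_zero_empty_and_monotone_in_alpha(self):
        pvals_m = {"rs1": 0.01, "rs2": 0.03, "rs3": 0.2}
        pvals_d = {"rs1": 0.02, "rs2": 0.04, "rs3": 0.01}
        m, d = self._scan("cgA", pvals_m), self._scan("gout", pvals_d)
        assert find_shared_variants(m, d, alpha=0.0) == []
        prev: set = set()
        for alpha in (0.015, 0.025, 0.05, 0.5):
            cur = set(find_shared_variants(m, d, alpha))
            assert prev <= cur
            prev = cur
        assert prev == {"rs1", "rs2", "rs3"}

    def test_mismatched_windows_raise(self):
        m = self._scan("cgA", {"rs1": 0.01})
        d = self._scan("gout", {"rs1": 0.01}, window=CisWindow("2", 1, 1000))
        with pytest.raises(ValueError, match="mismatched windows"):
            find_shared_variants(m, d)

    def test_mediation_causal_variant_shared(self, strong_cohort, strong_samples):
        tr = strong_cohort.truth
        probe = tr.index[tr.scenario == "mediation"][0]
        causal = tr.loc[probe, "causal_variant"]
        w = CisWindow.around(strong_cohort.cpg_annotation, probe, 200_000)
        m = scan_meqtl(strong_cohort.betas, strong_cohort.genotypes,
                       strong_samples, probe, w, strong_cohort.variant_annotation)
        d = scan_disease(strong_cohort.genotypes, strong_samples, w,
                         strong_cohort.variant_annotation)
        assert causal in find_shared_variants(m, d)
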