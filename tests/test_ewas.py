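"""EWAS regressions, FDR, group contrasts, trait screens, co-methylation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methmediate.ewas import (
    bh_qvalues,
    comethylation_neighbors,
    fit_cpg_association,
    inflammation_pattern_flags,
    manhattan_table,
    promoter_ewas,
    three_group_contrasts,
    trait_specificity,
)
from methmediate.io_formats import BetaMatrix, CpGAnnotation, SampleTable
from methmediate.synthetic_data import SimulationConfig, simulate_cohort


def _samples(gout, **extra):
    n = len(gout)
    base = {
        "sex": 0.0, "age": 50.0, "pack_years": 0.0, "smoking_status": "never",
        "alcohol": 0.0, "gout": np.asarray(gout, dtype=float),
        "urate_group": ["gout" if g else "normouricemia" for g in gout],
        "bmi": 24.0, "hba1c": 5.5, "total_cholesterol": 190.0,
    }
    base.update(extra)
    return SampleTable(pd.DataFrame(base, index=[f"s{i}" for i in range(n)]))


def _betas(cols, n):
    return BetaMatrix(pd.DataFrame(cols, index=[f"s{i}" for i in range(n)]))


class TestFitCpgAssociation:
    def test_binary_outcome_without_covariates_is_difference_of_means(self):
        gout = np.r_[np.ones(30), np.zeros(30)]
        y = np.where(gout == 1, 0.55, 0.50) + np.r_[np.linspace(-0.01, 0.01, 60)]
        bm = _betas({"cgA": y}, 60)
        res = fit_cpg_association(bm, _samples(gout), "cgA", covariate_set=())
        diff = y[gout == 1].mean() - y[gout == 0].mean()
        assert np.isclose(res.delta_beta, diff, atol=1e-14)

    def test_orthogonal_covariate_leaves_delta_beta(self, rng):
        n = 200
        gout = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        y = 0.5 + 0.03 * gout + rng.normal(0, 0.01, n)
        # build a covariate numerically orthogonal to both outcome and methylation
        z = rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), gout, y])
        z -= X @ np.linalg.lstsq(X, z, rcond=None)[0]
        st_ = _samples(gout, age=50.0 + z)
        bm = _betas({"cgA": y}, n)
        r0 = fit_cpg_association(bm, st_, "cgA", covariate_set=())
        r1 = fit_cpg_association(bm, st_, "cgA", covariate_set=("age",))
        assert abs(r0.delta_beta - r1.delta_beta) < 1e-10

    def test_delta_beta_antisymmetric_under_label_swap(self, rng):
        n = 120
        gout = rng.binomial(1, 0.4, n).astype(float)
        y = np.clip(0.5 + 0.05 * gout + rng.normal(0, 0.05, n), 0, 1)
        bm = _betas({"cgA": y}, n)
        a = fit_cpg_association(bm, _samples(gout), "cgA", covariate_set=())
        b = fit_cpg_association(bm, _samples(1 - gout), "cgA", covariate_set=())
        assert np.isclose(a.delta_beta, -b.delta_beta, atol=1e-12)
        assert np.isclose(a.p, b.p, atol=1e-12)

    def test_degenerate_probe_and_collinear_covariates(self, rng):
        n = 60
        gout = rng.binomial(1, 0.5, n).astype(float)
        bm = _betas({"cgA": np.full(n, 0.4),
                     "cgB": rng.uniform(0.3, 0.6, n)}, n)
        with pytest.raises(ValueError, match="degenerate probe"):
            fit_cpg_association(bm, _samples(gout), "cgA", covariate_set=())
        age = rng.normal(50, 5, n)
        st_ = _samples(gout, age=age, bmi=age * 2.0)  # exact collinearity
        with pytest.raises(ValueError, match="age.*bmi|bmi.*age"):
            fit_cpg_association(bm, st_, "cgB", covariate_set=("age", "bmi"))

    def test_coverage_of_generative_effect_with_confounder(self, rng):
        """A covariate driving both gout and methylation: the adjusted estimate
        covers the generative effect ~95% of the time (checked over 25 runs)."""
        hits = 0
        true_eff = 0.03
        for k in range(25):
            r = np.random.default_rng(k)
            n = 500
            z = r.normal(0, 1, n)
            gout = (r.random(n) < 1 / (1 + np.exp(-(-1.0 + 1.5 * z)))).astype(float)
            y = np.clip(0.5 + true_eff * gout + 0.04 * z + r.normal(0, 0.03, n), 0, 1)
            st_ = _samples(gout, age=50 + 5 * z)
            res = fit_cpg_association(_betas({"cgA": y}, n), st_, "cgA",
                                      covariate_set=("age",))
            hits += abs(res.delta_beta - true_eff) < 2 * res.se
        assert hits >= 21


class TestBH:
    def test_worked_example(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, pvals):
        p = np.array(pvals)
        q = bh_qvalues(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        cummin = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            cummin = min(cummin, p[i] * m / rank)
            brute[i] = cummin
        assert np.allclose(q, brute, atol=1e-12)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)


def _annotation(probes, feature="TSS200", gene="G1", chrom="1", start=100):
    return CpGAnnotation(pd.DataFrame({
        "chromosome": chrom, "position": range(start, start + len(probes)),
        "gene": gene, "genomic_feature": feature, "cpg_island": True,
    }, index=pd.Index(probes, name="probe_id")))


class TestPromoterEwas:
    def test_non_promoter_only_raises(self, rng):
        n = 60
        bm = _betas({"cgA": rng.uniform(0.2, 0.8, n)}, n)
        ann = _annotation(["cgA"], feature="Body")
        with pytest.raises(ValueError, match="promoter"):
            promoter_ewas(bm, _samples(rng.binomial(1, 0.5, n)), ann, covariate_set=())

    def test_fast_path_agrees_with_per_probe_statsmodels(self, strong_cohort, strong_samples):
        res = promoter_ewas(strong_cohort.betas, strong_samples,
                            strong_cohort.cpg_annotation)
        for r in res[:4]:
            single = fit_cpg_association(strong_cohort.betas, strong_samples,
                                         r.probe_id)
            assert np.isclose(r.delta_beta, single.delta_beta, atol=1e-10)
            assert np.isclose(r.p, single.p, atol=1e-10)
        assert all(r.q >= r.p - 1e-15 for r in res)

    def test_invariant_to_probe_and_sample_permutation(self, strong_cohort, strong_samples):
        res = promoter_ewas(strong_cohort.betas, strong_samples,
                            strong_cohort.cpg_annotation)
        rng = np.random.default_rng(4)
        vals = strong_cohort.betas.values
        shuffled = BetaMatrix(
            vals.loc[rng.permutation(vals.index), rng.permutation(vals.columns)])
        res2 = promoter_ewas(shuffled, strong_samples, strong_cohort.cpg_annotation)
        a = {r.probe_id: (r.delta_beta, r.p, r.q) for r in res}
        b = {r.probe_id: (r.delta_beta, r.p, r.q) for r in res2}
        for pid in a:
            assert np.allclose(a[pid], b[pid], atol=1e-10)

    def test_true_signals_reach_fdr_significance(self):
        """Five genuinely shifted CpGs among nulls attain q < 0.05 (stable
        probes, 1-2% shifts) in nearly every replicate."""
        found, n_seeds = 0, 5
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_samples=2000, seed=seed, n_cpgs=105,
                scenarios=("independent",) * 5,
                delta_beta_target=0.015, noise_sd=0.1)
            coh = simulate_cohort(cfg)
            res = promoter_ewas(coh.betas, coh.samples, coh.cpg_annotation,
                                covariate_set=("sex", "age"))
            qs = {r.probe_id: r.q for r in res}
            found += all(qs[p] < 0.05 for p in coh.truth.index[:5])
        assert found >= n_seeds - 1

    def test_manhattan_table_sorted(self, strong_cohort, strong_samples):
        res = promoter_ewas(strong_cohort.betas, strong_samples,
                            strong_cohort.cpg_annotation)
        tbl = manhattan_table(res, strong_cohort.cpg_annotation)
        assert list(tbl.columns[:3]) == ["probe_id", "chromosome", "position"]
        assert (tbl.groupby("chromosome")["position"].apply(
            lambda s: s.is_monotonic_increasing)).all()


class TestTraitSpecificity:
    def test_strong_trait_signal_detected_and_constant_trait_raises(self, rng):
        n = 2000
        gout = rng.binomial(1, 0.1, n).astype(float)
        y = rng.uniform(0.3, 0.7, n)
        st_ = _samples(gout, bmi=24 + 40 * y + rng.normal(0, 0.01, n))
        bm = _betas({"cgA": y}, n)
        res, flags = trait_specificity(bm, st_, ["cgA"], traits=("bmi",),
                                       covariate_set=())
        assert res[0].p < 1e-6 and not flags["cgA"]
        st_bad = _samples(gout, hba1c=5.5)
        with pytest.raises(ValueError, match="constant outcome"):
            trait_specificity(bm, st_bad, ["cgA"], traits=("hba1c",), covariate_set=())

    def test_null_traits_flag_gout_specific(self, strong_cohort, strong_samples):
        probes = list(strong_cohort.truth.index[:3])
        _, flags = trait_specificity(strong_cohort.betas, strong_samples, probes)
        # traits are generated independent of methylation; most probes pass
        assert sum(flags.values()) >= 2

    def test_type_one_error_calibrated(self, rng):
        """Null trait regressions reject at ~5%: within 3 binomial se over
        400 simulated probes."""
        n, m = 300, 400
        gout = rng.binomial(1, 0.1, n).astype(float)
        bm = _betas({f"cg{j}": rng.uniform(0.3, 0.7, n) for j in range(m)}, n)
        st_ = _samples(gout, bmi=rng.normal(24, 3, n))
        res, _ = trait_specificity(bm, st_, [f"cg{j}" for j in range(m)],
                                   traits=("bmi",), covariate_set=())
        rate = np.mean([r.p < 0.05 for r in res])
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / m)


class TestThreeGroupContrasts:
    def test_sign_pattern(self, rng):
        n = 300
        urate = np.array(["normouricemia"] * 100 + ["hyperuricemia"] * 100 + ["gout"] * 100)
        gout = (urate == "gout").astype(float)
        y = np.where(gout == 1, 0.6, 0.5) + rng.normal(0, 0.01, n)
        st_ = _samples(gout)
        st_.data["urate_group"] = urate
        bm = _betas({"cgA": np.clip(y, 0, 1)}, n)
        res = three_group_contrasts(bm, st_, ["cgA"], covariate_set=())
        by = {r.contrast: r for r in res}
        assert abs(by["normo_vs_hyper"].difference) < 0.01
        assert by["hyper_vs_gout"].difference > 0.05
        flags = inflammation_pattern_flags(res)
        assert flags["cgA"]

    def test_small_group_warns_and_skips(self, rng):
        n = 30
        urate = np.array(["normouricemia"] * 26 + ["hyperuricemia"] * 2 + ["gout"] * 2)
        gout = (urate == "gout").astype(float)
        st_ = _samples(gout)
        st_.data["urate_group"] = urate
        bm = _betas({"cgA": rng.uniform(0.4, 0.6, n)}, n)
        with pytest.warns(UserWarning, match="skipped"):
            res = three_group_contrasts(bm, st_, ["cgA"], covariate_set=())
        assert res == []

    def test_pattern_recovered_on_generated_targets(self, strong_cohort, strong_samples):
        probes = list(strong_cohort.truth.index[
            strong_cohort.truth.scenario == "independent"])
        res = three_group_contrasts(strong_cohort.betas, strong_samples, probes)
        flags = inflammation_pattern_flags(res)
        assert all(flags[p] for p in probes)


class TestComethylation:
    def test_identical_neighbor_r_one_and_block_flagging(self, rng):
        n = 500
        f = rng.normal(0, 1, n)
        def mk(load):
            z = load * f + np.sqrt(1 - load ** 2) * rng.normal(0, 1, n)
            return 1 / (1 + np.exp(-0.5 * z))
        cols = {"cgT": mk(0.95), "cgN1": mk(0.95), "cgN2": mk(0.95),
                "cgInd": 1 / (1 + np.exp(-rng.normal(0, 0.5, n)))}
        cols["cgSame"] = cols["cgT"]
        bm = _betas(cols, n)
        ann = _annotation(list(cols), feature="5UTR")
        res = comethylation_neighbors(bm, ann, "cgT", window_bp=50)
        by = {r.neighbor_probe: r for r in res}
        assert np.isclose(by["cgSame"].r, 1.0)
        assert by["cgN1"].comethylated and by["cgN2"].comethylated
        assert abs(by["cgInd"].r) < 0.15 and not by["cgInd"].comethylated

    def test_independent_neighbor_has_small_r(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 2000
            bm = _betas({"cgT": r.uniform(0.3, 0.7, n),
                         "cgN": r.uniform(0.3, 0.7, n)}, n)
            ann = _annotation(["cgT", "cgN"])
            res = comethylation_neighbors(bm, ann, "cgT", window_bp=50)
            hits += abs(res[0].r) < 0.1
        assert hits >= 9

    def test_no_neighbors_gives_empty_result(self, rng):
        n = 50
        bm = _betas({"cgT": rng.uniform(0.3, 0.7, n)}, n)
        ann = _annotation(["cgT"])
        assert comethylation_neighbors(bm, ann, "cgT", window_bp=10) == []

    def test_neighbor_gout_association_reported(self, rng):
        n = 400
        gout = rng.binomial(1, 0.2, n).astype(float)
        bm = _betas({"cgT": rng.uniform(0.3, 0.7, n),
                     "cgN": rng.uniform(0.3, 0.7, n)}, n)
        ann = _annotation(["cgT", "cgN"])
        res = comethylation_neighbors(bm, ann, "cgT", window_bp=50,
                                      samples=_samples(gout), covariate_set=())
        assert len(res) == 1
        assert 0 <= res[0].neighbor_gout_p <= 1
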