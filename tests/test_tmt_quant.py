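import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from cleaveqc.tmt_quant import (
    PEPTIDE_LEVEL,
    PROTEIN_LEVEL,
    PSM_LEVEL,
    LogRatioTable,
    ReporterMatrix,
    _trimmed_sd,
    align_and_scale,
    bh_adjust,
    dixon_filter,
    dixon_filter_table,
    fit_mixture,
    moderated_t_test,
    rollup,
    to_log_ratios,
)


def make_matrix(rows, roles):
    return ReporterMatrix(pd.DataFrame(rows), roles)


ROLES = {"ch1": "sample", "ch2": "sample", "ref1": "reference", "ref2": "reference"}


class TestToLogRatios:
    def test_ratio_against_reference_mean(self):
        m = make_matrix(
            [{"psm_id": "a", "peptide": "PEP", "protein": "P", "ch1": 200.0, "ch2": 100.0,
              "ref1": 100.0, "ref2": 100.0}],
            ROLES,
        )
        t = to_log_ratios(m)
        by_ch = t.data.set_index("channel")["log2_ratio"]
        assert by_ch["ch1"] == pytest.approx(1.0)
        assert by_ch["ch2"] == pytest.approx(0.0)

    def test_zero_reference_row_dropped_and_counted(self):
        m = make_matrix(
            [
                {"psm_id": "a", "peptide": "PEP", "protein": "P", "ch1": 200.0, "ch2": 10.0,
                 "ref1": 0.0, "ref2": 0.0},
                {"psm_id": "b", "peptide": "PEP", "protein": "P", "ch1": 50.0, "ch2": 10.0,
                 "ref1": 100.0, "ref2": 100.0},
            ],
            ROLES,
        )
        t = to_log_ratios(m)
        assert t.n_dropped_zero_reference == 1
        assert set(t.data["psm_id"]) == {"b"}

    def test_zero_sample_channel_treated_as_missing(self):
        m = make_matrix(
            [{"psm_id": "a", "peptide": "PEP", "protein": "P", "ch1": 0.0, "ch2": 100.0,
              "ref1": 100.0, "ref2": 100.0}],
            ROLES,
        )
        t = to_log_ratios(m)
        assert set(t.data["channel"]) == {"ch2"}

    def test_row_scaling_invariance(self):
        rows = [{"psm_id": "a", "peptide": "PEP", "protein": "P", "ch1": 120.0, "ch2": 80.0,
                 "ref1": 90.0, "ref2": 110.0}]
        scaled = [{k: (v * 7.0 if isinstance(v, float) else v) for k, v in rows[0].items()}]
        r1 = to_log_ratios(make_matrix(rows, ROLES)).data["log2_ratio"]
        r2 = to_log_ratios(make_matrix(scaled, ROLES)).data["log2_ratio"]
        assert np.allclose(r1, r2)

    def test_no_reference_channel_error(self):
        with pytest.raises(ValueError, match="reference"):
            make_matrix(
                [{"psm_id": "a", "peptide": "P", "protein": "P", "ch1": 1.0}],
                {"ch1": "sample"},
            )


class TestDixon:
    def test_n_le_2_never_altered(self):
        assert dixon_filter([1.0, 1.02]) == ([1.0, 1.02], [])
        assert dixon_filter([5.0]) == ([5.0], [])

    def test_gross_outlier_removed_in_triplicate(self):
        # r10 = (5.0-1.02)/(5.0-1.0) = 0.995 > 0.970 (two-tailed critical, n=3, alpha 0.05)
        retained, removed = dixon_filter([1.0, 1.02, 5.0], 0.05)
        assert removed == [5.0] and retained == [1.0, 1.02]

    def test_moderate_spread_kept(self):
        # r10 = 0.5, well below the n=3 critical value
        retained, removed = dixon_filter([1.0, 2.0, 3.0], 0.05)
        assert removed == []

    def test_low_outlier_removed_symmetrically(self):
        retained, removed = dixon_filter([-5.0, 1.0, 1.02], 0.05)
        assert removed == [-5.0]

    def test_conservation_partition(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            vals = list(rng.normal(0, 1, rng.integers(3, 12)))
            if rng.random() < 0.5:
                vals.append(float(rng.normal(0, 20)))
            retained, removed = dixon_filter(vals, 0.05)
            assert sorted(retained + removed) == sorted(vals)
            assert len(retained) >= 2

    def test_degenerate_constant_input_unchanged(self):
        assert dixon_filter([2.0, 2.0, 2.0]) == ([2.0, 2.0, 2.0], [])

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            dixon_filter([1.0, 2.0, 3.0], alpha=0.10)

    def test_false_removal_rate_matches_alpha(self):
        """On clean normal triplicates the two-tailed test removes ~5%."""
        rng = np.random.default_rng(11)
        removed = sum(
            bool(dixon_filter(rng.normal(0, 1, 3), 0.05)[1]) for _ in range(4000)
        )
        assert abs(removed / 4000 - 0.05) < 0.012

    def test_table_filter_only_touches_big_groups(self):
        df = pd.DataFrame(
            {
                "psm_id": [f"p{i}" for i in range(5)],
                "peptide": ["A", "A", "B", "B", "B"],
                "protein": ["P"] * 5,
                "channel": ["ch1"] * 5,
                "log2_ratio": [0.0, 9.0, 1.0, 1.02, 5.0],
                "mean_reporter_intensity": [1.0] * 5,
            }
        )
        out, n_removed = dixon_filter_table(LogRatioTable(PSM_LEVEL, df))
        assert n_removed == 1
        kept_a = out.data[out.data["peptide"] == "A"]["log2_ratio"].tolist()
        assert kept_a == [0.0, 9.0]  # pair untouched despite huge spread
        kept_b = out.data[out.data["peptide"] == "B"]["log2_ratio"].tolist()
        assert kept_b == [1.0, 1.02]


class TestRollup:
    def test_median_of_psms(self):
        df = pd.DataFrame(
            {
                "psm_id": ["a", "b", "c"],
                "peptide": ["PEP"] * 3,
                "protein": ["P"] * 3,
                "channel": ["ch1"] * 3,
                "log2_ratio": [0.9, 1.0, 1.1],
                "mean_reporter_intensity": [1.0, 2.0, 3.0],
            }
        )
        pep = rollup(LogRatioTable(PSM_LEVEL, df), PEPTIDE_LEVEL)
        assert pep.data["log2_ratio"].iloc[0] == pytest.approx(1.0)
        assert pep.data["mean_reporter_intensity"].iloc[0] == pytest.approx(2.0)

    def test_single_psm_identity(self):
        df = pd.DataFrame(
            {"psm_id": ["a"], "peptide": ["PEP"], "protein": ["P"], "channel": ["ch1"],
             "log2_ratio": [0.37], "mean_reporter_intensity": [5.0]}
        )
        pep = rollup(LogRatioTable(PSM_LEVEL, df), PEPTIDE_LEVEL)
        assert pep.data["log2_ratio"].iloc[0] == pytest.approx(0.37)

    def test_matches_two_stage_median_oracle(self):
        rng = np.random.default_rng(4)
        rows = []
        for prot in ("P1", "P2", "P3"):
            for pep_i in range(rng.integers(1, 5)):
                for psm_i in range(rng.integers(1, 6)):
                    rows.append(
                        {"psm_id": f"{prot}-{pep_i}-{psm_i}", "peptide": f"{prot}PEP{pep_i}",
                         "protein": prot, "channel": "ch1",
                         "log2_ratio": float(rng.normal()), "mean_reporter_intensity": 1.0}
                    )
        df = pd.DataFrame(rows)
        prot_table = rollup(rollup(LogRatioTable(PSM_LEVEL, df), PEPTIDE_LEVEL), PROTEIN_LEVEL)
        # brute-force two-stage median
        for prot, grp in df.groupby("protein"):
            pep_medians = grp.groupby("peptide")["log2_ratio"].median()
            expected = pep_medians.median()
            got = prot_table.data.set_index("protein").loc[prot, "log2_ratio"]
            assert got == pytest.approx(expected)

    def test_psm_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "psm_id": [f"p{i}" for i in range(30)],
                "peptide": list(rng.choice(["A", "B", "C"], 30)),
                "protein": ["P"] * 30,
                "channel": list(rng.choice(["ch1", "ch2"], 30)),
                "log2_ratio": rng.normal(size=30),
                "mean_reporter_intensity": rng.uniform(1, 9, 30),
            }
        )
        a = rollup(LogRatioTable(PSM_LEVEL, df), PEPTIDE_LEVEL).data
        shuffled = df.sample(frac=1, random_state=0).reset_index(drop=True)
        b = rollup(LogRatioTable(PSM_LEVEL, shuffled), PEPTIDE_LEVEL).data
        pd.testing.assert_frame_equal(a, b)


class TestFitMixture:
    def test_degenerate_constant_values(self):
        fit = fit_mixture([3.0] * 25)
        assert fit.degenerate and fit.density_mode == 3.0

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            fit_mixture([0.1] * 19)

    def test_bimodal_mode_at_major_component(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 0.2, 4000), rng.normal(2, 0.2, 1000)])
        fit = fit_mixture(x, seed=1)
        assert abs(fit.density_mode - 0.0) < 0.05
        assert np.isclose(fit.weights.sum(), 1.0)

    def test_unimodal_mode_at_mean(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0.7, 0.3, 2000)
        fit = fit_mixture(x, seed=1)
        assert abs(fit.density_mode - 0.7) < 0.05


class TestAlignAndScale:
    @staticmethod
    def _table(offsets, seed=7, n=600):
        rng = np.random.default_rng(seed)
        base = np.concatenate([rng.normal(0, 0.3, int(n * 0.85)), rng.normal(1.5, 0.3, n - int(n * 0.85))])
        intensity = rng.lognormal(10, 1, n)
        rows = []
        for ch, d in offsets.items():
            for i in range(n):
                rows.append(
                    {"protein": f"P{i}", "channel": ch, "log2_ratio": base[i] + d,
                     "mean_reporter_intensity": intensity[i]}
                )
        return LogRatioTable(PROTEIN_LEVEL, pd.DataFrame(rows))

    def test_centered_channel_has_near_zero_offset(self):
        table = self._table({"a": 0.0})
        _, diag = align_and_scale(table, seed=1)
        assert abs(diag[0].offset) < 0.05

    def test_known_shift_recovered_and_sds_equalized(self):
        table = self._table({"a": 0.0, "b": 0.5})
        norm, diag = align_and_scale(table, seed=1)
        offsets = {d.channel: d.offset for d in diag}
        assert offsets["b"] - offsets["a"] == pytest.approx(0.5, abs=0.05)
        sds = []
        for ch in ("a", "b"):
            sub = norm.data[norm.data["channel"] == ch]
            sds.append(
                _trimmed_sd(sub["log2_ratio"].to_numpy(), sub["mean_reporter_intensity"].to_numpy(), (5.0, 95.0))
            )
        assert abs(sds[0] - sds[1]) < 1e-6

    def test_prescaling_invariance(self):
        # three channels so the median trimmed SD is robust to rescaling one
        table = self._table({"a": 0.0, "b": 0.2, "c": -0.1})
        norm1, _ = align_and_scale(table, seed=1)
        scaled = self._table({"a": 0.0, "b": 0.2, "c": -0.1})
        mask = scaled.data["channel"] == "b"
        scaled.data.loc[mask, "log2_ratio"] *= 2.0
        norm2, _ = align_and_scale(scaled, seed=1)
        a = norm1.data.sort_values(["channel", "protein"])["log2_ratio"].to_numpy()
        b = norm2.data.sort_values(["channel", "protein"])["log2_ratio"].to_numpy()
        assert np.allclose(a, b, atol=0.02)

    def test_small_channel_falls_back_to_median(self):
        table = self._table({"a": 0.0}, n=10)
        _, diag = align_and_scale(table, seed=1)
        assert diag[0].method == "median_fallback"


class TestModeratedT:
    def test_identical_groups_null_result(self):
        df = pd.DataFrame(
            {"t1": [1.0], "t2": [2.0], "t3": [3.0], "u1": [1.0], "u2": [2.0], "u3": [3.0]},
            index=["P"],
        )
        res = moderated_t_test(df, ["t1", "t2", "t3"], ["u1", "u2", "u3"])
        assert res.loc["P", "log2_fc"] == 0.0
        assert res.loc["P", "t_statistic"] == pytest.approx(0.0)

    def test_zero_prior_df_limit_equals_pooled_t(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(0, 1, (40, 6)), columns=["t1", "t2", "t3", "u1", "u2", "u3"])
        df.iloc[:5, :3] += 2.0
        res = moderated_t_test(df, ["t1", "t2", "t3"], ["u1", "u2", "u3"], d0_override=1e-12)
        from scipy import stats as sps

        for i in range(len(df)):
            t_ref, _ = sps.ttest_ind(df.iloc[i, :3], df.iloc[i, 3:], equal_var=True)
            assert res["t_statistic"].iloc[i] == pytest.approx(t_ref, rel=1e-4)

    def test_untested_proteins_reported(self):
        df = pd.DataFrame(
            {"t1": [1.0, 1.0], "t2": [2.0, np.nan], "t3": [1.5, np.nan],
             "u1": [1.0, 1.0], "u2": [2.0, 2.0], "u3": [1.5, 2.0]},
            index=["ok", "missing"],
        )
        res = moderated_t_test(df, ["t1", "t2", "t3"], ["u1", "u2", "u3"])
        assert bool(res.loc["ok", "tested"])
        assert not bool(res.loc["missing", "tested"])

    def test_null_type_one_error_close_to_alpha(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.normal(0, 0.3, (1000, 6)), columns=["t1", "t2", "t3", "u1", "u2", "u3"])
        res = moderated_t_test(df, ["t1", "t2", "t3"], ["u1", "u2", "u3"])
        frac = float((res["p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_agrees_with_limma_oracle(self, tmp_path):
        """Independent cross-check of the moderated statistics against limma eBayes."""
        rng = np.random.default_rng(3)
        data = rng.normal(0, 0.3, (120, 6))
        data[:10, :3] += 1.0
        df = pd.DataFrame(data, columns=["t1", "t2", "t3", "u1", "u2", "u3"],
                          index=[f"P{i}" for i in range(120)])
        res = moderated_t_test(df, ["t1", "t2", "t3"], ["u1", "u2", "u3"])
        csv = tmp_path / "d.csv"
        out = tmp_path / "out.csv"
        df.to_csv(csv)
        script = f"""
        suppressMessages(library(limma))
        d <- read.csv("{csv}", row.names=1)
        design <- cbind(Intercept=1, Treat=c(1,1,1,0,0,0))
        fit <- eBayes(lmFit(d, design))
        write.csv(data.frame(t=fit$t[,"Treat"], p=fit$p.value[,"Treat"]), "{out}")
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        limma = pd.read_csv(out, index_col=0)
        merged = res.join(limma)
        corr = np.corrcoef(merged["t_statistic"], merged["t"])[0, 1]
        assert corr > 0.999
        rel = np.abs(merged["t_statistic"] - merged["t"]) / np.abs(merged["t"]).clip(lower=0.5)
        assert rel.max() < 0.05


class TestBHAdjust:
    def test_step_up_example(self):
        # brute force from the step-up definition: q_i = min_{j>=i} p_(j)*m/j
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.04, 0.04, 0.04]), [0.04, 0.04, 0.04])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 37)
        m = len(p)
        order = np.argsort(p)
        sorted_p = p[order]
        q_sorted = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_adjust(p), expected)

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
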