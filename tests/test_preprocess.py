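"""Probe/sample exclusions, lipid trimming, zygosity calling, adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidmeth import (
    SimulationConfig,
    adjust_cell_and_batch,
    apply_probe_filters,
    call_zygosity,
    exclude_samples,
    log_transform_and_trim,
    preprocess_cohort,
    simulate_cohort,
)
from lipidmeth.preprocess import ProbeQC


def make_qc(n_probes, n_samples, det_p=0.001, beads=12):
    probes = [f"cg{j:03d}" for j in range(n_probes)]
    cols = [f"s{j}" for j in range(n_samples)]
    return ProbeQC(
        detection_p=pd.DataFrame(det_p, index=probes, columns=cols),
        bead_counts=pd.DataFrame(beads, index=probes, columns=cols),
        flags=pd.DataFrame(
            False,
            index=probes,
            columns=["non_cpg", "multi_hit", "snp_maf_gt_005", "sex_chromosome"],
        ),
    )


def beta_like(qc):
    return pd.DataFrame(
        0.5, index=qc.detection_p.index, columns=qc.detection_p.columns
    )


class TestProbeFilters:
    def test_clean_probes_all_retained(self):
        qc = make_qc(100, 20)
        kept, report = apply_probe_filters(beta_like(qc), qc)
        assert len(kept) == 100
        assert all(len(v) == 0 for v in report.values())

    def test_detection_threshold_arithmetic(self):
        # p = 0.2 in 2 of 100 samples -> 2% > 1% -> removed
        qc = make_qc(10, 100)
        qc.detection_p.iloc[0, :2] = 0.2
        kept, report = apply_probe_filters(beta_like(qc), qc)
        assert report["detection"] == ["cg000"]
        assert "cg000" not in kept.index
        # exactly 1 of 100 (1%, not > 1%) is kept
        qc2 = make_qc(10, 100)
        qc2.detection_p.iloc[1, :1] = 0.2
        kept2, report2 = apply_probe_filters(beta_like(qc2), qc2)
        assert report2["detection"] == []

    def test_bead_count_filter(self):
        qc = make_qc(10, 100)
        qc.bead_counts.iloc[3, :6] = 2  # 6% > 5%
        _, report = apply_probe_filters(beta_like(qc), qc)
        assert report["beads"] == ["cg003"]

    def test_attribution_follows_filter_order(self):
        qc = make_qc(5, 100)
        qc.detection_p.iloc[2, :5] = 0.9
        qc.flags.loc["cg002", "sex_chromosome"] = True
        _, report = apply_probe_filters(beta_like(qc), qc)
        assert report["detection"] == ["cg002"]
        assert report["sex_chromosome"] == []

    def test_filters_idempotent(self):
        qc = make_qc(30, 50)
        qc.flags.iloc[4, 0] = True
        qc.detection_p.iloc[7, :10] = 0.5
        once, _ = apply_probe_filters(beta_like(qc), qc)
        twice, report2 = apply_probe_filters(
            once, ProbeQC(qc.detection_p.loc[once.index],
                          qc.bead_counts.loc[once.index],
                          qc.flags.loc[once.index])
        )
        pd.testing.assert_frame_equal(once, twice)
        assert all(len(v) == 0 for v in report2.values())

    def test_probe_set_mismatch_error(self):
        qc = make_qc(10, 5)
        beta = beta_like(qc).drop(index=["cg000"])
        beta.loc["cg999"] = 0.5
        with pytest.raises(ValueError, match="differ"):
            apply_probe_filters(beta, qc)


class TestExcludeSamples:
    def test_identity_when_clean(self, null_cohort):
        cohort, _ = null_cohort
        out, report = exclude_samples(cohort)
        assert out.n_samples == cohort.n_samples
        assert report == {"medication": 0, "missing_lipid": 0, "sex_mismatch": 0}

    def test_medicated_participants_removed(self, null_cohort):
        cohort, _ = null_cohort
        cohort = cohort.subset(cohort.samples.index)
        meds = cohort.samples["participant"].unique()[:3]
        cohort.samples.loc[cohort.samples["participant"].isin(meds), "lipid_med"] = True
        out, report = exclude_samples(cohort)
        # each participant contributes two specimens (two visits)
        assert report["medication"] == 6
        assert not out.samples["participant"].isin(meds).any()

    def test_missing_single_lipid_removes_sample(self, null_cohort):
        cohort, _ = null_cohort
        cohort = cohort.subset(cohort.samples.index)
        victim = cohort.lipids.index[4]
        cohort.lipids.loc[victim, "HDL_C"] = np.nan
        out, report = exclude_samples(cohort)
        assert report["missing_lipid"] == 1
        assert victim not in out.samples.index


class TestLogTransformAndTrim:
    def test_constant_vector_untouched(self):
        df = pd.DataFrame({"TG": [2.0] * 12})
        out, report = log_transform_and_trim(df)
        assert report["TG"] == []
        assert np.allclose(out["TG"], np.log(2.0))

    def test_three_sd_outlier_removed(self):
        # ten 1.0s and one 10.0: z = 3.02 > 3
        df = pd.DataFrame({"TG": [1.0] * 10 + [10.0]})
        out, report = log_transform_and_trim(df)
        assert report["TG"] == [10]
        assert out["TG"].isna().sum() == 1
        assert np.allclose(out["TG"].dropna(), 0.0)

    def test_borderline_value_kept(self):
        # {1..10, 100}: z = 2.97 < 3 -> nothing removed
        df = pd.DataFrame({"TC": list(range(1, 11)) + [100]})
        out, report = log_transform_and_trim(df)
        assert report["TC"] == []
        assert out["TC"].notna().all()

    def test_non_positive_lipid_errors_before_log(self):
        df = pd.DataFrame({"TG": [1.0, -0.5, 2.0]})
        with pytest.raises(ValueError, match="non-positive"):
            log_transform_and_trim(df)


class TestCallZygosity:
    def test_identical_vectors_are_mz(self):
        snp = pd.DataFrame(
            {"a1": [0.05, 0.5, 0.95, 0.5], "a2": [0.05, 0.5, 0.95, 0.5]}
        )
        calls = call_zygosity(snp, ["p1", "p1"])
        assert calls["p1"] == "MZ"

    def test_anticorrelated_vectors_are_dz(self):
        snp = pd.DataFrame(
            {"a1": [0.05, 0.5, 0.95, 0.05], "a2": [0.95, 0.5, 0.05, 0.95]}
        )
        calls = call_zygosity(snp, ["p1", "p1"])
        assert calls["p1"] == "DZ"

    def test_singleton_pair_unknown(self):
        snp = pd.DataFrame({"a1": [0.05, 0.5, 0.95]})
        assert call_zygosity(snp, ["p1"])["p1"] == "unknown"

    def test_zero_variance_unknown_with_warning(self):
        snp = pd.DataFrame({"a1": [0.5, 0.5, 0.5], "a2": [0.05, 0.5, 0.95]})
        with pytest.warns(UserWarning, match="zero variance"):
            calls = call_zygosity(snp, ["p1", "p1"])
        assert calls["p1"] == "unknown"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetric_in_cotwins(self, seed):
        rng = np.random.default_rng(seed)
        snp = pd.DataFrame(
            rng.choice([0.05, 0.5, 0.95], size=(20, 2))
            + rng.normal(0, 0.03, size=(20, 2)),
            columns=["a1", "a2"],
        )
        fwd = call_zygosity(snp, ["p", "p"])["p"]
        rev = call_zygosity(snp[["a2", "a1"]], ["p", "p"])["p"]
        assert fwd == rev

    def test_simulated_cohort_agreement(self):
        cfg = SimulationConfig(n_pairs=200, n_cpgs=5, seed=13)
        cohort, truth = simulate_cohort(cfg)
        _, report = exclude_samples(cohort)
        proc, rep = preprocess_cohort(cohort)
        called = proc.samples.groupby("pair_id")["zygosity"].first()
        called = called.sort_index().to_numpy()
        assert (called == np.array(truth.zygosity)).mean() >= 0.99


class TestAdjustCellAndBatch:
    def _setup(self, rng, n_probes=20, n_samples=60, batches=1):
        cols = [f"s{j}" for j in range(n_samples)]
        beta = pd.DataFrame(
            rng.uniform(0.2, 0.8, size=(n_probes, n_samples)),
            index=[f"cg{j}" for j in range(n_probes)],
            columns=cols,
        )
        props = pd.DataFrame(
            rng.dirichlet(np.full(4, 10.0), size=n_samples),
            index=cols,
            columns=[f"cell_{k}" for k in range(4)],
        )
        batch = pd.Series(rng.integers(0, batches, n_samples), index=cols)
        return beta, props, batch

    def test_constant_proportions_single_batch_identity(self, rng):
        beta, props, batch = self._setup(rng, batches=1)
        props.loc[:, :] = 0.25
        out = adjust_cell_and_batch(beta, props, np.zeros(len(batch), int))
        assert np.allclose(out.to_numpy(), beta.to_numpy(), atol=1e-10)

    def test_cell_contamination_removed(self, rng):
        beta, props, batch = self._setup(rng, batches=1)
        contaminated = beta.copy()
        contaminated.iloc[0] = beta.iloc[0] + 0.3 * props.iloc[:, 0].to_numpy()
        out = adjust_cell_and_batch(contaminated, props, np.zeros(len(batch), int))
        r = np.corrcoef(out.iloc[0], props.iloc[:, 0])[0, 1]
        assert abs(r) < 1e-8

    def test_batch_offset_removed(self, rng):
        beta, props, batch = self._setup(rng, batches=2)
        props.loc[:, :] = 0.25
        shifted = beta.copy()
        mask = (batch == 1).to_numpy()
        shifted.iloc[0, mask] += 0.1
        out = adjust_cell_and_batch(shifted, props, batch)
        diff = out.iloc[0, mask].mean() - out.iloc[0, ~mask].mean()
        assert abs(diff) < 1e-10

    def test_pooled_probe_means_preserved(self, rng):
        beta, props, batch = self._setup(rng, batches=3)
        out = adjust_cell_and_batch(beta, props, batch)
        assert np.allclose(
            out.mean(axis=1).to_numpy(), beta.mean(axis=1).to_numpy(), atol=1e-10
        )

    def test_small_batch_errors(self, rng):
        beta, props, batch = self._setup(rng)
        bad = np.zeros(len(batch), int)
        bad[:2] = 1  # batch of size 2
        with pytest.raises(ValueError, match="fewer than 3"):
            adjust_cell_and_batch(beta, props, bad)
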