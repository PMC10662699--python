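"""Replicate-concordance QC, IS correction, enrichment normalization, assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import glycoprm as g

positive = st.floats(min_value=1e-3, max_value=1e9, allow_nan=False)


def _ref_runs(c_by_run: dict) -> pd.DataFrame:
    """Minimal run table with one reference peptide carrying the whole C."""
    rows = [
        (sid, rep, "REF01", "reference", c) for (sid, rep), c in c_by_run.items()
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "replicate_idx", "peptide_id", "channel", "area"]
    )


class TestSRD:
    def test_identical_replicates(self):
        assert g.compute_srd(10, 10) == 0.0

    def test_printed_formula(self):
        assert g.compute_srd(3, 1) == pytest.approx(2 / (2 * math.sqrt(2)))

    def test_twofold_difference_is_below_half(self):
        # a twofold recovery difference sits just below the 0.50 cutoff
        assert abs(g.compute_srd(2, 1)) == pytest.approx(0.4714, abs=1e-4)

    @given(positive, positive)
    def test_antisymmetric(self, c1, c2):
        assert g.compute_srd(c1, c2) == pytest.approx(-g.compute_srd(c2, c1))

    @pytest.mark.parametrize("c1,c2", [(0, 1), (1, 0), (-1, 2)])
    def test_nonpositive_rejected(self, c1, c2):
        with pytest.raises(ValueError):
            g.compute_srd(c1, c2)


class TestQCFilter:
    def test_discordant_pair_drops_lower_recovery(self):
        runs = _ref_runs(
            {("X", 1): 100.0, ("X", 2): 40.0}
            | {(f"F{i}", r): 100.0 for i in range(8) for r in (1, 2)}
        )
        retained, report = g.qc_filter(runs)
        assert g.compute_srd(100, 40) == pytest.approx(0.606, abs=1e-3)
        assert report.dropped.to_dict("records") == [
            {
                "sample_id": "X",
                "replicate_idx": 2,
                "C": 40.0,
                "reason": "discordant_pair_lower_recovery",
            }
        ]
        kept_x = retained[retained["sample_id"] == "X"]
        assert set(kept_x["replicate_idx"]) == {1}

    def test_two_sd_rule_is_one_sided_and_pre_exclusion(self):
        c = {(f"S{i}", 1): 100.0 for i in range(10)}
        c[("LOW", 1)] = 10.0
        c[("HIGH", 1)] = 160.0  # high outliers are never excluded
        runs = _ref_runs(c)
        _, report = g.qc_filter(runs)
        assert list(report.dropped["sample_id"]) == ["LOW"]
        assert report.dropped["reason"].iloc[0] == "low_recovery_2sd"
        # mean/SD computed over all runs before exclusions
        vals = np.array(list(c.values()))
        assert report.c_mean == pytest.approx(vals.mean())
        assert report.c_sd == pytest.approx(vals.std(ddof=1))

    def test_concordant_pairs_untouched(self):
        runs = _ref_runs({(f"S{i}", r): 90.0 + i for i in range(6) for r in (1, 2)})
        retained, report = g.qc_filter(runs)
        assert report.dropped.empty
        assert len(retained) == len(runs)

    def test_more_than_two_runs_rejected(self):
        runs = _ref_runs({("A", 1): 10.0, ("A", 2): 10.0, ("A", 3): 10.0})
        with pytest.raises(ValueError, match="more than two"):
            g.qc_filter(runs)

    def test_never_drops_both_members_of_a_pair(self, study_dataset):
        _, runs, _ = study_dataset
        retained, _ = g.qc_filter(runs)
        per_sample = retained.groupby("sample_id")["replicate_idx"].nunique()
        assert (per_sample >= 1).all()
        assert set(per_sample.index) == set(runs["sample_id"])


class TestCorrectionFormulas:
    def test_is_correction_identity_when_heavy_at_mean(self):
        assert g.is_correct(100.0, 5.0, 5.0) == pytest.approx(100.0)

    def test_is_correction_halves_at_double_spike(self):
        assert g.is_correct(100.0, 10.0, 5.0) == pytest.approx(50.0)

    @given(positive, positive, positive, st.floats(min_value=1e-3, max_value=1e3))
    def test_instrument_response_cancels(self, light, heavy, hm, k):
        # light and heavy of one run share the per-run response factor k
        a = g.is_correct(light, heavy, hm)
        b = g.is_correct(light * k, heavy * k, hm)
        assert b == pytest.approx(a, rel=1e-9)

    def test_zero_heavy_rejected(self):
        with pytest.raises(ValueError):
            g.is_correct(1.0, 0.0, 1.0)

    def test_enrichment_normalize(self):
        assert g.enrichment_normalize(10.0, 200.0, 100.0) == pytest.approx(5.0)
        assert g.enrichment_normalize(10.0, 100.0, 100.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            g.enrichment_normalize(1.0, 0.0, 1.0)


class TestAssembleMatrix:
    def _tiny_runs(self):
        rows = []
        for rep, light in ((1, 8.0), (2, 12.0)):
            rows.append(("S1", rep, "GVNFNVSK", "light", light))
            rows.append(("S1", rep, "GVNFNVSK", "heavy", 5.0))
            rows.append(("S1", rep, "REF01", "reference", 100.0))
        rows += [
            ("S2", 1, "GVNFNVSK", "light", 7.0),
            ("S2", 1, "GVNFNVSK", "heavy", 5.0),
            ("S2", 1, "REF01", "reference", 100.0),
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "replicate_idx", "peptide_id", "channel", "area"]
        )

    def _clinical(self):
        return pd.DataFrame(
            {"sample_id": ["S1", "S2"], "diagnosis": ["PCa", "BPH"], "tpsa": [8.0, 2.0]}
        )

    def test_replicates_averaged(self, panel):
        mat = g.assemble_matrix(self._tiny_runs(), self._clinical(), panel)
        row = mat.set_index("sample_id")
        assert row.loc["S1", "GVNFNVSK"] == pytest.approx(10.0)
        assert row.loc["S1", "n_runs_used"] == 2

    def test_singleton_uses_its_single_value(self, panel):
        mat = g.assemble_matrix(self._tiny_runs(), self._clinical(), panel)
        row = mat.set_index("sample_id")
        assert row.loc["S2", "GVNFNVSK"] == pytest.approx(7.0)
        assert row.loc["S2", "n_runs_used"] == 1

    def test_missing_clinical_sample_raises(self, panel):
        clinical = self._clinical().iloc[:1]
        with pytest.raises(ValueError, match="S2"):
            g.assemble_matrix(self._tiny_runs(), clinical, panel)

    def test_noise_free_recovery_is_exact(self, panel):
        """Without noise the matrix equals planted baseline x fold-change."""
        cfg = g.CohortConfig(n_pca=4, n_bph=4, n_nag=1, n_ag=3)
        sig = g.SignalConfig(
            enrichment_cv=0, heavy_spike_cv=0, measurement_cv=0,
            biological_cv=0, reference_biological_cv=0, frac_discordant_runs=0,
        )
        cohort, runs, truth = g.generate_dataset(cfg, sig, seed=21)
        retained, _ = g.qc_filter(runs)
        mat = g.assemble_matrix(retained, cohort, panel).set_index("sample_id")
        for pep in panel["peptide_id"]:
            expected_bph = truth["baselines"][pep]
            expected_pca = expected_bph * truth["fold_changes"][pep]
            bph_ids = cohort.loc[cohort["diagnosis"] == "BPH", "sample_id"]
            nag_ids = cohort.loc[cohort["aggressiveness"] == "NAG", "sample_id"]
            assert np.allclose(mat.loc[bph_ids, pep], expected_bph, rtol=1e-9)
            assert np.allclose(mat.loc[nag_ids, pep], expected_pca, rtol=1e-9)

    def test_enrichment_factor_cancels_end_to_end(self, panel):
        """Scaling one run's recovery leaves the matrix unchanged to 1e-9
        when the cohort constants (C_a, heavy means) are held fixed."""
        cfg = g.CohortConfig(n_pca=5, n_bph=5, n_nag=2, n_ag=3)
        sig = g.SignalConfig(frac_discordant_runs=0.0)
        cohort, base_runs, _ = g.generate_dataset(cfg, sig, seed=22)
        sid = cohort["sample_id"].iloc[2]
        scaled_runs, _ = g.generate_prm_runs(
            cohort, sig, seed=22 + 10_000,  # the sub-seed generate_dataset derives
            enrichment_scale={(sid, 1): 11.0},
        )
        from glycoprm.prm import reference_sums

        c = reference_sums(base_runs)
        c_a = float(c["C"].mean())
        heavy_means = (
            base_runs[base_runs["channel"] == "heavy"]
            .groupby("peptide_id")["area"]
            .mean()
        )
        m1 = g.assemble_matrix(base_runs, cohort, panel, c_a=c_a, heavy_means=heavy_means)
        m2 = g.assemble_matrix(scaled_runs, cohort, panel, c_a=c_a, heavy_means=heavy_means)
        peptides = list(panel["peptide_id"])
        assert np.allclose(
            m1.set_index("sample_id")[peptides],
            m2.set_index("sample_id")[peptides],
            rtol=1e-9,
        )

    def test_fold_change_recovery_within_ten_percent(self, panel):
        """At 5% measurement noise and 50 subjects per group the estimated
        group fold-change of every peptide lands within 10% of truth."""
        cfg = g.CohortConfig(n_pca=50, n_bph=50, n_nag=20, n_ag=30)
        sig = g.SignalConfig(
            measurement_cv=0.05, biological_cv=0.0, frac_discordant_runs=0.0
        )
        cohort, runs, truth = g.generate_dataset(cfg, sig, seed=23)
        retained, _ = g.qc_filter(runs)
        mat = g.assemble_matrix(retained, cohort, panel).set_index("sample_id")
        pca = cohort.loc[cohort["aggressiveness"] == "NAG", "sample_id"]
        bph = cohort.loc[cohort["diagnosis"] == "BPH", "sample_id"]
        for pep in panel["peptide_id"]:
            est = np.exp(
                np.log(mat.loc[pca, pep]).mean() - np.log(mat.loc[bph, pep]).mean()
            )
            assert abs(est / truth["fold_changes"][pep] - 1) < 0.10
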