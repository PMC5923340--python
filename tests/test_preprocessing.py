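"""QC filters, LOESS normalization, ratio construction and Z-scoring."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.nonparametric.smoothers_lowess import lowess

from omistrat.cohort_io import (
    CohortMetadata,
    CohortValidationError,
    OmicsTable,
    ProteinEvidence,
)
from omistrat.preprocessing import (
    compute_ratios,
    filter_metabolites,
    merge_ratio_tables,
    normalize_proteins,
    zscore,
)
from omistrat.synthetic_data import qc_challenge_cohort


def _meta(n_s=9, n_ns=8):
    idx = pd.Index([f"P{i:02d}" for i in range(n_s + n_ns)], name="sample_id")
    return CohortMetadata(
        pd.DataFrame({"group": ["S"] * n_s + ["NS"] * n_ns}, index=idx)
    )


def _met_tables(values_d1, values_d7, mask=None, lod=None):
    kw1 = {"below_lod_mask": mask, "lod": lod}
    kw7 = {"below_lod_mask": mask.copy() if mask is not None else None,
           "lod": lod}
    return (
        OmicsTable("metabolite", "D1", values_d1, **kw1),
        OmicsTable("metabolite", "D7", values_d7, **kw7),
    )


class TestFilterMetabolites:
    def _cohort(self, n_feat=3):
        meta = _meta()
        idx = meta.table.index
        rng = np.random.default_rng(0)
        cols = [f"m{j}" for j in range(n_feat)]
        d1 = pd.DataFrame(rng.uniform(1, 10, (17, n_feat)), index=idx,
                          columns=cols)
        d7 = pd.DataFrame(rng.uniform(1, 10, (17, n_feat)), index=idx,
                          columns=cols)
        mask = pd.DataFrame(False, index=idx, columns=cols)
        return meta, d1, d7, mask

    def test_missingness_rule_excludes_patchy_feature(self):
        meta, d1, d7, mask = self._cohort()
        s3 = meta.group_samples("S")[:3]  # 3 of 9 S patients, both time points
        d1.loc[s3, "m0"] = np.nan
        d7.loc[s3, "m0"] = np.nan
        t1, t7 = _met_tables(d1, d7, mask)
        retained, report = filter_metabolites(t1, t7, meta)
        assert "m0" not in retained
        row = report.records.set_index("feature").loc["m0"]
        assert "missingness_rule" in row["reasons"]

    def test_forty_percent_below_lod_is_retained(self):
        meta, d1, d7, mask = self._cohort()
        # 40% of the 34 cells below LOD, split over both time points
        mask.loc[mask.index[:7], "m1"] = True  # 7 at D1
        t1, t7 = _met_tables(d1, d7, mask)
        t7.below_lod_mask.loc[mask.index[:7], "m1"] = True  # 7 at D7 -> 14/34
        retained, _ = filter_metabolites(t1, t7, meta)
        assert "m1" in retained

    def test_majority_below_lod_is_excluded(self):
        meta, d1, d7, mask = self._cohort()
        mask.loc[mask.index[:9], "m2"] = True
        t1, t7 = _met_tables(d1, d7, mask)
        t7.below_lod_mask.loc[mask.index[:9], "m2"] = True  # 18/34 = 53%
        retained, report = filter_metabolites(t1, t7, meta)
        assert "m2" not in retained
        assert "lod_rule" in report.records.set_index("feature").loc[
            "m2", "reasons"]

    def test_feature_failing_both_rules_carries_both_reasons(self):
        meta, d1, d7, mask = self._cohort()
        s = meta.group_samples("S")[:3]
        d1.loc[s, "m0"] = np.nan
        d7.loc[s, "m0"] = np.nan
        mask.loc[mask.index[:9], "m0"] = True
        t1, t7 = _met_tables(d1, d7, mask)
        t7.below_lod_mask.loc[mask.index[:9], "m0"] = True
        _, report = filter_metabolites(t1, t7, meta)
        reasons = report.records.set_index("feature").loc["m0", "reasons"]
        assert "missingness_rule" in reasons and "lod_rule" in reasons

    def test_missing_mask_demands_explicit_opt_out(self):
        meta, d1, d7, _ = self._cohort()
        t1, t7 = _met_tables(d1, d7, None)
        with pytest.raises(CohortValidationError, match="mask"):
            filter_metabolites(t1, t7, meta)
        retained, _ = filter_metabolites(t1, t7, meta,
                                         min_above_lod_frac=None)
        assert len(retained) == 3

    def test_known_truth_panel_recovered(self):
        tables, meta, _, truth = qc_challenge_cohort(1)
        retained, report = filter_metabolites(
            tables[("metabolite", "D1")], tables[("metabolite", "D7")], meta
        )
        assert len(retained) == 137
        assert set(retained) == set(truth["retained"])
        counts = report.counts().loc["metabolite"]
        assert counts["retained"] + counts["excluded"] == counts["total"] == 186


class TestNormalizeProteins:
    def _setup(self, n=12, p=120, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"P{i:02d}" for i in range(n)], name="sample_id")
        cols = [f"prot_{j:04d}" for j in range(p)]
        base = rng.uniform(12, 18, p)
        log2x = base[None, :] + 0.05 * rng.standard_normal((n, p))
        evidence = ProteinEvidence(
            detected=pd.DataFrame(True, index=pd.Index(cols), columns=list("abcdef")),
            unique_peptides=pd.Series(3, index=cols),
            is_contaminant=pd.Series(False, index=cols),
        )
        return idx, cols, base, log2x, evidence

    def test_sample_matching_reference_is_unchanged(self):
        idx, cols, base, _, evidence = self._setup()
        log2x = np.tile(base, (12, 1))  # every sample equals the reference
        raw = {tp: pd.DataFrame(np.exp2(log2x), index=idx, columns=cols)
               for tp in ("D1", "D7")}
        out, _ = normalize_proteins(raw, evidence)
        np.testing.assert_allclose(
            out[("protein", "D1")].values.to_numpy(), log2x, atol=1e-8
        )

    def test_partial_detection_and_contaminants_excluded(self):
        idx, cols, base, log2x, evidence = self._setup()
        evidence.detected.loc["prot_0000", "c"] = False   # 5 of 6 runs
        evidence.is_contaminant.loc["prot_0001"] = True
        evidence.unique_peptides.loc["prot_0002"] = 1
        raw = {"D1": pd.DataFrame(np.exp2(log2x), index=idx, columns=cols)}
        out, report = normalize_proteins(raw, evidence)
        kept = out[("protein", "D1")].values.columns
        assert {"prot_0000", "prot_0001", "prot_0002"}.isdisjoint(kept)
        rec = report.records.set_index("feature")
        assert "evidence_rule" in rec.loc["prot_0000", "reasons"]
        assert "contaminant_rule" in rec.loc["prot_0001", "reasons"]
        assert "evidence_rule" in rec.loc["prot_0002", "reasons"]

    def test_nonpositive_intensity_error_names_cell(self):
        idx, cols, base, log2x, evidence = self._setup()
        raw = np.exp2(log2x)
        raw[3, 5] = -1.0
        tables = {"D1": pd.DataFrame(raw, index=idx, columns=cols)}
        with pytest.raises(CohortValidationError, match="prot_0005"):
            normalize_proteins(tables, evidence)

    def test_injected_intensity_bias_mostly_removed(self):
        """A smooth intensity-dependent bias added per sample shrinks by
        >= 90% after LOESS normalization."""
        idx, cols, base, log2x, evidence = self._setup(n=12, p=150, seed=3)
        rng = np.random.default_rng(4)
        a = (base - base.min()) / (base.max() - base.min())
        coeffs = rng.uniform(-1, 1, 12)
        biased = log2x + coeffs[:, None] * np.sin(np.pi * a)[None, :]
        raw = {"D1": pd.DataFrame(np.exp2(biased), index=idx, columns=cols)}
        out, _ = normalize_proteins(raw, evidence)
        corrected = out[("protein", "D1")].values.to_numpy()

        def amplitude(mat):
            ref = mat.mean(axis=0)
            amps = []
            for i in range(mat.shape[0]):
                tr = lowess(mat[i] - ref, ref, frac=0.75, it=2,
                            return_sorted=False)
                amps.append(np.sqrt(np.mean(tr ** 2)))
            return float(np.mean(amps))

        assert amplitude(corrected) < 0.1 * amplitude(biased)


class TestComputeRatios:
    def _pair(self, d1_vals, d7_vals, layer="clinical", **kw):
        n = len(d1_vals)
        idx = pd.Index([f"P{i:02d}" for i in range(n)], name="sample_id")
        meta = CohortMetadata(pd.DataFrame(
            {"group": ["S"] * (n // 2) + ["NS"] * (n - n // 2)}, index=idx))
        t1 = OmicsTable(layer, "D1", pd.DataFrame({"v": d1_vals}, index=idx), **kw)
        t7 = OmicsTable(layer, "D7", pd.DataFrame({"v": d7_vals}, index=idx), **kw)
        return t1, t7, meta

    def test_basic_ratio_value(self):
        t1, t7, meta = self._pair([2.0, 4.0], [1.0, 2.0])
        ratio, _ = compute_ratios(t1, t7, meta)
        assert ratio.values.loc["P00", "v"] == 0.5

    def test_identical_timepoints_give_unit_ratios(self):
        t1, t7, meta = self._pair([3.0, 7.0, 2.0, 5.0], [3.0, 7.0, 2.0, 5.0])
        ratio, _ = compute_ratios(t1, t7, meta)
        assert np.allclose(ratio.values.to_numpy(), 1.0)

    def test_patient_at_single_timepoint_is_named(self):
        t1, t7, meta = self._pair([2.0, 4.0], [1.0, 2.0])
        t7.values = t7.values.rename(index={"P01": "P77"})
        with pytest.raises(CohortValidationError, match="P77|P01"):
            compute_ratios(t1, t7, meta)

    def test_missing_denominator_drops_feature_with_reason(self):
        t1, t7, meta = self._pair([2.0, np.nan], [1.0, 2.0])
        ratio, report = compute_ratios(t1, t7, meta)
        assert "v" not in ratio.feature_ids
        assert "zero_denominator" in report.records.loc[0, "reasons"]

    def test_scaling_d7_scales_ratios(self):
        rng = np.random.default_rng(0)
        d1, d7 = rng.uniform(1, 5, 6), rng.uniform(1, 5, 6)
        t1, t7, meta = self._pair(d1, d7)
        r1, _ = compute_ratios(t1, t7, meta)
        t1b, t7b, _ = self._pair(d1, 3.0 * d7)
        r2, _ = compute_ratios(t1b, t7b, meta)
        np.testing.assert_allclose(r2.values.to_numpy(),
                                   3.0 * r1.values.to_numpy())

    def test_below_lod_cells_imputed_at_half_lod(self):
        idx = pd.Index(["P00", "P01"], name="sample_id")
        meta = CohortMetadata(pd.DataFrame({"group": ["S", "NS"]}, index=idx))
        lod = pd.Series([1.0], index=["v"])
        mask1 = pd.DataFrame({"v": [True, False]}, index=idx)
        mask7 = pd.DataFrame({"v": [False, False]}, index=idx)
        t1 = OmicsTable("metabolite", "D1",
                        pd.DataFrame({"v": [0.8, 2.0]}, index=idx),
                        below_lod_mask=mask1, lod=lod)
        t7 = OmicsTable("metabolite", "D7",
                        pd.DataFrame({"v": [1.0, 1.0]}, index=idx),
                        below_lod_mask=mask7, lod=lod)
        ratio, _ = compute_ratios(t1, t7, meta)
        assert ratio.values.loc["P00", "v"] == pytest.approx(1.0 / 0.5)
        assert ratio.values.loc["P01", "v"] == pytest.approx(0.5)

    def test_protein_log2_tables_yield_abundance_ratios(self):
        t1, t7, meta = self._pair([10.0, 12.0], [11.0, 12.0], layer="protein")
        ratio, _ = compute_ratios(t1, t7, meta)
        assert ratio.values.loc["P00", "v"] == pytest.approx(2.0)
        assert ratio.values.loc["P01", "v"] == pytest.approx(1.0)

    def test_merge_requires_same_patients(self):
        t1, t7, meta = self._pair([2.0, 4.0], [1.0, 2.0])
        r1, _ = compute_ratios(t1, t7, meta)
        t1b, t7b, metab = self._pair([2.0, 4.0, 3.0, 9.0], [1.0, 2.0, 3.0, 9.0])
        r2, _ = compute_ratios(t1b, t7b, metab)
        with pytest.raises(CohortValidationError, match="patient"):
            merge_ratio_tables(r1, r2)


class TestZscore:
    def test_hand_computed_standardization(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z = zscore(train)
        np.testing.assert_allclose(z.transformed[0]["a"], [-1.0, 0.0, 1.0])
        assert z.sd["a"] == pytest.approx(1.0)  # denominator n-1

    def test_idempotent_on_standardized_column(self):
        train = pd.DataFrame({"a": [-1.0, 0.0, 1.0]})
        z = zscore(train)
        np.testing.assert_allclose(z.transformed[0]["a"], train["a"],
                                   atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning, match="b"):
            z = zscore(train)
        assert z.dropped == ["b"]
        assert list(z.transformed[0].columns) == ["a"]

    def test_test_rows_use_training_statistics(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        test = pd.DataFrame({"a": [4.0]})
        z = zscore(train, test)
        assert z.transformed[1]["a"].iloc[0] == pytest.approx(2.0)
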