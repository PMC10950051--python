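"""Panel data model: I/O round trips, preprocessing, exclusion, subsetting."""

import numpy as np
import pytest

from adpanel.markers import MARKERS
from adpanel.panel import (CENTILOID_THRESHOLD, AnalysisConfig, BiomarkerPanel,
                           CohortLabels, exclude_sparse_subjects, preprocess,
                           read_panel, subset_cohort, write_panel)
from adpanel.synth import generate_cohort, preset


def _toy_csv(tmp_path, n=3, blank=None, extra_header=None, bad_cell=None):
    header = ["subject_id"] + list(MARKERS) + [
        "cdr_group", "centiloid", "age", "sex", "apoe4_carrier",
        "education", "race_nhw"]
    if extra_header:
        header = header + [extra_header]
    rows = []
    rng = np.random.default_rng(0)
    for i in range(n):
        vals = [f"{v:.4f}" for v in rng.uniform(1, 2, len(MARKERS))]
        row = [f"S{i}"] + vals + ["CDR0", "5.0", "70", "F", "0", "16", "1"]
        if extra_header:
            row += ["1.0"]
        rows.append(row)
    if blank is not None:
        rows[blank[0]][1 + blank[1]] = ""
    if bad_cell is not None:
        rows[bad_cell[0]][1 + bad_cell[1]] = "oops"
    path = tmp_path / "toy.csv"
    path.write_text("\n".join(",".join(r) for r in [header] + rows) + "\n")
    return path


class TestReadPanel:
    def test_single_empty_cell_becomes_single_masked_entry(self, tmp_path):
        path = _toy_csv(tmp_path, blank=(1, 4))
        panel, labels = read_panel(path)
        assert panel.missing_mask.sum() == 1
        assert panel.missing_mask[1, 4]
        assert np.isnan(panel.values[1, 4])

    def test_duplicated_marker_column_rejected(self, tmp_path):
        path = _toy_csv(tmp_path, extra_header=MARKERS[0])
        with pytest.raises(ValueError, match="duplicated"):
            read_panel(path)

    def test_unknown_column_rejected(self, tmp_path):
        path = _toy_csv(tmp_path, extra_header="mystery_marker")
        with pytest.raises(ValueError, match="mystery_marker"):
            read_panel(path)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = _toy_csv(tmp_path, bad_cell=(2, 3))
        with pytest.raises(ValueError, match=MARKERS[3]):
            read_panel(path)

    def test_synthetic_cohort_round_trip(self, tmp_path, entire_cohort):
        path = tmp_path / "cohort.csv"
        write_panel(entire_cohort.panel, entire_cohort.labels, path, seed=0)
        panel, labels = read_panel(path)
        np.testing.assert_array_equal(panel.missing_mask,
                                      entire_cohort.panel.missing_mask)
        np.testing.assert_allclose(
            np.nan_to_num(panel.values),
            np.nan_to_num(entire_cohort.panel.values), rtol=0, atol=1e-10)
        np.testing.assert_array_equal(labels.cdr_group,
                                      entire_cohort.labels.cdr_group)
        assert (path.with_suffix(".csv.json")).exists()

    def test_impaired_amyloid_negative_rejected_with_warning(self, tmp_path):
        path = _toy_csv(tmp_path, n=4)
        text = path.read_text().splitlines()
        # make row 2 impaired but amyloid negative
        parts = text[2].split(",")
        parts[len(MARKERS) + 1] = "CDRgt0"
        text[2] = ",".join(parts)
        path.write_text("\n".join(text) + "\n")
        with pytest.warns(UserWarning, match="rejected 1"):
            panel, labels = read_panel(path)
        assert panel.n_subjects == 3


class TestPreprocess:
    def test_log_then_zscore_known_column(self):
        values = np.c_[[1.0, np.e, np.e**2], [1.0, 2.0, 3.0]]
        panel = BiomarkerPanel(["a", "b", "c"], values,
                               np.zeros_like(values, bool), ["csf_nfl", "x"])
        out = preprocess(panel, log_markers=("csf_nfl",))
        expected = np.array([0.0, 1.0, 2.0])
        expected = (expected - 1.0) / 1.0  # mean 1, sd(ddof=1) = 1
        np.testing.assert_allclose(out.values[:, 0], expected, atol=1e-12)
        assert abs(out.values[:, 0][0] + 1.0) < 1e-12

    def test_non_positive_log_marker_rejected(self):
        values = np.c_[[0.0, 1.0, 2.0]]
        panel = BiomarkerPanel(["a", "b", "c"], values,
                               np.zeros_like(values, bool), ["csf_nfl"])
        with pytest.raises(ValueError, match="non-positive"):
            preprocess(panel, log_markers=("csf_nfl",))

    def test_constant_column_rejected(self):
        values = np.c_[[2.0, 2.0, 2.0]]
        panel = BiomarkerPanel(["a", "b", "c"], values,
                               np.zeros_like(values, bool), ["x"])
        with pytest.raises(ValueError, match="constant"):
            preprocess(panel, log_markers=())

    def test_zscore_uses_present_values_only(self):
        vals = np.array([[1.0], [2.0], [np.nan], [4.0]])
        mask = np.isnan(vals)
        panel = BiomarkerPanel(list("abcd"), vals, mask, ["x"])
        out = preprocess(panel, log_markers=())
        present = np.array([1.0, 2.0, 4.0])
        expected = (present - present.mean()) / present.std(ddof=1)
        np.testing.assert_allclose(out.values[[0, 1, 3], 0], expected)
        assert np.isnan(out.values[2, 0])

    def test_mask_untouched_and_columns_standardised(self, prepared):
        panel, _ = prepared
        obs = ~panel.missing_mask
        for j in range(panel.n_markers):
            col = panel.values[obs[:, j], j]
            assert abs(col.mean()) < 1e-10
            assert abs(col.std(ddof=1) - 1.0) < 1e-10


class TestExcludeSparse:
    def _panel_with_missing(self, n_missing):
        values = np.ones((2, 27))
        mask = np.zeros((2, 27), bool)
        mask[0, :n_missing] = True
        values[mask] = np.nan
        return BiomarkerPanel(["sparse", "full"], values, mask, list(MARKERS))

    def test_majority_missing_subject_removed(self):
        out = exclude_sparse_subjects(self._panel_with_missing(14), 0.5)
        assert out.subject_ids == ["full"]

    def test_half_missing_subject_retained(self):
        out = exclude_sparse_subjects(self._panel_with_missing(13), 0.5)
        assert out.subject_ids == ["sparse", "full"]

    def test_exclusion_monotone_in_fraction(self, entire_cohort):
        panel = entire_cohort.panel
        kept = None
        for frac in (0.8, 0.5, 0.3, 0.1):
            ids = set(exclude_sparse_subjects(panel, frac).subject_ids)
            if kept is not None:
                assert ids <= kept
            kept = ids


class TestSubsetCohort:
    def _labels(self, centiloids, cdr):
        n = len(centiloids)
        return CohortLabels(cdr, centiloids, np.full(n, 70.0),
                            np.array(["F"] * n, object), np.zeros(n, bool),
                            np.full(n, 16.0), np.ones(n, bool))

    def _panel(self, n):
        vals = np.ones((n, 2))
        return BiomarkerPanel([f"s{i}" for i in range(n)], vals,
                              np.zeros_like(vals, bool), ["a", "b"])

    def test_centiloid_threshold_inclusive(self):
        labels = self._labels(np.array([16.4, 16.39]),
                              np.array(["CDR0", "CDR0"], object))
        panel = self._panel(2)
        sub, sub_labels = subset_cohort(panel, labels, "preclinical")
        assert sub.subject_ids == ["s0"]
        ent, _ = subset_cohort(panel, labels, "entire")
        assert ent.n_subjects == 2

    def test_empty_subset_rejected(self):
        labels = self._labels(np.array([5.0, 3.0]),
                              np.array(["CDR0", "CDR0"], object))
        with pytest.raises(ValueError, match="empty"):
            subset_cohort(self._panel(2), labels, "impaired")

    def test_default_preset_subset_sizes(self, entire_cohort):
        panel, labels = entire_cohort.panel, entire_cohort.labels
        pre, _ = subset_cohort(panel, labels, "preclinical")
        imp, _ = subset_cohort(panel, labels, "impaired")
        ent, _ = subset_cohort(panel, labels, "entire")
        assert (ent.n_subjects, pre.n_subjects, imp.n_subjects) == (527, 228, 88)
        neg = ent.n_subjects - subset_cohort(panel, labels, "amyloid_positive")[0].n_subjects
        assert neg == 211
        # impaired + preclinical + CN(A-) partition the cohort
        assert pre.n_subjects + imp.n_subjects + neg == ent.n_subjects


def test_config_validation():
    with pytest.raises(ValueError):
        AnalysisConfig(holdout_fraction=1.5)
    with pytest.raises(ValueError):
        AnalysisConfig(n_permutations=0)
    cfg = AnalysisConfig.scaled(seed=3)
    assert cfg.n_permutations == 100 and cfg.bo_iterations == 30
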