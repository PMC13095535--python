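"""Synthetic cohort generator, CSV round-trips and patient-level splitting."""

import numpy as np
import pytest

from sepselect import (SynthConfig, generate_synthetic_cohort,
                       informative_feature_indices, load_cohort, save_cohort,
                       split_train_test, true_risk_score)
from sepselect.cohort import CohortLoadError
from sepselect.metrics import compute_metrics


def small_cfg(**kw):
    base = dict(n=120, positive_count=6, T=8, seed=3)
    base.update(kw)
    return SynthConfig(**base)


class TestGenerator:
    def test_default_shape_matches_target_cohort(self):
        cohort, signals = generate_synthetic_cohort(SynthConfig(T=4))
        assert cohort.n == 1538
        assert int(cohort.y.sum()) == 82
        assert cohort.X_s.shape == (1538, 20)
        assert signals.X_v.shape == (1538, 5, 4)

    def test_exact_class_counts_and_determinism(self):
        cfg = small_cfg()
        c1, s1 = generate_synthetic_cohort(cfg)
        c2, s2 = generate_synthetic_cohort(cfg)
        assert int(c1.y.sum()) == cfg.positive_count
        np.testing.assert_array_equal(c1.X_s, c2.X_s)
        np.testing.assert_array_equal(s1.X_v, s2.X_v)
        np.testing.assert_array_equal(c1.y, c2.y)

    def test_zero_effect_size_gives_chance_level_risk_score(self):
        cfg = SynthConfig(n=2000, positive_count=100, T=8, effect_size=0.0,
                          seed=11)
        cohort, _ = generate_synthetic_cohort(cfg)
        auc = compute_metrics(
            1 / (1 + np.exp(-true_risk_score(cfg))), cohort.y).auc
        assert abs(auc - 0.5) < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_features_correlate_more_than_noise(self, seed):
        cfg = SynthConfig(n=1200, positive_count=60, T=16, effect_size=1.0,
                          seed=seed)
        cohort, signals = generate_synthetic_cohort(cfg)
        from sepselect import compute_stat_features
        X = np.concatenate([cohort.X_s,
                            compute_stat_features(signals).X_m], axis=1)
        r = np.array([abs(np.corrcoef(X[:, j], cohort.y)[0, 1])
                      for j in range(X.shape[1])])
        inf = informative_feature_indices(cfg)
        noise_static = [j for j in range(cfg.p_s) if j not in inf]
        assert r[inf].min() > r[noise_static].max()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_cohort(small_cfg(positive_count=1000))
        with pytest.raises(ValueError):
            generate_synthetic_cohort(small_cfg(informative_signal=9))
        with pytest.raises(ValueError):
            generate_synthetic_cohort(small_cfg(effect_size=-1.0))


class TestRoundTrip:
    def test_save_load_full_precision(self, tmp_path):
        cohort, signals = generate_synthetic_cohort(small_cfg())
        save_cohort(cohort, signals, tmp_path / "s.csv", tmp_path / "t.csv")
        c2, s2 = load_cohort(tmp_path / "s.csv", tmp_path / "t.csv")
        assert c2.patient_id == cohort.patient_id
        np.testing.assert_array_equal(c2.X_s, cohort.X_s)
        np.testing.assert_array_equal(c2.y, cohort.y)
        np.testing.assert_array_equal(s2.X_v, signals.X_v)

    def test_toy_csv_pair(self, tmp_path):
        (tmp_path / "s.csv").write_text(
            "patient_id,A,B,label\np1,1,2,0\np2,3,4,1\np3,5,6,0\n")
        (tmp_path / "t.csv").write_text(
            "patient_id,time_index,HR\np1,0,80\np1,1,82\np2,0,70\np2,1,71\n"
            "p3,0,90\np3,1,95\n")
        cohort, signals = load_cohort(tmp_path / "s.csv", tmp_path / "t.csv")
        assert cohort.n == 3
        assert signals.X_v.shape == (3, 1, 2)

    def test_missing_patient_error_names_the_id(self, tmp_path):
        (tmp_path / "s.csv").write_text(
            "patient_id,A,label\np1,1,0\np2,2,1\n")
        (tmp_path / "t.csv").write_text(
            "patient_id,time_index,HR\np1,0,80\np2,0,70\npX,0,60\n")
        with pytest.raises(CohortLoadError, match="pX"):
            load_cohort(tmp_path / "s.csv", tmp_path / "t.csv")
        cohort, _ = load_cohort(tmp_path / "s.csv", tmp_path / "t.csv",
                                on_missing="drop")
        assert cohort.patient_id == ["p1", "p2"]

    def test_blank_cell_imputed_with_column_median(self, tmp_path, caplog):
        (tmp_path / "s.csv").write_text(
            "patient_id,A,label\np1,1,0\np2,,1\np3,5,0\n")
        (tmp_path / "t.csv").write_text(
            "patient_id,time_index,HR\np1,0,80\np2,0,70\np3,0,60\n")
        with caplog.at_level("WARNING"):
            cohort, _ = load_cohort(tmp_path / "s.csv", tmp_path / "t.csv")
        assert cohort.X_s[1, 0] == 3.0    # median of {1, 5}
        assert any("imputing" in r.message for r in caplog.records)

    def test_duplicate_time_index_rejected(self, tmp_path):
        (tmp_path / "s.csv").write_text("patient_id,A,label\np1,1,0\n")
        (tmp_path / "t.csv").write_text(
            "patient_id,time_index,HR\np1,0,80\np1,0,81\n")
        with pytest.raises(CohortLoadError, match="duplicate"):
            load_cohort(tmp_path / "s.csv", tmp_path / "t.csv")

    def test_non_numeric_cell_reported_with_context(self, tmp_path):
        (tmp_path / "s.csv").write_text(
            "patient_id,A,label\np1,abc,0\n")
        (tmp_path / "t.csv").write_text(
            "patient_id,time_index,HR\np1,0,80\n")
        with pytest.raises(CohortLoadError, match="non-numeric"):
            load_cohort(tmp_path / "s.csv", tmp_path / "t.csv")

    def test_variable_length_series_padded_with_lengths(self, tmp_path):
        (tmp_path / "s.csv").write_text(
            "patient_id,A,label\np1,1,0\np2,2,1\n")
        (tmp_path / "t.csv").write_text(
            "patient_id,time_index,HR\np1,0,80\np1,1,90\np1,2,100\np2,0,70\n")
        _, signals = load_cohort(tmp_path / "s.csv", tmp_path / "t.csv")
        assert signals.X_v.shape == (2, 1, 3)
        np.testing.assert_array_equal(signals.lengths, [3, 1])
        np.testing.assert_array_equal(signals.X_v[1, 0], [70, 70, 70])


class TestSplit:
    def test_80_20_split_sizes(self):
        cohort, signals = generate_synthetic_cohort(SynthConfig(T=2))
        (ctr, _), (cte, _) = split_train_test(cohort, signals, 0.8, seed=0)
        assert ctr.n in (1230, 1231)
        assert ctr.n + cte.n == 1538
        assert 0 < ctr.y.sum() < 82

    def test_tiny_stratified_split(self):
        from sepselect.cohort import CohortTable, TemporalSignals
        cohort = CohortTable(["a", "b", "c", "d"], np.zeros((4, 2)),
                             [1, 1, 0, 0], feature_names=["A", "B"])
        signals = TemporalSignals(["a", "b", "c", "d"], np.zeros((4, 1, 2)),
                                  signal_names=["HR"])
        (ctr, _), (cte, _) = split_train_test(cohort, signals, 0.5, seed=0)
        assert int(ctr.y.sum()) == 1 and int(cte.y.sum()) == 1

    def test_split_reproducible_and_disjoint(self):
        cohort, signals = generate_synthetic_cohort(small_cfg())
        (a, sa), (b, _) = split_train_test(cohort, signals, 0.7, seed=5)
        (a2, _), (b2, _) = split_train_test(cohort, signals, 0.7, seed=5)
        assert a.patient_id == a2.patient_id and b.patient_id == b2.patient_id
        assert not set(a.patient_id) & set(b.patient_id)
        assert sa.patient_id == a.patient_id   # signals follow the cohort

    def test_bad_inputs(self):
        cohort, signals = generate_synthetic_cohort(small_cfg())
        with pytest.raises(ValueError):
            split_train_test(cohort, signals, 1.5, seed=0)
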