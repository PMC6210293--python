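"""ROC threshold search, AUC, reference-activity selection, calibration."""

import numpy as np
import pandas as pd
import pytest

from wristcal.roc_calibration import (
    PUBLISHED_CUTPOINTS,
    CalibrationConfig,
    calibrate,
    roc_auc,
    select_reference_activity,
    youden_cutpoint,
)


def brute_force_youden(sed, light):
    """Exhaustive scan over every candidate threshold (oracle)."""
    sed, light = np.asarray(sed, float), np.asarray(light, float)
    cand = np.unique(np.concatenate([sed, light]))
    cand = np.append(cand, cand.max() + 1)
    best = None
    for t in cand:  # ascending: first strict improvement keeps smallest t
        # integer score proportional to sens + spec, so ties are exact
        score = int((light >= t).sum()) * sed.size + int((sed < t).sum()) * light.size
        if best is None or score > best[0]:
            sens = 100.0 * np.mean(light >= t)
            spec = 100.0 * np.mean(sed < t)
            best = (score, t, sens, spec)
    return best[1], best[2], best[3]


def all_pairs_auc(sed, light):
    """Average over every (light, sedentary) pair of 1 / 0.5 / 0 (oracle)."""
    total = 0.0
    for l in light:
        for s in sed:
            total += 1.0 if l > s else (0.5 if l == s else 0.0)
    return total / (len(light) * len(sed))


class TestYoudenCutpoint:
    def test_separable_classes(self):
        thr, sens, spec = youden_cutpoint([0, 1, 2], [10, 11, 12])
        assert (thr, sens, spec) == (10.0, 100.0, 100.0)

    def test_overlapping_matches_brute_force(self):
        got = youden_cutpoint([0, 5, 10], [5, 10, 20])
        want = brute_force_youden([0, 5, 10], [5, 10, 20])
        assert got[0] == want[0]
        assert got[1:] == pytest.approx(want[1:])

    def test_identical_classes_chance_level(self):
        vals = [3, 8, 8, 15]
        thr, sens, spec = youden_cutpoint(vals, vals)
        assert sens + spec == pytest.approx(100.0)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            sed = rng.integers(0, 30, size=rng.integers(1, 50))
            light = rng.integers(0, 30, size=rng.integers(1, 50))
            got = youden_cutpoint(sed, light)
            want = brute_force_youden(sed, light)
            assert got[0] == want[0]
            assert got[1:] == pytest.approx(want[1:])

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            youden_cutpoint([], [1])


class TestRocAuc:
    def test_identical_distributions(self):
        assert roc_auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert roc_auc([0, 1], [5, 6]) == 1.0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            sed = rng.integers(0, 12, size=rng.integers(1, 50))
            light = rng.integers(0, 12, size=rng.integers(1, 50))
            assert roc_auc(sed, light) == pytest.approx(all_pairs_auc(sed, light))

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            sed = rng.integers(0, 50, 30)
            light = rng.integers(0, 50, 30)
            assert roc_auc(sed, light) + roc_auc(light, sed) == pytest.approx(1.0)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(19)
        sed = rng.integers(0, 300, 200)
        light = rng.integers(100, 600, 150)
        y = np.r_[np.zeros(len(sed)), np.ones(len(light))]
        scores = np.r_[sed, light]
        assert roc_auc(sed, light) == pytest.approx(roc_auc_score(y, scores))


class TestReferenceActivity:
    def test_board_games_is_reference(self):
        # needs a cohort large enough for the board-games and cards medians
        # (129/83 vs 106/74) to separate reliably
        from wristcal.profiles import reference_profiles
        from wristcal.synthetic_data import GeneratorConfig, generate_dataset

        cfg = GeneratorConfig(
            n_children=60, epochs_per_activity=60,
            activities=reference_profiles(), p_stand=0.0, seed=8,
        )
        epochs, _ = generate_dataset(cfg)
        for wrist in ("dominant", "non_dominant"):
            assert select_reference_activity(epochs, "axis1", wrist) == "Board Games"

    def test_single_seated_activity(self):
        df = pd.DataFrame(
            {
                "child_id": ["K0"] * 4,
                "wrist": ["dominant"] * 4,
                "activity": ["Only", "Only", "Walk", "Walk"],
                "posture": ["seated", "seated", "walking", "walking"],
                "axis1": [5, 6, 300, 310],
            }
        )
        assert select_reference_activity(df, "axis1", "dominant") == "Only"

    def test_tie_broken_lexicographically(self):
        df = pd.DataFrame(
            {
                "child_id": ["K0"] * 4,
                "wrist": ["dominant"] * 4,
                "activity": ["Zeta", "Zeta", "Alpha", "Alpha"],
                "posture": "seated",
                "axis1": [10, 20, 10, 20],
            }
        )
        assert select_reference_activity(df, "axis1", "dominant") == "Alpha"

    def test_no_seated_rejected(self):
        df = pd.DataFrame(
            {"child_id": ["K0"], "wrist": ["dominant"], "activity": ["Walk"],
             "posture": ["walking"], "axis1": [300]}
        )
        with pytest.raises(ValueError):
            select_reference_activity(df, "axis1", "dominant")


def _separable_cohort(n_children=24, epochs=20, gap=(50, 400), seed=0):
    """Sedentary counts below gap[0], light above gap[1]; trivially separable."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_children):
        for activity, posture, lo, hi in (
            ("Desk", "seated", 0, gap[0]),
            ("Walk", "walking", gap[1], gap[1] + 200),
        ):
            for wrist in ("dominant", "non_dominant"):
                vals = rng.integers(lo, hi, size=epochs)
                vals[0] = lo  # class boundary present for every child
                rows.append(
                    pd.DataFrame(
                        {
                            "child_id": f"K{i:03d}",
                            "wrist": wrist,
                            "activity": activity,
                            "posture": posture,
                            "epoch_index": np.arange(epochs),
                            "axis1": vals,
                            "axis2": vals,
                            "axis3": vals,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


class TestCalibrate:
    def test_separable_classes_are_perfectly_classified(self):
        epochs = _separable_cohort()
        cfg = CalibrationConfig(k=4, seed=1)
        res = calibrate(epochs, cfg, "dominant", "axis1")
        assert res.sensitivity == 100.0
        assert res.specificity == 100.0
        assert res.auc_calibration == 1.0
        assert res.auc_validation == 1.0
        assert 50 <= res.cutpoint <= 400  # inside the separating gap
        assert all(f.auc == 1.0 for f in res.folds)

    def test_fold_count_insensitive_in_separable_limit(self):
        epochs = _separable_cohort(n_children=40, gap=(50, 51))
        cuts = []
        for k in (2, 10):
            cfg = CalibrationConfig(k=k, seed=2)
            cuts.append(calibrate(epochs, cfg, "dominant", "axis1").cutpoint)
        assert cuts[0] == pytest.approx(cuts[1])

    def test_child_level_split_is_disjoint_and_seeded(self):
        epochs = _separable_cohort()
        cfg = CalibrationConfig(k=4, seed=3)
        a = calibrate(epochs, cfg, "dominant", "axis1")
        b = calibrate(epochs, cfg, "dominant", "axis1")
        assert a == b  # determinism under a fixed seed

    def test_repeats_mode_runs(self):
        epochs = _separable_cohort()
        cfg = CalibrationConfig(k=4, seed=4, mode="repeats")
        res = calibrate(epochs, cfg, "dominant", "axis1")
        assert res.auc_calibration == 1.0

    def test_vm_signal_computed_on_demand(self):
        epochs = _separable_cohort()
        res = calibrate(epochs, CalibrationConfig(k=3, seed=5), "dominant", "vm")
        assert res.signal == "vm"
        assert res.cutpoint > 0

    def test_missing_class_everywhere_rejected(self):
        epochs = _separable_cohort()
        seated_only = epochs[epochs["posture"] == "seated"]
        with pytest.raises(ValueError):
            calibrate(seated_only, CalibrationConfig(seed=6), "dominant", "axis1")


def test_published_cutpoints_complete_and_ordered():
    # constants exposed for applying the published thresholds downstream;
    # each dominant-wrist cut-point exceeds its non-dominant counterpart
    for signal in ("axis1", "axis2", "axis3", "vm"):
        nd = PUBLISHED_CUTPOINTS[(signal, "non_dominant")]
        dom = PUBLISHED_CUTPOINTS[(signal, "dominant")]
        assert dom > nd > 0
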