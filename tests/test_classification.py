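"""Random-forest classification, cross-validation and burden-index tests."""

import numpy as np
import pandas as pd
import pytest

import flimplaque as fp
from flimplaque.classify import (
    UNCLASSIFIED,
    ClassificationMap,
    RfcConfig,
    burden_index,
    classify_pullback,
    cross_validate,
    train_rfc,
)
from flimplaque.core import CLASS_LABELS
from flimplaque.synthetic import (
    ComponentSignature,
    PhantomConfig,
    build_vessel_phantom,
    default_signatures,
    simulate_decays,
)


def _separable_table(n_per_class=60, rois_per_class=6, spread=0.01, seed=0):
    """Five tight, well-separated clusters in feature space."""
    rng = np.random.default_rng(seed)
    centers = {
        "normal": (4.0, 2.0, 1.2), "fibrotic": (4.0, 4.5, 2.0), "lipid": (6.5, 6.0, 0.8),
        "macrophage": (2.5, 4.5, 0.4), "lipid_macrophage": (6.5, 6.0, 2.8),
    }
    rows = []
    roi = 0
    for ci, (label, c) in enumerate(centers.items()):
        for r in range(rois_per_class):
            for _ in range(n_per_class // rois_per_class):
                rows.append({
                    "roi_id": roi, "label": label,
                    "FL_ch1": c[0] + rng.normal(0, spread),
                    "FL_ch2": c[1] + rng.normal(0, spread),
                    "IR1": c[2] + rng.normal(0, spread),
                })
            roi += 1
    return pd.DataFrame(rows)


class TestTraining:
    def test_missing_class_rejected_with_names(self):
        table = _separable_table()
        sub = table[table.label == "lipid"]
        with pytest.raises(ValueError, match="fibrotic"):
            train_rfc(sub)

    def test_separable_clusters_resubstitution_perfect(self):
        table = _separable_table()
        model = train_rfc(table, RfcConfig(n_trees=30, seed=0))
        x = table[list(model.features)].to_numpy()
        pred = np.array(CLASS_LABELS)[model.predict_proba(x).argmax(axis=1)]
        assert (pred == table.label.to_numpy()).all()

    def test_model_stores_feature_contract(self):
        model = train_rfc(_separable_table(), RfcConfig(n_trees=10, seed=0))
        assert model.features == ("FL_ch1", "FL_ch2", "IR1")
        assert model.class_order == CLASS_LABELS


class TestCrossValidation:
    def test_separable_clusters_perfect_cv(self):
        rep = cross_validate(_separable_table(), k=5, config=RfcConfig(n_trees=30, seed=1))
        assert rep.accuracy == 1.0
        assert all(a == 1.0 for a in rep.auc.values())

    def test_permuted_labels_fall_to_chance(self):
        rng = np.random.default_rng(2)
        table = _separable_table(spread=0.2)
        # permute labels at the ROI level to keep grouping intact
        roi_labels = table.groupby("roi_id").label.first()
        permuted = pd.Series(rng.permutation(roi_labels.values), index=roi_labels.index)
        table["label"] = table.roi_id.map(permuted)
        try:
            rep = cross_validate(table, k=5, config=RfcConfig(n_trees=30, seed=2))
        except ValueError:
            pytest.skip("permutation starved a class below k ROIs")
        assert 0.05 < rep.accuracy < 0.40  # 5-class chance is 0.20

    def test_roi_grouping_no_leakage(self, default_cv, default_dataset):
        table, _, _ = default_dataset
        fold = default_cv.fold_of_roi
        assert len(fold) == table.roi_id.nunique()
        # each ROI appears in exactly one (test) fold
        assert all(isinstance(f, int) and 0 <= f < 5 for f in fold.values())

    def test_confusion_marginals_conserve_counts(self, default_cv, default_dataset):
        table, _, _ = default_dataset
        cm = default_cv.confusion
        truth_counts = table.label.value_counts()
        for i, name in enumerate(CLASS_LABELS):
            assert cm[i].sum() == truth_counts[name]
        assert cm.sum() == default_cv.n_locations

    def test_accuracy_is_prevalence_weighted_recall(self, default_cv):
        cm = default_cv.confusion
        recall = np.diag(cm) / cm.sum(axis=1)
        weighted = np.sum(recall * cm.sum(axis=1)) / cm.sum()
        assert default_cv.accuracy == pytest.approx(weighted, abs=1e-12)

    def test_too_few_rois_in_a_class_rejected(self):
        table = _separable_table(rois_per_class=3)
        with pytest.raises(ValueError, match="fewer ROIs than folds"):
            cross_validate(table, k=5, config=RfcConfig(seed=0))

    def test_deterministic_for_seed(self):
        table = _separable_table(spread=0.5)
        a = cross_validate(table, k=3, config=RfcConfig(n_trees=20, seed=7))
        b = cross_validate(table, k=3, config=RfcConfig(n_trees=20, seed=7))
        assert np.array_equal(a.confusion, b.confusion)
        assert a.accuracy == b.accuracy and a.fold_of_roi == b.fold_of_roi

    def test_accuracy_monotone_in_class_separation(self):
        """Widening the generator's class separation never hurts CV accuracy."""
        accs = []
        for scale in (0.15, 0.5, 1.0):
            sigs = {}
            for c, s in default_signatures().items():
                grand = 4.5
                mean = tuple(grand + scale * (m - grand) for m in s.lifetime_mean)
                rel = tuple(1.0 + scale * (r - 1.0) if i < 2 else r
                            for i, r in enumerate(s.rel_intensity))
                modes = None
                if s.ch2_mode_lifetimes:
                    modes = tuple(grand + scale * (m - grand) for m in s.ch2_mode_lifetimes)
                sigs[c] = ComponentSignature(mean, s.lifetime_sd, rel, s.intensity_sd,
                                             modes, s.mixing_weight)
            level_accs = []
            for seed in (0, 1, 2):
                cfg = fp.roi_dataset_config({c: 6 for c in fp.CLASS_ORDER})
                ph = build_vessel_phantom(cfg, seed=seed)
                cube = simulate_decays(ph, signatures=sigs, seed=seed + 100)
                table = fp.extract_roi_features(
                    fp.process_pullback(cube), fp.rois_from_phantom(ph.rois)
                )
                rep = cross_validate(table, k=3, config=RfcConfig(n_trees=30, seed=seed))
                level_accs.append(rep.accuracy)
            accs.append(np.mean(level_accs))
        assert accs[0] <= accs[1] + 0.02 and accs[1] <= accs[2] + 0.02


class TestClassificationMap:
    @pytest.fixture(scope="class")
    def model_and_map(self, default_dataset):
        table, _, _ = default_dataset
        model = train_rfc(table, RfcConfig(n_trees=50, seed=0))
        ph = build_vessel_phantom(PhantomConfig(n_frames=2, n_locations=128), seed=5)
        cube = simulate_decays(ph, seed=6)
        readouts = fp.process_pullback(cube)
        return model, classify_pullback(model, readouts), readouts

    def test_pure_normal_phantom_classified_normal(self, model_and_map):
        _, cmap, _ = model_and_map
        classified = cmap.classes[cmap.classes != UNCLASSIFIED]
        frac_normal = np.mean(classified == fp.CLASS_ORDER.index(fp.ComponentClass.NORMAL))
        assert frac_normal >= 0.95

    def test_argmax_consistency(self, model_and_map):
        _, cmap, _ = model_and_map
        ok = cmap.classes != UNCLASSIFIED
        assert np.array_equal(cmap.proba[ok].argmax(axis=1), cmap.classes[ok])
        assert np.allclose(cmap.proba[ok].sum(axis=1), 1.0)

    def test_invalid_location_left_unclassified(self, model_and_map, default_dataset):
        model, _, readouts = model_and_map
        broken = fp.PullbackReadouts(readouts.fl.copy(), readouts.ir.copy(),
                                     readouts.valid.copy())
        broken.valid[0, :5] = False
        cmap = classify_pullback(model, broken)
        assert (cmap.classes[0, :5] == UNCLASSIFIED).all()
        assert np.isnan(cmap.proba[0, :5]).all()


class TestBurdenIndex:
    def test_all_normal_map(self):
        classes = np.zeros((3, 8), dtype=np.int8)
        idx = burden_index(ClassificationMap(classes, np.zeros((3, 8, 5))))
        assert idx["normal"] == 100.0
        assert all(idx[c] == 0.0 for c in CLASS_LABELS[1:])

    def test_quarter_split(self):
        classes = np.repeat(np.arange(4, dtype=np.int8), 25).reshape(1, 100)
        idx = burden_index(ClassificationMap(classes, np.zeros((1, 100, 5))))
        assert [idx[c] for c in CLASS_LABELS] == [25.0, 25.0, 25.0, 25.0, 0.0]

    def test_random_maps_sum_to_100(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            classes = rng.integers(-1, 5, size=(4, 32)).astype(np.int8)
            if (classes == UNCLASSIFIED).all():
                continue
            idx = burden_index(ClassificationMap(classes, np.zeros((4, 32, 5))))
            assert sum(idx.values()) == pytest.approx(100.0, abs=1e-6)

    def test_all_invalid_map_rejected(self):
        classes = np.full((2, 4), UNCLASSIFIED, dtype=np.int8)
        with pytest.raises(ValueError):
            burden_index(ClassificationMap(classes, np.zeros((2, 4, 5))))
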