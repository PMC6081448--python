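"""Sliding-box features, signature training, classification and the rollup."""

import numpy as np
import pytest

from lungquant.patterns import (
    BIN_EDGES,
    SignatureSet,
    box_features,
    classify_parenchyma,
    summarize_patterns,
    train_signatures,
)
from lungquant.phantom import PATTERN_CODES, generate_labeled_boxes
from lungquant.segmentation import build_zone_map
from scipy import ndimage


class TestBoxFeatures:
    def test_uniform_region_concentrates_histogram(self, noise_free_bundle):
        organ = noise_free_bundle.organ_truth
        center = tuple(np.array(np.nonzero(ndimage.binary_erosion(organ.lung_mask(), iterations=10))).T[0])
        hist, aux = box_features(noise_free_bundle.ct, organ, center)
        bin_of_850 = np.digitize(-850.0, BIN_EDGES) - 1
        assert hist[bin_of_850] == 1.0
        assert hist.sum() == pytest.approx(1.0)

    def test_histogram_normalized(self, ggo_bundle, ggo_organ):
        center = tuple(np.argwhere(ggo_organ.lung_mask())[1000])
        hist, aux = box_features(ggo_bundle.ct, ggo_organ, center)
        assert hist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mean_aux_equals_direct_recomputation(self, ggo_bundle, ggo_organ):
        """Oracle: the mean-HU feature must equal an independent mean over the
        same in-lung box voxels."""
        center = tuple(np.argwhere(ggo_organ.lung_mask())[5000])
        _, aux = box_features(ggo_bundle.ct, ggo_organ, center)
        z, y, x = center
        sl = tuple(slice(max(0, c - 7), c + 8) for c in center)
        patch = ggo_bundle.ct.voxels[sl]
        expected = patch[ggo_organ.lung_mask()[sl]].mean()
        assert aux[0] == pytest.approx(expected, abs=1e-9)

    def test_non_lung_center_rejected(self, ggo_bundle, ggo_organ):
        with pytest.raises(ValueError, match="lung"):
            box_features(ggo_bundle.ct, ggo_organ, (0, 0, 0))


class TestTrainSignatures:
    def test_single_class_rejected(self, ggo_bundle):
        boxes = generate_labeled_boxes(ggo_bundle, n_per_class=15, classes=("ggo",))
        with pytest.raises(ValueError, match="2 classes"):
            train_signatures(boxes)

    def test_too_few_boxes_rejected(self, ggo_bundle):
        boxes = generate_labeled_boxes(ggo_bundle, n_per_class=5)
        with pytest.raises(ValueError, match=">= 10"):
            train_signatures(boxes)

    def test_signature_histograms_sum_to_one(self, ggo_signatures):
        for sig in ggo_signatures.signatures:
            assert sig.histogram.sum() == pytest.approx(1.0, abs=1e-9)

    def test_distant_classes_have_disjoint_histograms(self, ggo_signatures):
        """Classes 500 HU apart share almost no histogram mass."""
        by_name = {s.class_name: s for s in ggo_signatures.signatures}
        inter = np.minimum(by_name["normal"].histogram, by_name["ggo"].histogram).sum()
        assert inter < 0.1

    def test_json_roundtrip(self, ggo_signatures, tmp_path):
        path = ggo_signatures.to_json(tmp_path / "sigs.json")
        back = SignatureSet.from_json(path)
        assert back.class_names == ggo_signatures.class_names
        for a, b in zip(back.signatures, ggo_signatures.signatures):
            np.testing.assert_allclose(a.histogram, b.histogram)


class TestClassify:
    def test_agreement_with_truth_on_box_interior(self, ggo_bundle, ggo_pattern_map):
        """Voxels whose whole box lies in one truth class must agree ≥ 95%."""
        truth = ggo_bundle.pattern_truth
        lo = ndimage.minimum_filter(truth, size=15, mode="constant", cval=0)
        hi = ndimage.maximum_filter(truth, size=15, mode="constant", cval=0)
        interior = (lo == hi) & (lo > 0)
        agreement = (ggo_pattern_map.labels[interior] == truth[interior]).mean()
        assert agreement >= 0.95

    def test_all_normal_phantom_classified_normal(self, plain_bundle, ggo_signatures):
        from lungquant.segmentation import segment_lungs

        organ = segment_lungs(plain_bundle.ct)
        pm = classify_parenchyma(plain_bundle.ct, organ, ggo_signatures)
        lung = organ.lung_mask()
        frac_normal = (pm.labels[lung] == PATTERN_CODES["normal"]).mean()
        assert frac_normal >= 0.99

    def test_signature_order_does_not_matter(self, ggo_bundle, ggo_organ, ggo_signatures, ggo_pattern_map):
        reversed_set = SignatureSet(
            signatures=list(reversed(ggo_signatures.signatures)),
            bin_edges=ggo_signatures.bin_edges,
            aux_center=ggo_signatures.aux_center,
            aux_scale=ggo_signatures.aux_scale,
        )
        pm2 = classify_parenchyma(ggo_bundle.ct, ggo_organ, reversed_set)
        np.testing.assert_array_equal(pm2.labels, ggo_pattern_map.labels)

    def test_deterministic(self, ggo_bundle, ggo_organ, ggo_signatures, ggo_pattern_map):
        pm2 = classify_parenchyma(ggo_bundle.ct, ggo_organ, ggo_signatures)
        np.testing.assert_array_equal(pm2.labels, ggo_pattern_map.labels)

    def test_stride_3_close_to_stride_1(self, ggo_bundle, ggo_organ, ggo_signatures, ggo_pattern_map):
        pm3 = classify_parenchyma(ggo_bundle.ct, ggo_organ, ggo_signatures, stride=3)
        lung = ggo_organ.lung_mask()
        agreement = (pm3.labels[lung] == ggo_pattern_map.labels[lung]).mean()
        assert agreement >= 0.9

    def test_every_lung_voxel_labeled(self, ggo_organ, ggo_pattern_map):
        lung = ggo_organ.lung_mask()
        assert np.all(ggo_pattern_map.labels[lung] > 0)
        assert np.all(ggo_pattern_map.labels[~lung] == 0)


class TestSummary:
    def test_involved_close_to_truth(self, ggo_bundle, ggo_zones, ggo_pattern_map):
        summary = summarize_patterns(ggo_pattern_map, ggo_zones)
        truth_involved = 100.0 * ggo_bundle.truth_fraction("ggo")
        assert summary.totals["involved_percent"] == pytest.approx(truth_involved, abs=3.0)

    def test_zone_volumes_sum_to_totals(self, ggo_zones, ggo_pattern_map):
        summary = summarize_patterns(ggo_pattern_map, ggo_zones)
        assert summary.per_zone["involved_ml"].sum() == pytest.approx(
            summary.totals["involved_ml"], abs=1e-9
        )
        assert summary.per_zone["parenchyma_ml"].sum() == pytest.approx(
            summary.totals["parenchyma_ml"], abs=1e-9
        )

    def test_involved_plus_uninvolved_is_100(self, ggo_zones, ggo_pattern_map):
        summary = summarize_patterns(ggo_pattern_map, ggo_zones)
        assert summary.totals["involved_percent"] + summary.totals[
            "uninvolved_percent"
        ] == pytest.approx(100.0, abs=1e-6)

    def test_honeycomb_flag_widens_involved(self, ggo_zones, ggo_pattern_map):
        base = summarize_patterns(ggo_pattern_map, ggo_zones)
        wide = summarize_patterns(ggo_pattern_map, ggo_zones, include_honeycomb_in_involved=True)
        assert wide.totals["involved_percent"] >= base.totals["involved_percent"]

    def test_shape_mismatch_rejected(self, ggo_pattern_map):
        from lungquant.segmentation import ZoneMap

        small = ZoneMap(zones=np.zeros((4, 4, 4), dtype=int), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="shapes differ"):
            summarize_patterns(ggo_pattern_map, small)
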