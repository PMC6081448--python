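"""Densitometry: the HU→density conversion, predicted mass line, percent error
and the full volume/mass readout against phantom truth."""

import numpy as np
import pytest

from lungquant.densitometry import (
    hu_to_density,
    lung_volume,
    percent_error,
    predicted_tlm,
    run_densitometry,
)
from lungquant.phantom import LesionSpec, PhantomSpec, generate_phantom
from lungquant.segmentation import segment_lungs
from lungquant.volume_io import OrganLabelMap


class TestHuToDensity:
    def test_water_is_unit_density_in_both_conventions(self):
        assert hu_to_density(0.0, "air_referenced") == 1.0
        assert hu_to_density(0.0, "as_printed") == 1.0

    def test_air_limit(self):
        assert hu_to_density(-1000.0, "air_referenced") == 0.0

    def test_printed_formula_evaluates_literally(self):
        # the printed form (1000 − HU)/1000 gives air a density of 2 g/ml —
        # kept selectable for auditing against reports using that form
        assert hu_to_density(-1000.0, "as_printed") == 2.0

    def test_unknown_convention(self):
        with pytest.raises(ValueError, match="convention"):
            hu_to_density(0.0, "imperial")


class TestPredictedTlm:
    def test_at_170_cm(self):
        assert predicted_tlm(170.0) == pytest.approx(659.803, abs=1e-9)

    def test_slope_per_cm(self):
        assert predicted_tlm(171.0) - predicted_tlm(170.0) == pytest.approx(9.8759)

    def test_intercept_returned_with_warning_for_tiny_height(self):
        with pytest.warns(UserWarning, match="outside"):
            val = predicted_tlm(1e-9)
        assert val == pytest.approx(-1019.1, abs=1e-4)

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError):
            predicted_tlm(0.0)


class TestPercentError:
    @pytest.mark.parametrize(
        "tlm, pred, expected", [(2.0, 1.0, 100.0), (1.0, 1.0, 0.0), (0.5, 1.0, -50.0)]
    )
    def test_scaling(self, tlm, pred, expected):
        assert percent_error(tlm, pred) == expected

    def test_zero_predicted_rejected(self):
        with pytest.raises(ValueError):
            percent_error(1.0, 0.0)


class TestLungVolume:
    def test_voxel_arithmetic(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        labels[:5, :5, :4] = 1  # 100 voxels left
        labels[:5, :5, 6:] = 2  # 100 voxels right... (5*5*4)=100
        organ = OrganLabelMap(labels=labels, spacing=(2.5, 2.0, 2.0))
        assert lung_volume(organ, side="left") == pytest.approx(100 * 0.01)
        assert lung_volume(organ, side="both") == pytest.approx(
            lung_volume(organ, side="left") + lung_volume(organ, side="right")
        )

    def test_absent_side_rejected(self):
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[0, 0, 0] = 1
        organ = OrganLabelMap(labels=labels, spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="absent"):
            lung_volume(organ, side="right")

    def test_phantom_volume_close_to_truth(self, ggo_bundle, ggo_organ):
        truth_ml = ggo_bundle.truth_summary["volume_ml"].sum()
        assert lung_volume(ggo_organ) == pytest.approx(truth_ml, rel=0.05)


class TestRunDensitometry:
    def test_closed_form_on_noise_free_phantom(self, noise_free_bundle):
        """Uniform −850 HU lungs: TLM must equal volume × 0.15 g/ml."""
        organ = segment_lungs(noise_free_bundle.ct)
        res = run_densitometry(noise_free_bundle.ct, organ)
        expected = res.both.volume_ml * (1000.0 - 850.0) / 1000.0
        assert res.tlm_g == pytest.approx(expected, rel=0.05)

    def test_mass_additivity_and_percent_identity(self, ggo_bundle, ggo_organ):
        res = run_densitometry(ggo_bundle.ct, ggo_organ, height_cm=170.0)
        assert res.tlm_g == pytest.approx(res.left.mass_g + res.right.mass_g, abs=1e-6)
        assert res.percent_of_predicted == pytest.approx(100.0 + res.percent_error, abs=1e-9)

    def test_missing_height_leaves_predicted_fields_absent(self, ggo_bundle, ggo_organ):
        res = run_densitometry(ggo_bundle.ct, ggo_organ)
        assert res.predicted_tlm_g is None
        assert res.percent_error is None
        assert res.percent_of_predicted is None

    def test_lesions_increase_tlm(self, plain_bundle, ggo_bundle):
        """A higher-attenuation burden can only add mass (air-referenced)."""
        r_plain = run_densitometry(plain_bundle.ct, segment_lungs(plain_bundle.ct))
        r_ggo = run_densitometry(ggo_bundle.ct, segment_lungs(ggo_bundle.ct))
        assert r_ggo.tlm_g > r_plain.tlm_g

    def test_scale_equivariance(self):
        """Doubling the spacing multiplies volumes and masses by exactly 8."""
        spec = PhantomSpec(seed=2, shape=(48, 64, 64), lesions=(LesionSpec("ggo", 0.1),))
        b = generate_phantom(spec)
        organ = segment_lungs(b.ct)
        res1 = run_densitometry(b.ct, organ)
        from lungquant.volume_io import CTVolume

        ct2 = CTVolume(voxels=b.ct.voxels, spacing=tuple(2 * s for s in b.ct.spacing))
        organ2 = OrganLabelMap(labels=organ.labels, spacing=ct2.spacing)
        res2 = run_densitometry(ct2, organ2)
        assert res2.both.volume_ml == pytest.approx(8 * res1.both.volume_ml)
        assert res2.tlm_g == pytest.approx(8 * res1.tlm_g)

    def test_result_table_carries_units(self, ggo_bundle, ggo_organ):
        res = run_densitometry(ggo_bundle.ct, ggo_organ, height_cm=170.0)
        table = res.to_result_table()
        units = {r["name"]: r["unit"] for r in table.records}
        assert units["tlm"] == "g"
        assert units["percent_error"] == "%"
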