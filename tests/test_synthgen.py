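"""The simulator's truth masks, determinism, and interference contracts."""

import numpy as np
import pytest
from scipy import ndimage

from deepblastoid import synthgen as sg
from deepblastoid.labels import ClassLabel
from deepblastoid.plate_io import PlateLayout


class TestRenderMicrowell:
    def test_empty_well_has_no_foreground(self):
        _, mask = sg.render_microwell("W", seed=1, image_size=64)
        assert np.all(mask == sg.MASK_BACKGROUND)

    def test_class_a_mask_topology(self):
        """A complete ring enclosing a cavity, plus exactly one ICM blob."""
        _, mask = sg.render_microwell("A", seed=1, image_size=128)
        icm_lab, n_icm = ndimage.label(mask == sg.MASK_ICM)
        assert n_icm == 1
        # the ring closes: background does not leak into the cavity region
        outside = ndimage.label(mask != sg.MASK_RING)[0]
        cavity_ids = np.unique(outside[mask == sg.MASK_CAVITY])
        corner_id = outside[0, 0]
        assert corner_id not in cavity_ids
        assert np.any(mask == sg.MASK_CAVITY)

    def test_determinism_bit_exact(self):
        a, ma = sg.render_microwell("A", seed=1, image_size=64)
        b, mb = sg.render_microwell("A", seed=1, image_size=64)
        assert np.array_equal(a, b) and np.array_equal(ma, mb)

    def test_images_span_16bit_range(self):
        img, _ = sg.render_microwell("A", seed=0, image_size=64)
        assert img.dtype == np.uint16
        assert img.max() <= 65535

    def test_morphology_violations_rejected(self):
        bad = sg.MorphologySpec(60, 20, 0.5, True, 6, True, 0)  # broken ring for A
        with pytest.raises(sg.MorphologyError, match="completeness"):
            sg.render_microwell("A", bad, seed=0, image_size=64)
        with pytest.raises(sg.MorphologyError, match="cavity"):
            sg.render_microwell(
                "D", sg.MorphologySpec(60, 0, 0, False, 0, True, 5), seed=0, image_size=64
            )

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            sg.render_microwell("W", seed=0, image_size=32)

    @pytest.mark.parametrize("label", list("ABCDW"))
    def test_mask_oracle_recovers_label(self, label, rng):
        """Interference-free renders are classifiable from the mask alone."""
        for _ in range(20):
            morph = sg.default_morphology(label, 64, rng=rng)
            _, mask = sg.render_microwell(
                label, morph, seed=int(rng.integers(2**31)), image_size=64
            )
            assert sg.label_from_mask(mask) is ClassLabel[label]


class TestInterference:
    def test_zero_spec_is_identity(self):
        img, _ = sg.render_microwell("A", seed=0, image_size=64)
        out = sg.apply_interference(img, sg.InterferenceSpec(), seed=5)
        assert np.array_equal(out, img)

    def test_illumination_ramp_range_on_flat_image(self):
        """Constant image v maps exactly onto [v(1-a), v(1+a)]."""
        v, a = 0.5, 0.3
        img = np.full((80, 80), v)
        out = sg.apply_interference(
            img, sg.InterferenceSpec(illumination_gradient=(0.3, a)), seed=0
        )
        assert out.min() == pytest.approx(v * (1 - a), abs=1e-12)
        assert out.max() == pytest.approx(v * (1 + a), abs=1e-12)

    def test_defocus_conserves_total_intensity(self):
        img, _ = sg.render_microwell("A", seed=0, image_size=128)
        img = img.astype(np.float64)
        out = sg.apply_interference(img, sg.InterferenceSpec(defocus_sigma_px=2.0), seed=0)
        assert abs(out.sum() - img.sum()) / img.sum() < 1e-3

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sg.InterferenceSpec(defocus_sigma_px=-1)
        with pytest.raises(ValueError):
            sg.InterferenceSpec(illumination_gradient=(0.0, 1.5))

    def test_interference_preserves_shape_and_finiteness(self):
        img, _ = sg.render_microwell("C", seed=3, image_size=64)
        spec = sg.InterferenceSpec(1.5, (1.0, 0.4), clutter_count=3)
        out = sg.apply_interference(img, spec, seed=9)
        assert out.shape == img.shape
        assert np.all(np.isfinite(out.astype(np.float64)))


class TestRenderPlate:
    def test_degenerate_mixture_all_empty(self):
        layout = PlateLayout(4, 6, tile_px=(64, 64), pitch_px=(64, 64))
        _, manifest = sg.render_plate(layout, (0, 0, 0, 0, 1), seed=0)
        assert len(manifest) == 24
        assert (manifest["label"] == "W").all()

    def test_label_counts_conserved(self):
        layout = PlateLayout(10, 10, tile_px=(64, 64), pitch_px=(64, 64))
        _, manifest = sg.render_plate(layout, (0.2,) * 5, seed=5)
        assert len(manifest) == 100
        assert manifest["label"].isin(list("ABCDW")).all()

    def test_multinomial_counts_within_bound(self):
        """Realized class counts stay within 4 sigma of the multinomial mean."""
        layout = PlateLayout(30, 40, tile_px=(64, 64), pitch_px=(64, 64))
        mixture = (0.1, 0.2, 0.2, 0.2, 0.3)
        _, manifest = sg.render_plate(layout, mixture, seed=7)
        n = 1200
        counts = manifest["label"].value_counts()
        for cls, p in zip("ABCDW", mixture):
            bound = 4 * np.sqrt(n * p * (1 - p))
            assert abs(counts.get(cls, 0) - n * p) <= bound

    def test_bad_mixture_rejected(self):
        layout = PlateLayout(2, 2, tile_px=(64, 64), pitch_px=(64, 64))
        with pytest.raises(ValueError, match="sum to 1"):
            sg.render_plate(layout, (0.5, 0.5, 0.5, 0, 0), seed=0)


class TestMakeDataset:
    def test_manifest_shape_and_batches(self, tmp_path):
        spec = sg.SyntheticDatasetSpec(
            n_images=60, image_size_px=64, n_batches=3, seed=2, exact_counts=True
        )
        manifest = sg.make_dataset(spec, tmp_path)
        assert len(manifest) == 60
        assert sorted(manifest["label"].unique()) == list("ABCDW")
        assert manifest["batch"].value_counts().tolist() == [20, 20, 20]
        assert (tmp_path / manifest["path"].iloc[0]).exists()

    def test_rerun_reproduces_identical_files(self, tmp_path):
        spec = sg.SyntheticDatasetSpec(n_images=10, image_size_px=64, seed=4)
        m1 = sg.make_dataset(spec, tmp_path / "a")
        m2 = sg.make_dataset(spec, tmp_path / "b")
        assert sg.manifest_checksum(m1) == sg.manifest_checksum(m2)
        for p in m1["path"]:
            assert (tmp_path / "a" / p).read_bytes() == (tmp_path / "b" / p).read_bytes()

    def test_rle_roundtrip(self):
        _, mask = sg.render_microwell("C", seed=1, image_size=64)
        assert np.array_equal(sg.rle_to_mask(sg.mask_to_rle(mask)), mask)
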