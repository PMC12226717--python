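"""Image normalization stack and tabular imputation."""

import numpy as np
import pytest

from multiglau.preprocessing import (
    PolarSpec,
    apply_clahe,
    impute_tabular,
    inverse_polar_transform,
    normalize_minmax,
    polar_transform,
    preprocess_image,
    resample_image,
)

from conftest import make_record


class TestResample:
    def test_constant_preserved_at_any_size(self):
        img = np.full((40, 60), 7.25)
        for size in (8, 32, 100):
            out = resample_image(img, size)
            assert out.shape == (size, size)
            np.testing.assert_allclose(out, 7.25, atol=1e-6)

    def test_identity_resample(self, rng):
        img = rng.random((256, 256))
        np.testing.assert_allclose(resample_image(img, 256), img, atol=1e-6)

    def test_checkerboard_mean_preserved(self):
        img = np.indices((512, 512)).sum(axis=0) % 2 * 1.0
        out = resample_image(img, 256)
        assert abs(out.mean() - img.mean()) < 0.01 * img.mean()

    def test_small_size_rejected(self):
        with pytest.raises(ValueError):
            resample_image(np.ones((16, 16)), 4)

    def test_uint8_stays_in_dtype_range(self, rng):
        img = (rng.random((64, 64)) * 255).astype(np.uint8)
        out = resample_image(img, 32)
        assert out.dtype == np.uint8


class TestCLAHE:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 0.5)
        np.testing.assert_array_equal(apply_clahe(img), img)

    def test_range_contract_uint8(self, rng):
        img = (rng.random((64, 64)) * 120 + 30).astype(np.uint8)
        out = apply_clahe(img)
        assert out.dtype == np.uint8  # implies [0, 255]

    def test_contrast_increases_on_low_contrast_gradient(self):
        img = np.tile(np.linspace(0.45, 0.55, 64), (64, 1))
        out = apply_clahe(img)
        assert out.std() >= img.std()

    def test_bad_clip_rejected(self):
        with pytest.raises(ValueError):
            apply_clahe(np.ones((8, 8)), clip_limit=0.0)


class TestMinMax:
    def test_closed_form(self):
        np.testing.assert_allclose(normalize_minmax(np.array([[0., 128., 255.]])),
                                   [[0.0, 128 / 255, 1.0]])

    def test_binary_image_unchanged(self):
        img = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(normalize_minmax(img), img)

    def test_endpoints_and_constant_convention(self, rng):
        img = rng.normal(size=(16, 16))
        out = normalize_minmax(img)
        assert out.min() == 0.0 and out.max() == 1.0
        with pytest.warns(RuntimeWarning):
            out = normalize_minmax(np.full((4, 4), 3.0))
        np.testing.assert_array_equal(out, 0.0)


class TestPolar:
    def test_rotationally_symmetric_rows_constant(self):
        size = 101
        r = np.hypot(*np.mgrid[0:size, 0:size] - (size - 1) / 2)
        img = np.exp(-r / 20) * 255
        spec = PolarSpec(center=((size - 1) / 2, (size - 1) / 2), radius=40,
                         output_size=(50, 90))
        out = polar_transform(img, spec)
        assert (out.max(axis=1) - out.min(axis=1)).max() < 2.0

    def test_uniform_image_uniform_output(self):
        spec = PolarSpec(center=(16, 16), radius=10, output_size=(20, 30))
        out = polar_transform(np.full((33, 33), 4.0), spec)
        np.testing.assert_allclose(out, 4.0)

    def test_center_outside_rejected(self):
        spec = PolarSpec(center=(100, 100), radius=5)
        with pytest.raises(ValueError):
            polar_transform(np.ones((16, 16)), spec)

    def test_roundtrip_within_disc(self):
        # smooth test pattern; forward polar then oracle inverse
        size = 96
        rows, cols = np.mgrid[0:size, 0:size]
        img = 0.5 + 0.4 * np.sin(rows / 9.0) * np.cos(cols / 11.0)
        c = (size - 1) / 2
        spec = PolarSpec(center=(c, c), radius=40, output_size=(128, 256))
        back = inverse_polar_transform(polar_transform(img, spec), spec,
                                       (size, size))
        r = np.hypot(rows - c, cols - c)
        inside = r < 38
        mae = np.abs(back - img)[inside].mean()
        assert mae < 0.03 * (img.max() - img.min())

    def test_pure_function(self, rng):
        img = rng.random((40, 40))
        spec = PolarSpec(center=(19.5, 19.5), radius=15, output_size=(16, 24))
        np.testing.assert_array_equal(polar_transform(img, spec),
                                      polar_transform(img, spec))


class TestPipelineRange:
    def test_final_values_in_unit_interval(self, rng):
        img = (rng.random((100, 100)) * 255).astype(np.uint8)
        out = preprocess_image(img, size=64)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestImpute:
    def _records(self, n, rng, missing_frac=0.0, cdr_fn=None):
        recs = []
        for i in range(n):
            age = float(rng.uniform(40, 80))
            cdr = cdr_fn(age, rng) if cdr_fn else float(rng.uniform(0.2, 0.8))
            r = make_record(i, age=age, cdr=cdr,
                            bcva=float(rng.uniform(0.2, 1.0)),
                            iop=float(rng.uniform(10, 30)))
            recs.append(r)
        idx = rng.choice(n, int(n * missing_frac), replace=False)
        for i in idx:
            recs[i].cdr = None
        return recs, idx

    def test_no_missing_is_identity(self, rng):
        recs, _ = self._records(30, rng)
        out = impute_tabular(recs, seed=0)
        assert out == recs

    def test_constant_column_imputed_to_constant(self, rng):
        recs, idx = self._records(100, rng, missing_frac=0.1,
                                  cdr_fn=lambda a, g: 0.5)
        out = impute_tabular(recs, seed=0)
        for i in idx:
            assert abs(out[i].cdr - 0.5) < 1e-6

    def test_linear_relation_recovered(self, rng):
        recs, idx = self._records(
            500, rng, missing_frac=0.2,
            cdr_fn=lambda a, g: float(np.clip(0.01 * a + g.normal(0, 0.01), 0, 1)))
        out = impute_tabular(recs, seed=1)
        truth = np.array([0.01 * recs[i].age for i in idx])
        imputed = np.array([out[i].cdr for i in idx])
        rmse = np.sqrt(np.mean((imputed - truth) ** 2))
        assert rmse < 0.03

    def test_observed_cells_never_altered(self, rng):
        recs, idx = self._records(80, rng, missing_frac=0.2)
        out = impute_tabular(recs, seed=2)
        for i, (a, b) in enumerate(zip(recs, out)):
            for f in ("age", "gender", "bcva", "iop"):
                assert getattr(a, f) == getattr(b, f)
            if i not in idx:
                assert a.cdr == b.cdr
            else:
                assert b.cdr is not None

    def test_entirely_missing_column_rejected(self, rng):
        recs, _ = self._records(20, rng)
        for r in recs:
            r.bcva = None
        with pytest.raises(ValueError, match="bcva"):
            impute_tabular(recs)

    def test_deterministic_given_seed(self, rng):
        recs, _ = self._records(60, rng, missing_frac=0.15)
        a = impute_tabular(recs, seed=3)
        b = impute_tabular(recs, seed=3)
        assert a == b
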