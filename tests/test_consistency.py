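import numpy as np
import pytest

import firmap as fm
from firmap.consistency import circular_kspace_mask, sparsity_select
from firmap.data_model_io import ModelSeries
from firmap.fourier import fft2c, ifft2c


def dft2_oracle(img):
    """Brute-force centered unitary 2-D DFT (double loop over frequencies)."""
    n = img.shape[0]
    c = n // 2
    out = np.zeros((n, n), dtype=complex)
    pos = np.arange(n) - c
    for ky in pos:
        for kx in pos:
            phase = np.exp(-2j * np.pi * (ky * pos[:, None] + kx * pos[None, :]) / n)
            out[ky + c, kx + c] = np.sum(img * phase) / n
    return out


def random_gridded(seed=0, n_proj=3, n_coil=2, n=8, density=0.3):
    rng = np.random.default_rng(seed)
    mask = rng.random((n_proj, n, n)) < density
    values = np.where(
        mask[:, None],
        rng.normal(size=(n_proj, n_coil, n, n)) + 1j * rng.normal(size=(n_proj, n_coil, n, n)),
        0,
    )
    meta = fm.AcquisitionMeta(
        tr_ms=6.0, te_ms=2.5, flip_deg=7.0,
        n_proj=n_proj, n_coil=n_coil, n_read=n, matrix=n,
    )
    return fm.GriddedProjections(values=values, mask=mask, meta=meta)


def random_model_k(seed, shape):
    rng = np.random.default_rng(seed)
    return rng.normal(size=shape) + 1j * rng.normal(size=shape)


class TestFourier:
    def test_delta_image_has_flat_magnitude_spectrum(self):
        n = 8
        img = np.zeros((n, n), dtype=complex)
        img[n // 2, n // 2] = 1.0
        ksp = fft2c(img)
        np.testing.assert_allclose(np.abs(ksp), 1.0 / n, rtol=1e-12)

    def test_inverse_then_forward_is_identity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 3, 8, 8)) + 1j * rng.normal(size=(2, 3, 8, 8))
        np.testing.assert_allclose(fft2c(ifft2c(x)), x, rtol=1e-12, atol=1e-13)

    def test_matches_direct_dft_oracle(self):
        rng = np.random.default_rng(2)
        for seed in range(3):
            img = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
            np.testing.assert_allclose(fft2c(img), dft2_oracle(img), atol=1e-10)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        b = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        np.testing.assert_allclose(
            fft2c(a + b), fft2c(a) + fft2c(b), rtol=1e-12, atol=1e-13
        )

    def test_model_to_kspace_wraps_fft(self):
        rng = np.random.default_rng(4)
        imgs = rng.normal(size=(2, 1, 8, 8)) + 1j * rng.normal(size=(2, 1, 8, 8))
        series = ModelSeries(images=imgs)
        np.testing.assert_array_equal(fm.model_to_kspace(series), fft2c(imgs))


class TestReinsert:
    def test_sampled_nodes_equal_originals_exactly(self):
        gridded = random_gridded()
        model_k = random_model_k(9, gridded.values.shape)
        out = fm.reinsert(model_k, gridded, circular_mask=False)
        mask = np.broadcast_to(gridded.mask[:, None], out.shape)
        assert np.array_equal(out[mask], gridded.values[mask])

    def test_unsampled_nodes_keep_model(self):
        gridded = random_gridded()
        model_k = random_model_k(9, gridded.values.shape)
        out = fm.reinsert(model_k, gridded, circular_mask=False)
        mask = np.broadcast_to(gridded.mask[:, None], out.shape)
        assert np.array_equal(out[~mask], model_k[~mask])

    def test_idempotent(self):
        gridded = random_gridded()
        model_k = random_model_k(9, gridded.values.shape)
        once = fm.reinsert(model_k, gridded)
        twice = fm.reinsert(once, gridded)
        np.testing.assert_array_equal(once, twice)

    def test_zero_radius_keeps_only_dc(self):
        gridded = random_gridded(density=1.0)
        model_k = random_model_k(9, gridded.values.shape)
        out = fm.reinsert(model_k, gridded, circular_mask=True, radius=0.0)
        n = gridded.meta.matrix
        nonzero = out != 0
        nonzero[:, :, n // 2, n // 2] = False
        assert not np.any(nonzero)

    def test_circular_mask_never_alters_inner_samples(self):
        gridded = random_gridded()
        model_k = random_model_k(9, gridded.values.shape)
        out = fm.reinsert(model_k, gridded, circular_mask=True)
        n = gridded.meta.matrix
        disk = circular_kspace_mask(n, gridded.meta.n_read / 2)
        mask = gridded.mask[:, None] & disk[None, None]
        mask = np.broadcast_to(mask, out.shape)
        assert np.array_equal(out[mask], gridded.values[mask])


class TestConsistencyMetric:
    def test_zero_when_model_matches(self):
        gridded = random_gridded()
        model_k = np.array(gridded.values)  # equal at sampled nodes
        assert fm.consistency_metric(model_k, gridded) == 0.0

    def test_unit_offset_counts_sampled_nodes(self):
        gridded = random_gridded()
        model_k = gridded.values + (1.0 + 0.0j)
        m = int(gridded.mask.sum()) * gridded.meta.n_coil
        assert fm.consistency_metric(model_k, gridded) == pytest.approx(m, rel=1e-12)

    def test_homogeneous_in_scale(self):
        gridded = random_gridded()
        model_k = random_model_k(5, gridded.values.shape)
        base = fm.consistency_metric(model_k, gridded)
        scaled = fm.GriddedProjections(
            values=3.0 * gridded.values, mask=gridded.mask, meta=gridded.meta
        )
        assert fm.consistency_metric(3.0 * model_k, scaled) == pytest.approx(
            3.0 * base, rel=1e-12
        )

    def test_zero_after_reinsertion(self):
        gridded = random_gridded()
        model_k = random_model_k(5, gridded.values.shape)
        out = fm.reinsert(model_k, gridded, circular_mask=False)
        assert fm.consistency_metric(out, gridded) == 0.0

    def test_near_zero_at_ground_truth_model(self, small_phantom):
        # a model initialised at the truth is already consistent with the data
        gt, times, gridded = (
            small_phantom["gt"],
            small_phantom["times"],
            small_phantom["gridded"],
        )
        series = fm.simulate_series(gt, times)
        model_k = fm.model_to_kspace(series)
        metric = fm.consistency_metric(model_k, gridded)
        scale = np.sum(np.abs(gridded.values))
        assert metric / scale < 1e-10


def test_sparsity_selection_keeps_strong_nodes_only():
    gridded = random_gridded(density=1.0, n_proj=2, n_coil=1)
    ref = np.full((1,) + gridded.values.shape[2:], 1.0, dtype=complex)
    sel = sparsity_select(gridded, ref, fraction=1e9)  # nothing strong enough
    assert not sel.any()
    sel_all = sparsity_select(gridded, ref, fraction=0.0)
    keep = np.abs(gridded.values[:, 0]) > 0
    assert np.array_equal(sel_all, gridded.mask & keep)
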