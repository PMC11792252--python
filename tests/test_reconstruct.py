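import numpy as np
import pytest

from qobm import (
    ARM_LABELS,
    DPCImage,
    NoiseModel,
    OpticalSystem,
    FrequencyGrid,
    RawFrameSet,
    TissuePhantom,
    compute_dpc,
    compute_wotf,
    dpc_transfer,
    make_pupil,
    make_source,
    reconstruct_field,
    reconstruct_stack,
    simulate_intensities,
    tikhonov_phase,
)

from oracles import bandlimited_phase


def _phantom(phi):
    return TissuePhantom(
        phase=phi, absorption=np.zeros_like(phi),
        labels=np.zeros(phi.shape, dtype=np.uint8), meta={},
    )


def _frame_set(**arms):
    base = {a: np.ones((16, 16)) for a in ARM_LABELS}
    base.update({k: np.asarray(v, dtype=float) * np.ones((16, 16))
                 for k, v in arms.items()})
    return RawFrameSet(frames=base)


def _band_rmse(rec, truth, grid, band=(0.1, 0.7)):
    annulus = (grid.radius >= band[0] * grid.f_cutoff) & (
        grid.radius <= band[1] * grid.f_cutoff
    )
    diff = np.fft.ifft2(np.fft.fft2(rec - truth) * annulus).real
    return float(np.sqrt(np.mean(diff**2)))


class TestComputeDPC:
    def test_equal_arms_give_zero(self):
        d = compute_dpc(_frame_set(), "x")
        assert np.all(d.values == 0.0)

    def test_uniform_difference_value(self):
        d = compute_dpc(_frame_set(**{"+x": 3.0, "-x": 1.0}), "x")
        assert np.allclose(d.values, 0.5)

    def test_swapping_arms_negates(self):
        d1 = compute_dpc(_frame_set(**{"+y": 3.0, "-y": 1.0}), "y")
        d2 = compute_dpc(_frame_set(**{"+y": 1.0, "-y": 3.0}), "y")
        assert np.array_equal(d1.values, -d2.values)

    def test_missing_arm_named_in_error(self):
        frames = RawFrameSet(frames={"+x": np.ones((16, 16))})
        with pytest.raises(KeyError, match="-x"):
            compute_dpc(frames, "x")

    def test_guarded_pixels_zeroed_and_counted(self):
        ia = np.ones((16, 16))
        ib = np.ones((16, 16))
        ia[0, 0] = 1e-9
        ib[0, 0] = -1e-9
        d = compute_dpc(RawFrameSet(frames={"+x": ia, "-x": ib}), "x")
        assert d.values[0, 0] == 0.0
        assert d.provenance["guarded_pixels"] == 1


class TestTikhonov:
    def test_zero_dpc_gives_zero_phase(self, tfs32):
        zeros = np.zeros((32, 32))
        h_x = dpc_transfer(tfs32["+x"], tfs32["-x"])
        h_y = dpc_transfer(tfs32["+y"], tfs32["-y"])
        img = tikhonov_phase(DPCImage(zeros, "x"), DPCImage(zeros, "y"),
                             h_x, h_y, alpha=1e-4)
        assert np.all(img.phase == 0.0)

    def test_single_mode_inversion_closed_form(self, tfs32):
        """A one-mode DPC spectrum inverts to H*d/(|H|^2+alpha) at that mode."""
        h_x = dpc_transfer(tfs32["+x"], tfs32["-x"])
        h_y = dpc_transfer(tfs32["+y"], tfs32["-y"])
        k = (2, 7)
        d = 0.03
        n = 32
        spec = np.zeros((n, n), dtype=complex)
        spec[k] = d * n * n / 2
        spec[(-k[0]) % n, (-k[1]) % n] = d * n * n / 2
        dpc_x = DPCImage(np.fft.ifft2(spec).real, "x")
        dpc_y = DPCImage(np.zeros((n, n)), "y")
        alpha = 1e-4
        img = tikhonov_phase(dpc_x, dpc_y, h_x, h_y, alpha)
        phi_hat = np.fft.fft2(img.phase)
        expected = np.conj(h_x[k]) * spec[k] / (
            np.abs(h_x[k]) ** 2 + np.abs(h_y[k]) ** 2 + alpha
        )
        assert abs(phi_hat[k] - expected) < 1e-10 * abs(expected)

    def test_alpha_must_be_positive(self, tfs32):
        zeros = np.zeros((32, 32))
        h_x = dpc_transfer(tfs32["+x"], tfs32["-x"])
        with pytest.raises(ValueError):
            tikhonov_phase(DPCImage(zeros, "x"), DPCImage(zeros, "y"),
                           h_x, h_x, alpha=0.0)

    def test_all_zero_transfer_rejected(self):
        zeros = np.zeros((32, 32))
        with pytest.raises(ValueError, match="no phase transfer"):
            tikhonov_phase(DPCImage(zeros, "x"), DPCImage(zeros, "y"),
                           zeros.astype(complex), zeros.astype(complex), 1e-4)


@pytest.fixture(scope="module")
def setup256():
    osys = OpticalSystem(0.72, 0.6, 0.25, (256, 256))
    grid = FrequencyGrid.from_system(osys)
    pupil = make_pupil(osys, grid)
    tfs = {a: compute_wotf(osys, grid, pupil, make_source(osys, grid, a))
           for a in ARM_LABELS}
    return osys, grid, tfs


class TestRoundTrip:
    def test_noiseless_roundtrip_recovers_bandlimited_phase(self, setup256):
        osys, grid, tfs = setup256
        peak = 0.3
        phi = bandlimited_phase(osys.shape, grid.f_cutoff, grid.radius,
                                seed=5, peak=peak)
        fs = simulate_intensities(_phantom(phi), tfs)
        rec = reconstruct_field(fs, tfs, alpha=1e-4)
        assert _band_rmse(rec.phase, phi, grid) < 0.02 * peak

    def test_band_rmse_nondecreasing_in_alpha(self, setup256):
        osys, grid, tfs = setup256
        phi = bandlimited_phase(osys.shape, grid.f_cutoff, grid.radius,
                                seed=6, peak=0.3)
        fs = simulate_intensities(_phantom(phi), tfs)
        rmses = [
            _band_rmse(reconstruct_field(fs, tfs, alpha=a).phase, phi, grid)
            for a in (1e-6, 1e-5, 1e-4, 1e-3, 1e-2)
        ]
        assert all(b >= a for a, b in zip(rmses, rmses[1:]))

    def test_constant_phase_offset_is_unobservable(self, osys32, grid32, tfs32):
        phi = bandlimited_phase(osys32.shape, grid32.f_cutoff, grid32.radius,
                                seed=7, peak=0.2)
        rec = reconstruct_field(simulate_intensities(_phantom(phi), tfs32),
                                tfs32, 1e-4).phase
        rec_off = reconstruct_field(
            simulate_intensities(_phantom(phi + 0.4), tfs32), tfs32, 1e-4
        ).phase
        assert np.abs(rec - rec_off).max() < 1e-10

    def test_rotating_the_object_rotates_the_reconstruction(
        self, osys32, grid32, tfs32
    ):
        phi = bandlimited_phase(osys32.shape, grid32.f_cutoff, grid32.radius,
                                seed=8, peak=0.2)
        r1 = reconstruct_field(simulate_intensities(_phantom(phi), tfs32),
                               tfs32, 1e-4).phase
        r2 = reconstruct_field(
            simulate_intensities(_phantom(np.rot90(phi)), tfs32), tfs32, 1e-4
        ).phase
        assert np.abs(np.rot90(r1) - r2).max() < 1e-10

    def test_noisy_optimal_alpha_exceeds_noiseless_optimum(self, setup256):
        osys, grid, tfs = setup256
        phi = bandlimited_phase(osys.shape, grid.f_cutoff, grid.radius,
                                seed=9, peak=0.3)
        ph = _phantom(phi)
        alphas = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2)
        clean = simulate_intensities(ph, tfs)
        noisy = simulate_intensities(ph, tfs, NoiseModel("poisson", 10_000, seed=3))
        rm_clean = [_band_rmse(reconstruct_field(clean, tfs, a).phase, phi, grid)
                    for a in alphas]
        rm_noisy = [_band_rmse(reconstruct_field(noisy, tfs, a).phase, phi, grid)
                    for a in alphas]
        assert np.isfinite(rm_noisy).all()
        assert alphas[int(np.argmin(rm_noisy))] >= alphas[int(np.argmin(rm_clean))]


class TestStack:
    def test_identical_fields_reconstruct_identically(self, osys32, grid32, tfs32):
        phi = bandlimited_phase(osys32.shape, grid32.f_cutoff, grid32.radius,
                                seed=10, peak=0.2)
        fs = simulate_intensities(_phantom(phi), tfs32)
        out = reconstruct_stack([fs, fs, fs], tfs32, alpha=1e-4)
        assert len(out) == 3
        assert np.array_equal(out[0].phase, out[2].phase)
        single = reconstruct_field(fs, tfs32, alpha=1e-4)
        assert np.array_equal(out[0].phase, single.phase)
        assert [img.provenance["slice_index"] for img in out] == [0, 1, 2]

    def test_empty_stack_rejected(self, tfs32):
        with pytest.raises(ValueError, match="empty"):
            reconstruct_stack([], tfs32)

    def test_slice_errors_annotated_with_index(self, tfs32):
        bad = RawFrameSet(frames={"+x": np.ones((32, 32))})
        with pytest.raises(KeyError, match="slice 0"):
            reconstruct_stack([bad], tfs32)
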