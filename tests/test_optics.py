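import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qobm import (
    ARM_LABELS,
    FrequencyGrid,
    OpticalSystem,
    SourceDistribution,
    TransferFunctions,
    compute_wotf,
    dpc_transfer,
    make_pupil,
    make_source,
)
from qobm.optics import lattice_reflect

from oracles import wotf_direct


class TestOpticalSystem:
    def test_cutoff_is_na_over_lambda(self, osys32):
        assert osys32.f_cutoff == pytest.approx(0.6 / 0.72)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"wavelength_um": -0.5},
            {"na_objective": 0.0},
            {"na_objective": 1.2},
            {"pixel_um": 0.0},
            {"shape": (15, 32)},
            {"shape": (32, 14)},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(wavelength_um=0.72, na_objective=0.6, pixel_um=0.25,
                    shape=(32, 32))
        base.update(kwargs)
        with pytest.raises(ValueError):
            OpticalSystem(**base)

    def test_undersampled_grid_warns(self):
        # Nyquist 1/(2*1.0) = 0.5 cyc/um < cutoff 0.833 cyc/um
        with pytest.warns(UserWarning, match="Nyquist"):
            OpticalSystem(0.72, 0.6, 1.0, (32, 32))


class TestPupil:
    def test_dc_inside_and_beyond_cutoff_outside(self, osys32, grid32, pupil32):
        assert pupil32[0, 0] == 1.0
        beyond = grid32.radius > 1.5 * grid32.f_cutoff
        assert np.all(pupil32[beyond] == 0.0)
        inside = grid32.radius <= grid32.f_cutoff
        assert np.all(pupil32[inside] == 1.0)


class TestSource:
    def test_zero_offset_centers_source_at_origin(self, osys32, grid32):
        src = make_source(osys32, grid32, "+x", offset_frac=0.0, width_frac=0.3)
        assert np.unravel_index(np.argmax(src.weights), src.weights.shape) == (0, 0)

    def test_centroid_lands_on_offset_axis(self):
        osys = OpticalSystem(0.72, 0.6, 0.25, (256, 256))
        grid = FrequencyGrid.from_system(osys)
        src = make_source(osys, grid, "+x", offset_frac=1.0, width_frac=0.25)
        i, j = np.unravel_index(np.argmax(src.weights), src.weights.shape)
        # nearest lattice sample to (fx, fy) = (f_cutoff, 0)
        fx_target = np.argmin(np.abs(np.fft.fftfreq(256, 0.25) - grid.f_cutoff))
        assert (i, j) == (0, fx_target)

    @pytest.mark.parametrize("pair", [("+x", "-x"), ("+y", "-y")])
    def test_opposing_arms_are_exact_mirrors(self, osys32, grid32, pair):
        pos = make_source(osys32, grid32, pair[0])
        neg = make_source(osys32, grid32, pair[1])
        assert np.array_equal(neg.weights, lattice_reflect(pos.weights))

    def test_unknown_arm_label_names_valid_ones(self, osys32, grid32):
        with pytest.raises(ValueError, match=r"\+x"):
            make_source(osys32, grid32, "up")

    def test_parameter_bounds(self, osys32, grid32):
        with pytest.raises(ValueError):
            make_source(osys32, grid32, "+x", offset_frac=2.5)
        with pytest.raises(ValueError):
            make_source(osys32, grid32, "+x", width_frac=0.0)

    def test_negative_or_empty_weights_rejected(self, grid32):
        with pytest.raises(ValueError):
            SourceDistribution(weights=-np.ones(grid32.shape), label="+x")
        with pytest.raises(ValueError):
            SourceDistribution(weights=np.zeros(grid32.shape), label="+x")


class TestWOTF:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_sum_oracle(self, osys32, grid32, pupil32, seed):
        """Vectorized lattice sums equal a literal double-loop evaluation."""
        rng = np.random.default_rng(seed)
        weights = rng.uniform(0.0, 1.0, size=grid32.shape)
        src = SourceDistribution(weights=weights, label="+x")
        tf = compute_wotf(osys32, grid32, pupil32, src)
        b_ref, h_abs_ref, h_ph_ref = wotf_direct(pupil32, weights)
        scale_a = np.abs(h_abs_ref).max()
        scale_p = np.abs(h_ph_ref).max()
        assert tf.background == pytest.approx(b_ref, rel=1e-12)
        assert np.abs(tf.h_abs - h_abs_ref).max() < 1e-10 * scale_a
        assert np.abs(tf.h_ph - h_ph_ref).max() < 1e-10 * scale_p

    def test_phase_transfer_vanishes_at_dc(self, tfs32):
        for tf in tfs32.values():
            assert abs(tf.h_ph[0, 0]) < 1e-12

    def test_symmetric_source_has_no_phase_contrast(self, osys32, grid32, pupil32):
        src = make_source(osys32, grid32, "+x", offset_frac=0.0)
        tf = compute_wotf(osys32, grid32, pupil32, src)
        assert np.abs(tf.h_ph).max() < 1e-12

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(
        offset=st.floats(0.0, 2.0),
        width=st.floats(0.05, 1.0),
        arm=st.sampled_from(ARM_LABELS),
    )
    def test_zero_dc_and_hermitian_symmetry_for_any_source(
        self, osys32, grid32, pupil32, offset, width, arm
    ):
        src = make_source(osys32, grid32, arm, offset_frac=offset, width_frac=width)
        tf = compute_wotf(osys32, grid32, pupil32, src)
        assert abs(tf.h_ph[0, 0]) < 1e-12
        assert np.abs(lattice_reflect(tf.h_ph) - np.conj(tf.h_ph)).max() < 1e-10

    def test_phase_response_to_real_object_is_real(self, tfs32, rng):
        phi = rng.standard_normal((32, 32))
        out = np.fft.ifft2(tfs32["+x"].h_ph * np.fft.fft2(phi))
        assert np.abs(out.imag).max() < 1e-10 * np.abs(out.real).max()

    def test_dark_field_source_rejected(self, osys32, grid32, pupil32):
        weights = np.where(grid32.radius > 1.2 * grid32.f_cutoff, 1.0, 0.0)
        src = SourceDistribution(weights=weights, label="+x")
        with pytest.raises(ValueError, match="dark field"):
            compute_wotf(osys32, grid32, pupil32, src)


class TestDPCTransfer:
    def test_identical_arms_give_zero(self, tfs32):
        h = dpc_transfer(tfs32["+x"], tfs32["+x"])
        assert np.abs(h).max() == 0.0

    def test_swap_negates(self, tfs32):
        h_ab = dpc_transfer(tfs32["+x"], tfs32["-x"])
        h_ba = dpc_transfer(tfs32["-x"], tfs32["+x"])
        assert np.array_equal(h_ab, -h_ba)

    def test_mirror_pair_antisymmetric_with_zero_dc(self, tfs32, grid32):
        h = dpc_transfer(tfs32["+x"], tfs32["-x"])
        assert abs(h[0, 0]) < 1e-12
        assert np.abs(lattice_reflect(h) + h).max() < 1e-12 * np.abs(h).max() + 1e-15

    def test_zero_background_rejected(self, tfs32):
        dead = TransferFunctions(
            h_abs=tfs32["+x"].h_abs, h_ph=tfs32["+x"].h_ph, background=0.0,
            source_label="+x",
        )
        dead_b = TransferFunctions(
            h_abs=tfs32["-x"].h_abs, h_ph=tfs32["-x"].h_ph, background=0.0,
            source_label="-x",
        )
        with pytest.raises(ValueError):
            dpc_transfer(dead, dead_b)
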