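"""Forward simulation of the four raw oblique-illumination intensity images.

The default forward model is the weak-object linearization: for each arm

    I = B + IFFT[ H_abs * FFT(mu) + H_ph * FFT(phi) ]  (real part)

optionally followed by seeded Poisson shot noise at a configurable photon
scale.  This is the model under which the DPC reconstruction chain is an
exact linear inversion.

An Abbe-sum reference simulator — the full partially coherent image as an
incoherent sum of coherent images over discrete source points, with the
un-linearized transmittance exp(-mu + i*phi) — is also provided.  It is
deliberately slow and simple; its role is to bound the linearization error
of the weak-object model on weak phantoms, not to be the default path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .optics import ARM_LABELS, SourceDistribution, TransferFunctions
from .phantom import TissuePhantom

__all__ = [
    "NoiseModel",
    "RawFrameSet",
    "simulate_intensities",
    "simulate_zstack",
    "truncate_source",
    "abbe_image",
    "abbe_frame_set",
]

_IMAG_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class NoiseModel:
    """Shot-noise settings: 'none', or 'poisson' at ``photon_scale`` photons
    per pixel at the background level B."""

    kind: str = "none"
    photon_scale: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "poisson"):
            raise ValueError(f"noise kind must be 'none' or 'poisson', got {self.kind!r}")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")


@dataclass(frozen=True)
class RawFrameSet:
    """The four intensity images of one field/depth, keyed by arm label."""

    frames: dict[str, np.ndarray]
    exposure_meta: dict = field(default_factory=dict)
    sys_ref: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {f.shape for f in self.frames.values()}
        if len(shapes) > 1:
            raise ValueError(f"all frames must share one shape, got {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.frames.values())).shape


def simulate_intensities(
    ph: TissuePhantom,
    tfs: Mapping[str, TransferFunctions],
    noise: NoiseModel | None = None,
) -> RawFrameSet:
    """Simulate the raw intensity image of each illumination arm.

    Under the weak-object model the noiseless image is exactly linear in
    the phantom's phase and absorption maps.  With Poisson noise, each
    pixel is an independent draw with mean ``photon_scale * I / B_mean``
    rescaled back to intensity units, seeded through ``noise.seed``.
    Negative noiseless intensities (possible only for strong phantoms
    where the linearization breaks down) are kept and flagged in the
    metadata rather than clipped.
    """
    noise = noise or NoiseModel()
    mu_hat = np.fft.fft2(ph.absorption)
    phi_hat = np.fft.fft2(ph.phase)
    frames: dict[str, np.ndarray] = {}
    has_negative = False
    for label, tf in tfs.items():
        if tf.h_ph.shape != ph.shape:
            raise ValueError(
                f"grid mismatch: transfer functions {tf.h_ph.shape} vs "
                f"phantom {ph.shape}"
            )
        img_c = np.fft.ifft2(tf.h_abs * mu_hat + tf.h_ph * phi_hat)
        resid = np.abs(img_c.imag).max()
        scale = max(np.abs(img_c.real).max(), tf.background)
        if resid > _IMAG_RESIDUAL_TOL * scale:
            raise AssertionError(
                f"imaginary residual {resid:.3e} exceeds tolerance; "
                "transfer functions violate Hermitian symmetry"
            )
        img = tf.background + img_c.real
        has_negative = has_negative or bool(np.any(img < 0))
        frames[label] = img

    if noise.kind == "poisson":
        rng = np.random.default_rng(noise.seed)
        b_mean = float(np.mean([tf.background for tf in tfs.values()]))
        gain = noise.photon_scale / b_mean
        for label in frames:
            lam = np.clip(frames[label] * gain, 0.0, None)
            frames[label] = rng.poisson(lam).astype(float) / gain

    meta = {
        "noise": noise.kind,
        "photon_scale": noise.photon_scale,
        "seed": noise.seed,
        "negative_intensities": has_negative,
        "phantom_state": ph.meta.get("state"),
        "phantom_regime": ph.meta.get("regime"),
    }
    return RawFrameSet(frames=frames, exposure_meta=meta)


def simulate_zstack(
    ph_stack: Sequence[TissuePhantom],
    tfs: Mapping[str, TransferFunctions],
    noise: NoiseModel | None = None,
    slice_spacing_um: float = 1.5,
) -> list[RawFrameSet]:
    """Simulate a depth stack slice by slice.

    Each slice is an independent 2D simulation (no defocus cross-talk);
    with Poisson noise, per-slice seeds are derived from the base seed so
    slices are independent but the stack is reproducible.  The default
    slice spacing of 1.5 um matches a typical qOBM depth scan.
    """
    if len(ph_stack) == 0:
        raise ValueError("empty phantom stack")
    out = []
    for k, ph in enumerate(ph_stack):
        slice_noise = noise
        if noise is not None and noise.kind == "poisson":
            slice_noise = replace(noise, seed=noise.seed + k)
        fs = simulate_intensities(ph, tfs, slice_noise)
        fs.exposure_meta["slice_index"] = k
        fs.exposure_meta["slice_spacing_um"] = slice_spacing_um
        out.append(fs)
    return out


def truncate_source(source: SourceDistribution, max_points: int) -> SourceDistribution:
    """Keep only the ``max_points`` largest source weights, zeroing the rest.

    Used to put the weak-object transfer functions and the Abbe reference
    on exactly the same discrete source, so that comparing them isolates
    the linearization error from source-sampling differences.
    """
    w = source.weights
    if max_points >= w.size:
        return source
    flat = w.ravel()
    threshold = np.partition(flat, -max_points)[-max_points]
    kept = np.where(w >= threshold, w, 0.0)
    return SourceDistribution(weights=kept, label=source.label, params=dict(source.params))


def abbe_image(
    ph: TissuePhantom, pupil: np.ndarray, source: SourceDistribution
) -> np.ndarray:
    """Full partially coherent image of one arm by Abbe's source summation.

    Each nonzero source lattice point illuminates the object with a tilted
    plane wave; the camera sees the incoherent, weight-summed coherent
    images ``sum_s S(u_s) |IFFT[P(u) T_hat(u - u_s)]|^2`` with the exact
    transmittance ``t = exp(-mu + i*phi)``.  Runtime is one FFT per source
    point — use :func:`truncate_source` first on large grids.
    """
    t = np.exp(-ph.absorption + 1j * ph.phase)
    t_hat = np.fft.fft2(t)
    img = np.zeros(ph.shape)
    idx = np.argwhere(source.weights > 0)
    for i, j in idx:
        shifted = np.roll(t_hat, shift=(i, j), axis=(0, 1))
        field_img = np.fft.ifft2(pupil * shifted)
        img += source.weights[i, j] * np.abs(field_img) ** 2
    return img


def abbe_frame_set(
    ph: TissuePhantom,
    pupil: np.ndarray,
    sources: Mapping[str, SourceDistribution],
    max_points: int = 200,
) -> RawFrameSet:
    """Abbe-sum reference images for all arms, truncated to ``max_points``
    source samples per arm."""
    frames = {
        label: abbe_image(ph, pupil, truncate_source(src, max_points))
        for label, src in sources.items()
    }
    meta = {"noise": "none", "model": "abbe", "max_points": max_points}
    return RawFrameSet(frames=frames, exposure_meta=meta)
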