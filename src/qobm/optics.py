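"""Optical model for an epi-mode DPC/qOBM imager.

This module builds the three ingredients of the linear imaging model used
throughout the package:

* an ideal circular pupil set by the objective NA,
* parametric oblique effective-source distributions (offset Gaussians in
  pupil coordinates, one per illumination arm), and
* the weak-object transfer functions (WOTFs) of a partially coherent
  imager, which define both the forward simulation and the deconvolution.

Conventions, used everywhere in the package:

* spatial frequencies are in cycles/um, on the discrete FFT lattice of the
  image grid (``numpy.fft.fftfreq`` ordering; the zero frequency is the
  ``[0, 0]`` sample);
* phase is in radians, with object transmittance ``t = exp(-mu + i*phi)``
  and ``phi > 0`` for refractive index above background;
* the weak-object linearization ``t ~ 1 - mu + i*phi`` gives the image
  spectrum ``I_hat(u) = B*delta(u) + H_abs(u)*mu_hat(u) + H_ph(u)*phi_hat(u)``
  with, as discrete lattice sums over source weights S and pupil P,

      B        = sum_u' S(u') |P(u')|^2
      Gamma(u) = sum_u' S(u') conj(P(u')) P(u' + u)
      H_abs(u) = -(Gamma(u) + conj(Gamma(-u)))
      H_ph(u)  = i*(Gamma(u) - conj(Gamma(-u)))

  where the pupil is zero outside the lattice (linear, not circular,
  correlation).

``H_ph`` vanishes identically at zero frequency — constant phase offsets
are unobservable, which is the low-frequency insensitivity characteristic
of DPC-type reconstructions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ARM_LABELS",
    "OpticalSystem",
    "FrequencyGrid",
    "SourceDistribution",
    "TransferFunctions",
    "make_pupil",
    "make_source",
    "compute_wotf",
    "dpc_transfer",
    "lattice_reflect",
]

#: Valid illumination-arm labels: two opposing pairs along x and y.
ARM_LABELS = ("+x", "-x", "+y", "-y")

#: Axis unit vector (fx, fy) for the positive arm of each axis.
_ARM_DIRECTIONS = {
    "+x": (1.0, 0.0),
    "-x": (-1.0, 0.0),
    "+y": (0.0, 1.0),
    "-y": (0.0, -1.0),
}


@dataclass(frozen=True)
class OpticalSystem:
    """Objective + camera geometry defining the pupil and frequency grid.

    Parameters
    ----------
    wavelength_um : float
        Illumination wavelength in micrometers (e.g. 0.72 for 720-nm LEDs).
    na_objective : float
        Numerical aperture of the collection objective, in (0, 1].
    pixel_um : float
        Object-plane sampling in micrometers per pixel.
    shape : tuple of int
        (rows, cols) of the simulation grid; both even and >= 16.
    """

    wavelength_um: float
    na_objective: float
    pixel_um: float
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError(f"wavelength_um must be > 0, got {self.wavelength_um}")
        if not 0 < self.na_objective <= 1:
            raise ValueError(
                f"na_objective must be in (0, 1], got {self.na_objective}"
            )
        if self.pixel_um <= 0:
            raise ValueError(f"pixel_um must be > 0, got {self.pixel_um}")
        rows, cols = self.shape
        object.__setattr__(self, "shape", (int(rows), int(cols)))
        for n in self.shape:
            if n < 16 or n % 2:
                raise ValueError(f"grid sides must be even and >= 16, got {self.shape}")
        # Sampling below Nyquist is allowed, but the pupil then wraps.
        nyquist = 1.0 / (2.0 * self.pixel_um)
        if self.f_cutoff > nyquist:
            warnings.warn(
                f"pupil cutoff {self.f_cutoff:.3f} cyc/um exceeds the grid "
                f"Nyquist frequency {nyquist:.3f} cyc/um; the pupil is "
                "truncated by the frequency lattice",
                stacklevel=2,
            )

    @property
    def f_cutoff(self) -> float:
        """Pupil cutoff frequency NA/lambda in cycles/um."""
        return self.na_objective / self.wavelength_um


@dataclass(frozen=True)
class FrequencyGrid:
    """Discrete Fourier frequency lattice of an image grid (cycles/um)."""

    fx: np.ndarray
    fy: np.ndarray
    f_cutoff: float

    @classmethod
    def from_system(cls, sys: OpticalSystem) -> "FrequencyGrid":
        rows, cols = sys.shape
        fy = np.fft.fftfreq(rows, d=sys.pixel_um)[:, None] * np.ones((1, cols))
        fx = np.fft.fftfreq(cols, d=sys.pixel_um)[None, :] * np.ones((rows, 1))
        return cls(fx=fx, fy=fy, f_cutoff=sys.f_cutoff)

    @property
    def shape(self) -> tuple[int, int]:
        return self.fx.shape

    @property
    def radius(self) -> np.ndarray:
        """Radial frequency |u| per lattice sample."""
        return np.hypot(self.fx, self.fy)


@dataclass(frozen=True)
class SourceDistribution:
    """Angular intensity of one oblique illumination arm in pupil coordinates.

    ``weights`` is a nonnegative intensity per frequency-lattice sample, in
    ``fftfreq`` ordering like everything else.  Opposing arms are exact
    lattice mirror images of each other (see :func:`make_source`).
    """

    weights: np.ndarray
    label: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("source weights must be nonnegative")
        if not np.sum(w) > 0:
            raise ValueError("source weights must not be all zero")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class TransferFunctions:
    """Weak-object transfer functions of one illumination arm.

    Attributes
    ----------
    h_abs, h_ph : complex ndarray
        Amplitude- and phase-contrast transfer functions on the frequency
        lattice (fftfreq ordering).
    background : float
        DC intensity B = sum S |P|^2 of the arm.
    source_label : str
        Provenance: which arm produced these.
    """

    h_abs: np.ndarray
    h_ph: np.ndarray
    background: float
    source_label: str


def lattice_reflect(a: np.ndarray) -> np.ndarray:
    """Reflect an fft-ordered array through the frequency origin.

    Maps sample index ``(i, j)`` to ``(-i mod n, -j mod m)``; the DC sample
    and (for even sides) the Nyquist row/column are fixed points.
    """
    return np.roll(a[::-1, ::-1], shift=(1, 1), axis=(0, 1))


def make_pupil(sys: OpticalSystem, grid: FrequencyGrid) -> np.ndarray:
    """Ideal unaberrated circular pupil: 1 inside |u| <= NA/lambda, else 0."""
    return (grid.radius <= grid.f_cutoff).astype(complex)


def make_source(
    sys: OpticalSystem,
    grid: FrequencyGrid,
    arm_label: str,
    offset_frac: float = 0.8,
    width_frac: float = 0.35,
) -> SourceDistribution:
    """Offset-Gaussian effective source for one oblique illumination arm.

    The source is a Gaussian in pupil coordinates with centroid at radius
    ``offset_frac * f_cutoff`` along the arm's axis and standard deviation
    ``width_frac * f_cutoff``.  This is a parametric stand-in for the
    effective epi-mode source produced by multiply scattered light: the
    offset carries the obliquity that generates phase contrast, the width
    the angular spread.  Negative arms are constructed by lattice-mirroring
    the corresponding positive arm so opposing pairs are mirror images
    sample for sample, exactly.
    """
    if arm_label not in _ARM_DIRECTIONS:
        raise ValueError(
            f"unknown arm label {arm_label!r}; valid labels are {ARM_LABELS}"
        )
    if not 0 <= offset_frac <= 2:
        raise ValueError(f"offset_frac must be in [0, 2], got {offset_frac}")
    if width_frac <= 0:
        raise ValueError(f"width_frac must be > 0, got {width_frac}")

    params = {"offset_frac": float(offset_frac), "width_frac": float(width_frac)}
    if arm_label in ("-x", "-y"):
        positive = make_source(sys, grid, "+" + arm_label[1], offset_frac, width_frac)
        return SourceDistribution(
            weights=lattice_reflect(positive.weights), label=arm_label, params=params
        )

    dx, dy = _ARM_DIRECTIONS[arm_label]
    cx = offset_frac * grid.f_cutoff * dx
    cy = offset_frac * grid.f_cutoff * dy
    sigma = width_frac * grid.f_cutoff
    r2 = (grid.fx - cx) ** 2 + (grid.fy - cy) ** 2
    weights = np.exp(-r2 / (2.0 * sigma**2))
    return SourceDistribution(weights=weights, label=arm_label, params=params)


def _lattice_correlation(a: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Linear lattice correlation Gamma(u) = sum_u' a(u') p(u' + u).

    Both inputs are fft-ordered maps on the same frequency lattice; ``p``
    is treated as zero outside the lattice (no circular wrap).  Computed
    exactly (to rounding) with zero-padded FFTs; the result is returned in
    fft ordering.
    """
    a_c = np.fft.fftshift(a)
    p_c = np.fft.fftshift(p)
    n0, n1 = a.shape
    m0, m1 = 2 * n0, 2 * n1
    a_pad = np.zeros((m0, m1), dtype=complex)
    p_pad = np.zeros((m0, m1), dtype=complex)
    a_pad[:n0, :n1] = a_c
    p_pad[:n0, :n1] = p_c
    # C[k] = sum_m p_pad[m] * a_pad[m - k]  (circular on the padded grid);
    # with half-empty padding the wrap never mixes signal, so this is the
    # linear correlation, and Gamma at centered offset d is C[d].
    c = np.fft.ifft2(np.fft.fft2(p_pad) * np.conj(np.fft.fft2(np.conj(a_pad))))
    d0 = (np.arange(n0) - n0 // 2) % m0
    d1 = (np.arange(n1) - n1 // 2) % m1
    gamma_centered = c[np.ix_(d0, d1)]
    return np.fft.ifftshift(gamma_centered)


def compute_wotf(
    sys: OpticalSystem,
    grid: FrequencyGrid,
    pupil: np.ndarray,
    source: SourceDistribution,
) -> TransferFunctions:
    """Weak-object transfer functions of one arm from its source and pupil.

    Implements the discrete lattice sums given in the module docstring.
    For a real pupil and real source weights (the only case this package
    constructs) Gamma is real-valued, which makes ``H_ph(0)`` exactly zero
    and guarantees the Hermitian symmetry ``H_ph(-u) = conj(H_ph(u))`` that
    keeps reconstructed phase maps real.

    Raises
    ------
    ValueError
        If the source does not overlap the pupil support (B = 0: dark
        field, outside the weak-object model).
    """
    if pupil.shape != grid.shape or source.weights.shape != grid.shape:
        raise ValueError("pupil and source must live on the frequency grid lattice")
    s = source.weights
    b = float(np.real(np.sum(s * np.abs(pupil) ** 2)))
    if b <= 0:
        raise ValueError("dark field: B = 0 (source does not overlap the pupil)")

    gamma = _lattice_correlation(s * np.conj(pupil), pupil)
    if np.isrealobj(s) and np.allclose(pupil.imag, 0.0):
        gamma = gamma.real.astype(complex)
    gamma_rev = np.conj(lattice_reflect(gamma))
    h_abs = -(gamma + gamma_rev)
    h_ph = 1j * (gamma - gamma_rev)
    return TransferFunctions(
        h_abs=h_abs, h_ph=h_ph, background=b, source_label=source.label
    )


def dpc_transfer(tf_a: TransferFunctions, tf_b: TransferFunctions) -> np.ndarray:
    """Transfer function of the normalized-difference (DPC) image of a pair.

    For opposing arms a, b the DPC image D = (I_a - I_b)/(I_a + I_b) obeys
    ``D_hat(u) = H_dpc(u) * phi_hat(u)`` under the weak-object, pure-phase
    approximation, with ``H_dpc = (H_ph_a - H_ph_b) / (B_a + B_b)``.
    """
    denom = tf_a.background + tf_b.background
    if denom == 0:
        raise ValueError("B_a + B_b = 0: cannot normalize the DPC difference")
    return (tf_a.h_ph - tf_b.h_ph) / denom
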