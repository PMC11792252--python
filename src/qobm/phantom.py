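"""Synthetic thick-tissue phantoms and the acetowhitening (AA) transform.

The generator emulates a single en-face optical section of fresh tissue as
seen by a quantitative phase microscope: cell nuclei (smooth-phase disks),
a textured cytoplasmic/extracellular background, and occasional small
high-phase round inclusions resembling lipid droplets.  Fields are purely
synthetic — geometry is kept fixed between the fresh and stained states so
that supervised comparisons are possible, which real tissue does not allow
(staining deforms it).

The AA transform is a parametric model of acetowhitening as it appears in
phase images: protein denaturation and chromatin condensation raise the
nuclear refractive index (multiplicative phase gain on nuclei) while
non-nuclear structure becomes more homogeneous (background phase mixed
toward its mean).  Magnitudes are free parameters; defaults are chosen so
the qualitative effect — higher nuclear contrast alongside an overall
decrease in phase variance — holds robustly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .optics import OpticalSystem

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_NUCLEUS",
    "LABEL_INCLUSION",
    "PhantomSpec",
    "TissuePhantom",
    "AAParams",
    "generate_phantom",
    "apply_aa_transform",
]

LABEL_BACKGROUND = 0
LABEL_NUCLEUS = 1
LABEL_INCLUSION = 2

#: Placement attempts per requested object before giving up.
_MAX_ATTEMPTS_PER_OBJECT = 200


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters for one synthetic tissue field.

    Defaults describe a field of cortical-tissue-like density at the
    package's default optics (0.25 um pixels): a dozen nuclei of 3-6 um
    radius whose peak phase (~0.15 rad) barely exceeds the zero-mean
    background texture (~0.1 rad SD) — fresh, unstained tissue gives
    nuclei only limited phase contrast — plus a few bright round
    inclusions resembling lipid droplets.
    """

    n_nuclei: int = 12
    nucleus_radius_um: tuple[float, float] = (3.0, 6.0)
    nucleus_phase: float = 0.15
    background_texture_sd: float = 0.10
    background_smooth_um: float = 1.0
    n_inclusions: int = 3
    inclusion_radius_um: tuple[float, float] = (0.8, 1.6)
    inclusion_phase: float = 0.6
    absorption_level: float = 0.0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0 or self.n_inclusions < 0:
            raise ValueError("object counts must be nonnegative")
        for lo, hi in (self.nucleus_radius_um, self.inclusion_radius_um):
            if not 0 < lo <= hi:
                raise ValueError("radius ranges must satisfy 0 < lo <= hi")
        if self.background_texture_sd < 0:
            raise ValueError("background_texture_sd must be >= 0")
        if self.absorption_level < 0:
            raise ValueError("absorption_level must be >= 0")


@dataclass(frozen=True)
class TissuePhantom:
    """Per-pixel phase (radians) and absorption maps with a label mask.

    ``labels`` assigns each pixel exactly one of background (0),
    nucleus (1), inclusion (2).  ``meta`` records the generator settings,
    the seed, and a ``regime`` flag: ``"weak"`` when max |phase| <= 1 rad
    and max absorption <= 0.2 (the weak-object linearization is trusted),
    ``"nonlinear"`` otherwise.
    """

    phase: np.ndarray
    absorption: np.ndarray
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase must be finite everywhere")
        if np.any(self.absorption < 0):
            raise ValueError("absorption must be nonnegative")
        if self.phase.shape != self.absorption.shape or self.phase.shape != self.labels.shape:
            raise ValueError("phase, absorption and labels must share one shape")
        valid = (LABEL_BACKGROUND, LABEL_NUCLEUS, LABEL_INCLUSION)
        if not np.isin(self.labels, valid).all():
            raise ValueError(f"labels must be one of {valid}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape


@dataclass(frozen=True)
class AAParams:
    """Parametric acetowhitening transform.

    Parameters
    ----------
    nuclear_gain : float
        Multiplicative phase gain on nucleus pixels, >= 1.
    homogenization : float
        Mixing weight in [0, 1] pulling background phase toward its mean
        (0: untouched; 1: fully homogenized).
    inclusion_gain : float
        Phase gain on inclusion pixels (lipid droplets are not chromatin;
        default leaves them unchanged).
    homogenization_mode : {"global", "local"}
        Whether the homogenization target is the global background mean or
        a local (Gaussian-smoothed) mean.
    local_scale_um : float
        Smoothing scale of the local mean, used only in "local" mode.
    """

    nuclear_gain: float = 1.8
    homogenization: float = 0.7
    inclusion_gain: float = 1.0
    homogenization_mode: Literal["global", "local"] = "global"
    local_scale_um: float = 5.0

    def __post_init__(self) -> None:
        if self.nuclear_gain < 1:
            raise ValueError(f"nuclear_gain must be >= 1, got {self.nuclear_gain}")
        if not 0 <= self.homogenization <= 1:
            raise ValueError(
                f"homogenization must be in [0, 1], got {self.homogenization}"
            )
        if self.homogenization_mode not in ("global", "local"):
            raise ValueError("homogenization_mode must be 'global' or 'local'")


def _place_disks(
    shape: tuple[int, int],
    n: int,
    radius_px_range: tuple[float, float],
    rng: np.random.Generator,
    occupied: np.ndarray,
    kind: str,
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping disk placements (cy, cx, r) in pixels.

    Disks must not overlap anything already marked in ``occupied`` (updated
    in place) and must lie fully inside the field.
    """
    rows, cols = shape
    placed: list[tuple[float, float, float]] = []
    yy, xx = np.mgrid[0:rows, 0:cols]
    attempts_left = _MAX_ATTEMPTS_PER_OBJECT * max(n, 1)
    while len(placed) < n and attempts_left > 0:
        attempts_left -= 1
        r = rng.uniform(*radius_px_range)
        cy = rng.uniform(r, rows - r)
        cx = rng.uniform(r, cols - r)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if occupied[mask].any():
            continue
        # one-pixel moat so components stay disjoint under 8-connectivity
        moat = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r + 1.5) ** 2
        occupied |= moat
        placed.append((cy, cx, r))
    if len(placed) < n:
        raise RuntimeError(
            f"could not place {n} non-overlapping {kind} disks "
            f"(achieved {len(placed)}); reduce count or radii"
        )
    return placed


def generate_phantom(
    sys: OpticalSystem, spec: PhantomSpec, seed: int
) -> TissuePhantom:
    """Generate a seeded synthetic tissue field on the system's pixel grid.

    Nuclei are non-overlapping disks with a smooth dome-shaped interior
    phase peaking at ``nucleus_phase`` (slight per-nucleus brightness
    jitter); the background is zero-mean Gaussian noise smoothed to
    ``background_smooth_um`` and rescaled to ``background_texture_sd``;
    inclusions are small bright disks.  The same seed reproduces the
    phantom bit for bit.
    """
    rows, cols = sys.shape
    px = sys.pixel_um
    r_nuc = (spec.nucleus_radius_um[0] / px, spec.nucleus_radius_um[1] / px)
    if r_nuc[0] < 2.0:
        raise ValueError(
            f"nucleus radius {spec.nucleus_radius_um[0]} um is under 2 pixels "
            f"at {px} um/pixel"
        )
    rng = np.random.default_rng(seed)

    phase = np.zeros((rows, cols))
    labels = np.full((rows, cols), LABEL_BACKGROUND, dtype=np.uint8)
    occupied = np.zeros((rows, cols), dtype=bool)

    nuclei = _place_disks((rows, cols), spec.n_nuclei, r_nuc, rng, occupied, "nucleus")
    r_inc = (spec.inclusion_radius_um[0] / px, spec.inclusion_radius_um[1] / px)
    r_inc = (max(r_inc[0], 1.0), max(r_inc[1], 1.0))
    inclusions = _place_disks(
        (rows, cols), spec.n_inclusions, r_inc, rng, occupied, "inclusion"
    )

    if spec.background_texture_sd > 0:
        noise = rng.standard_normal((rows, cols))
        texture = ndimage.gaussian_filter(
            noise, sigma=spec.background_smooth_um / px, mode="wrap"
        )
        texture -= texture.mean()
        sd = texture.std()
        if sd > 0:
            texture *= spec.background_texture_sd / sd
        phase += texture

    yy, xx = np.mgrid[0:rows, 0:cols]
    for cy, cx, r in nuclei:
        rho2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / r**2
        inside = rho2 <= 1.0
        level = spec.nucleus_phase * rng.uniform(0.85, 1.15)
        dome = level * np.sqrt(np.clip(1.0 - rho2, 0.0, None))
        phase[inside] = dome[inside]
        labels[inside] = LABEL_NUCLEUS
    for cy, cx, r in inclusions:
        rho2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / r**2
        inside = rho2 <= 1.0
        dome = spec.inclusion_phase * np.sqrt(np.clip(1.0 - rho2, 0.0, None))
        phase[inside] = dome[inside]
        labels[inside] = LABEL_INCLUSION

    absorption = np.full((rows, cols), spec.absorption_level)
    regime = (
        "weak"
        if np.max(np.abs(phase)) <= 1.0 and np.max(absorption) <= 0.2
        else "nonlinear"
    )
    meta = {
        "seed": int(seed),
        "pixel_um": px,
        "n_nuclei": spec.n_nuclei,
        "nucleus_radius_um": list(spec.nucleus_radius_um),
        "nucleus_phase": spec.nucleus_phase,
        "background_texture_sd": spec.background_texture_sd,
        "n_inclusions": spec.n_inclusions,
        "inclusion_phase": spec.inclusion_phase,
        "regime": regime,
        "state": "fresh",
    }
    return TissuePhantom(phase=phase, absorption=absorption, labels=labels, meta=meta)


def apply_aa_transform(ph: TissuePhantom, p: AAParams) -> TissuePhantom:
    """Apply the parametric acetowhitening transform to a phantom.

    Nucleus phase is multiplied by ``nuclear_gain``; background phase is
    mixed toward its (global or local) mean with weight ``homogenization``;
    inclusion phase is multiplied by ``inclusion_gain``.  Labels, geometry
    and absorption are unchanged, so fresh/stained pairs stay pixel-aligned.
    """
    phase = ph.phase.copy()
    nuc = ph.labels == LABEL_NUCLEUS
    bg = ph.labels == LABEL_BACKGROUND
    inc = ph.labels == LABEL_INCLUSION

    phase[nuc] *= p.nuclear_gain
    phase[inc] *= p.inclusion_gain
    if bg.any() and p.homogenization > 0:
        if p.homogenization_mode == "global":
            target = ph.phase[bg].mean()
        else:
            px = ph.meta.get("pixel_um", 1.0)
            sigma = p.local_scale_um / px
            # local mean over background only (normalized masked smoothing)
            num = ndimage.gaussian_filter(np.where(bg, ph.phase, 0.0), sigma)
            den = ndimage.gaussian_filter(bg.astype(float), sigma)
            target = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)[bg]
        phase[bg] = (1.0 - p.homogenization) * ph.phase[bg] + p.homogenization * target

    meta = dict(ph.meta)
    meta["state"] = "aa"
    meta["aa_params"] = {
        "nuclear_gain": p.nuclear_gain,
        "homogenization": p.homogenization,
        "inclusion_gain": p.inclusion_gain,
        "homogenization_mode": p.homogenization_mode,
    }
    regime = (
        "weak"
        if np.max(np.abs(phase)) <= 1.0 and np.max(ph.absorption) <= 0.2
        else "nonlinear"
    )
    meta["regime"] = regime
    return replace(ph, phase=phase, labels=ph.labels.copy(), meta=meta)
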