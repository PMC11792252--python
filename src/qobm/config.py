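"""Run configuration: YAML parsing, validation, and seed fan-out.

A run config collects the blocks consumed by the pipeline — optics,
phantom, AA transform, noise, reconstruction, metrics — plus the root
seed and output directory.  Validation is strict: unknown keys are
rejected so typos fail before any compute starts.  Per-stage random seeds
are derived deterministically from the root seed and the stage name, so
one integer reproduces a whole experiment.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .forward import NoiseModel
from .optics import ARM_LABELS, OpticalSystem
from .phantom import AAParams, PhantomSpec

__all__ = ["RunConfig", "load_config", "stage_seed"]

_DEFAULT_ARM_PARAMS = {"offset_frac": 0.8, "width_frac": 0.35}


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one end-to-end experiment."""

    optics: OpticalSystem
    arm_params: dict[str, dict[str, float]]
    phantom: PhantomSpec
    aa: AAParams
    noise_kind: str
    photon_scale: float
    alpha: float
    n_fields: int
    seed: int
    out_dir: Path

    def noise_model(self, seed: int) -> NoiseModel:
        return NoiseModel(kind=self.noise_kind, photon_scale=self.photon_scale,
                          seed=seed)


def _check_keys(block: dict, allowed: set[str], name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config block {name!r}")


def _build_from_dataclass(cls, block: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    _check_keys(block, allowed, name)
    kwargs = dict(block)
    for key in ("nucleus_radius_um", "inclusion_radius_um"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(source, seed: int | None = None, out_dir=None) -> RunConfig:
    """Build a validated :class:`RunConfig` from a YAML file or a dict.

    ``seed`` and ``out_dir`` override the corresponding config entries
    (CLI precedence).
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    _check_keys(
        raw,
        {"optics", "phantom", "aa", "noise", "reconstruction", "metrics",
         "seed", "out_dir"},
        "<top level>",
    )

    optics_block = dict(raw.get("optics", {}))
    arm_block = optics_block.pop("arms", {})
    _check_keys(
        optics_block, {"wavelength_um", "na_objective", "pixel_um", "shape"}, "optics"
    )
    defaults = {"wavelength_um": 0.72, "na_objective": 0.6, "pixel_um": 0.25,
                "shape": (512, 512)}
    defaults.update(optics_block)
    defaults["shape"] = tuple(defaults["shape"])
    optics = OpticalSystem(**defaults)

    _check_keys(arm_block, set(ARM_LABELS) | {"default"}, "optics.arms")
    arm_params: dict[str, dict[str, float]] = {}
    base = dict(_DEFAULT_ARM_PARAMS)
    base.update(arm_block.get("default", {}))
    for arm in ARM_LABELS:
        params = dict(base)
        params.update(arm_block.get(arm, {}))
        _check_keys(params, {"offset_frac", "width_frac"}, f"optics.arms.{arm}")
        arm_params[arm] = params

    phantom = _build_from_dataclass(PhantomSpec, raw.get("phantom", {}), "phantom")
    aa = _build_from_dataclass(AAParams, raw.get("aa", {}), "aa")

    noise_block = dict(raw.get("noise", {}))
    _check_keys(noise_block, {"kind", "photon_scale"}, "noise")
    noise_kind = noise_block.get("kind", "poisson")
    photon_scale = float(noise_block.get("photon_scale", 10_000.0))
    NoiseModel(kind=noise_kind, photon_scale=photon_scale)  # validate early

    recon_block = dict(raw.get("reconstruction", {}))
    _check_keys(recon_block, {"alpha"}, "reconstruction")
    alpha = float(recon_block.get("alpha", 1e-3 if noise_kind == "poisson" else 1e-4))
    if alpha <= 0:
        raise ValueError("reconstruction.alpha must be > 0")

    metrics_block = dict(raw.get("metrics", {}))
    _check_keys(metrics_block, {"n_fields"}, "metrics")
    n_fields = int(metrics_block.get("n_fields", 50))
    if n_fields < 2:
        raise ValueError("metrics.n_fields must be >= 2")

    final_seed = int(raw.get("seed", 0) if seed is None else seed)
    final_out = Path(out_dir if out_dir is not None else raw.get("out_dir", "qobm_run"))
    return RunConfig(
        optics=optics,
        arm_params=arm_params,
        phantom=phantom,
        aa=aa,
        noise_kind=noise_kind,
        photon_scale=photon_scale,
        alpha=alpha,
        n_fields=n_fields,
        seed=final_seed,
        out_dir=final_out,
    )
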