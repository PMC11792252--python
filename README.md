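# qobm

Simulation and reconstruction toolkit for **quantitative oblique
back-illumination microscopy (qOBM)** — an epi-mode quantitative phase
imaging (QPI) technique for thick tissue — with a synthetic-tissue study
of **acetic-acid (acetowhitening) nuclear contrast enhancement**.

## Who this is for

Researchers in computational phase microscopy who want a desk-scale,
fully seeded model of the qOBM measurement chain: to prototype
differential phase contrast (DPC) reconstruction settings, to study how
staining-induced refractive-index changes propagate into phase
statistics, or to generate paired fresh/stained synthetic data that real
tissue cannot provide (staining deforms tissue, so real pairs never
pixel-match).

## The model

Four oblique illumination arms (two opposing pairs) image a weakly
scattering object `t = exp(-mu + i*phi)`. Each arm's image obeys the
weak-object transfer model of a partially coherent imager,

    I_hat(u) = B d(u) + H_abs(u) mu_hat(u) + H_ph(u) phi_hat(u),

with `B = sum S|P|^2` and, writing `Gamma(u) = sum S(u') P*(u') P(u'+u)`
over the discrete frequency lattice,

    H_abs(u) = -(Gamma(u) + Gamma*(-u)),
    H_ph(u)  =  i(Gamma(u) - Gamma*(-u)).

`P` is the NA-limited pupil and `S` a per-arm offset-Gaussian effective
source. Reconstruction follows the standard qOBM/DPC chain: opposing
images are subtracted and normalized by their sum,
`D = (I_a - I_b)/(I_a + I_b)`, and the two orthogonal DPC images are
jointly deconvolved by Tikhonov-regularized least squares,

    phi_hat = (Hx* Dx_hat + Hy* Dy_hat) / (|Hx|^2 + |Hy|^2 + alpha).

`H_ph(0) = 0` identically, so the reconstruction is insensitive to very
low spatial frequencies — a property the tests pin down exactly.

The phantom module generates seeded tissue fields (weak-contrast nuclei,
cytoplasmic texture, lipid-droplet-like inclusions) and a parametric
acetowhitening transform: nuclear phase gain plus background
homogenization, emulating the observed effect of acetic acid on phase
images — brighter nuclei, smoother surroundings, lower overall phase
variance. The metrics module quantifies it via per-image phase standard
deviations, nuclear contrast-to-noise ratio (CNR), and Welch two-sample
t-tests across image groups. See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

```python
import numpy as np
from qobm import (AAParams, NoiseModel, apply_aa_transform, generate_phantom,
                  load_config, nuclear_cnr, phase_std, reconstruct_field,
                  simulate_intensities)
from qobm.pipeline import build_transfer_functions

cfg = load_config({
    "optics": {"shape": [128, 128], "pixel_um": 0.5},
    "phantom": {"n_nuclei": 8, "nucleus_radius_um": [2.5, 4.5],
                "n_inclusions": 2, "inclusion_radius_um": [0.8, 1.4]},
}, seed=1)
_, _, tfs = build_transfer_functions(cfg)

ph = generate_phantom(cfg.optics, cfg.phantom, seed=1)   # fresh tissue field
aa = apply_aa_transform(ph, AAParams())                  # acetowhitened copy
for state, p in (("fresh", ph), ("aa", aa)):
    frames = simulate_intensities(p, tfs, NoiseModel("poisson", 10_000, seed=1))
    rec = reconstruct_field(frames, tfs, alpha=1e-3)
    print(f"{state:5s}  phase SD = {phase_std(rec):.4f} rad"
          f"   nuclear CNR = {nuclear_cnr(rec, p.labels):.2f}")
```

prints

```
fresh  phase SD = 0.0990 rad   nuclear CNR = 0.97
aa     phase SD = 0.0575 rad   nuclear CNR = 5.26
```

The stained field's reconstructed phase is *less* variable overall (the
non-nuclear texture is homogenized) while its nuclei stand out five times
more strongly against the background — the acetowhitening signature.

## Command line

```sh
qobm pipeline --config config.yaml --seed 7 --out run/   # full experiment
qobm stain --out sim/                                    # fresh/AA phantom pair
qobm reconstruct --frames sim/frames_aa.tif --out phase.tif --alpha 1e-3
qobm metrics --group fresh=phase_fresh/ --group aa=phase_aa/ --out summary.csv
```

`pipeline` writes phantom/frame/phase TIFFs, CSV tables of per-image
phase SDs, nuclear CNRs and pairwise Welch tests, a distribution figure,
and a manifest with SHA-256 checksums; the same config and seed reproduce
every numeric output byte for byte.

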