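"""Independent reference implementations used only to check the package.

These deliberately use the slowest, most literal formulation available
(double loops over the frequency lattice) so that they share no code path
with the vectorized implementations they validate.
"""

from __future__ import annotations

import numpy as np


def wotf_direct(pupil: np.ndarray, weights: np.ndarray):
    """Direct double-loop evaluation of the weak-object transfer sums.

    Returns (B, H_abs, H_ph) on the fft-ordered lattice, computed from

        Gamma(u) = sum_u' S(u') conj(P(u')) P(u' + u)

    with P zero outside the lattice, H_abs = -(Gamma(u) + conj(Gamma(-u)))
    and H_ph = i (Gamma(u) - conj(Gamma(-u))).
    """
    n0, n1 = pupil.shape
    p_c = np.fft.fftshift(pupil)
    s_c = np.fft.fftshift(weights)
    gamma_c = np.zeros((n0, n1), dtype=complex)
    for i in range(n0):
        for j in range(n1):
            di, dj = i - n0 // 2, j - n1 // 2
            acc = 0.0 + 0.0j
            for ii in range(n0):
                for jj in range(n1):
                    ki, kj = ii + di, jj + dj
                    if 0 <= ki < n0 and 0 <= kj < n1:
                        acc += s_c[ii, jj] * np.conj(p_c[ii, jj]) * p_c[ki, kj]
            gamma_c[i, j] = acc
    gamma = np.fft.ifftshift(gamma_c)
    gamma_neg = np.roll(gamma[::-1, ::-1], (1, 1), axis=(0, 1))
    h_abs = -(gamma + np.conj(gamma_neg))
    h_ph = 1j * (gamma - np.conj(gamma_neg))
    b = float(np.real(np.sum(weights * np.abs(pupil) ** 2)))
    return b, h_abs, h_ph


def bandlimited_phase(shape, f_cutoff, radius_map, seed, peak,
                      band=(0.1, 0.7)) -> np.ndarray:
    """Seeded random phase map with spectral support restricted to an
    annulus ``band`` (in fractions of the pupil cutoff), scaled to ``peak``
    max absolute value."""
    rng = np.random.default_rng(seed)
    spec = np.fft.fft2(rng.standard_normal(shape))
    annulus = (radius_map >= band[0] * f_cutoff) & (radius_map <= band[1] * f_cutoff)
    phi = np.fft.ifft2(spec * annulus).real
    return phi * (peak / np.abs(phi).max())
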