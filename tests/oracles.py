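"""Independent brute-force oracles used to validate the fast implementations."""

import numpy as np


def morlet_cwt_direct(x: np.ndarray, rate: float, freqs: np.ndarray,
                      omega0: float = 6.0) -> np.ndarray:
    """Morlet CWT by direct time-domain convolution with the sampled wavelet.

    W(s, n) = sqrt(dt/s) * sum_m x[m] * conj(psi0((m - n) dt / s)) with
    psi0(t) = pi**(-1/4) exp(i omega0 t) exp(-t**2 / 2).  O(N^2) per scale;
    usable only for short records, which is the point: it shares nothing
    with the FFT implementation it checks.
    """
    x = np.asarray(x, dtype=float)
    dt = 1.0 / rate
    n = x.size
    ff = 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))
    scales = 1.0 / (ff * np.asarray(freqs, float))
    m_idx = np.arange(n)
    out = np.empty((scales.size, n), dtype=complex)
    for i, s in enumerate(scales):
        for t_idx in range(n):
            u = (m_idx - t_idx) * dt / s
            psi = np.pi**-0.25 * np.exp(1j * omega0 * u) * np.exp(-0.5 * u**2)
            out[i, t_idx] = np.sqrt(dt / s) * np.sum(x * np.conj(psi))
    return out


def grand_sum_loop(coeffs: np.ndarray) -> complex:
    """Element-by-element loop over a complex matrix (Eq.-style double sum)."""
    total = 0.0 + 0.0j
    for m in range(coeffs.shape[0]):
        for n in range(coeffs.shape[1]):
            total += coeffs[m, n]
    return total


def average_loop(matrices) -> np.ndarray:
    """Element-by-element average of equally shaped complex matrices."""
    mats = list(matrices)
    out = np.zeros_like(mats[0], dtype=complex)
    for m in range(out.shape[0]):
        for n in range(out.shape[1]):
            acc = 0.0 + 0.0j
            for mat in mats:
                acc += mat[m, n]
            out[m, n] = acc / len(mats)
    return out


def blank_union_indices(stim_times, pre_s, post_s, rate, n_samples):
    """Set of sample indices inside the union of blanking windows."""
    idx = set()
    for t in stim_times:
        a = int(np.floor((t - pre_s) * rate))
        b = int(np.ceil((t + post_s) * rate))
        idx.update(range(max(a, 0), min(b, n_samples)))
    return idx
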