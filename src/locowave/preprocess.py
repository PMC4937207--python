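"""Raw neurogram -> rectified, low-passed, resampled burst envelope.

The chain is: 50 Hz high-pass, digital stimulus-artifact removal, half-wave
rectification, 5 Hz low-pass, resampling to 50 Hz.  All IIR filtering is
4th-order Butterworth applied forward-backward (zero phase), because burst
phase is the quantity the downstream cross-wavelet analysis measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .io import ChannelRole, Neurogram

__all__ = ["Envelope", "highpass", "blank_artifacts", "rectify", "envelope",
           "preprocess_pipeline"]

_FILTER_ORDER = 4  # per pass; filtfilt doubles the effective order


@dataclass
class Envelope:
    """Nonnegative burst envelopes at the analysis rate (nominally 50 Hz)."""

    samples: np.ndarray
    rate: float
    roles: tuple[ChannelRole, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.roles = tuple(self.roles)
        if np.any(self.samples < 0):
            raise ValueError("envelope samples must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    @property
    def canonical_roles(self) -> tuple[str, ...]:
        return tuple(r.canonical for r in self.roles)

    def channel(self, role: str) -> np.ndarray:
        return self.samples[self.canonical_roles.index(role)]


def _sos(kind: str, cutoff: float, rate: float) -> np.ndarray:
    return signal.butter(_FILTER_ORDER, cutoff, btype=kind, fs=rate, output="sos")


def highpass(n: Neurogram, cutoff: float = 50.0) -> Neurogram:
    """Zero-phase high-pass; removes DC and slow potentials below ``cutoff``."""
    if cutoff >= n.rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {n.rate / 2} Hz")
    out = signal.sosfiltfilt(_sos("highpass", cutoff, n.rate), n.samples, axis=1)
    meta = dict(n.meta, highpass_hz=cutoff)
    return n.replace(samples=out, meta=meta)


def blank_artifacts(n: Neurogram, window: tuple[float, float] = (2.0, 8.0)) -> Neurogram:
    """Remove stimulus artifacts by linear interpolation around each pulse.

    ``window`` is (pre_ms, post_ms) around every stimulus time.  Overlapping
    windows are merged; windows extending past the record edge are clipped
    (edge samples are held at the boundary value).
    """
    if n.stim_times.size == 0:
        return n
    pre, post = window[0] / 1000.0, window[1] / 1000.0
    starts = np.floor((n.stim_times - pre) * n.rate).astype(int)
    stops = np.ceil((n.stim_times + post) * n.rate).astype(int)  # exclusive
    spans: list[list[int]] = []
    for a, b in zip(starts, stops):
        a, b = max(a, 0), min(b, n.n_samples)
        if b <= a:
            continue
        if spans and a <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], b)
        else:
            spans.append([a, b])
    out = n.samples.copy()
    for a, b in spans:
        has_left, has_right = a > 0, b < n.n_samples
        if not has_left and not has_right:  # span covers the whole record
            out[:, a:b] = 0.0
            continue
        left = out[:, a - 1] if has_left else out[:, b]
        right = out[:, b] if has_right else out[:, a - 1]
        # interpolate between the boundary samples at indices a-1 and b
        frac = (np.arange(a, b) - (a - 1)) / (b - (a - 1))
        out[:, a:b] = left[:, None] + (right - left)[:, None] * frac[None, :]
    meta = dict(n.meta, blank_window_ms=tuple(window))
    return n.replace(samples=out, meta=meta)


def rectify(n: Neurogram, mode: str = "half") -> Neurogram:
    """Half-wave (negative samples -> 0) or full-wave (absolute value)."""
    if mode == "half":
        out = np.maximum(n.samples, 0.0)
    elif mode == "full":
        out = np.abs(n.samples)
    else:
        raise ValueError(f"mode must be 'half' or 'full', got {mode!r}")
    return n.replace(samples=out, meta=dict(n.meta, rectify=mode))


def envelope(n: Neurogram, lp_cutoff: float = 5.0, out_rate: float = 50.0) -> Envelope:
    """Low-pass the rectified neurogram and resample to the analysis rate.

    The 5 Hz low-pass recovers the envelope of multi-unit spiking and doubles
    as the anti-alias filter for the decimation to ``out_rate``; polyphase
    resampling handles non-integer rate ratios.  Residual filter undershoot
    below zero is clipped.
    """
    if out_rate <= 2 * lp_cutoff:
        raise ValueError(f"out_rate {out_rate} must exceed 2 x lp_cutoff {lp_cutoff}")
    low = signal.sosfiltfilt(_sos("lowpass", lp_cutoff, n.rate), n.samples, axis=1)
    ratio = Fraction(out_rate / n.rate).limit_denominator(10000)
    if ratio != 1:
        low = signal.resample_poly(low, ratio.numerator, ratio.denominator, axis=1)
    prov = dict(n.meta, lp_cutoff_hz=lp_cutoff, out_rate_hz=out_rate)
    return Envelope(samples=np.maximum(low, 0.0), rate=out_rate, roles=n.roles,
                    provenance=prov)


def preprocess_pipeline(
    n: Neurogram,
    hp_cutoff: float = 50.0,
    blank_window: tuple[float, float] | None = (2.0, 8.0),
    rectify_mode: str = "half",
    lp_cutoff: float = 5.0,
    out_rate: float = 50.0,
) -> Envelope:
    """Full chain: high-pass -> artifact blanking -> rectify -> envelope.

    Accepts a raw :class:`Neurogram` only; an :class:`Envelope` is a distinct
    terminal type, so a second application is rejected rather than silently
    re-filtering already-integrated data.
    """
    if isinstance(n, Envelope):
        raise TypeError("input is already a preprocessed Envelope")
    if not isinstance(n, Neurogram):
        raise TypeError(f"expected Neurogram, got {type(n).__name__}")
    x = highpass(n, hp_cutoff)
    if blank_window is not None and n.stim_times.size:
        x = blank_artifacts(x, blank_window)
    x = rectify(x, rectify_mode)
    return envelope(x, lp_cutoff=lp_cutoff, out_rate=out_rate)
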