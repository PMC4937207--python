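"""Data model and file I/O for multi-channel ventral-root neurograms.

A *neurogram* is an extracellular multi-unit recording from a spinal ventral
root.  Episodes of fictive locomotion are analysed from four canonical roots:
the flexor-dominated left/right L1-L2 roots and the extensor-dominated
left/right L5 roots, written fL, fR, eL, eR.  This module defines the
in-memory containers shared by the whole pipeline and their exchange formats:
comma-separated text for raw neurograms and result tables, and a flat HDF5
container for complex cross-wavelet spectrograms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np

__all__ = [
    "ChannelRole",
    "Neurogram",
    "CrossSpectrum",
    "StrengthResult",
    "RoleError",
    "FormatError",
    "CANONICAL_ROLES",
    "read_neurogram",
    "write_neurogram",
    "read_spectrum",
    "write_spectrum",
]

#: The four canonical root identities used throughout the analysis.
CANONICAL_ROLES = ("fL", "fR", "eL", "eR")

_SIDES = {"left": "L", "right": "R"}
_FUNCTIONS = {"flexor": "f", "extensor": "e"}


class RoleError(ValueError):
    """Raised when channel-role assignment is missing, duplicated or invalid."""


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected layout."""


@dataclass(frozen=True)
class ChannelRole:
    """Identity of one recorded root: side, motor function and segment.

    The (side, function) pair maps bijectively onto the four canonical role
    symbols fL, fR, eL, eR; ``segment_label`` is free text such as "L1" or
    "L5" and does not participate in the mapping.
    """

    side: str
    function: str
    segment_label: str = ""

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise RoleError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.function not in _FUNCTIONS:
            raise RoleError(
                f"function must be 'flexor' or 'extensor', got {self.function!r}"
            )

    @property
    def canonical(self) -> str:
        """Canonical symbol in {fL, fR, eL, eR}."""
        return _FUNCTIONS[self.function] + _SIDES[self.side]

    @classmethod
    def from_canonical(cls, symbol: str, segment_label: str = "") -> "ChannelRole":
        symbol = symbol.strip()
        if len(symbol) != 2 or symbol not in CANONICAL_ROLES:
            raise RoleError(f"unknown canonical role {symbol!r}")
        function = {"f": "flexor", "e": "extensor"}[symbol[0]]
        side = {"L": "left", "R": "right"}[symbol[1]]
        if not segment_label:
            segment_label = {"flexor": "L1", "extensor": "L5"}[function]
        return cls(side=side, function=function, segment_label=segment_label)

    def mirrored(self) -> "ChannelRole":
        """Same role with left/right swapped."""
        side = "right" if self.side == "left" else "left"
        return ChannelRole(side=side, function=self.function,
                           segment_label=self.segment_label)


@dataclass
class Neurogram:
    """Multi-channel root recording with stimulus timestamps.

    Parameters
    ----------
    samples
        Real matrix, shape (channels, time), arbitrary voltage units.
    rate
        Sampling rate in Hz.
    roles
        One :class:`ChannelRole` per channel; canonical roles must be unique.
    stim_times
        Stimulus-pulse timestamps in seconds from record start, strictly
        increasing and within the record.
    meta
        Free-form provenance (filter settings, simulation parameters, ...).
    """

    samples: np.ndarray
    rate: float
    roles: tuple[ChannelRole, ...]
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        self.roles = tuple(self.roles)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if len(self.roles) != self.samples.shape[0]:
            raise RoleError(
                f"{self.samples.shape[0]} channels but {len(self.roles)} roles"
            )
        canon = [r.canonical for r in self.roles]
        dupes = {c for c in canon if canon.count(c) > 1}
        if dupes:
            raise RoleError(f"duplicate canonical roles: {sorted(dupes)}")
        if self.stim_times.size:
            if np.any(np.diff(self.stim_times) <= 0):
                raise ValueError("stim_times must be strictly increasing")
            if self.stim_times[0] < 0 or self.stim_times[-1] > self.duration:
                raise ValueError("stim_times must lie within [0, duration]")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def canonical_roles(self) -> tuple[str, ...]:
        return tuple(r.canonical for r in self.roles)

    def channel(self, role: str) -> np.ndarray:
        """1-D sample vector for a canonical role symbol."""
        try:
            idx = self.canonical_roles.index(role)
        except ValueError:
            raise RoleError(f"no channel with role {role!r}") from None
        return self.samples[idx]

    def replace(self, **kw) -> "Neurogram":
        return dataclasses.replace(self, **kw)


@dataclass
class CrossSpectrum:
    """Complex coefficient matrix over frequency x time.

    Holds either a single-signal wavelet transform or a cross-wavelet
    transform Wxy = Wx conj(Wy); the modulus of a coefficient is the (cross-)
    wavelet power, its argument the phase (difference) at that location.

    ``coi_freq`` gives, per time step, the lowest frequency unaffected by
    edge effects; a bin (i, j) is outside the cone of influence iff
    ``freqs[i] >= coi_freq[j]``.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    normalized: bool = False
    sig_mask: np.ndarray | None = None
    phase_filtered: bool = False
    coi_freq: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coeffs.shape != (self.freqs.size, self.times.size):
            raise ValueError(
                f"coeffs shape {self.coeffs.shape} does not match "
                f"(freqs, times) = ({self.freqs.size}, {self.times.size})"
            )
        d = np.diff(self.freqs)
        if self.freqs.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("freqs must be strictly monotone")
        if self.sig_mask is not None:
            self.sig_mask = np.asarray(self.sig_mask, dtype=bool)
            if self.sig_mask.shape != self.coeffs.shape:
                raise ValueError("sig_mask shape must match coeffs")

    @property
    def power(self) -> np.ndarray:
        """Cross-wavelet power: the modulus (vector length) per coefficient."""
        return np.abs(self.coeffs)

    @property
    def phase_deg(self) -> np.ndarray:
        """Coefficient arguments in degrees on [0, 360)."""
        return np.mod(np.degrees(np.angle(self.coeffs)), 360.0)

    def outside_coi(self) -> np.ndarray:
        """Boolean matrix, True where a bin lies outside the cone of influence."""
        if self.coi_freq is None:
            return np.ones(self.coeffs.shape, dtype=bool)
        return self.freqs[:, None] >= self.coi_freq[None, :]

    def replace(self, **kw) -> "CrossSpectrum":
        return dataclasses.replace(self, **kw)


@dataclass
class StrengthResult:
    """Locomotor strength S with the averaged spectrum it came from."""

    S: float
    wavg: CrossSpectrum
    pair_ids: tuple[str, ...]
    normalized_S: float | None = None

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError("S must be nonnegative")


# ---------------------------------------------------------------------------
# Delimited-text neurogram exchange
#
# Layout: optional '#'-prefixed comment lines, of which '# rate_hz=<float>'
# declares the sampling rate and '# stim_times_s=<t1,t2,...>' the stimulus
# train; one header row naming the channels by canonical role (or arbitrary
# names resolved through an explicit role mapping); an optional leading
# 'time' column checked for uniform sampling.
# ---------------------------------------------------------------------------

def write_neurogram(path: str | Path, n: Neurogram) -> None:
    """Write a neurogram as commented CSV (6 significant digits)."""
    path = Path(path)
    header = ",".join(n.canonical_roles)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={float(n.rate)!r}\n")
        if n.stim_times.size:
            fh.write("# stim_times_s="
                     + ",".join(repr(float(t)) for t in n.stim_times) + "\n")
        fh.write(header + "\n")
        np.savetxt(fh, n.samples.T, fmt="%.6g", delimiter=",")


def read_neurogram(
    path: str | Path,
    rate: float | None = None,
    role_map: Mapping[str, str] | None = None,
    stim_times: Sequence[float] | None = None,
) -> Neurogram:
    """Read a delimited-text neurogram.

    Parameters
    ----------
    rate
        Sampling rate; overrides any ``# rate_hz=`` comment.  Required when
        the file declares neither a rate nor a time column.
    role_map
        Optional mapping from header token to canonical role symbol, for
        files whose columns are not named fL/fR/eL/eR directly.
    stim_times
        Stimulus times in seconds; overrides any ``# stim_times_s=`` comment.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    file_rate: float | None = None
    file_stims: list[float] = []
    header: list[str] | None = None
    data_rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("rate_hz="):
                    file_rate = float(body.split("=", 1)[1])
                elif body.startswith("stim_times_s="):
                    val = body.split("=", 1)[1].strip()
                    if val:
                        file_stims = [float(t) for t in val.split(",")]
                continue
            if header is None:
                header = [tok.strip() for tok in line.split(",")]
            else:
                data_rows.append(line)
    if header is None or not data_rows:
        raise FormatError(f"{path}: no header or no data rows")
    data = np.array([[float(v) for v in row.split(",")] for row in data_rows])
    if data.shape[1] != len(header):
        raise FormatError(f"{path}: ragged rows")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise RoleError(f"{path}: duplicate column names {dupes}")

    cols = {name: data[:, i] for i, name in enumerate(header)}
    time_col = None
    for tok in ("time", "time_s", "t"):
        if tok in cols:
            time_col = cols.pop(tok)
            break
    if time_col is not None:
        dt = np.diff(time_col)
        if dt.size == 0 or dt[0] <= 0:
            raise FormatError(f"{path}: degenerate time column")
        if np.max(np.abs(dt - dt[0])) > 1e-4 * dt[0]:
            raise FormatError(f"{path}: non-uniform sampling in time column")
        inferred = 1.0 / dt[0]
        if rate is None and file_rate is None:
            file_rate = inferred
    eff_rate = rate if rate is not None else file_rate
    if eff_rate is None:
        raise FormatError(f"{path}: no rate_hz comment, time column or rate argument")

    roles, samples = [], []
    for name, col in cols.items():
        symbol = role_map.get(name, name) if role_map else name
        roles.append(ChannelRole.from_canonical(symbol))
        samples.append(col)
    stims = np.asarray(stim_times if stim_times is not None else file_stims, float)
    return Neurogram(
        samples=np.array(samples), rate=float(eff_rate), roles=tuple(roles),
        stim_times=stims, meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# HDF5 spectrum container: /coeffs_re, /coeffs_im, /freqs, /times, /flags
# plus optional /sig_mask and /coi_freq.  Lossless round-trip.
# ---------------------------------------------------------------------------

def write_spectrum(spec: CrossSpectrum, path: str | Path) -> None:
    # __post_init__ already enforces monotone freqs / shape agreement; revalidate
    # in case the arrays were mutated in place after construction.
    CrossSpectrum(spec.coeffs, spec.freqs, spec.times, spec.normalized,
                  spec.sig_mask, spec.phase_filtered, spec.coi_freq)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("coeffs_re", data=spec.coeffs.real)
        h5.create_dataset("coeffs_im", data=spec.coeffs.imag)
        h5.create_dataset("freqs", data=spec.freqs)
        h5.create_dataset("times", data=spec.times)
        h5.create_dataset(
            "flags", data=np.array([spec.normalized, spec.phase_filtered], dtype=np.int8)
        )
        if spec.sig_mask is not None:
            h5.create_dataset("sig_mask", data=spec.sig_mask.astype(np.int8))
        if spec.coi_freq is not None:
            h5.create_dataset("coi_freq", data=spec.coi_freq)


def read_spectrum(path: str | Path) -> CrossSpectrum:
    with h5py.File(path, "r") as h5:
        coeffs = h5["coeffs_re"][()] + 1j * h5["coeffs_im"][()]
        flags = h5["flags"][()]
        sig_mask = h5["sig_mask"][()].astype(bool) if "sig_mask" in h5 else None
        coi_freq = h5["coi_freq"][()] if "coi_freq" in h5 else None
        return CrossSpectrum(
            coeffs=coeffs, freqs=h5["freqs"][()], times=h5["times"][()],
            normalized=bool(flags[0]), sig_mask=sig_mask,
            phase_filtered=bool(flags[1]), coi_freq=coi_freq,
        )
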