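"""Seeded generator of four-channel fictive-locomotion neurograms.

The generator is phenomenological: each channel is a high-frequency
"multi-unit" noise carrier gated by a periodic burst envelope at the
locomotor frequency (0.2-2 Hz range; episodes observed in the neonatal
mouse cord run at roughly 0.46-1.4 Hz), with per-cycle phase jitter,
additive Gaussian background noise and optional stimulus-locked biphasic
artifact transients.  The default phase map makes the four canonical root
pairs {fL,eL}, {fL,fR}, {fR,eR}, {eL,eR} alternate (180 deg apart), the
ground truth every pipeline stage is tested against.

A single global seed expands into fixed per-channel substreams keyed by
canonical role, so adding or dropping a channel never perturbs the samples
of the others.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .io import CANONICAL_ROLES, ChannelRole, Neurogram, write_neurogram

__all__ = ["SimulationConfig", "simulate", "simulate_white_pair",
           "fixture_configs", "make_fixture_suite"]

_DEFAULT_PHASE_MAP = {"fL": 0.0, "eL": 180.0, "fR": 180.0, "eR": 0.0}


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters; the seed fully determines the output.

    ``locomotor_freq`` is a frequency in Hz or a piecewise-constant schedule
    ``((t0, f0), (t1, f1), ...)`` with breakpoint times in seconds, emulating
    mid-episode frequency switches.  ``phase_map`` gives each channel's burst
    phase offset in degrees; the default encodes left/right and
    flexor/extensor alternation.  ``phase_jitter_sd`` jitters each burst's
    timing (degrees of cycle, per channel per cycle).  ``burst_amplitude``
    is a scalar or per-channel mapping, in units of the background noise SD.
    Stimulus artifacts are biphasic transients of ``stim_duration_ms`` at
    ``stim_freq`` inside ``stim_window`` (defaults to the episode window).
    """

    rate: float = 5000.0
    duration: float = 20.0
    locomotor_freq: float | tuple = 0.77
    phase_map: dict = field(default_factory=lambda: dict(_DEFAULT_PHASE_MAP))
    phase_jitter_sd: float = 5.0
    burst_duty: float = 0.5
    burst_amplitude: float | dict = 5.0
    carrier_band: tuple[float, float] = (100.0, 1000.0)
    noise_sd: float = 1.0
    stim_freq: float = 4.0
    stim_amplitude: float = 50.0
    stim_duration_ms: float = 0.25
    episode_window: tuple[float, float] | None = None
    stim_window: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.burst_duty < 1:
            raise ValueError("burst_duty must be in (0, 1)")
        bad = set(self.phase_map) - set(CANONICAL_ROLES)
        if bad:
            raise ValueError(f"phase_map has unknown channels: {sorted(bad)}")
        if not self.phase_map:
            raise ValueError("phase_map must name at least one channel")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(r for r in CANONICAL_ROLES if r in self.phase_map)

    def amplitude(self, role: str) -> float:
        if isinstance(self.burst_amplitude, dict):
            return float(self.burst_amplitude.get(role, 0.0))
        return float(self.burst_amplitude)

    def freq_at(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous locomotor frequency at times ``t``."""
        if np.isscalar(self.locomotor_freq):
            return np.full_like(t, float(self.locomotor_freq))
        f = np.zeros_like(t)
        for t0, f0 in self.locomotor_freq:
            f[t >= t0] = f0
        return f

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if not np.isscalar(d["locomotor_freq"]):
            d["locomotor_freq"] = [list(seg) for seg in d["locomotor_freq"]]
        return d


def _rng(seed: int, stream: str, role: str = "") -> np.random.Generator:
    """Substream keyed by (seed, stream name, canonical role), order-free."""
    stream_id = {"carrier": 1, "noise": 2, "jitter": 3, "white": 4}[stream]
    role_id = CANONICAL_ROLES.index(role) if role else 99
    return np.random.default_rng(np.random.SeedSequence((seed, stream_id, role_id)))


def _burst_envelope(cfg: SimulationConfig, role: str, t: np.ndarray) -> np.ndarray:
    """Raised-cosine burst gate with per-cycle timing jitter, in [0, 1]."""
    dt = t[1] - t[0] if t.size > 1 else 1.0 / cfg.rate
    cycles = np.cumsum(cfg.freq_at(t)) * dt  # phase in cycle units
    u = cycles + cfg.phase_map[role] / 360.0
    if cfg.phase_jitter_sd > 0:
        k = np.floor(u).astype(int)
        jit = _rng(cfg.seed, "jitter", role).normal(
            0.0, cfg.phase_jitter_sd / 360.0, int(k.max()) + 2)
        u = u - jit[k]
    w = u - np.floor(u)
    d = np.abs(w - 0.5)
    gate = np.where(d <= cfg.burst_duty / 2,
                    0.5 * (1.0 + np.cos(2.0 * np.pi * d / cfg.burst_duty)), 0.0)
    if cfg.episode_window is not None:
        start, stop = cfg.episode_window
        gate = np.where((t >= start) & (t <= stop), gate, 0.0)
    return gate


def _carrier(cfg: SimulationConfig, role: str, n: int) -> np.ndarray:
    """Unit-SD Gaussian noise band-passed to the spiking carrier band."""
    x = _rng(cfg.seed, "carrier", role).standard_normal(n)
    lo, hi = cfg.carrier_band
    hi = min(hi, 0.45 * cfg.rate)
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=cfg.rate, output="sos")
    x = signal.sosfilt(sos, x)
    return x / x.std()


def _stim_train(cfg: SimulationConfig, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Biphasic artifact waveform (added to every channel) and pulse times."""
    wave = np.zeros_like(t)
    if cfg.stim_freq <= 0:
        return wave, np.empty(0)
    window = cfg.stim_window or cfg.episode_window or (0.0, cfg.duration)
    times = np.arange(window[0], min(window[1], cfg.duration - 1e-9), 1.0 / cfg.stim_freq)
    n_half = max(1, int(round(cfg.stim_duration_ms / 1000.0 * cfg.rate / 2)))
    for st in times:
        i = int(round(st * cfg.rate))
        wave[i:i + n_half] = cfg.stim_amplitude
        wave[i + n_half:i + 2 * n_half] = -cfg.stim_amplitude
    return wave, times


def simulate(cfg: SimulationConfig) -> Neurogram:
    """Generate a multi-channel neurogram from ``cfg`` (seed-deterministic)."""
    f_max = np.max(cfg.freq_at(np.array([0.0, cfg.duration])))
    if not np.isscalar(cfg.locomotor_freq):
        f_max = max(f0 for _, f0 in cfg.locomotor_freq)
    if f_max >= 5.0:
        warnings.warn(
            f"locomotor frequency {f_max} Hz is at or above the default "
            "analysis band maximum (5 Hz)", stacklevel=2)
    n = int(round(cfg.duration * cfg.rate))
    t = np.arange(n) / cfg.rate
    stim_wave, stim_times = _stim_train(cfg, t)
    rows = []
    for role in cfg.channels:
        env = _burst_envelope(cfg, role, t)
        sig = cfg.amplitude(role) * env * _carrier(cfg, role, n)
        noise = cfg.noise_sd * _rng(cfg.seed, "noise", role).standard_normal(n)
        rows.append(sig + noise + stim_wave)
    roles = tuple(ChannelRole.from_canonical(r) for r in cfg.channels)
    return Neurogram(samples=np.array(rows), rate=cfg.rate, roles=roles,
                     stim_times=stim_times,
                     meta={"simulation": cfg.to_json_dict()})


def simulate_white_pair(
    rate: float = 50.0, duration: float = 100.0, seed: int = 0, sd: float = 1.0
) -> Neurogram:
    """Two statistically independent Gaussian white-noise channels.

    Calibration input for the white-noise significance test; generated at the
    analysis rate so it can be fed to the wavelet stage directly.
    """
    n = int(round(duration * rate))
    rng = _rng(seed, "white")
    samples = sd * rng.standard_normal((2, n))
    roles = (ChannelRole.from_canonical("fL"), ChannelRole.from_canonical("fR"))
    return Neurogram(samples=samples, rate=rate, roles=roles,
                     meta={"white_pair": {"seed": seed, "sd": sd}})


# ---------------------------------------------------------------------------
# Canonical fixture suite
# ---------------------------------------------------------------------------

#: Programmed amplitudes (x noise SD) of the 5-level ladder.
AMPLITUDE_LADDER = (1.25, 2.5, 5.0, 10.0, 20.0)
#: Programmed per-cycle jitter SDs (degrees).
JITTER_LEVELS = (10.0, 30.0, 60.0, 90.0)


def fixture_configs(seed: int = 0) -> dict[str, SimulationConfig]:
    """Named simulation configs for the canonical test-fixture suite.

    Every config derives its own seed deterministically from ``seed``.  The
    suite covers: strong alternation at 0.77 Hz, an in-phase control, a
    jitter series, a 0.46 -> 1.4 Hz mid-episode frequency step, a 5-level
    amplitude ladder and a white-noise pair.
    """
    def sub(i: int) -> int:
        return (seed * 1000 + i) % (2**31 - 1)

    cfgs: dict[str, SimulationConfig] = {}
    cfgs["strong_alternation"] = SimulationConfig(duration=40.0, seed=sub(0))
    cfgs["in_phase"] = SimulationConfig(
        duration=40.0, phase_map={r: 0.0 for r in CANONICAL_ROLES}, seed=sub(1))
    # jitter series and amplitude ladder share one noise realization each
    # (paired design: only the programmed parameter varies along the series)
    for j in JITTER_LEVELS:
        cfgs[f"jitter_{int(j)}"] = SimulationConfig(
            duration=40.0, phase_jitter_sd=j, seed=sub(2))
    cfgs["freq_step"] = SimulationConfig(
        duration=60.0, locomotor_freq=((0.0, 0.46), (30.0, 1.4)),
        stim_window=(0.0, 60.0), seed=sub(6))
    for i, a in enumerate(AMPLITUDE_LADDER):
        cfgs[f"amp_{i + 1}"] = SimulationConfig(
            duration=40.0, burst_amplitude=a, seed=sub(7))
    cfgs["noise_only"] = SimulationConfig(
        duration=40.0, burst_amplitude=0.0, stim_freq=0.0, seed=sub(12))
    return cfgs


def _ground_truth(name: str, cfg: SimulationConfig) -> dict:
    gt: dict = {"locomotor_freq_hz": cfg.to_json_dict()["locomotor_freq"],
                "phase_jitter_sd_deg": cfg.phase_jitter_sd,
                "burst_amplitude": cfg.burst_amplitude,
                "alternating": cfg.phase_map != {r: 0.0 for r in cfg.channels}}
    gt["expected_pair_phase_deg"] = 180.0 if gt["alternating"] else 0.0
    return gt


def make_fixture_suite(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the canonical fixture suite as CSV + JSON ground-truth sidecars.

    Regenerating with the same seed reproduces byte-identical files.
    Returns a mapping fixture name -> CSV path; a ``manifest.json`` listing
    all fixtures is written alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, cfg in fixture_configs(seed).items():
        csv_path = outdir / f"{name}.csv"
        write_neurogram(csv_path, simulate(cfg))
        sidecar = {"fixture": name, "config": cfg.to_json_dict(),
                   "ground_truth": _ground_truth(name, cfg)}
        (outdir / f"{name}.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        paths[name] = csv_path
    # white-noise pair is generated at the analysis rate, not via simulate()
    wp = simulate_white_pair(seed=seed)
    write_neurogram(outdir / "white_pair.csv", wp)
    (outdir / "white_pair.json").write_text(json.dumps(
        {"fixture": "white_pair", "config": wp.meta["white_pair"],
         "ground_truth": {"independent_channels": True}}, indent=1, sort_keys=True))
    paths["white_pair"] = outdir / "white_pair.csv"
    (outdir / "manifest.json").write_text(
        json.dumps({"fixtures": sorted(paths)}, indent=1))
    return paths
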