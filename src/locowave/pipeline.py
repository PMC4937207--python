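"""End-to-end orchestration: neurogram -> envelopes -> cross-spectra -> S, P.

``analyze_episode`` runs the complete analysis chain on an in-memory
neurogram; ``run_pipeline`` drives it from a flat INI-style config file and
writes a reproducible result bundle (strength JSON, coupling CSV, spectrum
containers, parameter manifest).
"""

from __future__ import annotations

import configparser
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .coupling import pair_coupling
from .io import Neurogram, read_neurogram, write_spectrum
from .preprocess import Envelope, preprocess_pipeline
from .strength import LOCOMOTOR_PAIRS, average_pairs, strength
from .synthetic import SimulationConfig, simulate
from .wavelet import (WaveletParams, global_power_spectrum, phase_distribution,
                      phase_filter, significance_mask, xwt_pair)

__all__ = ["analyze_episode", "run_pipeline", "EpisodeResult"]

log = logging.getLogger("locowave")


def analyze_episode(
    n: Neurogram,
    params: WaveletParams | None = None,
    pairs: tuple[str, ...] = LOCOMOTOR_PAIRS,
    allow_partial: bool = False,
    apply_sqrt: bool = True,
    hp_cutoff: float = 50.0,
    blank_window: tuple[float, float] | None = (2.0, 8.0),
    rectify_mode: str = "half",
    lp_cutoff: float = 5.0,
    out_rate: float = 50.0,
) -> dict:
    """Full analysis of one episode.

    Returns a dict with the preprocessed envelope, the per-pair filtered
    spectra and coupling values P, the pair-averaged spectrum, the strength
    result, the global-power peak frequency and the power-weighted mean
    phase.  ``pairs`` may be restricted for partial recordings (requires
    ``allow_partial=True``).
    """
    if params is None:
        params = WaveletParams()
    if isinstance(n, Envelope):
        env = n
        log.info("input is already an envelope (%d ch @ %g Hz)",
                 env.samples.shape[0], env.rate)
    else:
        env = preprocess_pipeline(n, hp_cutoff=hp_cutoff, blank_window=blank_window,
                                  rectify_mode=rectify_mode, lp_cutoff=lp_cutoff,
                                  out_rate=out_rate)
        log.info("preprocessed %d ch: %d samples @ %g Hz -> %d @ %g Hz",
                 n.n_channels, n.n_samples, n.rate, env.n_samples, env.rate)
    missing = [p for p in pairs
               if p[:2] not in env.canonical_roles or p[2:] not in env.canonical_roles]
    if missing:
        raise ValueError(f"channels missing for pairs {missing}")
    spectra = {}
    coupling_P = {}
    for pair in pairs:
        s = xwt_pair(env, pair[:2], pair[2:], params)
        s = phase_filter(significance_mask(s, params), params)
        spectra[pair] = s
        coupling_P[pair] = pair_coupling(s)
    wavg = average_pairs(spectra, allow_partial=allow_partial or len(pairs) < 4)
    res = strength(wavg, apply_sqrt=apply_sqrt)
    freqs, gpow, peak_freq = global_power_spectrum(wavg)
    _, _, mean_phase, rlen = phase_distribution(wavg)
    log.info("strength S=%.4g, peak %.3g Hz, mean phase %.1f deg",
             res.S, peak_freq, mean_phase)
    return {
        "envelope": env, "spectra": spectra, "wavg": wavg, "strength": res,
        "S": res.S, "coupling_P": coupling_P, "peak_freq": peak_freq,
        "global_power": (freqs, gpow), "mean_phase_deg": mean_phase,
        "phase_resultant_length": rlen,
    }


# ---------------------------------------------------------------------------
# Config-file driven runs
# ---------------------------------------------------------------------------

def _load_config(path: str | Path) -> configparser.ConfigParser:
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise FileNotFoundError(path)
    return cp


def _input_from_config(cp: configparser.ConfigParser) -> Neurogram:
    sec = cp["input"]
    kind = sec.get("kind", "file")
    if kind == "file":
        role_map = None
        if "roles" in sec:  # e.g. roles = ch1:fL, ch2:fR
            role_map = dict(tok.strip().split(":") for tok in sec["roles"].split(","))
        return read_neurogram(sec["path"], rate=sec.getfloat("rate_hz", fallback=None),
                              role_map=role_map)
    if kind == "simulation":
        sim = dict(cp["simulation"]) if cp.has_section("simulation") else {}
        kwargs: dict = {}
        for key, val in sim.items():
            if key in ("rate", "duration", "locomotor_freq", "phase_jitter_sd",
                       "burst_duty", "burst_amplitude", "noise_sd", "stim_freq",
                       "stim_amplitude", "stim_duration_ms"):
                kwargs[key] = float(val)
            elif key == "seed":
                kwargs[key] = int(val)
        return simulate(SimulationConfig(**kwargs))
    raise ValueError(f"unknown input kind {kind!r}")


def run_pipeline(config_path: str | Path, outdir: str | Path,
                 seed: int | None = None) -> dict:
    """Run the full pipeline from a flat config file; write a result bundle.

    The bundle contains ``strength.json``, ``coupling.csv``, one spectrum
    container per pair plus the averaged spectrum, and ``manifest.json``
    echoing every parameter (and seed) for reproducibility.  Rerunning an
    identical config reproduces identical numbers.
    """
    cp = _load_config(config_path)
    if seed is not None:
        if not cp.has_section("simulation"):
            cp.add_section("simulation")
        cp["simulation"]["seed"] = str(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    wkw = {}
    if cp.has_section("wavelet"):
        sec = cp["wavelet"]
        for key in ("omega0", "fmin", "fmax", "sig_level", "phase_center",
                    "phase_halfwidth"):
            if key in sec:
                wkw[key] = sec.getfloat(key)
        if "voices_per_octave" in sec:
            wkw["voices_per_octave"] = sec.getint("voices_per_octave")
        if "coi_policy" in sec:
            wkw["coi_policy"] = sec["coi_policy"]
    params = WaveletParams(**wkw)

    pkw: dict = {}
    if cp.has_section("preprocess"):
        sec = cp["preprocess"]
        for key, conv in (("hp_cutoff", sec.getfloat), ("lp_cutoff", sec.getfloat),
                          ("out_rate", sec.getfloat), ("rectify_mode", sec.get)):
            if key in sec:
                pkw[key] = conv(key)
        if "blank_pre_ms" in sec or "blank_post_ms" in sec:
            pkw["blank_window"] = (sec.getfloat("blank_pre_ms", fallback=2.0),
                                   sec.getfloat("blank_post_ms", fallback=8.0))

    akw: dict = {}
    if cp.has_section("analysis"):
        sec = cp["analysis"]
        if "pairs" in sec:
            akw["pairs"] = tuple(t.strip() for t in sec["pairs"].split(","))
        akw["allow_partial"] = sec.getboolean("allow_partial", fallback=False)
        akw["apply_sqrt"] = sec.getboolean("apply_sqrt", fallback=True)

    n = _input_from_config(cp)
    result = analyze_episode(n, params, **pkw, **akw)

    strength_out = {
        "S": result["S"],
        "peak_freq_hz": result["peak_freq"],
        "mean_phase_deg": result["mean_phase_deg"],
        "phase_resultant_length": result["phase_resultant_length"],
        "coupling_P": result["coupling_P"],
    }
    (outdir / "strength.json").write_text(json.dumps(strength_out, indent=1,
                                                     sort_keys=True))
    with open(outdir / "coupling.csv", "w") as fh:
        fh.write("pair,P\n")
        for pair, p_val in result["coupling_P"].items():
            fh.write(f"{pair},{p_val!r}\n")
    for pair, s in result["spectra"].items():
        write_spectrum(s, outdir / f"xwt_{pair}.h5")
    write_spectrum(result["wavg"], outdir / "wavg.h5")

    manifest = {
        "locowave_version": __version__,
        "config_file": str(config_path),
        "wavelet": asdict(params),
        "preprocess": {"hp_cutoff": pkw.get("hp_cutoff", 50.0),
                       "blank_window_ms": list(pkw.get("blank_window", (2.0, 8.0))),
                       "rectify_mode": pkw.get("rectify_mode", "half"),
                       "lp_cutoff": pkw.get("lp_cutoff", 5.0),
                       "out_rate": pkw.get("out_rate", 50.0)},
        "analysis": {"pairs": list(akw.get("pairs", LOCOMOTOR_PAIRS)),
                     "allow_partial": akw.get("allow_partial", False),
                     "apply_sqrt": akw.get("apply_sqrt", True)},
        "input": dict(cp["input"]) if cp.has_section("input") else {},
        "simulation": dict(cp["simulation"]) if cp.has_section("simulation") else {},
    }
    tmp = outdir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    tmp.replace(outdir / "manifest.json")
    return result
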