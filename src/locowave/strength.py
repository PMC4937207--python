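"""Locomotor strength: pair-averaged cross-spectra and the scalar S.

Four root pairs are expected to alternate during locomotor-like activity:
{fL,eL}, {fL,fR}, {fR,eR}, {eL,eR}.  Their phase-filtered, significance-
masked, crossvariance-normalized cross-wavelet spectra are averaged
element-wise,

    Wavg = (W_fLeL + W_fLfR + W_fReR + W_eLeR) / 4,

and the strength of an episode is the square root of the length of the
resultant vector of the grand complex sum of Wavg:

    S = sqrt(| sum_m sum_n Wavg[m, n] |).

Because the coefficients are vector-summed, S rewards both high cross power
and tight phase coupling near 180 deg, and the phase-band filter makes it
blind to in-phase (synchronous, non-locomotor) rhythms.  Strengths from
different preparations or stimulus conditions are pooled after dividing by
the mean strength of a reference condition, and compared with the
Wilcoxon rank-sum (two conditions) or Kruskal-Wallis (three or more) test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import CrossSpectrum, StrengthResult

__all__ = ["ConditionSet", "average_pairs", "strength", "normalize_conditions",
           "compare_conditions", "LOCOMOTOR_PAIRS"]

#: The four canonical alternating root pairs, in (x, y) order.
LOCOMOTOR_PAIRS = ("fLeL", "fLfR", "fReR", "eLeR")


def _check_ready(s: CrossSpectrum, name: str) -> None:
    if not s.normalized:
        raise ValueError(f"{name}: spectrum must be crossvariance-normalized")
    if s.sig_mask is None:
        raise ValueError(f"{name}: spectrum must be significance-masked")
    if not s.phase_filtered:
        raise ValueError(f"{name}: spectrum must be phase-filtered")


def average_pairs(
    spectra: dict[str, CrossSpectrum], allow_partial: bool = False
) -> CrossSpectrum:
    """Element-wise complex mean of the four root-pair cross-spectra.

    ``spectra`` maps pair ids (e.g. "fLeL") to spectra that have already been
    normalized, significance-masked and phase-filtered.  Episodes with fewer
    than the four canonical pairs require ``allow_partial=True`` and are
    flagged in the result's metadata.
    """
    if not spectra:
        raise ValueError("no spectra supplied")
    missing = [p for p in LOCOMOTOR_PAIRS if p not in spectra]
    if missing and not allow_partial:
        raise ValueError(
            f"missing pairs {missing}; pass allow_partial=True for partial episodes"
        )
    items = list(spectra.items())
    ref = items[0][1]
    for name, s in items:
        _check_ready(s, name)
        if s.coeffs.shape != ref.coeffs.shape or not np.array_equal(s.freqs, ref.freqs) \
                or not np.array_equal(s.times, ref.times):
            raise ValueError(f"{name}: axis mismatch between pair spectra")
    coeffs = sum(s.coeffs for _, s in items) / len(items)
    mask = np.zeros(ref.coeffs.shape, dtype=bool)
    for _, s in items:
        mask |= s.sig_mask
    meta = {"kind": "wavg", "pairs": tuple(k for k, _ in items),
            "partial": bool(missing)}
    return CrossSpectrum(coeffs=coeffs, freqs=ref.freqs, times=ref.times,
                         normalized=True, sig_mask=mask, phase_filtered=True,
                         coi_freq=ref.coi_freq, meta=meta)


def strength(wavg: CrossSpectrum, apply_sqrt: bool = True) -> StrengthResult:
    """Locomotor strength of an episode from its pair-averaged spectrum.

    By default S is the square root of the modulus of the grand complex sum
    of ``wavg``; ``apply_sqrt=False`` returns the plain modulus instead.
    """
    resultant = complex(wavg.coeffs.sum())
    length = abs(resultant)
    s_val = float(np.sqrt(length)) if apply_sqrt else float(length)
    return StrengthResult(S=s_val, wavg=wavg,
                          pair_ids=tuple(wavg.meta.get("pairs", ())))


@dataclass
class ConditionSet:
    """Per-condition strength samples with a designated reference condition."""

    strengths: dict[str, list[float]]
    reference: str
    normalized: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference not in self.strengths:
            raise ValueError(f"reference condition {self.reference!r} not present")
        if not self.strengths[self.reference]:
            raise ValueError("reference condition has no trials")


def normalize_conditions(c: ConditionSet) -> ConditionSet:
    """Divide every strength by the reference-condition mean (its mean -> 1).

    This is how strengths from different preparations are pooled while
    preserving the relationships among conditions.
    """
    ref_mean = float(np.mean(c.strengths[c.reference]))
    if ref_mean == 0:
        raise ZeroDivisionError("reference condition mean strength is zero")
    normalized = {k: [v / ref_mean for v in vals] for k, vals in c.strengths.items()}
    return ConditionSet(strengths=c.strengths, reference=c.reference,
                        normalized=normalized)


def _pairwise_posthoc(groups: dict[str, list[float]], alpha: float) -> list[dict]:
    """Pairwise two-group Kruskal-Wallis (chi-square approximation) contrasts."""
    names = list(groups)
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                stat, p = stats.kruskal(groups[a], groups[b])
            except ValueError:  # all values identical
                stat, p = 0.0, 1.0
            out.append({"pair": (a, b), "statistic": float(stat),
                        "p_value": float(p), "significant": bool(p < alpha)})
    return out


def compare_conditions(
    c: ConditionSet, test: str = "auto", alpha: float = 0.05,
    posthoc: bool = False, use_normalized: bool = True,
) -> dict:
    """Nonparametric comparison of strength distributions across conditions.

    Wilcoxon rank-sum for two conditions, Kruskal-Wallis for three or more
    (``test='auto'`` picks by arity).  ``posthoc=True`` adds pairwise
    rank-based contrasts using the chi-square approximation.
    """
    groups = c.normalized if (use_normalized and c.normalized) else c.strengths
    n_cond = len(groups)
    if test == "auto":
        test = "wilcoxon_ranksum" if n_cond == 2 else "kruskal_wallis"
    if test == "wilcoxon_ranksum":
        if n_cond != 2:
            raise ValueError("rank-sum test requires exactly two conditions")
        (ga, gb) = groups.values()
        stat, p = stats.ranksums(ga, gb)
    elif test == "kruskal_wallis":
        if n_cond < 3:
            raise ValueError("Kruskal-Wallis requires three or more conditions")
        try:
            stat, p = stats.kruskal(*groups.values())
        except ValueError:  # all values identical across groups
            stat, p = 0.0, 1.0
    else:
        raise ValueError(f"unknown test {test!r}")
    report = {"test": test, "statistic": float(stat), "p_value": float(p),
              "alpha": alpha, "reject": bool(p < alpha),
              "n_per_condition": {k: len(v) for k, v in groups.items()}}
    if posthoc:
        report["posthoc"] = _pairwise_posthoc(groups, alpha)
    return report
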