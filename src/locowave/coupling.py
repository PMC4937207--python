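"""Pairwise coupling quantifier P and cross-preparation standardization.

For a single root pair the coupling quantifier is

    P = | sum_m sum_n W_alt[m, n] |,

the modulus of the grand complex sum of that pair's phase-filtered ("alt"),
significance-masked, normalized cross-wavelet spectrum.  Unlike the episode
strength S, no square root is taken.  P grows with both discharge amplitude
and the tightness of the alternating phase coupling.

P values from all pairs and trials of a preparation are sorted into four
groups -- ipsilateral flexor/extensor, bilateral flexor, contralateral
flexor/extensor, bilateral extensor -- relative to the stimulated side, and
standardized by dividing every value by the mean of the ipsilateral
flexor/extensor reference group, whose standardized mean is then exactly 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CrossSpectrum

__all__ = ["pair_coupling", "group_by_pair", "standardize", "PAIR_GROUPS"]

#: Group label per canonical pair id, given the stimulated side.
PAIR_GROUPS = {
    "left": {"fLeL": "ipsi_fe", "fReR": "contra_fe",
             "fLfR": "bi_ff", "eLeR": "bi_ee"},
    "right": {"fReR": "ipsi_fe", "fLeL": "contra_fe",
              "fLfR": "bi_ff", "eLeR": "bi_ee"},
}

REFERENCE_GROUP = "ipsi_fe"


def pair_coupling(s: CrossSpectrum) -> float:
    """Coupling quantifier P: modulus of the grand sum (no square root).

    ``s`` must carry the alternating-phase filter and the significance mask.
    """
    if not s.phase_filtered:
        raise ValueError("pair_coupling requires a phase-filtered ('alt') spectrum")
    if s.sig_mask is None:
        raise ValueError("pair_coupling requires a significance-masked spectrum")
    return float(abs(complex(s.coeffs.sum())))


def group_by_pair(
    trials: list[dict],
    stim_side: str | None = None,
) -> pd.DataFrame:
    """Tabulate per-trial, per-pair P values with laterality-resolved groups.

    Each element of ``trials`` is a dict with keys ``trial_id``, ``P``
    (mapping pair id -> P value) and optionally ``stim_side``; a missing
    per-trial side falls back to the ``stim_side`` argument.  Laterality
    (ipsi/contra) is resolved from metadata only, never inferred from the
    signals.
    """
    rows = []
    for t in trials:
        side = t.get("stim_side", stim_side)
        if side not in PAIR_GROUPS:
            raise ValueError(
                f"trial {t.get('trial_id')!r}: stimulated side must be 'left' or "
                f"'right' to resolve ipsi/contra groups, got {side!r}"
            )
        for pair, p_val in t["P"].items():
            if pair not in PAIR_GROUPS[side]:
                raise ValueError(f"unknown pair id {pair!r}")
            if p_val < 0:
                raise ValueError("P must be nonnegative")
            rows.append({"trial_id": t["trial_id"], "pair": pair,
                         "group": PAIR_GROUPS[side][pair], "P": float(p_val)})
    return pd.DataFrame(rows, columns=["trial_id", "pair", "group", "P"])


def standardize(table: pd.DataFrame, reference: str = REFERENCE_GROUP) -> pd.DataFrame:
    """Divide every P by the mean P of the reference group (adds ``P_std``).

    After standardization the reference group's mean is exactly 1, making
    group means comparable across preparations.  Idempotent: restandardizing
    the ``P_std`` column returns the same values.
    """
    if "group" not in table or "P" not in table:
        raise ValueError("table must have 'group' and 'P' columns")
    ref = table.loc[table["group"] == reference, "P"]
    if ref.empty:
        raise ValueError(f"reference group {reference!r} has no trials")
    ref_mean = float(ref.mean())
    if ref_mean == 0:
        raise ZeroDivisionError("reference group mean P is zero")
    out = table.copy()
    out["P_std"] = out["P"] / ref_mean
    return out


def group_means(table: pd.DataFrame, column: str = "P_std") -> pd.Series:
    """Mean of ``column`` per laterality-resolved group."""
    return table.groupby("group")[column].mean()
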