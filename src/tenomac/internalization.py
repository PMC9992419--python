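"""DQ-collagen internalization from explant-derived cell suspensions.

Cells imaged on chamber slides carry mean intensities for Col1-CFP
(fibroblast reporter), CD206 and F4/80 (macrophage markers), and DQ
collagen (fluorescent upon proteolytic degradation).  Run-level
per-channel thresholds set boolean marker flags; positivity percentages
are reported within each marker-defined denominator population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["classify_markers", "dq_positivity"]

FLAG_SUFFIX = "_pos"


def _flag(channel: str) -> str:
    return channel.replace("/", "") + FLAG_SUFFIX


def classify_markers(table: pd.DataFrame,
                     thresholds: dict[str, float]) -> pd.DataFrame:
    """Apply run-level intensity thresholds uniformly across all cells.

    ``thresholds`` maps channel name (e.g. ``"CD206"``) to the cutoff;
    flag columns are named ``<channel>_pos`` with ``/`` dropped.
    """
    out = table.copy()
    for ch, thr in thresholds.items():
        if ch not in table.columns:
            raise KeyError(f"channel {ch!r} missing from table")
        if not np.isfinite(thr) and thr != np.inf:
            raise ValueError(f"threshold for {ch!r} must be finite or +inf")
        out[_flag(ch)] = table[ch].to_numpy() > thr
    return out


def _pct_within(table: pd.DataFrame, numer_flag: str,
                denom_flag: str) -> tuple[float, int]:
    denom = table[denom_flag].to_numpy().astype(bool)
    n = int(denom.sum())
    if n == 0:
        return float("nan"), 0
    k = int((table[numer_flag].to_numpy().astype(bool) & denom).sum())
    return 100.0 * k / n, n


def dq_positivity(flagged: pd.DataFrame) -> dict:
    """Summary percentages with their denominators.

    Reports %DQ+ within CD206+, F4/80+, and Col1CFP+ populations, and
    the joint rarity checks %CD206+ and %F4/80+ within Col1CFP+.
    Empty denominators yield missing values with a note.
    """
    if len(flagged) == 0:
        raise ValueError("empty cell table")
    pairs = {
        "pct_dq_in_cd206": ("DQ_pos", "CD206_pos"),
        "pct_dq_in_f480": ("DQ_pos", "F480_pos"),
        "pct_dq_in_cfp": ("DQ_pos", "CFP_pos"),
        "pct_cd206_in_cfp": ("CD206_pos", "CFP_pos"),
        "pct_f480_in_cfp": ("F480_pos", "CFP_pos"),
    }
    out: dict = {"n_cells": int(len(flagged)), "notes": []}
    for key, (numer, denom) in pairs.items():
        pct, n = _pct_within(flagged, numer, denom)
        out[key] = pct
        out[f"{key}_n"] = n
        if n == 0:
            out["notes"].append(f"{key}: empty denominator population")
    return out
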