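"""Hemispheric balance indices from peak pseudo-Z values and speech scores.

All ratio indices are normalized differences in percent: cortical
lateralization contrasts the two auditory cortices within a stimulation
condition, cortical representation contrasts the two ears within one
hemisphere, bilateral enhancement is the signed pseudo-Z difference between
bilateral and ipsilateral-ear unilateral stimulation, and normalized
bilateral benefit expresses the speech-perception gain from adding an ear as
a percentage of the attainable headroom.

Sub-threshold peaks (non-significant omnibus-corrected pseudo-Z) are set to
exactly zero before index computation — absence of a significant cortical
response — and every substitution is logged. When both inputs of a ratio
index are zero the index is undefined and reported as missing, never as 0.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .source_imaging import RoiPeak

__all__ = [
    "apply_subthreshold_rule",
    "cortical_lateralization",
    "cortical_representation",
    "bilateral_enhancement",
    "bilateral_benefit",
    "normalized_bilateral_benefit",
    "build_index_table",
]

logger = logging.getLogger(__name__)


def apply_subthreshold_rule(peak: RoiPeak) -> float:
    """Omnibus-corrected pseudo-Z for index computation; zero if nonsignificant.

    A peak below the omnibus threshold represents the absence of a
    significant cortical response and enters the indices as exactly 0.
    """
    if peak.significant:
        return float(peak.pz_corrected)
    logger.info("subthreshold substitution: %s AC peak %.3f -> 0",
                peak.hemisphere, peak.pz_corrected)
    return 0.0


def _normalized_difference(a: float, b: float) -> float:
    """(a − b) / (a + b) × 100, or NaN when both are zero."""
    if a < 0 or b < 0:
        raise ValueError("inputs must be non-negative after zero-substitution")
    total = a + b
    if total == 0:
        return math.nan
    return float(np.clip(100.0 * (a - b) / total, -100.0, 100.0))


def cortical_lateralization(right_ac: float, left_ac: float) -> float:
    """Right-minus-left auditory-cortex activation difference in percent.

    Positive values indicate right-hemispheric lateralization; negative,
    left-hemispheric. Undefined (NaN) when both hemispheres are zero.
    """
    return _normalized_difference(right_ac, left_ac)


def cortical_representation(right_ear: float, left_ear: float) -> float:
    """Right-ear-minus-left-ear response difference within one hemisphere (%).

    Positive values mean the right (first-implanted) ear dominates; negative,
    the left (newly implanted) ear. Not defined for bilateral stimulation —
    use the two unilateral-condition peaks of a single hemisphere.
    """
    return _normalized_difference(right_ear, left_ear)


def bilateral_enhancement(bilateral: float, ipsilateral_unilateral: float,
                          hemisphere: str, *, ear: str | None = None) -> float:
    """Bilateral minus ipsilateral-ear unilateral response (pseudo-Z).

    The subtracted unilateral response must come from the ear on the same
    side as the cortex: left AC ↔ left ear, right AC ↔ right ear. Positive
    values mark the typical ipsilateral enhancement under bilateral listening.
    """
    if hemisphere not in ("left", "right"):
        raise ValueError(f"unknown hemisphere {hemisphere!r}")
    if ear is not None and ear != hemisphere:
        raise ValueError(
            f"{hemisphere} AC enhancement requires the {hemisphere}-ear "
            f"unilateral response, got ear={ear!r}")
    return float(bilateral) - float(ipsilateral_unilateral)


def bilateral_benefit(bilateral_score: float, opposite_ear_score: float) -> float:
    """Raw bilateral speech benefit: bilateral − opposite-ear score (%)."""
    for s in (bilateral_score, opposite_ear_score):
        if not 0.0 <= s <= 100.0:
            raise ValueError(f"speech scores must be in [0, 100], got {s}")
    return float(bilateral_score) - float(opposite_ear_score)


def normalized_bilateral_benefit(bilateral_score: float,
                                 opposite_ear_score: float) -> float:
    """Bilateral benefit as a percentage of the attainable headroom.

    (bilateral − opposite) / (100 − opposite) × 100; may be negative when
    bilateral listening is worse. Undefined (NaN) when the opposite ear is
    already at ceiling.
    """
    raw = bilateral_benefit(bilateral_score, opposite_ear_score)
    headroom = 100.0 - opposite_ear_score
    if headroom == 0:
        return math.nan
    return 100.0 * raw / headroom


# --------------------------------------------------------------------------
# tidy index tables from peak tables
# --------------------------------------------------------------------------

def build_index_table(peaks: pd.DataFrame) -> pd.DataFrame:
    """Derive all indices from a long-format peak table.

    ``peaks`` needs columns: participant_id, time_bin, condition
    (CI1/CI2/CIB), hemisphere (left/right), pz_corrected, significant.
    Returns one row per participant × session with zero-substituted peak
    values, lateralization per condition, representation per hemisphere and
    enhancement per hemisphere. Undefined (0/0) indices are NaN.
    """
    required = {"participant_id", "time_bin", "condition", "hemisphere",
                "pz_corrected", "significant"}
    missing = required - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns {sorted(missing)}")
    p = peaks.copy()
    p["pz_used"] = np.where(p["significant"], p["pz_corrected"], 0.0)
    n_sub = int((~p["significant"].astype(bool)).sum())
    if n_sub:
        logger.info("zero-substituted %d nonsignificant peaks", n_sub)

    wide = p.pivot_table(index=["participant_id", "time_bin"],
                         columns=["condition", "hemisphere"],
                         values="pz_used", aggfunc="first")
    rows = []
    for (pid, tb), r in wide.iterrows():
        def v(cond, hemi):
            try:
                val = r[(cond, hemi)]
            except KeyError:
                return math.nan
            return float(val) if pd.notna(val) else math.nan

        row = dict(participant_id=pid, time_bin=tb)
        for cond in ("CI1", "CI2", "CIB"):
            row[f"pz_left_{cond}"] = v(cond, "left")
            row[f"pz_right_{cond}"] = v(cond, "right")
            row[f"lateralization_{cond}"] = (
                cortical_lateralization(v(cond, "right"), v(cond, "left"))
                if not (math.isnan(v(cond, "right")) or math.isnan(v(cond, "left")))
                else math.nan)
        for hemi in ("left", "right"):
            a1, a2 = v("CI1", hemi), v("CI2", hemi)
            row[f"representation_{hemi}"] = (
                cortical_representation(a1, a2)
                if not (math.isnan(a1) or math.isnan(a2)) else math.nan)
            ab = v("CIB", hemi)
            ipsi = v("CI2" if hemi == "left" else "CI1", hemi)
            row[f"enhancement_{hemi}"] = (
                bilateral_enhancement(ab, ipsi, hemi)
                if not (math.isnan(ab) or math.isnan(ipsi)) else math.nan)
        rows.append(row)
    return pd.DataFrame(rows)
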