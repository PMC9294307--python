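"""Electrode geometry: a 62-channel 10-10 layout plus right-earlobe reference.

Positions come from the standard 10-10 montage shipped with MNE, projected
radially onto the scalp shell of the spherical head model so that the analytic
lead field sees electrodes exactly on the outer surface.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["standard_62_montage", "REFERENCE_NAME"]

REFERENCE_NAME = "A2"  # right earlobe

# 62 cephalic channels of the extended 10-20 (10-10) system
CHANNEL_NAMES_62 = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
]


def _fit_sphere_center(points: np.ndarray) -> np.ndarray:
    """Least-squares sphere centre of a point cloud."""
    A = np.hstack([2 * points, np.ones((len(points), 1))])
    b = np.sum(points ** 2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


from functools import lru_cache


@lru_cache(maxsize=4)
def _cached_positions(scalp_radius_mm: float):
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    wanted = CHANNEL_NAMES_62 + [REFERENCE_NAME]
    pts = np.array([pos[name] for name in wanted]) * 1000.0  # m -> mm
    center = _fit_sphere_center(pts)
    rel = pts - center
    rel = rel / np.linalg.norm(rel, axis=1, keepdims=True) * scalp_radius_mm
    return rel


def standard_62_montage(scalp_radius_mm: float = 92.0):
    """Return (channel_names, channel_positions_mm, reference_position_mm).

    62 cephalic electrodes and the right-earlobe reference, projected onto a
    sphere of ``scalp_radius_mm`` centred at the origin.
    """
    rel = _cached_positions(float(scalp_radius_mm))
    return list(CHANNEL_NAMES_62), rel[:-1].copy(), rel[-1].copy()
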