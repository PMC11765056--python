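"""Cohort-level reporting and slice-image export.

``per_roi_scores`` reproduces the per-region table format (one row per OAR /
PTV plus Overall); ``metric_summary`` the per-metric ``mean ± sd`` format
pooled over PTV entries (D99/D95/D1) and OAR entries (Dmean/D0.1cc).  Slice
export writes a grayscale CT image and a turbo-mapped dose image with the
dose color scale fixed to 0-70 Gy so different slices and patients are
directly comparable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib import image as mpimage

from .dvh_metrics import dvh_values
from .errors import DomainError
from .patient_io import MAX_CT, MAX_DOSE, STRUCTURE_NAMES, PatientCase

__all__ = ["per_roi_scores", "metric_summary", "export_slice"]


def _paired_value_diffs(true_doses, pred_doses, cases) -> List[Tuple[str, str, float]]:
    """|true - pred| per (structure, metric) entry, pooled over patients."""
    if not (len(true_doses) == len(pred_doses) == len(cases)):
        raise DomainError("true doses, predictions and cases must align")
    out: List[Tuple[str, str, float]] = []
    for dt, dp, case in zip(true_doses, pred_doses, cases):
        vt = dvh_values(dt, case.masks, case.grid)
        vp = dvh_values(dp, case.masks, case.grid)
        for (s, m, a), (_, _, b) in zip(vt.entries, vp.entries):
            out.append((s, m, abs(a - b)))
    return out


def per_roi_scores(true_doses: Sequence[np.ndarray], pred_doses: Sequence[np.ndarray],
                   cases: Sequence[PatientCase], *,
                   per_patient: bool = False) -> pd.DataFrame:
    """Mean absolute DVH-value difference per region of interest, plus Overall.

    By default entries are pooled across patients; ``per_patient=True``
    averages within each patient first and then across patients possessing
    the region.
    """
    diffs = _paired_value_diffs(true_doses, pred_doses, cases)
    rows = []
    if per_patient:
        per_case: Dict[str, List[List[float]]] = {}
        n = len(cases)
        for i, (dt, dp, case) in enumerate(zip(true_doses, pred_doses, cases)):
            vt = dvh_values(dt, case.masks, case.grid)
            vp = dvh_values(dp, case.masks, case.grid)
            for (s, m, a), (_, _, b) in zip(vt.entries, vp.entries):
                per_case.setdefault(s, [[] for _ in range(n)])[i].append(abs(a - b))
        for name in STRUCTURE_NAMES:
            if name in per_case:
                means = [np.mean(v) for v in per_case[name] if v]
                rows.append((name, float(np.mean(means))))
        patient_means = []
        for i in range(n):
            vals = [d for lists in per_case.values() for d in lists[i]]
            if vals:
                patient_means.append(np.mean(vals))
        rows.append(("Overall", float(np.mean(patient_means))))
    else:
        for name in STRUCTURE_NAMES:
            vals = [d for (s, _, d) in diffs if s == name]
            if vals:
                rows.append((name, float(np.mean(vals))))
        rows.append(("Overall", float(np.mean([d for (_, _, d) in diffs]))))
    return pd.DataFrame(rows, columns=["RoI", "dvh_score_gy"])


def metric_summary(true_doses: Sequence[np.ndarray], pred_doses: Sequence[np.ndarray],
                   cases: Sequence[PatientCase]) -> pd.DataFrame:
    """Mean and population sd of |true - pred| for each DVH-value metric."""
    diffs = _paired_value_diffs(true_doses, pred_doses, cases)
    rows = []
    for metric in ("D99", "D95", "D1", "Dmean", "D0.1cc"):
        vals = np.array([d for (_, m, d) in diffs if m == metric])
        if vals.size:
            rows.append((metric, float(vals.mean()), float(vals.std())))
    return pd.DataFrame(rows, columns=["metric", "mean_gy", "sd_gy"])


def export_slice(case: PatientCase, dose: np.ndarray, axis: int, index: int,
                 out_dir) -> Tuple[Path, Path]:
    """Write one CT slice (grayscale) and one dose slice (turbo, 0-70 Gy).

    Image pixel dimensions equal the slice dimensions.  Returns the two paths.
    """
    if axis not in (0, 1, 2):
        raise DomainError("axis must be 0, 1 or 2")
    extent = case.grid.shape[axis]
    if not 0 <= index < extent:
        raise DomainError(f"slice index {index} outside valid range 0..{extent - 1}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ct_slice = np.take(case.ct, index, axis=axis)
    dose_slice = np.take(np.asarray(dose), index, axis=axis)
    ct_path = out_dir / f"{case.id}_ax{axis}_{index}_ct.png"
    dose_path = out_dir / f"{case.id}_ax{axis}_{index}_dose.png"
    mpimage.imsave(ct_path, ct_slice, cmap="gray", vmin=0.0, vmax=MAX_CT)
    turbo = colormaps["turbo"]
    mpimage.imsave(dose_path, turbo(np.clip(dose_slice / MAX_DOSE, 0.0, 1.0)))
    return ct_path, dose_path
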