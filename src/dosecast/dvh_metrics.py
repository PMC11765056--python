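"""Dose-volume histogram metrics.

``D_k`` denotes the dose received by at least k% of a structure's voxels,
i.e. the (100-k)-th percentile of the voxel doses inside its mask.  The
percentile estimator is linear interpolation between adjacent order
statistics at fractional rank ``(100-k)/100 * (N-1)`` (numpy's default
"linear" method) — continuous in the dose values, which is what makes the
training loss built on these criteria differentiable almost everywhere.

Vectors computed here:

* *DVH criteria* — per present structure, ``D_1 .. D_99``; at most
  ``10 * 99 = 990`` entries per patient.
* *DVH values* — the evaluation vector: ``Dmean`` and ``D0.1cc`` per OAR,
  ``D1/D95/D99`` per PTV; at most ``7*2 + 3*3 = 23`` entries.
* *DVH-score* — mean absolute difference between two DVH-value vectors of
  one patient; the cohort score is the average over patients.

``D0.1cc`` (highest dose level covering at least 0.1 cm^3) is the m-th
largest voxel dose with ``m = max(1, floor(0.1 cc / voxel volume))`` —
a nearest-order-statistic convention, no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .errors import DomainError
from .patient_io import OAR_NAMES, PTV_NAMES, STRUCTURE_NAMES, VoxelGrid

__all__ = [
    "DVHCriteria",
    "DVHValues",
    "dose_at_volume",
    "dvh_criteria",
    "dvh_values",
    "dvh_score",
    "cohort_dvh_score",
    "dvh_curve",
    "OAR_VALUE_METRICS",
    "PTV_VALUE_METRICS",
]

OAR_VALUE_METRICS: Tuple[str, ...] = ("Dmean", "D0.1cc")
PTV_VALUE_METRICS: Tuple[str, ...] = ("D1", "D95", "D99")


@dataclass(frozen=True)
class DVHCriteria:
    """Ordered (structure, k, value-Gy) triples, 99 per present structure."""

    entries: Tuple[Tuple[str, int, float], ...]

    @property
    def n(self) -> int:
        return len(self.entries)

    def values(self) -> np.ndarray:
        return np.array([v for (_, _, v) in self.entries], dtype=np.float64)

    def labels(self) -> Tuple[Tuple[str, int], ...]:
        return tuple((s, k) for (s, k, _) in self.entries)


@dataclass(frozen=True)
class DVHValues:
    """Ordered (structure, metric, value-Gy) triples of the score vector."""

    entries: Tuple[Tuple[str, str, float], ...]

    def values(self) -> np.ndarray:
        return np.array([v for (_, _, v) in self.entries], dtype=np.float64)

    def labels(self) -> Tuple[Tuple[str, str], ...]:
        return tuple((s, m) for (s, m, _) in self.entries)


def dose_at_volume(values: np.ndarray, k: int) -> float:
    """Dose received by at least k% of the voxels: the (100-k)-th percentile."""
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    if values.size == 0:
        raise DomainError("empty structure")
    if not 1 <= int(k) <= 99:
        raise DomainError(f"k must lie in 1..99, got {k}")
    return float(np.percentile(values, 100 - int(k), method="linear"))


def _structure_doses(dose: np.ndarray, mask: np.ndarray, name: str) -> np.ndarray:
    if mask.shape != dose.shape:
        raise DomainError(f"mask {name} and dose have different shapes")
    vals = np.asarray(dose)[np.asarray(mask) > 0]
    if vals.size == 0:
        raise DomainError(
            f"structure {name} is present but has zero voxels "
            "(absent structures must be omitted from the mask map)")
    return vals.astype(np.float64)


def dvh_criteria(dose: np.ndarray, masks: Mapping[str, np.ndarray]) -> DVHCriteria:
    """``D_1 .. D_99`` for every present structure, in canonical order."""
    entries: List[Tuple[str, int, float]] = []
    ks = np.arange(1, 100)
    for name in STRUCTURE_NAMES:
        if name not in masks:
            continue
        vals = _structure_doses(dose, masks[name], name)
        qs = np.percentile(vals, 100 - ks, method="linear")
        entries.extend((name, int(k), float(q)) for k, q in zip(ks, qs))
    return DVHCriteria(entries=tuple(entries))


def dvh_values(dose: np.ndarray, masks: Mapping[str, np.ndarray],
               grid: VoxelGrid) -> DVHValues:
    """The evaluation vector: Dmean/D0.1cc per OAR, D1/D95/D99 per PTV."""
    entries: List[Tuple[str, str, float]] = []
    m_01cc = max(1, int(np.floor(0.1 / grid.voxel_volume_cc)))
    for name in OAR_NAMES:
        if name not in masks:
            continue
        vals = _structure_doses(dose, masks[name], name)
        entries.append((name, "Dmean", float(vals.mean())))
        m = min(m_01cc, vals.size)
        entries.append((name, "D0.1cc", float(np.sort(vals)[-m])))
    for name in PTV_NAMES:
        if name not in masks:
            continue
        vals = _structure_doses(dose, masks[name], name)
        for metric, k in (("D1", 1), ("D95", 95), ("D99", 99)):
            entries.append((name, metric, dose_at_volume(vals, k)))
    return DVHValues(entries=tuple(entries))


def dvh_score(true_values: DVHValues, pred_values: DVHValues,
              *, strict_sum: bool = False) -> float:
    """Per-patient DVH-score: mean |true - pred| over matched entries.

    The per-structure and overall magnitudes reported for this metric in the
    knowledge-based-planning literature correspond to a mean of absolute
    differences; ``strict_sum=True`` gives the unnormalized L1 norm instead.
    """
    if true_values.labels() != pred_values.labels():
        raise DomainError("DVH value vectors have mismatched entry labels")
    if not true_values.entries:
        raise DomainError("empty DVH value vectors")
    diff = np.abs(true_values.values() - pred_values.values())
    return float(diff.sum() if strict_sum else diff.mean())


def cohort_dvh_score(per_patient_scores: Sequence[float]) -> float:
    """Cohort score: plain average of per-patient DVH-scores."""
    scores = np.asarray(list(per_patient_scores), dtype=np.float64)
    if scores.size == 0:
        raise DomainError("no patients")
    return float(scores.mean())


def dvh_curve(dose: np.ndarray, mask: np.ndarray,
              bin_edges: np.ndarray) -> np.ndarray:
    """Cumulative DVH: fraction of mask voxels with dose >= each edge."""
    edges = np.asarray(bin_edges, dtype=np.float64).reshape(-1)
    if edges.size == 0 or edges[0] != 0 or np.any(np.diff(edges) <= 0):
        raise DomainError("bin edges must increase strictly and start at 0")
    vals = _structure_doses(dose, mask, "curve structure")
    return (vals[None, :] >= edges[:, None]).mean(axis=1)


def export_dvh_curve_csv(path, dose: np.ndarray, mask: np.ndarray,
                         bin_edges: np.ndarray) -> None:
    """Two-column CSV (dose edge in Gy, fractional volume) of a DVH curve."""
    frac = dvh_curve(dose, mask, bin_edges)
    arr = np.column_stack([np.asarray(bin_edges, dtype=np.float64), frac])
    np.savetxt(path, arr, delimiter=",", header="dose_gy,fraction_volume",
               comments="", fmt="%.9g")
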