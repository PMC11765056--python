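"""Domain types for a radiotherapy patient case and the sparse on-disk layout.

A case is a set of co-registered voxel volumes on one grid: a CT volume
(scanner counts 0-4095, 0 marks non-body air), binary masks for up to seven
organs at risk (OARs) and three planning target volumes (PTVs), a
possible-dose mask (voxels eligible to receive dose), and optionally the
clinically planned reference dose in Gy.

On disk each quantity is a two-column CSV of ``flattened_voxel_index,value``
in C order (last axis fastest); mask files store the index column only, the
value 1 being implied.  Voxel spacing in mm sits in ``voxel_dimensions.csv``
(three rows).  This mirrors the public OpenKBP challenge layout so real
archives drop in directly; a single non-numeric header line is tolerated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import DomainError, FormatError, LoadError

__all__ = [
    "VoxelGrid",
    "StructureName",
    "OAR_NAMES",
    "PTV_NAMES",
    "STRUCTURE_NAMES",
    "PTV_PRESCRIPTIONS",
    "PatientCase",
    "load_case",
    "write_case",
    "body_mask",
]

# Canonical structure order used everywhere (network channels, DVH vectors).
OAR_NAMES: Tuple[str, ...] = (
    "Brainstem",
    "SpinalCord",
    "RightParotid",
    "LeftParotid",
    "Larynx",
    "Esophagus",
    "Mandible",
)
PTV_NAMES: Tuple[str, ...] = ("PTV56", "PTV63", "PTV70")
STRUCTURE_NAMES: Tuple[str, ...] = OAR_NAMES + PTV_NAMES

#: Prescribed dose (Gy) carried by each PTV name.
PTV_PRESCRIPTIONS: Dict[str, float] = {"PTV56": 56.0, "PTV63": 63.0, "PTV70": 70.0}

MAX_CT = 4095.0
MAX_DOSE = 70.0


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid: per-axis extents and per-axis spacing in mm.

    Any positive extents are allowed here so that tiny volumes round-trip
    through the sparse layout; the network layer separately requires extents
    divisible by 16 (its four resolution halvings).
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float] = (3.5, 3.5, 2.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise DomainError("grid needs 3 extents and 3 spacings")
        if any(s < 1 for s in shape):
            raise DomainError(f"grid extents must be positive, got {shape}")
        if any(s <= 0 for s in spacing):
            raise DomainError(f"voxel spacings must be positive, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3 (spacing is in mm)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class StructureName:
    """A named structure: one of the 7 OARs or 3 PTVs.

    PTVs carry their prescription dose in Gy; OARs carry none.
    """

    name: str

    def __post_init__(self) -> None:
        if self.name not in STRUCTURE_NAMES:
            raise DomainError(f"unknown structure {self.name!r}")

    @property
    def kind(self) -> str:
        return "PTV" if self.name in PTV_NAMES else "OAR"

    @property
    def prescription(self) -> Optional[float]:
        return PTV_PRESCRIPTIONS.get(self.name)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass
class PatientCase:
    """One patient's co-registered volumes.

    ``masks`` maps structure name -> uint8 {0,1} volume; a structure that is
    clinically absent is simply *not a key* (never an all-zero mask), so the
    count of DVH criteria per patient is unambiguous.
    """

    id: str
    grid: VoxelGrid
    ct: np.ndarray
    masks: Dict[str, np.ndarray] = field(default_factory=dict)
    possible_dose_mask: np.ndarray = None
    reference_dose: Optional[np.ndarray] = None

    def validate(self) -> "PatientCase":
        """Check all invariants; raise :class:`DomainError` on violation."""
        shape = self.grid.shape
        if self.ct.shape != shape:
            raise DomainError(f"ct shape {self.ct.shape} != grid {shape}")
        if self.ct.min() < 0 or self.ct.max() > MAX_CT:
            raise DomainError("ct intensities must lie in [0, 4095]")
        if self.possible_dose_mask is None or self.possible_dose_mask.shape != shape:
            raise DomainError("possible_dose_mask missing or mis-shaped")
        for name, m in self.masks.items():
            if name not in STRUCTURE_NAMES:
                raise DomainError(f"unknown structure {name!r}")
            if m.shape != shape:
                raise DomainError(f"mask {name} shape {m.shape} != grid {shape}")
            if not np.isin(m, (0, 1)).all():
                raise DomainError(f"mask {name} is not binary")
        if self.reference_dose is not None:
            d = self.reference_dose
            if d.shape != shape:
                raise DomainError("reference_dose shape mismatch")
            if d.min() < 0 or d.max() > MAX_DOSE + 1e-6:
                raise DomainError("reference_dose must lie in [0, 70] Gy")
            if np.any(d[self.possible_dose_mask == 0] != 0):
                raise DomainError("reference_dose nonzero outside possible-dose mask")
        return self

    @property
    def present_structures(self) -> Tuple[str, ...]:
        """Present structure names in canonical order."""
        return tuple(n for n in STRUCTURE_NAMES if n in self.masks)

    def copy(self) -> "PatientCase":
        return PatientCase(
            id=self.id,
            grid=self.grid,
            ct=self.ct.copy(),
            masks={k: v.copy() for k, v in self.masks.items()},
            possible_dose_mask=self.possible_dose_mask.copy(),
            reference_dose=None if self.reference_dose is None else self.reference_dose.copy(),
        )


def body_mask(ct: np.ndarray) -> np.ndarray:
    """Binary body mask: 1 exactly where the CT intensity is positive.

    Zero-intensity voxels are the scanner's non-body convention.
    """
    ct = np.asarray(ct)
    if ct.size and ct.min() < 0:
        raise DomainError("negative CT intensity")
    return (ct > 0).astype(np.uint8)


# ---------------------------------------------------------------------------
# sparse CSV dialect
# ---------------------------------------------------------------------------

def _read_sparse(path: Path, n_voxels: int, *, with_value: bool) -> Tuple[np.ndarray, np.ndarray]:
    """Read a sparse (index[,value]) CSV; returns (indices, values).

    Tolerates one header line and an optional trailing empty-value column
    (real OpenKBP mask files are written as ``index,`` rows).
    """
    idx, val = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh):
            line = raw.strip()
            if not line:
                continue
            parts = [p for p in line.split(",")]
            try:
                i = int(float(parts[0]))
            except ValueError:
                if lineno == 0:
                    continue  # header line
                raise FormatError(f"{path.name}: bad index {parts[0]!r} on line {lineno + 1}")
            if not 0 <= i < n_voxels:
                raise FormatError(f"{path.name}: voxel index {i} outside grid of {n_voxels}")
            idx.append(i)
            if with_value:
                if len(parts) < 2 or parts[1] == "":
                    raise FormatError(f"{path.name}: missing value on line {lineno + 1}")
                val.append(float(parts[1]))
    return np.asarray(idx, dtype=np.int64), np.asarray(val, dtype=np.float64)


def _densify(indices: np.ndarray, values: np.ndarray, shape: Tuple[int, int, int],
             dtype) -> np.ndarray:
    out = np.zeros(int(np.prod(shape)), dtype=dtype)
    out[indices] = values
    return out.reshape(shape)


def _write_sparse(path: Path, volume: np.ndarray, *, with_value: bool, fmt: str = "%.9g") -> None:
    flat = np.ascontiguousarray(volume).reshape(-1)
    nz = np.flatnonzero(flat)
    with open(path, "w") as fh:
        if with_value:
            for i in nz:
                fh.write(f"{i},{fmt % flat[i]}\n")
        else:
            for i in nz:
                fh.write(f"{i}\n")


def load_case(directory_path: os.PathLike | str) -> PatientCase:
    """Load one patient directory in the sparse-CSV layout into a dense case.

    Structures whose file is absent *or empty* are recorded as missing.
    """
    d = Path(directory_path)
    ct_path = d / "ct.csv"
    if not ct_path.exists():
        raise LoadError(f"missing CT file {ct_path}")
    dims_path = d / "voxel_dimensions.csv"
    if not dims_path.exists():
        raise LoadError(f"missing spacing file {dims_path}")
    shape_path = d / "grid_shape.csv"
    if shape_path.exists():
        shape = tuple(int(x) for x in np.loadtxt(shape_path, delimiter=",").reshape(-1))
    else:
        shape = (128, 128, 128)
    spacing = tuple(float(x) for x in np.loadtxt(dims_path, delimiter=",").reshape(-1))
    grid = VoxelGrid(shape, spacing)
    n = grid.n_voxels

    idx, val = _read_sparse(ct_path, n, with_value=True)
    ct = _densify(idx, val, grid.shape, np.float32)

    masks: Dict[str, np.ndarray] = {}
    for name in STRUCTURE_NAMES:
        p = d / f"{name}.csv"
        if not p.exists():
            continue
        idx, _ = _read_sparse(p, n, with_value=False)
        if idx.size == 0:
            continue  # empty file = structure missing
        masks[name] = _densify(idx, np.ones(idx.size), grid.shape, np.uint8)

    pdm_path = d / "possible_dose_mask.csv"
    if pdm_path.exists():
        idx, _ = _read_sparse(pdm_path, n, with_value=False)
        pdm = _densify(idx, np.ones(idx.size), grid.shape, np.uint8)
    else:
        pdm = body_mask(ct)

    dose_path = d / "dose.csv"
    dose = None
    if dose_path.exists():
        idx, val = _read_sparse(dose_path, n, with_value=True)
        dose = _densify(idx, val, grid.shape, np.float32)

    case = PatientCase(
        id=d.name, grid=grid, ct=ct, masks=masks,
        possible_dose_mask=pdm, reference_dose=dose,
    )
    return case.validate()


def write_case(case: PatientCase, directory_path: os.PathLike | str) -> None:
    """Write a case to one directory in the sparse-CSV layout.

    Round-trips through :func:`load_case` bit-exactly for integer volumes and
    to <= 1e-6 Gy for dose.
    """
    case.validate()
    d = Path(directory_path)
    try:
        d.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise LoadError(f"cannot create {d}: {exc}")
    np.savetxt(d / "voxel_dimensions.csv", np.asarray(case.grid.spacing), fmt="%.9g")
    if case.grid.shape != (128, 128, 128):
        np.savetxt(d / "grid_shape.csv", np.asarray(case.grid.shape), fmt="%d")
    _write_sparse(d / "ct.csv", case.ct, with_value=True)
    _write_sparse(d / "possible_dose_mask.csv", case.possible_dose_mask, with_value=False)
    for name in case.present_structures:
        _write_sparse(d / f"{name}.csv", case.masks[name], with_value=False)
    if case.reference_dose is not None:
        _write_sparse(d / "dose.csv", case.reference_dose, with_value=True)
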