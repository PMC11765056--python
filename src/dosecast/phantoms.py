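"""Synthetic head-and-neck phantom cases.

The generator emulates the structure of a standardized head-and-neck planning
case: an ellipsoidal body on a voxel grid, seven OAR and up to three PTV
ellipsoids placed disjointly inside it, a CT volume with tissue-dependent base
intensities (soft tissue ~900 counts, bone-like mandible ~2500) plus Gaussian
scanner noise, and an analytic reference dose that is the per-voxel maximum
over present PTVs of ``prescription * exp(-d^2 / (2 sigma^2))`` with ``d`` the
Euclidean distance in mm to the PTV surface (0 inside).  The dose model is a
Gaussian-falloff surrogate, not beam physics: it exists to give the network a
learnable CT/mask -> dose mapping with realistic DVH structure (each PTV near
its prescription, OARs on monotone falloff shoulders).

Every case is fully determined by ``(config.seed, case_index)``; each case
draws from its own RNG stream, so cohorts are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.ndimage import distance_transform_edt

from .errors import DomainError, GenerationError
from .patient_io import (
    PTV_PRESCRIPTIONS,
    STRUCTURE_NAMES,
    PatientCase,
    VoxelGrid,
)

__all__ = ["PhantomConfig", "generate_phantom", "generate_cohort"]

#: Normalized (center, semi-axes) of each structure, in fractions of the grid
#: extent along (x, y, z).  Chosen so all ten ellipsoids are pairwise disjoint
#: and strictly inside the ~60%-volume body ellipsoid, with roughly anatomical
#: relative placement (brainstem above cord, parotids lateral, mandible
#: anterior bone bar, PTVs in the mid/lower head-and-neck region).
_LAYOUT = {
    "Brainstem": ((0.50, 0.62, 0.78), (0.055, 0.055, 0.095)),
    "SpinalCord": ((0.50, 0.68, 0.40), (0.048, 0.048, 0.20)),
    "RightParotid": ((0.24, 0.54, 0.66), (0.065, 0.065, 0.085)),
    "LeftParotid": ((0.76, 0.54, 0.66), (0.065, 0.065, 0.085)),
    "Larynx": ((0.50, 0.34, 0.42), (0.065, 0.065, 0.085)),
    "Esophagus": ((0.50, 0.54, 0.18), (0.048, 0.048, 0.09)),
    "Mandible": ((0.50, 0.24, 0.68), (0.15, 0.062, 0.05)),
    "PTV70": ((0.36, 0.38, 0.56), (0.085, 0.085, 0.085)),
    "PTV63": ((0.70, 0.36, 0.42), (0.075, 0.075, 0.075)),
    "PTV56": ((0.64, 0.68, 0.60), (0.078, 0.078, 0.078)),
}

# Clipped in x/y, a one-voxel-plus z margin: ~57% of the grid, and the body
# keeps a nonzero legal translation range along z on every supported grid.
_BODY_SEMI = (0.55, 0.55, 0.46)
_SOFT_TISSUE = 900.0
_BONE = 2500.0
_CENTER_JITTER = 0.012  # fraction of extent, per axis


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic cohort."""

    grid: VoxelGrid
    seed: int = 0
    missing_structure_rate: float = 0.2
    dose_falloff_sigma: float = 15.0  # mm
    noise_sd: float = 60.0  # CT counts

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_structure_rate < 1.0:
            raise DomainError("missing_structure_rate must lie in [0, 1)")
        if self.dose_falloff_sigma <= 0:
            raise DomainError("dose_falloff_sigma must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")


def _ellipsoid(coords, center, semi) -> np.ndarray:
    x, y, z = coords
    val = ((x - center[0]) / semi[0]) ** 2 \
        + ((y - center[1]) / semi[1]) ** 2 \
        + ((z - center[2]) / semi[2]) ** 2
    return (val <= 1.0).astype(np.uint8)


def generate_phantom(config: PhantomConfig, case_index: int) -> PatientCase:
    """Generate one deterministic phantom case.

    Raises :class:`GenerationError` if the grid is too small for every
    requested structure to come out non-empty, inside the body, and disjoint
    from the others.
    """
    if case_index < 0:
        raise DomainError("case_index must be non-negative")
    rng = np.random.default_rng([int(config.seed), int(case_index)])
    shape = config.grid.shape
    axes = [(np.arange(n) + 0.5) / n for n in shape]
    coords = np.meshgrid(*axes, indexing="ij")

    body = _ellipsoid(coords, (0.5, 0.5, 0.5), _BODY_SEMI)

    # Independent presence draw per optional structure (all ten are optional).
    present = {
        name: rng.random() >= config.missing_structure_rate
        for name in STRUCTURE_NAMES
    }
    jitter = rng.uniform(-_CENTER_JITTER, _CENTER_JITTER, size=(len(STRUCTURE_NAMES), 3))

    masks = {}
    for j, name in enumerate(STRUCTURE_NAMES):
        if not present[name]:
            continue
        center, semi = _LAYOUT[name]
        center = tuple(c + jitter[j, a] for a, c in enumerate(center))
        m = _ellipsoid(coords, center, semi)
        if m.sum() == 0:
            raise GenerationError(
                f"grid {shape} too small: structure {name} is empty")
        if np.any(m & ~body.astype(bool)):
            raise GenerationError(
                f"structure {name} does not fit inside the body on grid {shape}")
        masks[name] = m
    occupancy = np.zeros(shape, dtype=np.int16)
    for m in masks.values():
        occupancy += m
    if occupancy.max() > 1:
        raise GenerationError(f"structures overlap on grid {shape}")

    # CT: soft tissue everywhere in the body, bone in the mandible, noise on top.
    ct = np.where(body > 0, _SOFT_TISSUE, 0.0)
    if "Mandible" in masks:
        ct[masks["Mandible"] > 0] = _BONE
    noise = rng.normal(0.0, config.noise_sd, size=shape)
    inside = body > 0
    ct[inside] = np.clip(ct[inside] + noise[inside], 1.0, 4095.0)
    ct = ct.astype(np.float32)

    # Analytic dose: max over present PTVs of prescription * Gaussian falloff.
    dose = np.zeros(shape, dtype=np.float64)
    for name, presc in PTV_PRESCRIPTIONS.items():
        if name not in masks:
            continue
        d_mm = distance_transform_edt(1 - masks[name], sampling=config.grid.spacing)
        dose = np.maximum(
            dose, presc * np.exp(-(d_mm ** 2) / (2.0 * config.dose_falloff_sigma ** 2)))
    dose = np.clip(dose, 0.0, 70.0)
    dose[~inside] = 0.0

    case = PatientCase(
        id=f"pt_{case_index}",
        grid=config.grid,
        ct=ct,
        masks=masks,
        possible_dose_mask=body,
        reference_dose=dose.astype(np.float32),
    )
    return case.validate()


def generate_cohort(config: PhantomConfig, n: int) -> List[PatientCase]:
    """Generate ``n`` phantoms with case indices ``0 .. n-1`` and distinct ids."""
    if n < 0:
        raise DomainError("cohort size must be non-negative")
    return [generate_phantom(config, i) for i in range(n)]
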