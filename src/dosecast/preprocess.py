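"""CT standardization and body-preserving volumetric augmentation.

Standardization is ``z = (x - mu) / sigma`` with ``mu``/``sigma`` the
*population* mean and standard deviation of all CT voxels pooled over the
training cases (zeros included) — fitted on training data only, then applied
unchanged at validation/test time to avoid leakage.

The two augmentations are integer-voxel and therefore exact: axis flips and
translations limited so that no body voxel ever leaves the grid.  The offline
enumeration (identity, flip, translation, flip+translation) quadruples a
cohort, e.g. 200 cases -> 800.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .errors import DomainError, FitError
from .patient_io import PatientCase, body_mask

__all__ = [
    "Standardizer",
    "fit_standardizer",
    "standardize",
    "flip_case",
    "translate_case",
    "allowed_shift_range",
    "augment_dataset",
]


@dataclass(frozen=True)
class Standardizer:
    """Pooled CT intensity mean and population standard deviation."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise FitError("sigma must be positive")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.mu!r}\n{self.sigma!r}\n")

    @classmethod
    def load(cls, path) -> "Standardizer":
        with open(path) as fh:
            mu, sigma = (float(fh.readline()) for _ in range(2))
        return cls(mu, sigma)


def fit_standardizer(cases: Sequence[PatientCase]) -> Standardizer:
    """Fit pooled mean/sd over all CT voxels of all given cases.

    Accumulates sums rather than concatenating, so cohort size is not
    memory-bound.  Raises :class:`FitError` when the pooled voxels have zero
    variance and :class:`DomainError` for an empty collection.
    """
    cases = list(cases)
    if not cases:
        raise DomainError("cannot fit a standardizer on zero cases")
    n = 0
    s1 = 0.0
    s2 = 0.0
    for case in cases:
        ct = case.ct.astype(np.float64)
        n += ct.size
        s1 += float(ct.sum())
        s2 += float((ct * ct).sum())
    mu = s1 / n
    var = s2 / n - mu * mu
    if var <= 0:
        raise FitError("pooled CT voxels have zero variance")
    return Standardizer(mu=mu, sigma=float(np.sqrt(var)))


def standardize(ct: np.ndarray, s: Standardizer) -> np.ndarray:
    """Elementwise ``(ct - mu) / sigma``."""
    return (np.asarray(ct, dtype=np.float64) - s.mu) / s.sigma


def _check_axes(axes: Iterable[int]) -> Tuple[int, ...]:
    axes = tuple(sorted(set(int(a) for a in axes)))
    if any(a not in (0, 1, 2) for a in axes):
        raise DomainError(f"flip axes must be a subset of {{0,1,2}}, got {axes}")
    return axes


def flip_case(case: PatientCase, axes: Iterable[int]) -> PatientCase:
    """Reverse every volume of the case along the given axes (an involution)."""
    axes = _check_axes(axes)

    def f(v):
        return np.flip(v, axis=axes).copy() if axes else v.copy()

    return PatientCase(
        id=case.id,
        grid=case.grid,
        ct=f(case.ct),
        masks={k: f(v) for k, v in case.masks.items()},
        possible_dose_mask=f(case.possible_dose_mask),
        reference_dose=None if case.reference_dose is None else f(case.reference_dose),
    )


def allowed_shift_range(case: PatientCase) -> Tuple[Tuple[int, int], ...]:
    """Per-axis (min, max) integer shifts that keep every body voxel on-grid.

    With the body bounding box spanning ``lo..hi`` on an axis of extent ``n``
    the legal shifts are ``-lo .. n-1-hi`` inclusive.
    """
    body = body_mask(case.ct)
    if body.sum() == 0:
        raise DomainError("case has an empty body")
    ranges = []
    for axis in range(3):
        proj = np.any(body, axis=tuple(a for a in range(3) if a != axis))
        nz = np.flatnonzero(proj)
        lo, hi = int(nz[0]), int(nz[-1])
        ranges.append((-lo, case.grid.shape[axis] - 1 - hi))
    return tuple(ranges)


def translate_case(case: PatientCase, shift: Sequence[int]) -> PatientCase:
    """Translate every volume by the same integer voxel offsets.

    Vacated voxels are zero-filled.  A shift outside
    :func:`allowed_shift_range` raises :class:`DomainError` — body voxels are
    never silently cropped.
    """
    shift = tuple(int(s) for s in shift)
    if len(shift) != 3:
        raise DomainError("shift needs exactly 3 components")
    ranges = allowed_shift_range(case)
    for axis, (s, (lo, hi)) in enumerate(zip(shift, ranges)):
        if not lo <= s <= hi:
            raise DomainError(
                f"shift {s} along axis {axis} outside allowed range [{lo}, {hi}]")

    def t(v):
        out = np.zeros_like(v)
        src = tuple(
            slice(max(0, -s), v.shape[a] - max(0, s)) for a, s in enumerate(shift))
        dst = tuple(
            slice(max(0, s), v.shape[a] + min(0, s)) for a, s in enumerate(shift))
        out[dst] = v[src]
        return out

    return PatientCase(
        id=case.id,
        grid=case.grid,
        ct=t(case.ct),
        masks={k: t(v) for k, v in case.masks.items()},
        possible_dose_mask=t(case.possible_dose_mask),
        reference_dose=None if case.reference_dose is None else t(case.reference_dose),
    )


def _random_flip(case: PatientCase, rng: np.random.Generator) -> PatientCase:
    axes = [a for a in range(3) if rng.random() < 0.5]
    return flip_case(case, axes)


def _random_translation(case: PatientCase, rng: np.random.Generator) -> PatientCase:
    ranges = allowed_shift_range(case)
    shift = [int(rng.integers(lo, hi + 1)) for lo, hi in ranges]
    return translate_case(case, shift)


def augment_dataset(cases: Sequence[PatientCase], seed: int) -> List[PatientCase]:
    """Offline x4 enumeration: identity, flip, translation, flip+translation.

    Deterministic given ``seed``; each input case draws from its own RNG
    stream keyed by its position.
    """
    out: List[PatientCase] = []
    for i, case in enumerate(cases):
        rng = np.random.default_rng([int(seed), i])
        ident = case.copy()
        flipped = _random_flip(case, rng)
        translated = _random_translation(case, rng)
        both = _random_translation(_random_flip(case, rng), rng)
        for suffix, variant in (
            ("orig", ident), ("flip", flipped), ("shift", translated), ("flipshift", both),
        ):
            variant.id = f"{case.id}_{suffix}"
            out.append(variant)
    return out
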