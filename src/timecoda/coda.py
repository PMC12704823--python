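"""Aitchison geometry for 4-part daily time-use compositions.

A day is partitioned into sleep, sedentary behavior (SB), light-intensity
physical activity (LPA) and moderate-to-vigorous physical activity (MVPA).
Only the relative sizes of the four parts carry information, so the natural
sample space is the 3-simplex closed to ``kappa`` (1440 minutes, or 1).
This module provides closure, the four rotated pivot-coordinate isometric
log-ratio (ILR) bases, the forward/inverse ILR maps, compositional
(geometric-mean) averaging, and minute-space time reallocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical part order used throughout the package.
BEHAVIORS: tuple[str, ...] = ("sleep", "sb", "lpa", "mvpa")

#: Minutes in a day; the default closure constant.
MINUTES_PER_DAY: float = 1440.0

D = len(BEHAVIORS)


class InfeasibleReallocationError(ValueError):
    """Raised when a time reallocation would drive a part to zero or below."""


def behavior_index(behavior: int | str) -> int:
    """Resolve a behavior name or index to its position in :data:`BEHAVIORS`."""
    if isinstance(behavior, str):
        try:
            return BEHAVIORS.index(behavior.lower())
        except ValueError:
            raise ValueError(
                f"unknown behavior {behavior!r}; expected one of {BEHAVIORS}"
            ) from None
    i = int(behavior)
    if not 0 <= i < D:
        raise ValueError(f"behavior index {i} out of range 0..{D - 1}")
    return i


def closure(raw, kappa: float = MINUTES_PER_DAY) -> np.ndarray:
    """Rescale strictly positive parts so each row sums to ``kappa``.

    Accepts a single 4-vector or an (n, 4) array. Idempotent: applying
    closure twice equals applying it once.
    """
    x = np.asarray(raw, dtype=float)
    if x.shape[-1] != D:
        raise ValueError(f"expected {D} parts, got shape {x.shape}")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError(
            "closure requires strictly positive finite parts; "
            "apply a zero-replacement policy first"
        )
    return kappa * x / x.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class IlrBasis:
    """Orthonormal pivot-coordinate contrast matrix for the 4-part simplex.

    ``matrix`` is 3x4 in the canonical part order; row j contrasts the j-th
    part of the pivot ordering against the geometric mean of the parts after
    it (a sequential binary partition). Rows are orthonormal and orthogonal
    to the all-ones vector, so ILR coordinates are invariant to closure.
    """

    matrix: np.ndarray
    pivot: str
    order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (D - 1, D):
            raise ValueError(f"contrast matrix must be {(D - 1, D)}, got {m.shape}")
        object.__setattr__(self, "matrix", m)

    @property
    def coordinate_names(self) -> list[str]:
        return [f"ilr{j + 1}_{self.pivot}" for j in range(D - 1)]


def pivot_basis(pivot: int | str) -> IlrBasis:
    """Pivot-coordinate ILR basis isolating ``pivot`` in the first contrast.

    The pivot part is moved to the front; the remaining parts keep their
    canonical order and are split off one at a time. The first row carries
    coefficient sqrt(3/4) on the pivot and -sqrt(1/12) on each other part.
    Rotating the pivot across the four behaviors yields the four bases; all
    downstream model summaries (fitted values, F test, reallocation
    estimates) are invariant to this choice.
    """
    i = behavior_index(pivot)
    order = [i] + [j for j in range(D) if j != i]
    V = np.zeros((D - 1, D))
    for r in range(D - 1):
        k = D - r - 1  # parts remaining after the r-th isolated part
        coef = np.sqrt(k / (k + 1.0))
        V[r, order[r]] = coef
        V[r, order[r + 1:]] = -coef / k
    return IlrBasis(matrix=V, pivot=BEHAVIORS[i],
                    order=tuple(BEHAVIORS[j] for j in order))


def all_pivot_bases() -> list[IlrBasis]:
    """The four rotated pivot bases, one per behavior."""
    return [pivot_basis(b) for b in BEHAVIORS]


def ilr(parts, basis: IlrBasis) -> np.ndarray:
    """Map compositions to ILR coordinates: ``z = V @ log(parts)``.

    Scale-invariant, so ``parts`` may be closed to any constant. Works on a
    single 4-vector or an (n, 4) array; returns shape (..., 3).
    """
    x = np.asarray(parts, dtype=float)
    if np.any(x <= 0):
        raise ValueError("ILR requires strictly positive parts")
    return np.log(x) @ basis.matrix.T


def ilr_inverse(z, basis: IlrBasis, kappa: float = MINUTES_PER_DAY) -> np.ndarray:
    """Map ILR coordinates back to a composition closed to ``kappa``."""
    zz = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(zz)):
        raise ValueError("ILR coordinates must be finite")
    logx = zz @ basis.matrix
    # guard against exp overflow for absurd coordinates
    if np.any(np.abs(logx) > 500):
        raise ValueError("ILR coordinates out of representable range")
    return closure(np.exp(logx), kappa)


def geometric_mean_composition(comps, kappa: float = MINUTES_PER_DAY) -> np.ndarray:
    """Compositional mean: part-wise geometric mean, then closure.

    Equals the ILR-inverse of the arithmetic mean of ILR coordinates in any
    basis, which is why it serves as the reference point for reallocation.
    """
    x = np.atleast_2d(np.asarray(comps, dtype=float))
    if x.size == 0:
        raise ValueError("need at least one composition")
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive parts")
    return closure(np.exp(np.mean(np.log(x), axis=0)), kappa)


def reallocate(comp, frm: int | str, to: int | str, delta: float) -> np.ndarray:
    """Move ``delta`` minutes from one behavior to another, others fixed.

    Plain minute-space arithmetic (not a compositional perturbation): the
    source part loses ``delta``, the destination gains it, the other two
    parts and the 1440-min total are unchanged. ``delta`` may be negative,
    which is the reverse move. Raises :class:`InfeasibleReallocationError`
    if either affected part would not remain strictly positive — e.g.
    displacing 45 min from a 42.6-min MVPA reference.
    """
    i, j = behavior_index(frm), behavior_index(to)
    if i == j:
        raise ValueError("source and destination behaviors must differ")
    x = np.asarray(comp, dtype=float)
    if x.shape != (D,):
        raise ValueError(f"expected a single {D}-part composition")
    new = x.copy()
    new[i] -= delta
    new[j] += delta
    if new[i] <= 0 or new[j] <= 0:
        raise InfeasibleReallocationError(
            f"moving {delta:g} min from {BEHAVIORS[i]} to {BEHAVIORS[j]} "
            f"leaves a non-positive part"
        )
    return new
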