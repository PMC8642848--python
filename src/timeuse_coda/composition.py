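"""Aitchison-simplex geometry for 4-part 24-h behaviour compositions.

A day is treated as a composition of four behaviours — sitting, standing,
stepping and sleeping — closed to a constant total of 1440 minutes. Only the
relative information in the parts is meaningful, so all statistics are done
in Aitchison geometry: closure, perturbation (the simplex group operation),
compositional (geometric-mean) centres, and isometric log-ratio (ilr)
*pivot* coordinates.

Pivot coordinates single out one *reference part*: the first coordinate
contrasts the reference against the geometric mean of the remaining three,

    z1 = sqrt(3/4) * ln( ref / (o1*o2*o3)^(1/3) )
    z2 = sqrt(2/3) * ln( o1  / (o2*o3)^(1/2) )
    z3 = sqrt(1/2) * ln( o2  / o3 )

for remaining parts (o1, o2, o3). Refitting a regression after rotating the
reference part changes (z1, z2, z3) by an orthonormal rotation, so fitted
values are invariant and z1's coefficient can be read as "time in the
reference behaviour relative to the rest".

Zero parts are a hard error throughout: the analysis this module supports
assumes every participant spends at least one minute in each behaviour, and
silent zero-replacement would change the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Canonical part order used for every 4-vector / (n, 4) array in the package.
PARTS: tuple[str, ...] = ("sit", "stand", "step", "sleep")

#: Minutes in a day — the closure constant.
DAY_MINUTES: float = 1440.0


class CompositionError(ValueError):
    """Contract violation in a compositional operation."""


class ZeroPartError(CompositionError):
    """A part was zero or negative where strict positivity is required."""


def _as_parts(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(PARTS):
        raise CompositionError(
            f"expected {len(PARTS)} parts {PARTS}, got shape {x.shape}"
        )
    return x


def _check_positive(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise CompositionError("non-finite part value")
    if np.any(x <= 0):
        bad = np.argwhere(x <= 0)
        part = PARTS[int(bad[0][-1])]
        raise ZeroPartError(
            f"part '{part}' is non-positive; compositions must be strictly "
            "positive (zero minutes in a behaviour violates the model)"
        )


def close(parts, total: float = DAY_MINUTES) -> np.ndarray:
    """Rescale strictly positive parts so they sum to ``total``.

    Works on a single 4-vector or an (n, 4) array of compositions.
    """
    x = _as_parts(parts)
    _check_positive(x)
    if total <= 0:
        raise CompositionError(f"closure total must be positive, got {total}")
    return x * (total / x.sum(axis=-1, keepdims=True))


def perturb(a, b, total: float = DAY_MINUTES) -> np.ndarray:
    """Aitchison perturbation: element-wise product followed by closure.

    Both operands must already be closed to ``total``.
    """
    a = _as_parts(a)
    b = _as_parts(b)
    for name, x in (("first", a), ("second", b)):
        if not np.allclose(x.sum(axis=-1), total, rtol=1e-9):
            raise CompositionError(
                f"{name} operand is not closed to total {total}"
            )
    return close(a * b, total)


def inverse_composition(a, total: float = DAY_MINUTES) -> np.ndarray:
    """Aitchison inverse: perturb(x, inverse_composition(x)) is uniform."""
    a = _as_parts(a)
    _check_positive(a)
    return close(1.0 / a, total)


def geometric_mean_composition(samples, total: float = DAY_MINUTES) -> np.ndarray:
    """Closed per-part geometric mean across samples — the compositional centre.

    Parameters
    ----------
    samples : (n, 4) array-like of strictly positive compositions.
    """
    x = _as_parts(samples)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[0] == 0:
        raise CompositionError("need at least one composition")
    _check_positive(x)
    return close(np.exp(np.log(x).mean(axis=0)), total)


# ---------------------------------------------------------------------------
# Pivot ilr coordinates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PivotBasis:
    """Pivot ilr basis: a reference part and the order of the remaining parts.

    ``contrast`` is the 4x3 orthonormal log-contrast matrix aligned to the
    canonical part order, so ``z = ln(x) @ contrast`` and
    ``x = close(exp(z @ contrast.T))``.
    """

    reference_part: str
    remaining_order: tuple[str, str, str]
    contrast: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def part_order(self) -> tuple[str, ...]:
        return (self.reference_part, *self.remaining_order)


def pivot_basis(
    reference_part: str = "sit",
    remaining_order: Sequence[str] | None = None,
) -> PivotBasis:
    """Build the pivot ilr basis for a given reference behaviour.

    By default the remaining parts keep their canonical order with the
    reference moved to the front (e.g. reference ``sit`` gives the order
    sit, stand, step, sleep).
    """
    if reference_part not in PARTS:
        raise CompositionError(
            f"reference part {reference_part!r} not one of {PARTS}"
        )
    if remaining_order is None:
        remaining_order = tuple(p for p in PARTS if p != reference_part)
    else:
        remaining_order = tuple(remaining_order)
        if sorted(remaining_order) != sorted(p for p in PARTS if p != reference_part):
            raise CompositionError(
                f"remaining_order {remaining_order} must be a permutation of "
                f"the parts other than {reference_part!r}"
            )
    order = (reference_part, *remaining_order)
    # Standard pivot (sequential binary partition) contrasts in `order`:
    # row i of V_perm is the clr vector of coordinate z_{i+1}.
    d = len(PARTS)
    v_perm = np.zeros((d, d - 1))
    for j in range(d - 1):
        k = d - j - 1  # number of parts balanced against the pivot
        coef = np.sqrt(k / (k + 1.0))
        v_perm[j, j] = coef
        v_perm[j + 1 :, j] = -coef / k
    # re-align rows to canonical part order
    contrast = np.zeros_like(v_perm)
    for i, part in enumerate(order):
        contrast[PARTS.index(part), :] = v_perm[i, :]
    return PivotBasis(reference_part, remaining_order, contrast)


def ilr_pivot(parts, basis: PivotBasis | str = "sit") -> np.ndarray:
    """Map strictly positive compositions to pivot ilr coordinates.

    Scale-invariant: closure of the input does not change the result.
    Accepts a single 4-vector or an (n, 4) array; returns 3 coordinates per
    composition.
    """
    if isinstance(basis, str):
        basis = pivot_basis(basis)
    x = _as_parts(parts)
    _check_positive(x)
    return np.log(x) @ basis.contrast


def ilr_inverse(
    coords, basis: PivotBasis | str = "sit", total: float = DAY_MINUTES
) -> np.ndarray:
    """Map pivot ilr coordinates back to a closed composition."""
    if isinstance(basis, str):
        basis = pivot_basis(basis)
    z = np.asarray(coords, dtype=float)
    if z.shape[-1] != len(PARTS) - 1:
        raise CompositionError(
            f"expected {len(PARTS) - 1} ilr coordinates, got shape {z.shape}"
        )
    if not np.all(np.isfinite(z)):
        raise CompositionError("ilr coordinates must be finite")
    return close(np.exp(z @ basis.contrast.T), total)
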