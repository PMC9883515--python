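"""Lateral grids and concentration-field containers.

The model lives on a laterally periodic domain: a membrane plane and the
bulk volume above it, with the vertical bulk dimension integrated out.  All
six species are therefore fields over the same lateral grid, stored as
areal densities (1/μm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

#: Canonical species order used everywhere (state vectors, Jacobians).
SPECIES = ("m_d", "m_de", "c_DD", "c_DT", "c_Er", "c_Ei")

#: Membrane-bound species (never advected by bulk flow).
MEMBRANE_SPECIES = ("m_d", "m_de")

#: Bulk MinD species (always advected when v_f != 0).
BULK_D_SPECIES = ("c_DD", "c_DT")

#: Bulk MinE species (advected unless the ablation flag disables it).
BULK_E_SPECIES = ("c_Er", "c_Ei")


@dataclass(frozen=True)
class Grid:
    """Uniform periodic lateral grid (1D or 2D).

    Parameters
    ----------
    lengths : tuple of float
        Domain extent per lateral dimension (μm).
    shape : tuple of int
        Number of points per dimension.
    """

    lengths: tuple[float, ...]
    shape: tuple[int, ...]

    def __post_init__(self):
        if len(self.lengths) != len(self.shape):
            raise ValueError("lengths and shape must have equal rank")
        if len(self.shape) not in (1, 2):
            raise ValueError("only 1 or 2 lateral dimensions are supported")
        if any(L <= 0 for L in self.lengths) or any(n < 4 for n in self.shape):
            raise ValueError("domain lengths must be positive and N >= 4")

    @property
    def n_dims(self) -> int:
        return len(self.shape)

    @property
    def dx(self) -> tuple[float, ...]:
        return tuple(L / n for L, n in zip(self.lengths, self.shape))

    @property
    def x(self) -> np.ndarray:
        """Coordinates along the first (flow) axis."""
        return np.arange(self.shape[0]) * self.dx[0]

    def wavenumbers(self) -> tuple[np.ndarray, ...]:
        """Angular wavenumbers (2π·FFT frequencies) per dimension."""
        return tuple(
            2.0 * np.pi * np.fft.fftfreq(n, d=d)
            for n, d in zip(self.shape, self.dx)
        )

    @classmethod
    def line(cls, length: float, n: int) -> "Grid":
        return cls((float(length),), (int(n),))

    @classmethod
    def plane(cls, lengths: tuple[float, float], shape: tuple[int, int]) -> "Grid":
        return cls((float(lengths[0]), float(lengths[1])), (int(shape[0]), int(shape[1])))


@dataclass
class FieldState:
    """The six concentration fields at one instant.

    ``m_d``/``m_de`` are membrane-bound MinD and the MinDE complex;
    ``c_DD``/``c_DT`` are bulk MinD-ADP and MinD-ATP; ``c_Er``/``c_Ei`` are
    bulk reactive and latent MinE.  All are areal densities (1/μm²) over the
    same lateral grid; ``t`` is the time in seconds.
    """

    m_d: np.ndarray
    m_de: np.ndarray
    c_DD: np.ndarray
    c_DT: np.ndarray
    c_Er: np.ndarray
    c_Ei: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        shapes = {np.shape(getattr(self, s)) for s in SPECIES}
        if len(shapes) != 1:
            raise ValueError(f"field shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return np.shape(self.m_d)

    def fields(self) -> Iterator[tuple[str, np.ndarray]]:
        for s in SPECIES:
            yield s, getattr(self, s)

    def as_array(self) -> np.ndarray:
        """Stack into a (6, *grid) array in canonical species order."""
        return np.stack([np.asarray(getattr(self, s), dtype=float) for s in SPECIES])

    @classmethod
    def from_array(cls, a: np.ndarray, t: float = 0.0) -> "FieldState":
        if a.shape[0] != len(SPECIES):
            raise ValueError("expected leading axis of length 6")
        return cls(*(a[i].copy() for i in range(len(SPECIES))), t=t)

    @classmethod
    def uniform(cls, values, grid: Grid, t: float = 0.0) -> "FieldState":
        """Spatially uniform state from six scalars (canonical order)."""
        arrs = [np.full(grid.shape, float(v)) for v in values]
        return cls(*arrs, t=t)

    def copy(self) -> "FieldState":
        return FieldState.from_array(self.as_array(), t=self.t)

    def min_value(self) -> float:
        return float(self.as_array().min())

    def validate(self, tol: float = 1e-9) -> None:
        a = self.as_array()
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite concentration encountered")
        if a.min() < -tol:
            raise ValueError(f"negative concentration {a.min():.3e} beyond tolerance")

    def mirrored(self) -> "FieldState":
        """Reflect all fields along the flow (first) axis."""
        a = self.as_array()
        out = np.flip(a, axis=1)
        return FieldState.from_array(np.ascontiguousarray(out), t=self.t)


def state_replace(state: FieldState, **kw) -> FieldState:
    return replace(state, **kw)
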