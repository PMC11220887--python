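"""Shared array-backed record types used across the package.

The reciprocal-space state is a :class:`ReflectionSet` (one row per Miller
index), the real-space state a :class:`DensityGrid`.  Both are thin
dataclasses over numpy arrays so that every algorithmic module can operate
vectorised without copying in and out of per-reflection objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

__all__ = ["BijvoetPairSet", "ReflectionSet", "DensityGrid"]


def _as_hkl(hkl) -> np.ndarray:
    arr = np.asarray(hkl, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"hkl must have shape (N, 3), got {arr.shape}")
    return arr


@dataclass
class BijvoetPairSet:
    """Merged Friedel-pair amplitudes F+/F- with standard deviations.

    Unobserved mates are encoded as NaN amplitude (sigma ignored).
    """

    hkl: np.ndarray
    fplus: np.ndarray
    sig_fplus: np.ndarray
    fminus: np.ndarray
    sig_fminus: np.ndarray

    def __post_init__(self) -> None:
        self.hkl = _as_hkl(self.hkl)
        n = len(self.hkl)
        for name in ("fplus", "sig_fplus", "fminus", "sig_fminus"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.hkl)

    def select(self, mask: np.ndarray) -> "BijvoetPairSet":
        return BijvoetPairSet(
            self.hkl[mask],
            self.fplus[mask],
            self.sig_fplus[mask],
            self.fminus[mask],
            self.sig_fminus[mask],
        )


@dataclass
class ReflectionSet:
    """Indexed anomalous-difference amplitudes with per-reflection state.

    Flags: ``observed`` marks measured reflections, ``weak``/``strong``
    engine-selected subsets of observed ones, ``centric`` phase-restricted
    indices, ``absent`` systematic extinctions and ``beyond`` reflections
    outside the working resolution limit.
    """

    hkl: np.ndarray
    dF: np.ndarray = None
    sig_dF: np.ndarray = None
    E: np.ndarray = None
    phase: np.ndarray = None
    d: np.ndarray = None
    observed: np.ndarray = None
    weak: np.ndarray = None
    strong: np.ndarray = None
    centric: np.ndarray = None
    absent: np.ndarray = None
    beyond: np.ndarray = None

    _FLOATS = ("dF", "sig_dF", "E", "phase", "d")
    _BOOLS = ("observed", "weak", "strong", "centric", "absent", "beyond")

    def __post_init__(self) -> None:
        self.hkl = _as_hkl(self.hkl)
        n = len(self.hkl)
        for name in self._FLOATS:
            arr = getattr(self, name)
            arr = np.zeros(n) if arr is None else np.asarray(arr, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)
        for name in self._BOOLS:
            arr = getattr(self, name)
            if arr is None:
                arr = np.ones(n, bool) if name == "observed" else np.zeros(n, bool)
            else:
                arr = np.asarray(arr, dtype=bool)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.hkl)

    def copy(self) -> "ReflectionSet":
        kw = {f.name: getattr(self, f.name).copy() for f in fields(self)}
        return ReflectionSet(**kw)

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        kw = {f.name: getattr(self, f.name)[mask] for f in fields(self)}
        return ReflectionSet(**kw)

    def kept(self) -> "ReflectionSet":
        """Observed reflections usable by the engine (inside the limit)."""
        return self.select(self.observed & ~self.beyond & ~self.absent)

    @property
    def values(self) -> np.ndarray:
        """Complex coefficients E * exp(i*phase)."""
        return self.E * np.exp(1j * self.phase)

    def index_map(self) -> dict:
        return {tuple(h): i for i, h in enumerate(self.hkl)}


@dataclass
class DensityGrid:
    """Real 3D map over one unit cell on a uniform fractional grid."""

    values: np.ndarray
    cell: "object" = None  # UnitCell; kept loose to avoid circular import

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("density grid must be 3-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density grid contains non-finite values")

    @property
    def dims(self) -> tuple:
        return self.values.shape

    def sigma_scaled(self) -> np.ndarray:
        """Map values in sigma-of-map units (mean subtracted)."""
        v = self.values
        sd = v.std()
        if sd == 0:
            return np.zeros_like(v)
        return (v - v.mean()) / sd
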