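"""Data containers for gel-densitometry observations.

Three experiment types are represented, each as a small validated
container wrapping numpy arrays:

* :class:`ProgressCurve` — single-turnover strand-cleavage time course
  (fraction cleaved vs. time).
* :class:`CruciformTrajectory` — supercoiled / nicked / linear plasmid
  fractions vs. time in a cruciform-cleavage assay.
* :class:`BindingTitration` — fraction of junction bound vs. total protein
  concentration in a gel-shift titration.

Synthetic data carry their generating truth in ``truth`` (a plain dict) and
the seed used, so closed-loop recovery tests can compare fit to truth.

Fractions in kinetic tables are *not* clipped to [0, 1]: densitometry noise
legitimately produces slight excursions and clipping before least squares
biases the fit.  Clipping is available via :meth:`ProgressCurve.clipped`
for display only.  Bound fractions in titrations are physically confined to
[0, 1] (they are a ratio of two band intensities) and are validated as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError
from .units import check_time_unit

__all__ = ["ProgressCurve", "CruciformTrajectory", "BindingTitration"]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DomainError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise DomainError(f"{name} contains a non-finite value at index {bad}")
    return arr


def _check_schedule(t: np.ndarray, name: str = "times") -> None:
    if t.size == 0:
        raise DomainError(f"{name} is empty")
    if np.any(t < 0):
        raise DomainError(f"{name} must be nonnegative")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise DomainError(f"{name} must be strictly increasing (violated at row {bad})")


@dataclass(frozen=True)
class ProgressCurve:
    """Fraction of radiolabeled strand cleaved, F(t), at ordered times."""

    times: np.ndarray
    F: np.ndarray
    time_unit: str = "s"
    truth: dict | None = None
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "times", _as_1d(self.times, "times"))
        object.__setattr__(self, "F", _as_1d(self.F, "F"))
        _check_schedule(self.times)
        if self.F.shape != self.times.shape:
            raise DomainError("times and F must have equal length")
        check_time_unit(self.time_unit)

    def __len__(self) -> int:
        return self.times.size

    def clipped(self) -> "ProgressCurve":
        """Copy with F clipped to [0, 1] — for plotting, never for fitting."""
        return replace(self, F=np.clip(self.F, 0.0, 1.0))


@dataclass(frozen=True)
class CruciformTrajectory:
    """Fractional supercoiled (S), nicked (N) and linear (L) species over time.

    Rows are per-lane fractions; :meth:`renormalized` rescales each lane so
    S + N + L = 1, which is how raw gel intensities are reduced before
    fitting (lane-loading differences cancel in the ratio).
    """

    times: np.ndarray
    fS: np.ndarray
    fN: np.ndarray
    fL: np.ndarray
    time_unit: str = "min"
    truth: dict | None = None
    seed: int | None = None

    def __post_init__(self):
        for name in ("times", "fS", "fN", "fL"):
            object.__setattr__(self, name, _as_1d(getattr(self, name), name))
        _check_schedule(self.times)
        for name in ("fS", "fN", "fL"):
            if getattr(self, name).shape != self.times.shape:
                raise DomainError(f"{name} must match times in length")
        check_time_unit(self.time_unit)

    def __len__(self) -> int:
        return self.times.size

    @property
    def stacked(self) -> np.ndarray:
        """(3, n) array of [fS, fN, fL] rows."""
        return np.vstack([self.fS, self.fN, self.fL])

    def renormalized(self) -> "CruciformTrajectory":
        """Copy with each lane's (S, N, L) rescaled to sum to one."""
        total = self.fS + self.fN + self.fL
        if np.any(total <= 0):
            bad = int(np.flatnonzero(total <= 0)[0])
            raise DomainError(f"lane {bad} has nonpositive total intensity")
        return replace(self, fS=self.fS / total, fN=self.fN / total, fL=self.fL / total)


@dataclass(frozen=True)
class BindingTitration:
    """Gel-shift titration: fraction of junction bound vs. total protein.

    ``Pt`` is total protein concentration in nM under the declared
    ``stoichiometry`` convention (``"dimer"`` or ``"monomer"``); the package
    reports concentrations under that convention unchanged and never
    converts between the two implicitly.  ``Dt`` is total junction
    concentration in nM.
    """

    Pt: np.ndarray
    fb: np.ndarray
    Dt: float
    stoichiometry: str = "dimer"
    truth: dict | None = None
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "Pt", _as_1d(self.Pt, "Pt"))
        object.__setattr__(self, "fb", _as_1d(self.fb, "fb"))
        if self.fb.shape != self.Pt.shape:
            raise DomainError("Pt and fb must have equal length")
        if np.any(self.Pt < 0):
            raise DomainError("Pt must be nonnegative")
        if self.Pt.size > 1 and np.any(np.diff(self.Pt) <= 0):
            bad = int(np.flatnonzero(np.diff(self.Pt) <= 0)[0]) + 1
            raise DomainError(f"Pt must be strictly increasing (violated at row {bad})")
        if not float(self.Dt) > 0:
            raise DomainError("Dt must be positive")
        object.__setattr__(self, "Dt", float(self.Dt))
        if np.any((self.fb < 0) | (self.fb > 1)):
            bad = int(np.flatnonzero((self.fb < 0) | (self.fb > 1))[0])
            raise DomainError(f"fb must lie in [0, 1] (violated at row {bad})")
        if self.stoichiometry not in ("dimer", "monomer"):
            raise DomainError("stoichiometry must be 'dimer' or 'monomer'")

    def __len__(self) -> int:
        return self.Pt.size
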