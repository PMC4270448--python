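"""Dimer-stoichiometry mixing model.

A resolvase that binds its junction as a dimer gives a diagnostic band
pattern when two protein variants of different size — the native protein
(A) and a size-shifted fusion (B) — are mixed: three retarded complexes
(AA, AB, BB) of decreasing mobility.  Under the assumption that subunits
assort independently into the bound dimer, the complex fractions follow the
binomial law

    fAA = p²,   fAB = 2p(1 − p),   fBB = (1 − p)²,

with effective A-subunit fraction p = [A] / ([A] + ρ·[B]).  The single
parameter ρ captures non-equivalent incorporation of the fusion (ρ < 1:
fusion incorporated less readily, e.g. a bulky tag lowering affinity);
ρ = 1 means the variants are equivalent.  A monomeric binder would give at
most two bands, so observation of all three with fAB maximal near
equimolar mixing is the signature of a dimer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["DimerMixture", "ComplexDistribution", "predict_complex_fractions"]


@dataclass(frozen=True)
class DimerMixture:
    """Mixing condition: concentrations of native (A) and fusion (B) variants.

    ``rho`` weights B's incorporation into complexes relative to A
    (dimensionless, > 0; 1 = equivalent).
    """

    conc_a: float
    conc_b: float
    rho: float = 1.0

    def __post_init__(self):
        if self.conc_a < 0 or self.conc_b < 0:
            raise DomainError("concentrations must be nonnegative")
        if self.conc_a == 0 and self.conc_b == 0:
            raise DomainError("at least one variant must be present")
        if not (self.rho > 0 and np.isfinite(self.rho)):
            raise DomainError(f"rho must be positive and finite, got {self.rho}")

    @property
    def p(self) -> float:
        """Effective fraction of A among incorporated subunits."""
        return self.conc_a / (self.conc_a + self.rho * self.conc_b)


@dataclass(frozen=True)
class ComplexDistribution:
    """Fractions of the three dimer complexes; fAA + fAB + fBB = 1."""

    fAA: float
    fAB: float
    fBB: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.fAA, self.fAB, self.fBB)


def predict_complex_fractions(mix: DimerMixture) -> ComplexDistribution:
    """Binomial prediction of the three-band pattern for a dimeric binder.

    With p = conc_a / (conc_a + rho·conc_b), returns (p², 2p(1−p), (1−p)²).
    fAB is maximal at p = 1/2; a single variant gives a single band.
    """
    p = mix.p
    return ComplexDistribution(fAA=p * p, fAB=2.0 * p * (1.0 - p), fBB=(1.0 - p) ** 2)
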