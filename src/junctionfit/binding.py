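"""Equilibrium binding isotherms for gel-shift titrations.

Two models describe the fraction of junction bound, fb, as a function of
total protein concentration Pt at fixed total DNA Dt.

**Two-state binding with ligand depletion.**  At sub-nanomolar junction
concentrations comparable to the Kd, bound protein is a non-negligible
fraction of total, so the exact quadratic solution of the mass-action
equilibrium P + D ⇌ PD is required rather than the hyperbola:

    fb = [ (Kd + Pt + Dt) − sqrt((Kd + Pt + Dt)² − 4·Pt·Dt) ] / (2·Dt).

Only the minus branch is physical (fb → 0 as Pt → 0; the plus branch
exceeds 1).  In the Dt → 0 limit this reduces to the familiar hyperbola
fb = Pt/(Pt + Kd).

**Hill cooperativity.**  Phenomenological cooperative binding,

    fb = Ptⁿ / (Ptⁿ + K_app),

with Hill coefficient n.  Note the denominator constant is K_app, not
K_appⁿ, so its units depend on n (concentrationⁿ); the half-saturation
concentration is K_app^(1/n), exposed by :func:`hill_half_saturation`.
n > 1 indicates cooperative assembly (here, of a protein dimer on the
junction).

Concentrations are in nM throughout; the monomer/dimer accounting of Pt is
a declared convention of the titration, never altered here.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError

__all__ = ["depletion_isotherm", "hill_isotherm", "hill_half_saturation"]


def depletion_isotherm(Kd: float, Pt, Dt: float):
    """Exact two-state bound fraction with ligand depletion.

    Parameters
    ----------
    Kd : float
        Dissociation constant (nM), ≥ 0.
    Pt : float or array_like
        Total protein concentration(s) (nM), ≥ 0.
    Dt : float
        Total DNA junction concentration (nM), > 0.

    Returns
    -------
    float or ndarray
        Bound fraction in [0, min(1, Pt/Dt)]; monotone nondecreasing in Pt.
    """
    if not (Kd >= 0 and np.isfinite(Kd)):
        raise DomainError(f"Kd must be nonnegative and finite, got {Kd}")
    if not (Dt > 0 and np.isfinite(Dt)):
        raise DomainError(f"Dt must be positive and finite, got {Dt}")
    P = np.asarray(Pt, dtype=float)
    if np.any(P < 0) or not np.all(np.isfinite(P)):
        raise DomainError("Pt must be nonnegative and finite")
    b = Kd + P + Dt
    disc = b * b - 4.0 * P * Dt
    # Analytically disc = (Kd + (P - Dt))^2 + 4*Kd*Dt >= 0; clamp rounding.
    disc = np.maximum(disc, 0.0)
    root = np.sqrt(disc)
    # Compensated minus-branch quadratic: b - root loses precision when
    # 4*P*Dt << b^2, so use (b - root)/(2*Dt) = 2*P/(b + root) exactly.
    fb = 2.0 * P / (b + root)
    out = np.clip(fb, 0.0, 1.0)
    return float(out) if np.ndim(Pt) == 0 else out


def hill_isotherm(K_app: float, n: float, Pt):
    """Hill bound fraction fb = Ptⁿ / (Ptⁿ + K_app), exactly as written.

    ``K_app`` carries units of nMⁿ; the half-saturation concentration is
    K_app^(1/n) (see :func:`hill_half_saturation`).
    """
    if not (K_app > 0 and np.isfinite(K_app)):
        raise DomainError(f"K_app must be positive and finite, got {K_app}")
    if not (n > 0 and np.isfinite(n)):
        raise DomainError(f"Hill coefficient n must be positive, got {n}")
    P = np.asarray(Pt, dtype=float)
    if np.any(P < 0) or not np.all(np.isfinite(P)):
        raise DomainError("Pt must be nonnegative and finite")
    Pn = np.power(P, n)
    out = Pn / (Pn + K_app)
    return float(out) if np.ndim(Pt) == 0 else out


def hill_half_saturation(K_app: float, n: float) -> float:
    """Protein concentration at fb = 1/2 for the Hill model: K_app^(1/n)."""
    if not (K_app > 0 and n > 0):
        raise DomainError("K_app and n must be positive")
    return float(K_app ** (1.0 / n))
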