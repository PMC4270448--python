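"""Nonlinear least-squares models for the three gel-assay experiment types.

The public surface follows the statsmodels convention: a model object is
built from a data container, ``fit()`` returns a results object carrying
point estimates, standard errors, diagnostics and a ``summary()`` table,
and resampling (``bootstrap_ci``) and plotting hang off the results.

    >>> curve = simulate_cleavage_course(Ff=1.0, kc=0.008, noise_sd=0)
    >>> res = CleavageModel(curve).fit()
    >>> res.kc
    0.008

All models share one fitting engine: parameters are estimated on the log
scale (positivity by construction, and rate constants are scale
parameters), optimization uses scipy's trust-region-reflective least
squares from a deterministic, data-driven initial guess plus a fixed
schedule of multiplicative restarts (×/÷10, ×/÷√10 on rate-like
parameters) with the best residual sum of squares winning.  Standard
errors come from the Jacobian at the optimum (delta method back to the
natural scale); percentile intervals from a seeded residual-resampling
bootstrap.  Model comparison uses the small-sample-corrected Akaike
criterion on the Gaussian RSS likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .binding import depletion_isotherm, hill_half_saturation, hill_isotherm
from .containers import BindingTitration, CruciformTrajectory, ProgressCurve
from .errors import (
    DomainError,
    FitConvergenceError,
    NoSignalError,
    UnidentifiableError,
)
from .kinetics import CruciformRates, cruciform_fractions
from .units import convert_rate

__all__ = [
    "CleavageModel",
    "CruciformModel",
    "BindingModel",
    "NLSResults",
    "ModelComparison",
    "fit_exponential",
    "fit_cruciform",
    "fit_binding",
    "bootstrap_ci",
    "compare_models",
    "aicc",
]

#: Deterministic multistart schedule: multiplicative perturbations applied
#: to rate-like parameters (amplitudes are left at their data-driven start).
_RESTART_FACTORS = (1.0, 10.0, 0.1, math.sqrt(10.0), 1.0 / math.sqrt(10.0))


def aicc(rss: float, n: int, p: int) -> float:
    """Small-sample-corrected Akaike criterion for a Gaussian RSS fit.

    ``p`` model parameters plus the noise variance give k = p + 1.
    Returns +inf when the correction is undefined (n ≤ k + 1).
    """
    k = p + 1
    if n - k - 1 <= 0:
        return math.inf
    rss = max(float(rss), 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# ----------------------------------------------------------------------
# results


class NLSResults:
    """Estimates, uncertainties and diagnostics from a nonlinear LS fit.

    Attributes
    ----------
    params : dict[str, float]
        Point estimates on the natural scale.
    bse : dict[str, float]
        Asymptotic standard errors (Jacobian/delta method).
    rss : float
        Residual sum of squares at the optimum.
    nobs : int
        Number of observations entering the fit.
    aicc : float
        Small-sample-corrected information criterion.
    converged : bool
        Optimizer termination status.
    conf_int : dict[str, tuple] | None
        Bootstrap percentile intervals, after :meth:`bootstrap_ci`.
    """

    def __init__(self, model, params, bse, rss, converged, method="joint"):
        self.model = model
        self.params = dict(zip(model.param_names, (float(v) for v in params)))
        self.bse = dict(zip(model.param_names, (float(v) for v in bse)))
        self.rss = float(rss)
        self.nobs = int(model.nobs)
        self.nparams = len(model.param_names)
        self.converged = bool(converged)
        self.method = method
        self.aicc = aicc(self.rss, self.nobs, self.nparams)
        self.conf_int: dict[str, tuple[float, float]] | None = None
        self.boot_seed: int | None = None
        self.boot_nonconverged_frac: float | None = None
        self.boot_warning: str | None = None

    @property
    def _theta(self) -> np.ndarray:
        return np.array([self.params[k] for k in self.model.param_names])

    def predict(self, x=None) -> np.ndarray:
        """Fitted model curve at the data grid (or at ``x``)."""
        return self.model.predict(self._theta, x)

    def resid(self) -> np.ndarray:
        return self.model.observed - self.model.predict(self._theta)

    def bootstrap_ci(self, n_boot: int = 1000, seed: int | None = None,
                     alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """Residual-resampling bootstrap percentile intervals.

        Deterministic under ``seed`` (PCG64 generator).  Refits start from
        the point estimate; if more than 20% of replicates fail to
        converge a warning is recorded on the results object.
        """
        if n_boot < 100:
            raise DomainError("n_boot must be at least 100")
        rng = np.random.default_rng(seed)
        yhat = self.model.predict(self._theta)
        resid = self.model.observed - yhat
        n = resid.size
        draws, failures = [], 0
        for _ in range(n_boot):
            y_star = yhat + resid[rng.integers(0, n, n)]
            try:
                theta_b = self.model._solve(y_star, self._theta, restarts=False)
                draws.append(theta_b)
            except FitConvergenceError:
                failures += 1
        if not draws:
            raise FitConvergenceError("all bootstrap replicates failed to converge")
        draws = np.array(draws)
        lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
        self.conf_int = {
            name: (float(np.percentile(draws[:, j], lo)),
                   float(np.percentile(draws[:, j], hi)))
            for j, name in enumerate(self.model.param_names)
        }
        self.boot_seed = seed
        self.boot_nonconverged_frac = failures / n_boot
        if self.boot_nonconverged_frac > 0.20:
            self.boot_warning = (
                f"{failures}/{n_boot} bootstrap refits failed to converge"
            )
        return self.conf_int

    def summary(self) -> str:
        """Plain-text summary table."""
        lines = [
            f"{type(self).__name__}: {self.model.description}",
            f"  method: {self.method} least squares   nobs: {self.nobs}",
            f"  RSS: {self.rss:.6g}   AICc: {self.aicc:.4g}   "
            f"converged: {self.converged}",
            f"  {'parameter':<14}{'estimate':>12}{'std err':>12}"
            + ("{:>26}".format("bootstrap 95% CI") if self.conf_int else ""),
        ]
        for name in self.model.param_names:
            row = f"  {name:<14}{self.params[name]:>12.6g}{self.bse[name]:>12.3g}"
            if self.conf_int:
                lo, hi = self.conf_int[name]
                row += f"   [{lo:.6g}, {hi:.6g}]"
            lines.append(row)
        if self.boot_warning:
            lines.append(f"  warning: {self.boot_warning}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data (clipped to [0,1] for display) with the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        self.model._plot(self, ax)
        return ax

    def to_dict(self) -> dict:
        """JSON-serializable record of the fit."""
        out = {
            "model": self.model.description,
            "method": self.method,
            "params": self.params,
            "bse": self.bse,
            "rss": self.rss,
            "nobs": self.nobs,
            "aicc": self.aicc,
            "converged": self.converged,
        }
        if self.conf_int is not None:
            out["conf_int"] = {k: list(v) for k, v in self.conf_int.items()}
            out["bootstrap_seed"] = self.boot_seed
            out["bootstrap_nonconverged_frac"] = self.boot_nonconverged_frac
        if self.boot_warning:
            out["warning"] = self.boot_warning
        return out


class CleavageResults(NLSResults):
    @property
    def Ff(self) -> float:
        return self.params["Ff"]

    @property
    def kc(self) -> float:
        return self.params["kc"]

    @property
    def time_unit(self) -> str:
        return self.model.time_unit

    def kc_in(self, unit: str) -> float:
        """Cleavage rate converted to another reciprocal time unit."""
        return convert_rate(self.kc, self.time_unit, unit)


class CruciformResults(NLSResults):
    @property
    def k1(self) -> float:
        return self.params["k1"]

    @property
    def k2(self) -> float:
        return self.params["k2"]

    @property
    def acceleration(self) -> float:
        """Second-strand acceleration factor k2/k1."""
        return self.k2 / self.k1

    @property
    def rates(self) -> CruciformRates:
        return CruciformRates(self.k1, self.k2, time_unit=self.model.time_unit)


class BindingResults(NLSResults):
    @property
    def Kd(self) -> float:
        if "Kd" not in self.params:
            raise AttributeError("Kd is defined only for the two-state model")
        return self.params["Kd"]

    @property
    def K_app(self) -> float:
        if "K_app" not in self.params:
            raise AttributeError("K_app is defined only for the Hill model")
        return self.params["K_app"]

    @property
    def n(self) -> float:
        if "n" not in self.params:
            raise AttributeError("n is defined only for the Hill model")
        return self.params["n"]

    @property
    def half_saturation(self) -> float:
        """Protein concentration at half-maximal binding (nM)."""
        if "Kd" in self.params:
            # depletion model: fb = 1/2 when free protein equals Kd
            return self.params["Kd"] + 0.5 * self.model.Dt
        return hill_half_saturation(self.K_app, self.n)


# ----------------------------------------------------------------------
# models


class _CurveModel:
    """Shared engine: log-scale trust-region LS with deterministic restarts."""

    param_names: tuple[str, ...] = ()
    #: mask of parameters that receive the ×/÷10 restart perturbations
    rate_like: tuple[bool, ...] = ()
    #: upper bounds on the log scale (None = unbounded)
    log_upper: tuple[float | None, ...] = ()
    results_class = NLSResults
    description = "nonlinear least squares"

    observed: np.ndarray  # stacked observation vector
    nobs: int
    time_unit: str = "s"

    def predict(self, theta: np.ndarray, x=None) -> np.ndarray:
        raise NotImplementedError

    def _start(self) -> np.ndarray:
        raise NotImplementedError

    # -- engine --

    def _solve(self, y: np.ndarray, start: np.ndarray,
               restarts: bool = True) -> np.ndarray:
        """Minimize ||y − predict(θ)|| over log θ; returns natural θ."""
        ub = np.array([math.inf if u is None else u for u in self.log_upper])
        lb = np.full_like(ub, -math.inf)
        starts = [np.asarray(start, dtype=float)]
        if restarts:
            mask = np.asarray(self.rate_like)
            for f in _RESTART_FACTORS[1:]:
                s = starts[0].copy()
                s[mask] *= f
                starts.append(s)
        best = None
        diagnostics = []
        for s in starts:
            x0 = np.clip(np.log(s), lb + 1e-9, ub)
            try:
                sol = least_squares(
                    lambda lt: y - self.predict(np.exp(lt)),
                    x0, bounds=(lb, ub), method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception as exc:  # pragma: no cover - defensive
                diagnostics.append(str(exc))
                continue
            if sol.status > 0 and (best is None or sol.cost < best.cost):
                best = sol
            elif sol.status <= 0:
                diagnostics.append(sol.message)
        if best is None:
            raise FitConvergenceError(
                "optimizer failed to converge from all restarts",
                {"messages": diagnostics},
            )
        return np.exp(best.x)

    def fit(self, start=None) -> NLSResults:
        """Estimate parameters; ``start`` overrides the data-driven guess."""
        theta0 = np.asarray(start, dtype=float) if start is not None else self._start()
        if theta0.shape != (len(self.param_names),) or np.any(theta0 <= 0):
            raise DomainError("start must be positive, one value per parameter")
        theta = self._solve(self.observed, theta0, restarts=True)
        theta = self._canonicalize(theta)
        resid = self.observed - self.predict(theta)
        rss = float(resid @ resid)
        bse = self._standard_errors(theta, rss)
        return self.results_class(self, theta, bse, rss, converged=True)

    def _canonicalize(self, theta: np.ndarray) -> np.ndarray:
        return theta

    def _standard_errors(self, theta: np.ndarray, rss: float) -> np.ndarray:
        # finite-difference Jacobian w.r.t. log-params; delta method to natural
        n, p = self.nobs, len(theta)
        if n <= p:
            return np.full(p, np.nan)
        J = np.empty((n, p))
        log_t = np.log(theta)
        h = 1e-6
        for j in range(p):
            up, dn = log_t.copy(), log_t.copy()
            up[j] += h
            dn[j] -= h
            J[:, j] = (self.predict(np.exp(up)) - self.predict(np.exp(dn))) / (2 * h)
        s2 = rss / (n - p)
        try:
            cov_log = s2 * np.linalg.pinv(J.T @ J)
        except np.linalg.LinAlgError:  # pragma: no cover
            return np.full(p, np.nan)
        se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
        return theta * se_log

    def _plot(self, results: NLSResults, ax):  # pragma: no cover - visual
        raise NotImplementedError


class CleavageModel(_CurveModel):
    """Single-exponential fit of a strand-cleavage progress curve.

    Estimates the cleavage rate ``kc`` and final amplitude ``Ff`` of
    F(t) = Ff·(1 − exp(−kc·t)) by unweighted least squares.  Requires at
    least four time points with a nonzero signal.
    """

    param_names = ("Ff", "kc")
    rate_like = (False, True)
    log_upper = (0.0, None)  # Ff ≤ 1
    results_class = CleavageResults
    description = "single-exponential cleavage progress"

    def __init__(self, curve: ProgressCurve):
        if not isinstance(curve, ProgressCurve):
            raise DomainError("CleavageModel requires a ProgressCurve")
        if len(curve) < 4:
            raise DomainError("need at least 4 time points")
        if not np.any(curve.F != 0):
            raise NoSignalError("all cleavage fractions are zero")
        if np.ptp(curve.F) < 1e-12:
            raise NoSignalError("flat progress curve carries no rate information")
        self.curve = curve
        self.times = curve.times
        self.observed = curve.F
        self.nobs = len(curve)
        self.time_unit = curve.time_unit

    def predict(self, theta, x=None):
        Ff, kc = theta
        t = self.times if x is None else np.asarray(x, dtype=float)
        return -Ff * np.expm1(-kc * t)

    def _start(self):
        t, F = self.times, self.observed
        Ff0 = float(np.clip(np.max(F), 0.05, 1.0))
        # log-linear guess: −ln(1 − F/Fcap) grows ∝ kc·t
        Fcap = min(1.0, Ff0 * 1.05) + 1e-9
        ratio = np.clip(F / Fcap, 0.0, 0.999)
        mask = (t > 0) & (ratio > 1e-3)
        if mask.sum() >= 2:
            y = -np.log1p(-ratio[mask])
            kc0 = float(np.sum(y * t[mask]) / np.sum(t[mask] ** 2))
        else:
            kc0 = 0.0
        if not (kc0 > 0 and np.isfinite(kc0)):
            kc0 = 1.0 / max(np.median(t[t > 0]), 1e-12)
        return np.array([Ff0, kc0])

    def _plot(self, results, ax):  # pragma: no cover - visual
        tg = np.linspace(0, self.times[-1], 200)
        ax.plot(self.times, np.clip(self.observed, 0, 1), "o", label="data")
        ax.plot(tg, results.predict(tg), "-", label="fit")
        ax.set_xlabel(f"time ({self.time_unit})")
        ax.set_ylabel("fraction cleaved")
        ax.legend()


class CruciformModel(_CurveModel):
    """Joint fit of the consecutive-cleavage scheme to an S/N/L time course.

    Residuals over all three species are minimized simultaneously
    (``mode="joint"``, default); ``mode="sequential"`` first fits k1 to the
    supercoiled decay alone and then k2 to the nicked trace with k1 held.
    Per-lane intensities are renormalized to fractions before fitting.
    The supercoiled trace decays as exp(−k1·t) and thereby pins which rate
    is k1, so the fit is free of the A→B→C label-swap ambiguity.
    """

    param_names = ("k1", "k2")
    rate_like = (True, True)
    log_upper = (None, None)
    results_class = CruciformResults
    description = "consecutive cruciform cleavage (S→N→L)"

    def __init__(self, traj: CruciformTrajectory, renormalize: bool = True,
                 mode: str = "joint"):
        if not isinstance(traj, CruciformTrajectory):
            raise DomainError("CruciformModel requires a CruciformTrajectory")
        if len(traj) < 5:
            raise DomainError("need at least 5 time points")
        if mode not in ("joint", "sequential"):
            raise DomainError("mode must be 'joint' or 'sequential'")
        self.traj = traj.renormalized() if renormalize else traj
        self.mode = mode
        self.times = self.traj.times
        self.observed = np.concatenate(
            [self.traj.fS, self.traj.fN, self.traj.fL]
        )
        self.nobs = self.observed.size
        self.time_unit = traj.time_unit

    def predict(self, theta, x=None):
        k1, k2 = theta
        t = self.times if x is None else np.asarray(x, dtype=float)
        st = cruciform_fractions(CruciformRates(k1, k2, self.time_unit), t)
        return np.concatenate([st.fS, st.fN, st.fL])

    def _start(self):
        t, fS, fN = self.times, self.traj.fS, self.traj.fN
        mask = (t > 0) & (fS > 1e-3)
        if mask.sum() >= 2:
            k10 = float(-np.sum(np.log(fS[mask]) * t[mask]) / np.sum(t[mask] ** 2))
        else:
            k10 = 0.0
        if not (k10 > 0 and np.isfinite(k10)):
            k10 = 1.0 / max(float(np.median(t[t > 0])), 1e-12)
        k20 = self._k2_from_peak(k10)
        return np.array([k10, k20])

    def _k2_from_peak(self, k1: float) -> float:
        """Invert the nicked-peak time t* = ln(k2/k1)/(k2−k1) for k2."""
        from scipy.optimize import brentq

        i_pk = int(np.argmax(self.traj.fN))
        t_pk = float(self.times[i_pk])
        if t_pk <= 0:
            return 3.0 * k1
        g = lambda k2: math.log(k2 / k1) - t_pk * (k2 - k1)
        try:
            if t_pk < 1.0 / k1:  # peak earlier than 1/k1 → k2 > k1
                return brentq(g, k1 * (1 + 1e-9), k1 * 1e6, xtol=1e-12 * k1)
            if t_pk > 1.0 / k1:  # late peak → k2 < k1
                return brentq(g, k1 * 1e-6, k1 * (1 - 1e-9), xtol=1e-12 * k1)
        except ValueError:
            pass
        return k1

    def fit(self, start=None) -> CruciformResults:
        if self.mode == "sequential":
            return self._fit_sequential()
        return super().fit(start=start)

    def _fit_sequential(self) -> CruciformResults:
        t = self.times
        fS, fN = self.traj.fS, self.traj.fN
        k10 = self._start()[0]
        solS = least_squares(
            lambda lk: fS - np.exp(-np.exp(lk) * t), math.log(k10),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if solS.status <= 0:
            raise FitConvergenceError("sequential k1 stage failed", {"message": solS.message})
        k1 = float(np.exp(solS.x[0]))

        def nicked(k2):
            return cruciform_fractions(
                CruciformRates(k1, k2, self.time_unit), t
            ).fN

        k20 = self._k2_from_peak(k1)
        solN = least_squares(
            lambda lk: fN - nicked(float(np.exp(lk[0]))), math.log(k20),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if solN.status <= 0:
            raise FitConvergenceError("sequential k2 stage failed", {"message": solN.message})
        theta = np.array([k1, float(np.exp(solN.x[0]))])
        resid = self.observed - self.predict(theta)
        rss = float(resid @ resid)
        bse = self._standard_errors(theta, rss)
        return CruciformResults(self, theta, bse, rss, converged=True,
                                method="sequential")

    def _plot(self, results, ax):  # pragma: no cover - visual
        tg = np.linspace(0, self.times[-1], 300)
        pred = results.predict(tg).reshape(3, -1)
        for obs, line, label in zip(
            (self.traj.fS, self.traj.fN, self.traj.fL), pred,
            ("supercoiled", "nicked", "linear"),
        ):
            (pts,) = ax.plot(self.times, np.clip(obs, 0, 1), "o", label=label)
            ax.plot(tg, line, "-", color=pts.get_color())
        ax.set_xlabel(f"time ({self.time_unit})")
        ax.set_ylabel("fraction of plasmid")
        ax.legend()


class BindingModel(_CurveModel):
    """Equilibrium junction-binding fit: depletion two-state or Hill.

    ``model="two_state"`` fits the exact quadratic ligand-depletion
    isotherm for Kd at the titration's known DNA concentration;
    ``model="hill"`` fits the cooperative Hill form for (K_app, n).
    Titrations with no transition (all bound or all free) are rejected as
    unidentifiable rather than fitted.
    """

    results_class = BindingResults

    def __init__(self, titration: BindingTitration, model: str = "two_state"):
        if not isinstance(titration, BindingTitration):
            raise DomainError("BindingModel requires a BindingTitration")
        if len(titration) < 5:
            raise DomainError("need at least 5 protein concentrations")
        if model not in ("two_state", "hill"):
            raise DomainError("model must be 'two_state' or 'hill'")
        fb = titration.fb
        if np.max(fb) < 0.05:
            raise UnidentifiableError("titration shows no binding (all free)")
        if np.min(fb) > 0.95:
            raise UnidentifiableError("titration is saturated throughout (all bound)")
        if np.ptp(fb) < 0.05:
            raise UnidentifiableError("titration spans no binding transition")
        self.titration = titration
        self.model_name = model
        self.Dt = titration.Dt
        self.Pt = titration.Pt
        self.observed = fb
        self.nobs = len(titration)
        if model == "two_state":
            self.param_names = ("Kd",)
            self.rate_like = (True,)
            self.log_upper = (None,)
            self.description = "two-state binding with ligand depletion"
        else:
            self.param_names = ("K_app", "n")
            self.rate_like = (True, False)
            self.log_upper = (None, None)
            self.description = "Hill cooperative binding"

    def predict(self, theta, x=None):
        P = self.Pt if x is None else np.asarray(x, dtype=float)
        if self.model_name == "two_state":
            return depletion_isotherm(float(theta[0]), P, self.Dt)
        return hill_isotherm(float(theta[0]), float(theta[1]), P)

    def _half_saturation_guess(self) -> float:
        P, fb = self.Pt, self.observed
        target = 0.5 * (np.min(fb) + np.max(fb))
        above = np.flatnonzero(fb >= target)
        if above.size == 0 or above[0] == 0:
            return float(max(np.median(P[P > 0]), 1e-6))
        i = above[0]
        # linear interpolation in log concentration across the crossing
        p0, p1 = P[i - 1], P[i]
        f0, f1 = fb[i - 1], fb[i]
        if p0 <= 0 or f1 == f0:
            return float(p1)
        w = (target - f0) / (f1 - f0)
        return float(np.exp((1 - w) * np.log(p0) + w * np.log(p1)))

    def _start(self):
        p_half = self._half_saturation_guess()
        if self.model_name == "two_state":
            kd0 = max(p_half - 0.5 * self.Dt, 1e-6)
            return np.array([kd0])
        return np.array([p_half, 1.0])  # K_app = p_half^n with n0 = 1

    def _plot(self, results, ax):  # pragma: no cover - visual
        pg = np.geomspace(max(self.Pt[self.Pt > 0].min() / 2, 1e-6),
                          self.Pt.max() * 2, 200)
        ax.semilogx(self.Pt, self.observed, "o", label="data")
        ax.semilogx(pg, results.predict(pg), "-", label=self.description)
        ax.set_xlabel("protein (nM)")
        ax.set_ylabel("fraction bound")
        ax.legend()


# ----------------------------------------------------------------------
# model comparison


@dataclass(frozen=True)
class ModelComparison:
    """Relative support for two fits of the same data.

    ``delta_rss`` and ``delta_aicc`` are (A − B); ``preferred`` names the
    fit with the lower information criterion ("A", "B" or "tie").  The
    criterion expresses parsimony-penalized relative support only — it is
    not a significance test.
    """

    name_a: str
    name_b: str
    rss_a: float
    rss_b: float
    delta_rss: float
    aicc_a: float
    aicc_b: float
    delta_aicc: float
    preferred: str

    def to_dict(self) -> dict:
        return {
            "model_a": self.name_a, "model_b": self.name_b,
            "rss_a": self.rss_a, "rss_b": self.rss_b,
            "delta_rss": self.delta_rss,
            "aicc_a": self.aicc_a, "aicc_b": self.aicc_b,
            "delta_aicc": self.delta_aicc, "preferred": self.preferred,
        }


def compare_models(result_a: NLSResults, result_b: NLSResults) -> ModelComparison:
    """Compare two fits of identical data by ΔRSS and ΔAICc."""
    ma, mb = result_a.model, result_b.model
    if ma.nobs != mb.nobs or not np.array_equal(ma.observed, mb.observed):
        raise DomainError("fits being compared must share identical data")
    d_aicc = result_a.aicc - result_b.aicc
    if abs(d_aicc) < 1e-9:
        preferred = "tie"
    else:
        preferred = "A" if d_aicc < 0 else "B"
    return ModelComparison(
        name_a=ma.description, name_b=mb.description,
        rss_a=result_a.rss, rss_b=result_b.rss,
        delta_rss=result_a.rss - result_b.rss,
        aicc_a=result_a.aicc, aicc_b=result_b.aicc,
        delta_aicc=d_aicc, preferred=preferred,
    )


# ----------------------------------------------------------------------
# functional wrappers


def fit_exponential(curve: ProgressCurve) -> CleavageResults:
    """Fit F(t) = Ff·(1 − exp(−kc·t)) to a cleavage progress curve."""
    return CleavageModel(curve).fit()


def fit_cruciform(traj: CruciformTrajectory, mode: str = "joint",
                  start=None) -> CruciformResults:
    """Fit the consecutive-cleavage scheme to an S/N/L time course."""
    return CruciformModel(traj, mode=mode).fit(start=start)


def fit_binding(titration: BindingTitration, model: str = "two_state") -> BindingResults:
    """Fit a binding isotherm (two_state depletion or hill) to a titration."""
    return BindingModel(titration, model=model).fit()


def bootstrap_ci(results: NLSResults, n_boot: int = 1000,
                 seed: int | None = None) -> dict[str, tuple[float, float]]:
    """Convenience wrapper for :meth:`NLSResults.bootstrap_ci`."""
    return results.bootstrap_ci(n_boot=n_boot, seed=seed)
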