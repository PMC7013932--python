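"""Closed-form second-order reversible binding kinetics.

The model is the mass-action scheme E + B <=> C with association rate
constant ``k1`` and dissociation rate constant ``k_minus1``, started from
equal free concentrations ``[E](0) = [B](0) = E0`` and no complex.  Free
concentration then obeys

    d[E]/dt = -k1 [E]^2 + k_minus1 (E0 - [E])

whose solution is a ratio of exponentials in ``exp(-2 k1 k t)`` with

    k = sqrt(k_minus1^2 + 4 k1 k_minus1 E0) / (2 k1),
    a = k_minus1 / (2 k1),

satisfying the identity ``k^2 - a^2 = 2 a E0``.  Rate constants are kept
unitless: trajectory ensembles from coarse-grained simulations have a
distorted internal clock, so only ratios such as ``K_D = k_minus1/k1``
carry meaning across systems.

Fitting is nonlinear least squares over ``(log k1, log k_minus1)`` with
``E0`` held fixed, so positivity is structural rather than enforced by
bounds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "KineticsParams",
    "ConcentrationSeries",
    "KineticsFit",
    "compute_k",
    "free_concentration",
    "free_concentration_printed",
    "equilibrium_free_concentration",
    "integrate_binding_ode",
    "fit_second_order_kinetics",
    "dissociation_constant",
    "affinity_ratio",
]


@dataclass(frozen=True)
class KineticsParams:
    """Rate constants of the reversible bimolecular scheme (unitless)."""

    k1: float
    k_minus1: float
    E0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k1 > 0):
            raise ValueError(f"k1 must be positive, got {self.k1}")
        if self.k_minus1 < 0:
            raise ValueError(f"k_minus1 must be non-negative, got {self.k_minus1}")
        if not (self.E0 > 0):
            raise ValueError(f"E0 must be positive, got {self.E0}")


@dataclass
class ConcentrationSeries:
    """Free (unbound) concentration sampled on a time grid."""

    times: np.ndarray
    values: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    @classmethod
    def from_tsv(cls, path) -> "ConcentrationSeries":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame({"time": self.times, "fraction": self.values}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class KineticsFit:
    """Result of fitting the closed-form model to a concentration series."""

    params: KineticsParams
    k_d: float
    rss: float
    stderr_k1: float
    stderr_k_minus1: float
    converged: bool
    n_points: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "k1": self.params.k1,
                    "k_minus1": self.params.k_minus1,
                    "E0": self.params.E0,
                    "K_D": self.k_d,
                    "rss": self.rss,
                    "stderr_k1": self.stderr_k1,
                    "stderr_k_minus1": self.stderr_k_minus1,
                    "converged": self.converged,
                    "n_points": self.n_points,
                },
                fh,
                indent=2,
            )


def compute_k(params: KineticsParams) -> float:
    """Auxiliary rate ``k = sqrt(k_minus1^2 + 4 k1 k_minus1 E0) / (2 k1)``.

    ``2 k1 k`` is the relaxation rate of the exponential in the closed form;
    ``k`` satisfies ``k^2 - a^2 = 2 a E0`` with ``a = k_minus1 / (2 k1)``.
    """
    return math.sqrt(
        params.k_minus1**2 + 4.0 * params.k1 * params.k_minus1 * params.E0
    ) / (2.0 * params.k1)


def equilibrium_free_concentration(params: KineticsParams) -> float:
    """Long-time free concentration: the non-negative root of
    ``k1 x^2 + k_minus1 x - k_minus1 E0 = 0``, equal to ``k - a``."""
    a = params.k_minus1 / (2.0 * params.k1)
    return compute_k(params) - a


def _as_time_array(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times are not allowed")
    return t


def free_concentration(params: KineticsParams, t):
    """Closed-form free concentration ``[E](t)``.

    Uses the partial-fraction (root) arrangement: with equilibrium roots
    ``r+ = k - a`` and ``r- = -(k + a)``,

        [E](t) = (r+ (E0 - r-) - r- (E0 - r+) q) / ((E0 - r-) - (E0 - r+) q),
        q = exp(-2 k1 k t).

    For ``k_minus1 = 0`` the scheme is irreversible and the limit
    ``E0 / (1 + k1 E0 t)`` is evaluated directly (the general form is 0/0).
    """
    t = _as_time_array(t)
    if params.k_minus1 == 0.0:
        return params.E0 / (1.0 + params.k1 * params.E0 * t)
    k = compute_k(params)
    a = params.k_minus1 / (2.0 * params.k1)
    r_plus = k - a
    r_minus = -(k + a)
    q = np.exp(-2.0 * params.k1 * k * t)
    num = r_plus * (params.E0 - r_minus) - r_minus * (params.E0 - r_plus) * q
    den = (params.E0 - r_minus) - (params.E0 - r_plus) * q
    return num / den


def free_concentration_printed(params: KineticsParams, t):
    """The same closed form in its alternative algebraic arrangement,

        [E](t) = E0 ((a + k) + (k - a) q) / ((E0 + a + k) - (E0 + a - k) q),

    kept as an independent arrangement; equal to :func:`free_concentration`
    pointwise (the equality rests on ``k^2 - a^2 = 2 a E0``).
    """
    t = _as_time_array(t)
    if params.k_minus1 == 0.0:
        return params.E0 / (1.0 + params.k1 * params.E0 * t)
    k = compute_k(params)
    a = params.k_minus1 / (2.0 * params.k1)
    q = np.exp(-2.0 * params.k1 * k * t)
    num = params.E0 * ((a + k) + (k - a) * q)
    den = (params.E0 + a + k) - (params.E0 + a - k) * q
    return num / den


def integrate_binding_ode(params: KineticsParams, time_grid) -> ConcentrationSeries:
    """Numerical solution of ``d[E]/dt = -k1 [E]^2 + k_minus1 (E0 - [E])``.

    Independent of the closed form; serves as its cross-check.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if np.any(np.diff(time_grid) < 0):
        raise ValueError("time grid must be non-decreasing")

    def rhs(_t, y):
        e = y[0]
        return [-params.k1 * e * e + params.k_minus1 * (params.E0 - e)]

    t0, t1 = float(time_grid[0]), float(time_grid[-1])
    if t1 == t0:
        values = np.full_like(time_grid, params.E0)
    else:
        sol = solve_ivp(
            rhs,
            (t0, t1),
            [params.E0],
            t_eval=time_grid,
            method="Radau",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        values = sol.y[0]
    return ConcentrationSeries(time_grid, values)


def dissociation_constant(k1: float, k_minus1: float) -> float:
    """Equilibrium dissociation constant ``K_D = k_minus1 / k1``."""
    if k1 <= 0:
        raise ValueError(f"k1 must be positive, got {k1}")
    return k_minus1 / k1


def affinity_ratio(kd_a: float, kd_b: float) -> float:
    """Affinity ratio ``kd_a / kd_b`` (how much more strongly B binds)."""
    if kd_b == 0:
        raise ZeroDivisionError("kd_b must be nonzero")
    return kd_a / kd_b


def _initial_guess(series: ConcentrationSeries, e0: float) -> tuple[float, float]:
    # k1 from the initial slope of the pure second-order term,
    # k_minus1 from the plateau via the equilibrium quadratic.
    t, v = series.times, series.values
    n_head = max(2, len(t) // 100)
    slope = np.polyfit(t[:n_head], v[:n_head], 1)[0]
    k1 = max(-slope / e0**2, 1e-8)
    x_eq = float(np.clip(np.mean(v[-max(2, len(v) // 10) :]), 1e-12, e0 * (1 - 1e-9)))
    k_minus1 = max(k1 * x_eq**2 / (e0 - x_eq), 1e-12)
    return k1, k_minus1


def fit_second_order_kinetics(
    series: ConcentrationSeries,
    init: tuple[float, float] | None = None,
    e0: float = 1.0,
) -> KineticsFit:
    """Fit ``(k1, k_minus1)`` of the closed form to an unbound-concentration
    series by least squares, with ``E0`` fixed.

    Positivity is enforced by optimizing over logarithms.  If the solver
    stalls from the slope/plateau initialization, a small multi-start over
    log-spaced ``k1`` values is tried; non-convergence is flagged on the
    result, never silent.
    """
    t = series.times
    v = series.values
    if len(t) < 5:
        raise ValueError("need at least 5 points to fit two rate constants")
    if np.ptp(v) == 0:
        raise ValueError("series has zero variance; rate constants unidentifiable")
    if np.any(v < -1e-9) or np.any(v > e0 * (1 + 1e-9)):
        raise ValueError("values must lie within [0, E0]")

    def residuals(log_params):
        lp = np.clip(log_params, -250.0, 250.0)  # keep exp finite on wild steps
        p = KineticsParams(math.exp(lp[0]), math.exp(lp[1]), e0)
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            r = free_concentration(p, t) - v
        r = np.where(np.isfinite(r), r, 1e6)
        if series.weights is not None:
            r = r * series.weights
        return r

    starts = [init if init is not None else _initial_guess(series, e0)]
    starts += [(k1s, starts[0][1]) for k1s in np.logspace(-3, 4, 8)]

    def solve_from(k1_0, km1_0):
        sol = least_squares(
            residuals,
            x0=[math.log(k1_0), math.log(km1_0)],
            method="lm",
            xtol=1e-14,
            ftol=1e-14,
        )
        return sol, float(np.sum(sol.fun**2))

    # the surface has flat ridges (e.g. k_minus1 -> inf gives a constant
    # model), so the slope/plateau start is backed by a log-spaced
    # multi-start over k1 and the lowest-RSS solution wins
    sol, rss = solve_from(*starts[0])
    for k1_0, km1_0 in starts[1:]:
        cand, cand_rss = solve_from(k1_0, km1_0)
        if cand_rss < rss:
            sol, rss = cand, cand_rss

    k1 = math.exp(sol.x[0])
    k_minus1 = math.exp(sol.x[1])
    # delta-method standard errors back on the natural scale
    dof = max(len(t) - 2, 1)
    jtj = sol.jac.T @ sol.jac
    try:
        cov_log = np.linalg.inv(jtj) * rss / dof
        se_k1 = k1 * math.sqrt(max(cov_log[0, 0], 0.0))
        se_km1 = k_minus1 * math.sqrt(max(cov_log[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se_k1 = se_km1 = float("nan")
    params = KineticsParams(k1, k_minus1, e0)
    return KineticsFit(
        params=params,
        k_d=dissociation_constant(k1, k_minus1),
        rss=rss,
        stderr_k1=se_k1,
        stderr_k_minus1=se_km1,
        converged=bool(sol.success),
        n_points=len(t),
    )
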