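"""1:1 Langmuir SPR kinetics: simulation and global fitting.

A surface-immobilized ligand binds a single analyte reversibly,

    dR/dt = ka * C * (Rmax - R) - kd * R,

giving the usual biexponential sensorgram: during injection of analyte at
concentration C the response rises toward the plateau
``C ka Rmax / (C ka + kd)`` with observed rate ``C ka + kd``; after the
injection stops the response decays as ``exp(-kd t)``.  A single
``(ka, kd, Rmax)`` triple is fitted jointly across all curves (global
fit), which is what makes ka and kd separately identifiable.

Mass-transport limitation, baseline drift and bulk refractive-index jumps
are not modeled; curves are assumed reference-subtracted upstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram",
    "LangmuirParams",
    "LangmuirFit",
    "simulate_langmuir",
    "langmuir_response",
    "fit_langmuir_global",
]


@dataclass(frozen=True)
class LangmuirParams:
    """1:1 interaction constants: ka (1/(M s)), kd (1/s), Rmax (RU)."""

    ka: float
    kd: float
    rmax: float

    def __post_init__(self) -> None:
        if not (self.ka > 0):
            raise ValueError(f"ka must be positive, got {self.ka}")
        if self.kd < 0:
            raise ValueError(f"kd must be non-negative, got {self.kd}")
        if not (self.rmax > 0):
            raise ValueError(f"Rmax must be positive, got {self.rmax}")

    @property
    def k_d(self) -> float:
        """Equilibrium dissociation constant kd/ka (M)."""
        return self.kd / self.ka


@dataclass
class Sensorgram:
    """One SPR curve: response vs time at one analyte concentration."""

    times: np.ndarray  # s
    response: np.ndarray  # RU
    analyte_concentration: float  # M
    injection_start: float = 0.0  # s
    injection_stop: float = 0.0  # s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.shape != self.response.shape:
            raise ValueError("times and response must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.analyte_concentration < 0:
            raise ValueError("analyte concentration must be non-negative")
        if self.injection_stop <= self.injection_start:
            raise ValueError("injection stop must follow injection start")

    @classmethod
    def from_tsv(cls, path) -> "Sensorgram":
        df = pd.read_csv(path, sep="\t", comment="#")
        conc = float(df["concentration"].iloc[0])
        assoc = df["phase"] == "association"
        start = float(df.loc[assoc, "time"].min())
        stop = float(df.loc[assoc, "time"].max())
        return cls(
            times=df["time"].to_numpy(),
            response=df["response"].to_numpy(),
            analyte_concentration=conc,
            injection_start=start,
            injection_stop=stop,
        )

    def to_tsv(self, path) -> None:
        phase = np.where(
            self.times <= self.injection_stop, "association", "dissociation"
        )
        pd.DataFrame(
            {
                "time": self.times,
                "response": self.response,
                "concentration": self.analyte_concentration,
                "phase": phase,
            }
        ).to_csv(path, sep="\t", index=False)


def langmuir_response(
    params: LangmuirParams,
    times: np.ndarray,
    conc: float,
    injection_start: float,
    injection_stop: float,
) -> np.ndarray:
    """Noise-free 1:1 response at the given times (association then
    dissociation), starting from zero response at injection start."""
    times = np.asarray(times, dtype=float)
    t = np.clip(times - injection_start, 0.0, None)
    t_assoc_end = injection_stop - injection_start
    kobs = conc * params.ka + params.kd
    if kobs > 0:
        plateau = conc * params.ka * params.rmax / kobs
        r_assoc = plateau * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc_end)))
    else:
        r_assoc = np.zeros_like(t)
    r = r_assoc.copy()
    post = t > t_assoc_end
    r[post] = r_assoc[post] * np.exp(-params.kd * (t[post] - t_assoc_end))
    return r


def simulate_langmuir(
    params: LangmuirParams,
    conc: float,
    t_assoc: float,
    t_dissoc: float,
    dt: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Sensorgram:
    """Simulate one sensorgram: association for ``t_assoc`` seconds, then
    dissociation for ``t_dissoc``, sampled every ``dt``; optional i.i.d.
    Gaussian noise of the given standard deviation (RU)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    r = langmuir_response(params, times, conc, 0.0, t_assoc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(
        times=times,
        response=r,
        analyte_concentration=conc,
        injection_start=0.0,
        injection_stop=t_assoc,
    )


@dataclass
class LangmuirFit:
    """Globally fitted 1:1 constants with covariance-based standard errors."""

    params: LangmuirParams
    k_d: float
    rss: float
    stderr_ka: float
    stderr_kd: float
    stderr_rmax: float
    converged: bool
    single_concentration: bool = False

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "ka": self.params.ka,
                    "kd": self.params.kd,
                    "Rmax": self.params.rmax,
                    "K_D": self.k_d,
                    "rss": self.rss,
                    "stderr_ka": self.stderr_ka,
                    "stderr_kd": self.stderr_kd,
                    "stderr_Rmax": self.stderr_rmax,
                    "converged": self.converged,
                    "single_concentration": self.single_concentration,
                },
                fh,
                indent=2,
            )


def fit_langmuir_global(sensorgrams: list[Sensorgram]) -> LangmuirFit:
    """Fit one ``(ka, kd, Rmax)`` jointly to all curves by least squares.

    Positivity enforced via log-parameterization.  A single-concentration
    data set is fitted but flagged (ka and Rmax are then poorly
    identifiable); a data set with no signal raises.
    """
    if not sensorgrams:
        raise ValueError("need at least one sensorgram")
    signal = max(float(np.ptp(s.response)) for s in sensorgrams)
    if signal == 0:
        raise ValueError("all curves are flat: no binding signal to fit")
    concs = {s.analyte_concentration for s in sensorgrams if s.analyte_concentration > 0}
    single = len(concs) < 2

    def residuals(logp):
        p = LangmuirParams(math.exp(logp[0]), math.exp(logp[1]), math.exp(logp[2]))
        res = []
        for s in sensorgrams:
            model = langmuir_response(
                p, s.times, s.analyte_concentration, s.injection_start, s.injection_stop
            )
            res.append(model - s.response)
        return np.concatenate(res)

    # initialization: Rmax from the largest plateau, kd from the tail decay,
    # ka from the observed association rate at the highest concentration
    r_top = max(float(np.max(s.response)) for s in sensorgrams)
    rmax0 = max(r_top * 1.5, 1e-6)
    kd0 = 1e-3
    cmax = max(concs) if concs else 1e-6
    ka0 = max(1.0 / (cmax * 100.0), 1e-3)
    sol = least_squares(
        residuals,
        x0=[math.log(ka0), math.log(kd0), math.log(rmax0)],
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
    )
    if not sol.success:
        for ka_try in np.logspace(2, 7, 6):
            cand = least_squares(
                residuals,
                x0=[math.log(ka_try), math.log(kd0), math.log(rmax0)],
                method="lm",
                xtol=1e-14,
                ftol=1e-14,
            )
            if float(np.sum(cand.fun**2)) < float(np.sum(sol.fun**2)):
                sol = cand
    rss = float(np.sum(sol.fun**2))
    ka, kd, rmax = (math.exp(x) for x in sol.x)
    dof = max(len(sol.fun) - 3, 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / dof
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se_ka, se_kd, se_rmax = ka * ses[0], kd * ses[1], rmax * ses[2]
    except np.linalg.LinAlgError:
        se_ka = se_kd = se_rmax = float("nan")
    params = LangmuirParams(ka, kd, rmax)
    return LangmuirFit(
        params=params,
        k_d=params.k_d,
        rss=rss,
        stderr_ka=se_ka,
        stderr_kd=se_kd,
        stderr_rmax=se_rmax,
        converged=bool(sol.success),
        single_concentration=single,
    )
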