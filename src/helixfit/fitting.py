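"""Nonlinear least-squares estimation of (t0, h, hps, Q) from melting curves.

Three fitting modes share one engine:

* ``cd_long``  -- normalized CD helicity against the long-chain helicity.
* ``cd_short`` -- the same against the finite-chain helicity (needs N).
* ``dsc``      -- baseline-subtracted heat capacity against the model heat
  capacity, with residuals taken per amino acid (the data, in J/(mol K) per
  mole of protein, are divided by N).

The optimizer works in a normalized internal parameter space so that the
widely different magnitudes of the physical parameters (and the exponentials
they feed) cannot overflow or stall the trust region:

    z = [ log(T_min - t0),  h / 1000,  hps / 1000,  log Q ]

which makes every coordinate O(1)-O(10) and enforces ``t0 < min(T)`` and
``Q > 0`` by construction.  The solvent parameter q is held fixed (16 for
water).  Parameter uncertainties come from the residual-variance-scaled
Gauss-Newton covariance, mapped to physical units by the delta method, and
are reported as percentages of the estimates, mirroring standard
curve-fitting practice for these experiments.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from . import model
from .exceptions import ConfigError, FitError, RootNotFoundError
from .io_units import ThermalCurve

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_curve",
    "percent_errors",
    "r_squared",
    "evaluate_warnings",
    "PARAM_ERROR",
    "LOW_R2",
    "PARAM_ERROR_THRESHOLD",
    "LOW_R2_THRESHOLD",
    "DEFAULT_SOLVENT_Q",
]

#: Warning codes and their (strict) thresholds.
PARAM_ERROR = "PARAM_ERROR"
LOW_R2 = "LOW_R2"
PARAM_ERROR_THRESHOLD = 50.0  # percent
LOW_R2_THRESHOLD = 0.5

#: Entropic cost of polymer-solvent hydrogen bonding for water.
DEFAULT_SOLVENT_Q = 16.0

_MODES = ("cd_long", "cd_short", "dsc")
_PARAM_NAMES = ("t0", "h", "hps", "Q")

#: Default physical bounds.  The t0 bounds are offsets below the lowest data
#: temperature; energies span the plausible hydrogen-bond range in J/mol; Q
#: is capped a little above q**2 - 1 = 255, beyond which the renormalized
#: stability weight can never reach the helix threshold in water, so larger
#: values cannot describe a curve that shows any helix content.
_DEFAULT_T0_OFFSET = (10.0, 500.0)
_DEFAULT_ENERGY_BOUNDS = (500.0, 2.0e4)
_DEFAULT_Q_BOUNDS = (1.0, 300.0)

_MULTISTART_SEED = 20210314
_JITTER_SCALE = 0.3


@dataclasses.dataclass
class FitConfig:
    """Configuration of a single fit.

    ``initial_values=None`` uses the package defaults
    (t0 = min(T) - 100 K, h = 4000 J/mol, hps = 4500 J/mol, Q = 100), which
    experience shows land in the basin of typical single-domain melts; they
    can and sometimes must be adjusted when a fit is flagged.  ``bounds``
    maps parameter names to (low, high) in physical units.  ``n_units`` is
    the chain length N, required for cd_short and dsc.  ``multistart`` is
    the number of jittered restarts tried when the first solve fails or is
    flagged LOW_R2.
    """

    mode: str = "cd_long"
    initial_values: model.ModelParameters | None = None
    bounds: Mapping[str, tuple[float, float]] | None = None
    n_units: int | None = None
    max_iterations: int = 2000
    solvent_q: float = DEFAULT_SOLVENT_Q
    multistart: int = 5

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode in ("cd_short", "dsc") and not self.n_units:
            raise ConfigError(f"mode {self.mode!r} requires n_units (the chain length)")
        if self.bounds is not None:
            unknown = set(self.bounds) - set(_PARAM_NAMES)
            if unknown:
                raise ConfigError(f"unknown bound names: {sorted(unknown)}")


@dataclasses.dataclass
class FitResult:
    """Fitted parameters with uncertainties and fit diagnostics."""

    params: model.ModelParameters
    percent_errors: dict[str, float | None]
    r_squared: float
    covariance: np.ndarray
    warnings: list[str]
    fitted_curve: ThermalCurve
    mode: str
    melting_temperature: float | None

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "params": {
                "t0": self.params.t0,
                "h": self.params.h,
                "hps": self.params.hps,
                "Q": self.params.Q,
                "q": self.params.q,
                "N": self.params.N,
            },
            "percent_errors": dict(self.percent_errors),
            "r_squared": self.r_squared,
            "covariance": np.asarray(self.covariance).tolist(),
            "warnings": list(self.warnings),
            "melting_temperature": self.melting_temperature,
            "fitted_curve": {
                "temperatures": self.fitted_curve.temperatures.tolist(),
                "values": self.fitted_curve.values.tolist(),
                "kind": self.fitted_curve.kind,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        p = d["params"]
        return cls(
            params=model.ModelParameters(
                t0=p["t0"], h=p["h"], hps=p["hps"], Q=p["Q"], q=p["q"], N=p["N"]
            ),
            percent_errors=dict(d["percent_errors"]),
            r_squared=d["r_squared"],
            covariance=np.asarray(d["covariance"], dtype=float),
            warnings=list(d["warnings"]),
            fitted_curve=ThermalCurve(
                temperatures=np.asarray(d["fitted_curve"]["temperatures"], dtype=float),
                values=np.asarray(d["fitted_curve"]["values"], dtype=float),
                kind=d["fitted_curve"]["kind"],
            ),
            mode=d["mode"],
            melting_temperature=d["melting_temperature"],
        )


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ConfigError("observed and predicted must be equal-length with >= 3 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConfigError("R^2 undefined: observed values have zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def percent_errors(
    covariance: np.ndarray, estimates: Mapping[str, float]
) -> dict[str, float | None]:
    """Percent standard errors, 100*sqrt(diag(cov))/|estimate| per parameter.

    A parameter estimated as exactly zero has an undefined percentage and is
    reported as ``None``.
    """
    cov = np.asarray(covariance, dtype=float)
    names = list(estimates)
    if cov.shape != (len(names), len(names)):
        raise ConfigError("covariance shape does not match the number of estimates")
    out: dict[str, float | None] = {}
    for i, name in enumerate(names):
        est = estimates[name]
        sd = math.sqrt(max(cov[i, i], 0.0))
        out[name] = None if est == 0.0 else 100.0 * sd / abs(est)
    return out


def evaluate_warnings(
    percent_errs: Mapping[str, float | None], r2: float
) -> list[str]:
    """Warning codes from the fixed quality thresholds.

    ``PARAM_ERROR`` when any percent error strictly exceeds 50%;
    ``LOW_R2`` when R^2 is strictly below 0.5.  Undefined (None) percent
    errors do not trigger PARAM_ERROR.
    """
    out = []
    if any(pe is not None and pe > PARAM_ERROR_THRESHOLD for pe in percent_errs.values()):
        out.append(PARAM_ERROR)
    if r2 < LOW_R2_THRESHOLD:
        out.append(LOW_R2)
    return out


# ---------------------------------------------------------------------------
# The engine
# ---------------------------------------------------------------------------


class _Transform:
    """Map between physical parameters and the normalized fitting space."""

    def __init__(self, t_min: float):
        self.t_min = t_min

    def to_z(self, t0: float, h: float, hps: float, Q: float) -> np.ndarray:
        if not t0 < self.t_min:
            raise ConfigError(
                f"initial t0={t0} K must lie strictly below the lowest data "
                f"temperature {self.t_min} K"
            )
        return np.array([math.log(self.t_min - t0), h / 1e3, hps / 1e3, math.log(Q)])

    def to_phys(self, z: np.ndarray) -> tuple[float, float, float, float]:
        return (
            self.t_min - math.exp(z[0]),
            float(1e3 * z[1]),
            float(1e3 * z[2]),
            math.exp(z[3]),
        )

    def jacobian_diag(self, z: np.ndarray) -> np.ndarray:
        """d(physical)/dz, diagonal because the map is coordinate-wise."""
        return np.array([-math.exp(z[0]), 1e3, 1e3, math.exp(z[3])])


def _default_initial(t_min: float, q: float, n_units: int | None) -> model.ModelParameters:
    return model.ModelParameters(
        t0=t_min - 100.0, h=4000.0, hps=4500.0, Q=100.0, q=q, N=n_units
    )


def _z_bounds(
    tr: _Transform, bounds: Mapping[str, tuple[float, float]] | None
) -> tuple[np.ndarray, np.ndarray]:
    b = dict(bounds or {})
    t0_lo, t0_hi = b.get(
        "t0", (tr.t_min - _DEFAULT_T0_OFFSET[1], tr.t_min - _DEFAULT_T0_OFFSET[0])
    )
    if not t0_hi < tr.t_min:
        raise ConfigError("upper t0 bound must lie below the lowest data temperature")
    h_lo, h_hi = b.get("h", _DEFAULT_ENERGY_BOUNDS)
    hps_lo, hps_hi = b.get("hps", _DEFAULT_ENERGY_BOUNDS)
    q_lo, q_hi = b.get("Q", _DEFAULT_Q_BOUNDS)
    if q_lo <= 0:
        raise ConfigError("Q bounds must be positive")
    lower = np.array(
        [math.log(tr.t_min - t0_hi), h_lo / 1e3, hps_lo / 1e3, math.log(q_lo)]
    )
    upper = np.array(
        [math.log(tr.t_min - t0_lo), h_hi / 1e3, hps_hi / 1e3, math.log(q_hi)]
    )
    return lower, upper


def _model_values(
    T: np.ndarray, phys: tuple[float, float, float, float], config: FitConfig
) -> np.ndarray:
    t0, h, hps, Q = phys
    p = model.ModelParameters(
        t0=t0, h=h, hps=hps, Q=Q, q=config.solvent_q, N=config.n_units
    )
    if config.mode == "cd_long":
        return np.asarray(model.helicity(T, p, mode="long"))
    if config.mode == "cd_short":
        return np.asarray(model.helicity(T, p, mode="finite"))
    return np.asarray(model.heat_capacity(T, p, mode="long", per_residue=True))


def fit_curve(data: ThermalCurve, config: FitConfig) -> FitResult:
    """Least-squares fit of the mode's model function to a melting curve.

    Minimizes the unweighted sum of squared residuals over (t0, h, hps, Q)
    with q fixed.  If the first solve fails, or succeeds but is flagged
    LOW_R2, up to ``config.multistart`` deterministically jittered restarts
    are tried and the best R^2 is kept.  Raises :class:`FitError` when no
    start converges; the remedy is to inspect the data and the initial
    values and correct the source of the error.
    """
    if data.kind == "cd" and config.mode == "dsc":
        raise ConfigError("DSC fitting mode requires a DSC curve")
    if data.kind == "dsc" and config.mode != "dsc":
        raise ConfigError("CD fitting modes require a CD curve")

    T = data.temperatures
    tr = _Transform(float(T[0]))
    init = config.initial_values or _default_initial(tr.t_min, config.solvent_q, config.n_units)
    z0 = tr.to_z(init.t0, init.h, init.hps, init.Q)
    lower, upper = _z_bounds(tr, config.bounds)
    if np.any(z0 < lower) or np.any(z0 > upper):
        z0 = np.clip(z0, lower, upper)

    y = data.values / config.n_units if config.mode == "dsc" else data.values
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConfigError("data values are constant; nothing to fit")

    def residuals(z: np.ndarray) -> np.ndarray:
        return _model_values(T, tr.to_phys(z), config) - y

    def solve(z_start: np.ndarray):
        res = least_squares(
            residuals,
            z_start,
            bounds=(lower, upper),
            method="trf",
            max_nfev=config.max_iterations,
        )
        if not res.success or not np.all(np.isfinite(res.fun)):
            return None
        r2 = 1.0 - float(np.sum(res.fun**2)) / ss_tot
        return res, r2

    attempts = [solve(z0)]
    best = attempts[0]
    if best is None or LOW_R2 in evaluate_warnings({}, best[1]):
        rng = np.random.default_rng(_MULTISTART_SEED)
        for _ in range(config.multistart):
            z_j = np.clip(z0 + rng.normal(0.0, _JITTER_SCALE, 4), lower, upper)
            try:
                cand = solve(z_j)
            except (model.DomainError, FloatingPointError):  # pragma: no cover
                cand = None
            if cand is not None and (best is None or cand[1] > best[1]):
                best = cand
    if best is None:
        raise FitError(
            "fit did not converge from any start; inspect the data (units, "
            "normalization, baseline subtraction) and correct the source of the error"
        )

    res, r2 = best
    phys = tr.to_phys(res.x)
    fitted_params = model.ModelParameters(
        t0=phys[0], h=phys[1], hps=phys[2], Q=phys[3],
        q=config.solvent_q, N=config.n_units,
    )

    cov = _physical_covariance(res, tr, y.size)
    perr = percent_errors(cov, dict(zip(_PARAM_NAMES, phys)))
    warnings = evaluate_warnings(perr, r2)

    fitted_values = _model_values(T, phys, config)
    if config.mode == "dsc":
        fitted_values = fitted_values * config.n_units
    fitted_curve = ThermalCurve(
        temperatures=T,
        values=np.clip(fitted_values, 0.0, 1.0) if data.kind == "cd" else fitted_values,
        kind=data.kind,
    )

    theta_mode = "finite" if config.mode == "cd_short" else "long"
    try:
        tm = model.melting_temperature(
            fitted_params, mode=theta_mode,
            t_range=(fitted_params.t0 + 1.0, float(T[-1]) + 100.0),
        )
    except RootNotFoundError:
        tm = None

    return FitResult(
        params=fitted_params,
        percent_errors=perr,
        r_squared=r2,
        covariance=cov,
        warnings=warnings,
        fitted_curve=fitted_curve,
        mode=config.mode,
        melting_temperature=tm,
    )


def _physical_covariance(res, tr: _Transform, n_obs: int) -> np.ndarray:
    """Residual-variance-scaled covariance, delta-mapped to physical units."""
    dof = max(n_obs - 4, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    cov_z = s2 * np.linalg.pinv(jtj)
    g = tr.jacobian_diag(res.x)
    cov = (cov_z * g).T * g  # G @ cov_z @ G for diagonal G
    return 0.5 * (cov + cov.T)
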