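"""Water-renormalized Zimm-Bragg model of the helix-coil transition.

The classical Zimm-Bragg model assigns each of the ``N`` repeat units of a
polypeptide a statistical weight of 1 (coil) or ``s`` (helix), with a
nucleation penalty ``sigma`` per helix-coil junction.  Tracing out explicit
polypeptide-water hydrogen-bonding degrees of freedom renormalizes the helix
stability weight: an intra-chain N-H...C-O bond of energy ``h`` competes with
a polypeptide-solvent bond of energy ``hps`` that a water molecule can only
form in one of ``q`` orientations (``q = 16`` for water).  The renormalized
stability parameter becomes

    s_tilde(T) = (1/Q) * [ (A + (B - A)/q)**-2 - 1 ]

with the Boltzmann factors ``A = exp(-h * beta)`` (intra-chain) and
``B = exp((hps - h) * beta)`` (chain-solvent), where every Boltzmann exponent
in the model uses the same effective inverse temperature

    beta(T) = 1 / (R * (T - t0)).

The glass transition temperature ``t0`` encodes the non-Arrhenius temperature
dependence of hydrogen-bond statistics; all Boltzmann factors diverge as
``T -> t0`` so the model is only defined for ``T > t0``.  ``Q = 1/sigma`` is
the entropic cost of intra-chain bonding.

Observables:

* ``helicity`` -- the order parameter ``theta`` in [0, 1], the average
  fraction of hydrogen-bonded (helical) units, from the transfer-matrix
  partition function (finite-chain closed form or its long-chain limit).
* ``occupancy_X`` -- the probability that a water site adjacent to a broken
  intra-chain bond is in its bonding orientation.
* ``internal_energy`` -- the mean hydrogen-bonding energy per chain,
  ``E = -2N * (h*theta + hps*X*(1 - theta))``, which equals the derivative
  of the full (solvent-dressed) log partition function with respect to the
  effective inverse temperature.
* ``heat_capacity`` -- ``C = dE/dT``, expanded through the analytic
  temperature derivatives of ``theta`` and ``X``; single-peaked across a
  cooperative melting transition and directly comparable (after baseline
  subtraction, with the usual C_V ~ C_P reading for condensed phases) to a
  DSC excess heat-capacity thermogram.

All energies are in J/mol, temperatures in K.  Evaluation is overflow-safe:
the squared statistical weight is manipulated in log space and saturates at
``exp(+-LOG_WEIGHT_CAP)``, which leaves every observable exact to double
precision (the saturated regimes have theta pinned at 0 or 1 to within
1e-129) while keeping all outputs finite for ``|h|, |hps| <= 1e5`` J/mol and
``T - t0 >= 1`` K.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError, RootNotFoundError

__all__ = [
    "GAS_CONSTANT",
    "ModelParameters",
    "EigenPair",
    "eigenvalues",
    "stability_parameter",
    "occupancy_X",
    "log_partition_function",
    "helicity",
    "internal_energy",
    "heat_capacity",
    "melting_temperature",
]

#: Ideal gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: Saturation bound for the log of the squared statistical weight.  Chosen so
#: that s_tilde**2 stays far below float overflow in downstream algebra.
LOG_WEIGHT_CAP = 300.0

#: Relative eigenvalue gap below which the finite-chain partition function
#: switches to its confluent (equal-eigenvalue) limit.
_DEGENERATE_TOL = 1e-10


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """Physical parameter set driving all model evaluation.

    Attributes
    ----------
    t0:
        Glass transition temperature, K.  Every evaluation temperature must
        satisfy ``T > t0``.
    h:
        Intra-polypeptide (N-H...C-O) hydrogen-bond energy, J/mol.
    hps:
        Polypeptide-solvent hydrogen-bond energy, J/mol.
    Q:
        Entropic cost of intra-chain hydrogen bonding; the Zimm-Bragg
        nucleation parameter is ``sigma = 1/Q``.  Physically meaningful fits
        have ``Q >= 1``.
    q:
        Entropic cost of polymer-solvent hydrogen bonding; fixed at 16 for
        water.  Must exceed 1 so the solvent-site partition sum
        ``q - 1 + exp(hps*beta)`` is strictly positive.
    N:
        Number of repeat units (amino acids).  Required by finite-chain
        evaluation and by the extensive observables (energy, heat capacity);
        may be ``None`` for purely long-chain intensive quantities.
    """

    t0: float
    h: float
    hps: float
    Q: float
    q: float = 16.0
    N: int | None = None

    def __post_init__(self) -> None:
        if not self.Q > 0:
            raise DomainError(f"Q must be positive, got {self.Q}")
        if not self.q > 1:
            raise DomainError(f"q must exceed 1, got {self.q}")
        if self.N is not None and (int(self.N) != self.N or self.N < 1):
            raise DomainError(f"N must be a positive integer, got {self.N}")

    @property
    def sigma(self) -> float:
        """Zimm-Bragg cooperativity (nucleation) parameter, 1/Q."""
        return 1.0 / self.Q

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)


class EigenPair(NamedTuple):
    """Transfer-matrix eigenvalues, ``lambda1 >= lambda2``."""

    lambda1: float
    lambda2: float


def eigenvalues(s: float, sigma: float) -> EigenPair:
    """Eigenvalues of the 2x2 Zimm-Bragg transfer matrix.

    Roots of ``lam**2 - (1 + s)*lam + s*(1 - sigma) = 0``:

        lam_{1,2} = (1 + s +- sqrt((1 - s)**2 + 4*sigma*s)) / 2

    They satisfy the Vieta identities ``lam1 + lam2 = 1 + s`` and
    ``lam1 * lam2 = s * (1 - sigma)``.
    """
    if s < 0 or sigma < 0:
        raise DomainError(f"s and sigma must be non-negative, got s={s}, sigma={sigma}")
    disc = (1.0 - s) ** 2 + 4.0 * sigma * s
    root = math.sqrt(disc)
    return EigenPair(0.5 * (1.0 + s + root), 0.5 * (1.0 + s - root))


# ---------------------------------------------------------------------------
# Boltzmann factors and the renormalized stability parameter
# ---------------------------------------------------------------------------


def _check_temperature(T: np.ndarray | float, t0: float) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= t0):
        raise DomainError(
            f"temperatures must exceed the glass transition t0={t0} K "
            f"(min given: {np.min(T)} K)"
        )
    return T


def boltzmann_exponent(energy: float, T: np.ndarray | float, t0: float) -> np.ndarray:
    """Effective Boltzmann exponent ``energy / (R * (T - t0))``.

    Single site of truth for every exponential in the model: the stability
    parameter, the solvent occupancy and all their temperature derivatives
    use this same non-Arrhenius scaling.
    """
    T = _check_temperature(T, t0)
    return energy / (GAS_CONSTANT * (T - t0))


def _log_weight(T: np.ndarray | float, p: ModelParameters) -> np.ndarray:
    """log W(T) where ``W = (A + (B - A)/q)**-2`` is the squared helix weight.

    ``A + (B - A)/q`` collapses to ``exp(-h*beta) * (q - 1 + exp(hps*beta))/q``,
    so ``log W = 2*(h*beta + log q - logaddexp(log(q-1), hps*beta))`` -- no
    intermediate exponential is ever formed.  The result is clipped to
    ``+-LOG_WEIGHT_CAP``.
    """
    beta = 1.0 / (GAS_CONSTANT * (_check_temperature(T, p.t0) - p.t0))
    logw = 2.0 * (p.h * beta + math.log(p.q) - np.logaddexp(math.log(p.q - 1.0), p.hps * beta))
    return np.clip(logw, -LOG_WEIGHT_CAP, LOG_WEIGHT_CAP)


def stability_parameter(T: np.ndarray | float, params: ModelParameters) -> np.ndarray | float:
    """Solvent-renormalized stability parameter ``s_tilde(T) = (W - 1)/Q``.

    Bounded below by ``-1/Q`` (reached when the solvent-dressed coil state
    dominates completely); at that point the helicity vanishes exactly since
    the transfer-matrix weight ``s_tilde + sigma = W/Q`` goes to zero.
    With ``h = hps = 0`` both Boltzmann factors equal 1 and
    ``s_tilde = 0`` identically.
    """
    out = np.expm1(_log_weight(T, params)) / params.Q
    return out if out.ndim else float(out)


def _weight_over_Q(T: np.ndarray | float, p: ModelParameters) -> np.ndarray:
    """``W/Q = s_tilde + sigma``, computed without cancellation near zero."""
    return np.exp(_log_weight(T, p)) / p.Q


def occupancy_X(T: np.ndarray | float, params: ModelParameters) -> np.ndarray | float:
    """Fraction of bonding-oriented water at a solvent-accessible site.

    ``X = exp(hps*beta) / (q + exp(hps*beta) - 1)``: one bonding orientation
    of weight ``exp(hps*beta)`` against ``q - 1`` inert orientations of unit
    weight, hence ``X in (0, 1]`` with ``X = 1/q`` when ``hps = 0``.
    """
    expo = boltzmann_exponent(params.hps, T, params.t0)
    # clip keeps (q - 1) * exp(.) finite; beyond the clip X is 0 or 1 to 1e-129
    out = 1.0 / (1.0 + (params.q - 1.0) * np.exp(np.clip(-expo, -700.0, 700.0)))
    out = np.asarray(out)
    return out if out.ndim else float(out)


def _occupancy_and_slope(T: np.ndarray, p: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """(X, dX/dT); dX/dbeta = hps*X*(1-X) and dbeta/dT = -1/(R*(T-t0)^2)."""
    x = np.asarray(occupancy_X(T, p))
    dx_dT = -p.hps * x * (1.0 - x) / (GAS_CONSTANT * (np.asarray(T, dtype=float) - p.t0) ** 2)
    return x, dx_dT


# ---------------------------------------------------------------------------
# Transfer-matrix spectrum and partition function
# ---------------------------------------------------------------------------


class _Spectrum(NamedTuple):
    """Eigenvalues of the transfer matrix with first and second s-derivatives."""

    l1: np.ndarray
    l2: np.ndarray
    l1p: np.ndarray
    l2p: np.ndarray
    l1pp: np.ndarray
    l2pp: np.ndarray
    root: np.ndarray  # sqrt of the discriminant


def _spectrum(s: np.ndarray, sigma: float) -> _Spectrum:
    """Spectral data for ``s >= -sigma`` (the internal domain of s_tilde).

    The discriminant ``(1-s)**2 + 4*sigma*s`` has minimum ``4*sigma*(1-sigma)``
    over real ``s``, so for ``sigma in [0, 1]`` the eigenvalues are real
    everywhere; tiny negative values from rounding are clipped to zero.
    """
    s = np.asarray(s, dtype=float)
    disc = (1.0 - s) ** 2 + 4.0 * sigma * s
    if np.any(disc < -1e-12 * np.maximum(1.0, s * s)):
        raise DomainError("complex transfer-matrix eigenvalues (sigma > 1 with s < 0)")
    root = np.sqrt(np.maximum(disc, 0.0))
    half = 0.5 * (1.0 + s)
    l1 = half + 0.5 * root
    # lam2 from the Vieta product lam1*lam2 = s*(1-sigma): the difference
    # form (1 + s - root)/2 cancels catastrophically for s >> 1, where
    # lam2 -> 1 - sigma must stay resolved for the finite-chain remainder.
    l2 = np.where(
        l1 > 0,
        s * (1.0 - sigma) / np.where(l1 > 0, l1, 1.0),
        half - 0.5 * root,
    )
    slope = np.divide(s - 1.0 + 2.0 * sigma, root, out=np.zeros_like(root), where=root > 0)
    # 1 - slope cancels catastrophically as slope -> 1 (s >> 1); rewrite via
    # root - (s - 1 + 2*sigma) = 4*sigma*(1 - sigma) / (root + s - 1 + 2*sigma)
    shifted = s - 1.0 + 2.0 * sigma
    safe = (shifted > 0) & (root > 0)
    denom = np.where(safe, root * (root + shifted), 1.0)
    l2p = np.where(safe, 2.0 * sigma * (1.0 - sigma) / denom, 0.5 * (1.0 - slope))
    with np.errstate(over="ignore"):
        curv = np.divide(
            2.0 * sigma * (1.0 - sigma), root**3, out=np.full_like(root, np.inf),
            where=root > 0,
        )
    return _Spectrum(
        l1=l1,
        l2=l2,
        l1p=0.5 * (1.0 + slope),
        l2p=l2p,
        l1pp=curv,
        l2pp=-curv,
        root=root,
    )


def _pow(r: np.ndarray, n: int) -> np.ndarray:
    """r**n for |r| < 1, stable for very large n (underflows to 0).

    r = lam2/lam1 may be slightly negative on the internal branch
    s_tilde in [-sigma, 0), so the sign is carried explicitly.
    """
    mag = np.abs(np.asarray(r, dtype=float))
    with np.errstate(divide="ignore"):
        logmag = np.log(np.where(mag > 0.0, mag, 1.0))
    out = np.where(mag > 0.0, np.exp(n * logmag), 0.0)
    if n % 2 == 1:
        out = np.where(r < 0.0, -out, out)
    return out


def _log_Z_confluent(l1: np.ndarray, N: int) -> np.ndarray:
    # Z_N = lam^(N-1) * (lam + N*(1 - lam)) when lam1 == lam2 == lam
    return (N - 1) * np.log(l1) + np.log(l1 + N * (1.0 - l1))


def log_partition_function(
    s_tilde: np.ndarray | float,
    sigma: float,
    N: int,
    mode: str = "long",
) -> np.ndarray | float:
    """Log of the Zimm-Bragg partition function.

    mode="finite" evaluates the closed form

        Z = [ (1 - lam2) * lam1**N + (lam1 - 1) * lam2**N ] / (lam1 - lam2)

    with ``lam1**N`` factored out so chains up to N = 1e6 cannot overflow;
    when the eigenvalues are degenerate to within ``_DEGENERATE_TOL`` the
    analytic confluent limit replaces the 0/0 expression.  mode="long"
    returns the thermodynamic-limit form ``N * log(lam1)``.

    Note the finite form carries the fixed boundary normalization of the
    transfer-matrix construction: ``Z(N=1) = 1`` identically (a single unit
    cannot close a hydrogen bond), not the independent-unit sum ``1 + s``.
    """
    if N < 1:
        raise DomainError(f"N must be >= 1, got {N}")
    s = np.asarray(s_tilde, dtype=float)
    sp = _spectrum(s, sigma)
    if mode == "long":
        out = N * np.log(sp.l1)
        return out if out.ndim else float(out)
    if mode != "finite":
        raise ValueError(f"mode must be 'finite' or 'long', got {mode!r}")

    r = sp.l2 / sp.l1
    scaled = (1.0 - sp.l2) + (sp.l1 - 1.0) * _pow(r, N)  # Z / lam1^N * (lam1 - lam2)
    with np.errstate(divide="ignore", invalid="ignore"):
        regular = N * np.log(sp.l1) + np.log(scaled) - np.log(sp.root)
    degenerate = sp.root < _DEGENERATE_TOL * sp.l1
    if np.any(degenerate):
        regular = np.where(degenerate, _log_Z_confluent(sp.l1, N), regular)
    return regular if regular.ndim else float(regular)


def _dlnZ_finite(s: np.ndarray, sigma: float, N: int) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives of ln Z (finite chain) w.r.t. s_tilde.

    Uses ``ln Z = N ln lam1 + ln P - ln Delta`` with the scaled remainder
    ``P = (1 - lam2) + (lam1 - 1) * r**N``, ``r = lam2/lam1 in [0, 1)`` and
    ``Delta = lam1 - lam2``; every term is differentiated analytically so the
    result is exact up to rounding for any N.
    """
    sp = _spectrum(s, sigma)
    if np.any(sp.root < _DEGENERATE_TOL * sp.l1):
        raise DomainError("degenerate transfer-matrix spectrum: derivative undefined here")
    if N == 1:  # Z == 1 identically
        z = np.zeros_like(sp.l1)
        return z, z

    l1, l2, l1p, l2p, l1pp, l2pp, delta = (
        sp.l1, sp.l2, sp.l1p, sp.l2p, sp.l1pp, sp.l2pp, sp.root,
    )
    r = l2 / l1
    rp = (l2p * l1 - l2 * l1p) / l1**2
    rpp = (l2pp * l1 - l2 * l1pp) / l1**2 - 2.0 * l1p * (l2p * l1 - l2 * l1p) / l1**3
    rN = _pow(r, N)
    rN1 = _pow(r, N - 1)
    rN2 = _pow(r, N - 2) if N >= 2 else np.zeros_like(r)

    v = l1 - 1.0
    P = (1.0 - l2) + v * rN
    Pp = -l2p + l1p * rN + v * N * rN1 * rp
    Ppp = (
        -l2pp
        + l1pp * rN
        + 2.0 * l1p * N * rN1 * rp
        + v * N * (N - 1) * rN2 * rp**2
        + v * N * rN1 * rpp
    )
    deltap = l1p - l2p
    deltapp = l1pp - l2pp

    first = N * l1p / l1 + Pp / P - deltap / delta
    second = (
        N * (l1pp / l1 - (l1p / l1) ** 2)
        + Ppp / P
        - (Pp / P) ** 2
        - deltapp / delta
        + (deltap / delta) ** 2
    )
    return first, second


def _dlnZ_long(s: np.ndarray, sigma: float, N: int) -> tuple[np.ndarray, np.ndarray]:
    sp = _spectrum(s, sigma)
    first = N * sp.l1p / sp.l1
    second = N * (sp.l1pp / sp.l1 - (sp.l1p / sp.l1) ** 2)
    return first, second


def _require_N(p: ModelParameters) -> int:
    if p.N is None:
        raise DomainError("this observable requires the chain length N")
    return int(p.N)


def _theta_and_slope(
    T: np.ndarray, p: ModelParameters, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """(theta, dtheta/dT) through the analytic chain rule.

    theta = (s_tilde + sigma)/N * dlnZ/ds with ``s_tilde + sigma = W/Q``
    evaluated directly from the log weight (no cancellation at the coil
    limit, where theta -> 0 exactly as W -> 0).
    """
    T = np.asarray(T, dtype=float)
    s = np.asarray(stability_parameter(T, p))
    woq = _weight_over_Q(T, p)
    sigma = p.sigma
    if mode == "finite":
        n = _require_N(p)
        first, second = _dlnZ_finite(s, sigma, n)
        theta = woq / n * first
        dtheta_ds = first / n + woq / n * second
    elif mode == "long":
        first, second = _dlnZ_long(s, sigma, 1)
        theta = woq * first
        dtheta_ds = first + woq * second
    else:
        raise ValueError(f"mode must be 'finite' or 'long', got {mode!r}")

    x = np.asarray(occupancy_X(T, p))
    # ds/dT = (W/Q) * dlnW/dbeta * dbeta/dT, with dlnW/dbeta = 2*(h - hps*X)
    ds_dT = -woq * 2.0 * (p.h - p.hps * x) / (GAS_CONSTANT * (T - p.t0) ** 2)
    return theta, dtheta_ds * ds_dT


def helicity(
    T: np.ndarray | float, params: ModelParameters, mode: str = "long"
) -> np.ndarray | float:
    """Degree of helicity theta(T) in [0, 1].

    mode="finite" uses the analytic derivative of the finite-chain log
    partition function (requires ``params.N``); mode="long" uses the
    closed-form thermodynamic limit.  The two agree to O(1/N) boundary
    corrections as N grows.
    """
    theta, _ = _theta_and_slope(np.asarray(T, dtype=float), params, mode)
    return theta if theta.ndim else float(theta)


def internal_energy(
    T: np.ndarray | float, params: ModelParameters, mode: str = "long"
) -> np.ndarray | float:
    """Mean hydrogen-bonding energy per chain, J/mol.

    ``E = -2N * (h*theta + hps*X*(1 - theta))``: each helical unit holds an
    intra-chain bond of energy h, each coil unit offers a solvent site that
    is bonded with probability X.  This closed form is exactly the derivative
    of the solvent-dressed log partition function with respect to the
    effective inverse temperature ``beta = 1/(R*(T - t0))``, so the heat
    capacity below is its exact temperature derivative.  With
    ``h = hps = 0`` the energy is identically zero (constant in T).
    """
    T = np.asarray(T, dtype=float)
    n = _require_N(params)
    theta, _ = _theta_and_slope(T, params, mode)
    x = np.asarray(occupancy_X(T, params))
    out = -2.0 * n * (params.h * theta + params.hps * x * (1.0 - theta))
    return out if out.ndim else float(out)


def heat_capacity(
    T: np.ndarray | float,
    params: ModelParameters,
    mode: str = "long",
    per_residue: bool = False,
) -> np.ndarray | float:
    """Excess heat capacity ``C = dE/dT``, J mol^-1 K^-1 per chain.

        C = -2N*h*dtheta/dT - 2N*hps*dX/dT*(1 - theta) + 2N*hps*X*dtheta/dT

    with both slopes taken analytically.  ``per_residue=True`` divides by N,
    matching the per-amino-acid convention of reported DSC fits.  With
    ``hps = 0`` only the first term survives.
    """
    T = np.asarray(T, dtype=float)
    n = _require_N(params)
    theta, dtheta = _theta_and_slope(T, params, mode)
    x, dx = _occupancy_and_slope(T, params)
    out = (
        -2.0 * n * params.h * dtheta
        - 2.0 * n * params.hps * dx * (1.0 - theta)
        + 2.0 * n * params.hps * x * dtheta
    )
    if per_residue:
        out = out / n
    return out if out.ndim else float(out)


def melting_temperature(
    params: ModelParameters,
    mode: str = "long",
    t_range: tuple[float, float] | None = None,
    xtol: float = 1e-4,
) -> float:
    """Heat-denaturation midpoint: the T where theta crosses 1/2 downward.

    The search window defaults to ``(t0 + 1, t0 + 1000)`` K.  A dense scan
    brackets sign changes of ``theta - 1/2``; the crossing with negative
    slope (helix melting on heating) is refined by bisection to ``xtol`` K.
    Re-entrant parameter sets also cross 1/2 upward at low temperature
    (cold denaturation); that root is deliberately not reported.
    """
    lo, hi = t_range if t_range is not None else (params.t0 + 1.0, params.t0 + 1000.0)
    if not lo > params.t0:
        raise DomainError("search window must lie above t0")
    grid = np.linspace(lo, hi, 1024)
    theta = np.asarray(helicity(grid, params, mode=mode)) - 0.5
    signs = np.sign(theta)
    crossings = np.nonzero(np.diff(signs) != 0)[0]
    for i in crossings[::-1]:  # prefer the high-temperature, melting-side root
        if theta[i] > theta[i + 1]:
            return float(
                brentq(
                    lambda t: float(np.asarray(helicity(t, params, mode=mode))) - 0.5,
                    grid[i],
                    grid[i + 1],
                    xtol=xtol,
                )
            )
    raise RootNotFoundError("helicity does not cross 1/2 downward in the search window")
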