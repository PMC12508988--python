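"""Model-layer tests: transfer matrix, renormalized weights, observables.

Independent oracles: mpmath arbitrary-precision re-evaluation for the
Boltzmann-factor algebra, the three-term characteristic recurrence for the
finite-chain partition function, and central finite differences for every
analytic derivative.
"""

import math

import mpmath as mp
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import helixfit as hf
from helixfit import model
from helixfit.exceptions import DomainError, RootNotFoundError

R = hf.GAS_CONSTANT


# ---------------------------------------------------------------------------
# eigenvalues
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "s, sigma, expected",
    [
        (1.0, 0.01, (1.1, 0.9)),  # discriminant 4*sigma at s=1
        (2.0, 1.0, (3.0, 0.0)),  # at sigma=1 the discriminant is (1+s)^2
        (0.0, 0.5, (1.0, 0.0)),  # lam^2 - lam = 0
    ],
)
def test_eigenvalue_closed_forms(s, sigma, expected):
    lam = hf.eigenvalues(s, sigma)
    assert lam.lambda1 == pytest.approx(expected[0], abs=1e-14)
    assert lam.lambda2 == pytest.approx(expected[1], abs=1e-14)
    assert lam.lambda1 >= lam.lambda2


@pytest.mark.parametrize("s, sigma", [(-0.1, 0.5), (1.0, -0.01)])
def test_eigenvalues_reject_negative_arguments(s, sigma):
    with pytest.raises(DomainError):
        hf.eigenvalues(s, sigma)


def test_vieta_identities_hold_over_random_draws():
    rng = np.random.default_rng(42)
    s = rng.uniform(0.0, 50.0, 10_000)
    sigma = rng.uniform(0.0, 1.0, 10_000)
    lam = [hf.eigenvalues(si, gi) for si, gi in zip(s[:200], sigma[:200])]
    for (l1, l2), si, gi in zip(lam, s, sigma):
        assert l1 + l2 == pytest.approx(1.0 + si, rel=1e-12)
        assert l1 * l2 == pytest.approx(si * (1.0 - gi), rel=1e-12, abs=1e-12)
    # vectorized check over the full draw via the internal spectrum
    sp = model._spectrum(s, 0.5)  # fixed sigma, vector s
    np.testing.assert_allclose(sp.l1 + sp.l2, 1.0 + s, rtol=1e-12)
    np.testing.assert_allclose(sp.l1 * sp.l2, s * 0.5, rtol=1e-12, atol=1e-12)


# ---------------------------------------------------------------------------
# stability parameter and solvent occupancy
# ---------------------------------------------------------------------------


def _mp_stability(T, t0, h, hps, Q, q):
    """Arbitrary-precision transcription of the renormalized weight."""
    with mp.workdps(40):
        beta = 1 / (mp.mpf(R) * (mp.mpf(T) - t0))
        A = mp.e ** (-h * beta)
        B = mp.e ** ((hps - h) * beta)
        return float((1 / mp.mpf(Q)) * ((A + (B - A) / q) ** -2 - 1))


def test_stability_zero_energies_gives_zero():
    p = hf.ModelParameters(t0=200.0, h=0.0, hps=0.0, Q=7.0, q=16.0)
    assert hf.stability_parameter(300.0, p) == pytest.approx(0.0, abs=1e-15)


def test_stability_matches_arbitrary_precision_oracle():
    p = hf.ModelParameters(t0=200.0, h=4000.0, hps=4500.0, Q=100.0, q=16.0)
    got = hf.stability_parameter(300.0, p)
    # frozen regression value, mpmath at 40 digits
    assert got == pytest.approx(0.66549879680077689, rel=1e-12)
    assert got == pytest.approx(_mp_stability(300, 200, 4000, 4500, 100, 16), rel=1e-12)


@given(
    h=st.floats(-2e4, 2e4),
    hps=st.floats(-2e4, 2e4),
    Q=st.floats(1.0, 300.0),
    dT=st.floats(5.0, 500.0),
)
def test_stability_bounded_below_by_minus_sigma(h, hps, Q, dT):
    p = hf.ModelParameters(t0=250.0, h=h, hps=hps, Q=Q)
    assert hf.stability_parameter(250.0 + dT, p) >= -1.0 / Q - 1e-15


def test_stability_rejects_temperatures_at_or_below_t0():
    p = hf.ModelParameters(t0=250.0, h=4000.0, hps=4500.0, Q=10.0)
    with pytest.raises(DomainError):
        hf.stability_parameter(250.0, p)
    with pytest.raises(DomainError):
        hf.stability_parameter(np.array([300.0, 240.0]), p)


def test_occupancy_limits_and_oracle_value():
    p0 = hf.ModelParameters(t0=200.0, h=4000.0, hps=0.0, Q=10.0, q=16.0)
    assert hf.occupancy_X(300.0, p0) == pytest.approx(1.0 / 16.0, rel=1e-14)
    strong = hf.ModelParameters(t0=200.0, h=4000.0, hps=5e5, Q=10.0, q=16.0)
    assert hf.occupancy_X(300.0, strong) == pytest.approx(1.0, abs=1e-12)
    p = hf.ModelParameters(t0=200.0, h=4000.0, hps=4500.0, Q=100.0, q=16.0)
    # frozen mpmath value under the shared Boltzmann-exponent convention
    assert hf.occupancy_X(300.0, p) == pytest.approx(0.93729206442341797, rel=1e-12)


@given(hps=st.floats(-5e4, 5e4), T=st.floats(260.0, 500.0))
def test_occupancy_in_unit_interval(hps, T):
    p = hf.ModelParameters(t0=250.0, h=4000.0, hps=hps, Q=10.0)
    x = hf.occupancy_X(T, p)
    assert 0.0 < x <= 1.0


# ---------------------------------------------------------------------------
# partition function
# ---------------------------------------------------------------------------


def _recurrence_log_Z(s, sigma, N):
    """Oracle: Z_{k+1} = (1+s) Z_k - s (1-sigma) Z_{k-1}, Z_0 = Z_1 = 1."""
    z_prev, z = 1.0, 1.0
    for _ in range(N - 1):
        z_prev, z = z, (1.0 + s) * z - s * (1.0 - sigma) * z_prev
    return math.log(z)


def test_single_unit_partition_function_is_one():
    for s in (0.5, 2.0, 10.0):
        assert hf.log_partition_function(s, 0.1, 1, "finite") == pytest.approx(0.0, abs=1e-14)


@pytest.mark.parametrize("sigma", [1e-3, 0.1, 0.9])
@pytest.mark.parametrize("s", [0.1, 1.0, 2.0, 8.0])
def test_closed_form_matches_recurrence(s, sigma):
    for N in (2, 3, 5, 17, 50):
        got = hf.log_partition_function(s, sigma, N, "finite")
        assert got == pytest.approx(_recurrence_log_Z(s, sigma, N), rel=1e-12, abs=1e-12)


def test_long_chain_limit_dominates():
    """The boundary correction ln(P/Delta) is O(1), so per-unit it vanishes."""
    s, sigma = 2.0, 0.1
    per_unit = [
        abs(
            hf.log_partition_function(s, sigma, N, "finite")
            - hf.log_partition_function(s, sigma, N, "long")
        ) / N
        for N in (100, 10_000, 1_000_000)
    ]
    assert per_unit[0] > per_unit[1] > per_unit[2]
    assert per_unit[1] < 1e-3 and per_unit[2] < 1e-5


def test_degenerate_spectrum_uses_confluent_limit():
    # sigma = 0, s = 1 is the only degenerate point: lam1 = lam2 = 1
    for N in (2, 5, 20):
        got = hf.log_partition_function(1.0, 0.0, N, "finite")
        assert math.isfinite(got)
        assert got == pytest.approx(_recurrence_log_Z(1.0, 0.0, N), rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# helicity
# ---------------------------------------------------------------------------


def test_helicity_saturates_in_the_strong_helix_limit():
    p = hf.ModelParameters(t0=200.0, h=20000.0, hps=1000.0, Q=10.0, N=500)
    assert hf.helicity(260.0, p, mode="long") == pytest.approx(1.0, abs=1e-6)


def test_helicity_bounded_on_parameter_grid(cd_grid):
    rng = np.random.default_rng(7)
    for _ in range(30):
        p = hf.ModelParameters(
            t0=rng.uniform(150, 280),
            h=rng.uniform(500, 10000),
            hps=rng.uniform(500, 10000),
            Q=rng.uniform(1, 250),
            N=int(rng.integers(2, 500)),
        )
        for mode in ("long", "finite"):
            th = np.asarray(hf.helicity(cd_grid, p, mode=mode))
            assert np.all(th >= -1e-12) and np.all(th <= 1.0 + 1e-12)


def test_finite_chain_converges_to_long_chain(truth_long, transition_grid):
    """Boundary corrections decay as O(1/N): gaps shrink ~10x per decade."""
    gaps = []
    for n in (100, 1_000, 100_000):
        p = truth_long.replace(N=n)
        fin = np.asarray(hf.helicity(transition_grid, p, mode="finite"))
        lng = np.asarray(hf.helicity(transition_grid, p, mode="long"))
        gaps.append(float(np.max(np.abs(fin - lng))))
    assert gaps[0] > gaps[1] > gaps[2]
    assert gaps[2] < 1e-4


def test_finite_size_gap_matches_quadrature_oracle():
    """At s=1, sigma=0.001, N=1e5 the exact gap is 1.58e-4 (mpmath-frozen)."""
    sigma, N = 0.001, 100_000
    first, _ = model._dlnZ_finite(np.array([1.0]), sigma, N)
    theta_fin = (1.0 + sigma) / N * first[0]
    sp = model._spectrum(np.array([1.0]), sigma)
    theta_long = (1.0 + sigma) * sp.l1p[0] / sp.l1[0]
    gap = abs(theta_fin - theta_long)
    assert gap == pytest.approx(1.58272e-4, rel=1e-4)
    # an order smaller again at N=1e6
    first6, _ = model._dlnZ_finite(np.array([1.0]), sigma, 10 * N)
    gap6 = abs((1.0 + sigma) / (10 * N) * first6[0] - theta_long)
    assert gap6 == pytest.approx(gap / 10.0, rel=1e-3)


def test_helicity_monotone_through_the_melting_transition(truth_long, transition_grid):
    th = np.asarray(hf.helicity(transition_grid, truth_long, mode="long"))
    assert np.all(np.diff(th) <= 1e-12)


# ---------------------------------------------------------------------------
# internal energy and heat capacity
# ---------------------------------------------------------------------------


def _log_Z_solvated(T, p, mode):
    """Full log partition function including the solvent background factor."""
    s = hf.stability_parameter(T, p)
    beta = 1.0 / (R * (T - p.t0))
    log_c2 = 2.0 * (np.logaddexp(math.log(p.q - 1.0), p.hps * beta) - math.log(p.q))
    return p.N * log_c2 + hf.log_partition_function(s, p.sigma, p.N, mode)


@pytest.mark.parametrize("mode", ["long", "finite"])
def test_internal_energy_matches_inverse_temperature_derivative(truth_long, mode):
    """E equals -d(lnZ_full)/d(beta_eff) by central difference, step 1e-4 K."""
    p = truth_long.replace(N=100)
    for T in (330.0, 360.0, 390.0):
        dT = 1e-4
        beta = lambda t: 1.0 / (R * (t - p.t0))
        dlnz = _log_Z_solvated(T + dT, p, mode) - _log_Z_solvated(T - dT, p, mode)
        dbeta = beta(T + dT) - beta(T - dT)
        expected = -dlnz / dbeta
        got = hf.internal_energy(T, p, mode=mode)
        assert got == pytest.approx(expected, rel=1e-4)


def test_internal_energy_constant_when_bonding_vanishes():
    p = hf.ModelParameters(t0=200.0, h=0.0, hps=0.0, Q=50.0, N=100)
    e = np.asarray(hf.internal_energy(np.linspace(280.0, 400.0, 50), p))
    assert np.allclose(e, e[0], atol=1e-9)


def test_internal_energy_is_smooth(truth_long, transition_grid):
    e = np.asarray(hf.internal_energy(transition_grid, truth_long.replace(N=100)))
    slopes = np.diff(e) / np.diff(transition_grid)
    assert np.all(np.isfinite(slopes))
    # no jumps: consecutive slopes vary smoothly on this fine grid
    assert np.max(np.abs(np.diff(slopes))) < 0.05 * np.max(np.abs(slopes))


@pytest.mark.parametrize("mode", ["long", "finite"])
def test_heat_capacity_is_the_derivative_of_the_energy(truth_long, transition_grid, mode):
    p = truth_long.replace(N=100)
    dT = 1e-3
    dEdT = (
        np.asarray(hf.internal_energy(transition_grid + dT, p, mode=mode))
        - np.asarray(hf.internal_energy(transition_grid - dT, p, mode=mode))
    ) / (2.0 * dT)
    c = np.asarray(hf.heat_capacity(transition_grid, p, mode=mode))
    scale = np.max(np.abs(dEdT))
    assert np.max(np.abs(c - dEdT)) / scale < 1e-3


def test_heat_capacity_reduces_to_helix_term_without_solvent_bonding():
    p = hf.ModelParameters(t0=210.0, h=6000.0, hps=0.0, Q=50.0, N=100)
    T = np.linspace(300.0, 420.0, 50)
    c = np.asarray(hf.heat_capacity(T, p))
    dT = 1e-4
    dtheta = (
        np.asarray(hf.helicity(T + dT, p)) - np.asarray(hf.helicity(T - dT, p))
    ) / (2.0 * dT)
    expected = -2.0 * p.N * p.h * dtheta
    scale = np.max(np.abs(expected))
    np.testing.assert_allclose(c, expected, atol=1e-5 * scale)


def test_heat_capacity_peaks_near_the_melting_midpoint(truth_long):
    p = truth_long.replace(N=100)
    tm = hf.melting_temperature(p)
    T = np.linspace(tm - 40.0, tm + 40.0, 400)
    c = np.asarray(hf.heat_capacity(T, p))
    peaks = np.nonzero((c[1:-1] > c[:-2]) & (c[1:-1] > c[2:]))[0]
    assert peaks.size == 1
    # the peak of the excess heat capacity tracks the theta = 1/2 midpoint;
    # the offset grows with transition width, ~6 K for this fixture
    assert abs(T[peaks[0] + 1] - tm) < 10.0
    assert hf.heat_capacity(tm, p, per_residue=True) == pytest.approx(
        hf.heat_capacity(tm, p) / p.N, rel=1e-14
    )


def test_no_overflow_at_parameter_extremes():
    for h, hps in [(1e5, 1e5), (1e5, -1e5), (-1e5, 1e5), (-1e5, -1e5)]:
        p = hf.ModelParameters(t0=299.0, h=h, hps=hps, Q=100.0, N=1_000_000)
        for T in (300.0, 350.0, 1000.0):
            s = hf.stability_parameter(T, p)
            assert np.isfinite(s)
            assert np.isfinite(hf.log_partition_function(max(s, 0.0), p.sigma, p.N, "long"))
            for f in (hf.helicity, hf.internal_energy, hf.heat_capacity):
                assert np.isfinite(f(T, p))


# ---------------------------------------------------------------------------
# melting temperature
# ---------------------------------------------------------------------------


def test_melting_temperature_agrees_with_dense_grid_scan(truth_long):
    tm = hf.melting_temperature(truth_long)
    grid = np.linspace(330.0, 420.0, 400_001)  # 0.000225 K spacing
    th = np.asarray(hf.helicity(grid, truth_long))
    scan = grid[np.argmin(np.abs(th - 0.5))]
    assert tm == pytest.approx(scan, abs=1e-3)
    assert tm == pytest.approx(386.2336, abs=1e-3)  # frozen fixture regression


def test_melting_temperature_invariant_under_window_refinement(truth_long):
    a = hf.melting_temperature(truth_long, t_range=(300.0, 420.0), xtol=1e-6)
    b = hf.melting_temperature(truth_long, t_range=(350.0, 500.0), xtol=1e-6)
    assert a == pytest.approx(b, abs=1e-4)


def test_melting_temperature_not_found_when_always_helical():
    p = hf.ModelParameters(t0=200.0, h=20000.0, hps=1000.0, Q=5.0, N=100)
    with pytest.raises(RootNotFoundError):
        hf.melting_temperature(p, t_range=(250.0, 400.0))
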