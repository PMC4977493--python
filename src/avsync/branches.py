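"""Analytic synchronized branches of the balanced delayed network.

For balanced coupling (kappa1 = kappa2 = kappa) the frequency-synchronized
state theta_i(t) = Omega*t + psi_i reduces the dynamics to three algebraic
equations in the collective frequency Omega and the phase shifts
phi1 = theta3 - theta1, phi2 = theta3 - theta2.  For visual-leads dynamics:

    Omega = omega1 + kappa * sin(phi1)
    Omega = omega2 + kappa * sin(phi2 - Omega*tau)
    Omega = omega3 - kappa * sin(phi1) - kappa * sin(phi2 + Omega*tau)

Summing eliminates phi1 and yields the transcendental collective-frequency
equation

    Omega = mean(omega) - (2*kappa/3) * sin(Omega*tau) * cos(phi2),
    phi2  = Omega*tau + arcsin((Omega - omega2) / kappa),

whose multiple roots are the candidate synchronized states (the
auditory-leads case swaps the roles of phi1/omega1 and phi2/omega2).  Both
arcsin branches (x and pi - x) are enumerated for each phase shift; the
stability filter prunes the spurious fixed points.

Linear stability: perturbing the locked state and linearizing gives a DDE
with instantaneous coefficient A = kappa*cos(phi_inst) on the undelayed
edge and delayed coefficients B = kappa*cos(phi_del - Omega*tau),
C = kappa*cos(phi_del + Omega*tau) on the delayed edge.  Two verdict modes
are provided:

* ``"spectral"`` (default): eigenvalues of a pseudospectral (Chebyshev
  collocation) discretization of the linearized DDE's generator — the full
  quasi-polynomial spectrum, including the delay exponentials.
* ``"cubic"``: roots of the cubic obtained by dropping the delay
  exponentials from the characteristic function,
  lambda * (lambda**2 + (2A + B + C)*lambda + A*(2B + C)) = 0.

The cubic is cheap and correct near tau = 0 but can over-report stability
at large Omega*tau, where the delay exponentials matter; the spectral
verdict agrees with direct perturbation tests of the nonlinear DDE and is
therefore the default.  In both modes the structural zero eigenvalue from
global phase invariance is identified and excluded from the verdict.

The closed-form order parameter of a locked configuration is

    R = |1 + exp(-i*phi1) + exp(-i*phi2)| / 3
      = sqrt(3 + 2*cos(phi1) + 2*cos(phi2) + 2*cos(phi1 - phi2)) / 3.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .model import LagSign, NetworkParams

__all__ = [
    "SynchronizedBranch",
    "UnbalancedCouplingError",
    "BranchDoesNotExistError",
    "collective_frequencies",
    "phase_shifts",
    "phase_shift_candidates",
    "fixed_point_residual",
    "stability",
    "closed_form_R",
    "enumerate_branches",
    "stable_branches",
    "locked_initial_state",
]

_ROOT_TOL = 1e-10
_FP_TOL = 1e-6
_ZERO_MODE_TOL = 1e-9


class UnbalancedCouplingError(ValueError):
    """The analytic theory covers balanced coupling only."""


class BranchDoesNotExistError(ValueError):
    """No locked state exists at this collective frequency (arcsin domain)."""


@dataclass(frozen=True)
class SynchronizedBranch:
    """One analytic synchronized state.

    ``eigenvalues`` are the characteristic roots used for the verdict
    (spectral or cubic mode); ``stable`` means no eigenvalue has positive
    real part once the structural zero mode is excluded.
    """

    Omega: float
    phi1: float
    phi2: float
    eigenvalues: Tuple[complex, ...]
    stable: bool
    R: float
    lag_sign: LagSign
    #: arcsin-branch indices (0 = principal, 1 = pi - arcsin) for phi1, phi2
    arcsin_branches: Tuple[int, int] = (0, 0)


def _require_balanced(params: NetworkParams) -> float:
    if not params.balanced:
        raise UnbalancedCouplingError(
            "analytic branches exist only for balanced coupling "
            f"(kappa1 = kappa2); got kappa1={params.kappa1}, "
            f"kappa2={params.kappa2}. Use numerical integration instead."
        )
    return params.kappa1


def _delayed_omega(params: NetworkParams) -> float:
    """Intrinsic frequency of the node on the delayed edge."""
    return (
        params.omega2
        if params.lag_sign == LagSign.VISUAL_LEADS
        else params.omega1
    )


def _sum_residual(Omega: float, params: NetworkParams, arcsin_branch: int) -> float:
    """Residual of the summed (collective-frequency) equation at Omega.

    ``arcsin_branch`` selects the principal (0) or pi - arcsin (1) branch
    of the delayed-edge phase shift.  Returns NaN outside the arcsin domain.
    """
    kappa = params.kappa1
    s = (Omega - _delayed_omega(params)) / kappa
    if abs(s) > 1.0:
        return math.nan
    inner = math.asin(s) if arcsin_branch == 0 else math.pi - math.asin(s)
    phi_del = Omega * params.tau + inner
    wsum = params.omega1 + params.omega2 + params.omega3
    return 3.0 * Omega - wsum + 2.0 * kappa * math.sin(Omega * params.tau) * math.cos(phi_del)


def collective_frequencies(
    params: NetworkParams,
    omega_bracket: Optional[Tuple[float, float]] = None,
    n_grid: int = 2000,
) -> List[float]:
    """All real roots of the collective-frequency equation in the bracket.

    Scans ``n_grid`` points for sign changes and polishes each bracketed
    root; both arcsin branches of the delayed-edge phase shift are scanned
    so no candidate synchronized state is missed.  Roots are merged at
    tolerance 1e-8 and satisfy |residual| < 1e-10.

    The default bracket [min(omega) - 2*kappa, max(omega) + 2*kappa]
    contains all candidate roots (each locked-state equation bounds
    |Omega - omega_i| by at most 2*kappa).
    """
    kappa = _require_balanced(params)
    if omega_bracket is None:
        w = params.omegas
        omega_bracket = (min(w) - 2.0 * kappa, max(w) + 2.0 * kappa)
    lo, hi = omega_bracket
    if not (hi > lo):
        raise ValueError(f"empty bracket {omega_bracket}")
    if kappa == 0.0:
        return []  # uncoupled oscillators never share a frequency
    grid = np.linspace(lo, hi, n_grid)
    roots: List[float] = []
    for branch in (0, 1):
        vals = np.array([_sum_residual(x, params, branch) for x in grid])
        for i in range(n_grid - 1):
            a, b = vals[i], vals[i + 1]
            if math.isnan(a) or math.isnan(b):
                continue
            if a == 0.0:
                roots.append(float(grid[i]))
            elif a * b < 0.0:
                r = brentq(
                    _sum_residual, grid[i], grid[i + 1],
                    args=(params, branch), xtol=1e-14, rtol=1e-15,
                )
                roots.append(float(r))
        if vals[-1] == 0.0:
            roots.append(float(grid[-1]))
    merged: List[float] = []
    for r in sorted(roots):
        if not merged or abs(r - merged[-1]) > 1e-8:
            merged.append(r)
    return merged


def phase_shift_candidates(
    Omega: float, params: NetworkParams
) -> List[Tuple[float, float, Tuple[int, int]]]:
    """All four (phi1, phi2) arcsin-branch combinations at frequency Omega.

    The principal/principal pair comes first.  Raises
    :class:`BranchDoesNotExistError` if either arcsin argument lies outside
    [-1, 1] (no locked state at this Omega).
    """
    kappa = _require_balanced(params)
    s1 = (Omega - params.omega1) / kappa
    s2 = (Omega - params.omega2) / kappa
    if abs(s1) > 1.0 or abs(s2) > 1.0:
        raise BranchDoesNotExistError(
            f"no locked state at Omega={Omega}: |Omega - omega_i| > kappa"
        )
    shift = Omega * params.tau
    if params.lag_sign == LagSign.VISUAL_LEADS:
        phi1_opts = [math.asin(s1), math.pi - math.asin(s1)]
        phi2_opts = [shift + math.asin(s2), shift + math.pi - math.asin(s2)]
    else:
        phi1_opts = [shift + math.asin(s1), shift + math.pi - math.asin(s1)]
        phi2_opts = [math.asin(s2), math.pi - math.asin(s2)]
    out = []
    for b1, p1 in enumerate(phi1_opts):
        for b2, p2 in enumerate(phi2_opts):
            out.append((p1, p2, (b1, b2)))
    return out


def phase_shifts(Omega: float, params: NetworkParams) -> Tuple[float, float]:
    """Principal-branch phase shifts (phi1, phi2) at frequency Omega."""
    return phase_shift_candidates(Omega, params)[0][:2]


def fixed_point_residual(
    Omega: float, phi1: float, phi2: float, params: NetworkParams
) -> float:
    """Max absolute residual of the three locked-state equations."""
    kappa = _require_balanced(params)
    w1, w2, w3 = params.omegas
    ot = Omega * params.tau
    if params.lag_sign == LagSign.VISUAL_LEADS:
        r1 = w1 + kappa * math.sin(phi1) - Omega
        r2 = w2 + kappa * math.sin(phi2 - ot) - Omega
        r3 = w3 - kappa * math.sin(phi1) - kappa * math.sin(phi2 + ot) - Omega
    else:
        r1 = w1 + kappa * math.sin(phi1 - ot) - Omega
        r2 = w2 + kappa * math.sin(phi2) - Omega
        r3 = w3 - kappa * math.sin(phi1 + ot) - kappa * math.sin(phi2) - Omega
    return max(abs(r1), abs(r2), abs(r3))


def _linearization_matrices(
    Omega: float, phi1: float, phi2: float, params: NetworkParams
) -> Tuple[np.ndarray, np.ndarray, Tuple[float, float, float]]:
    """Instantaneous (L0) and delayed (L1) Jacobians of the locked state."""
    kappa = params.kappa1
    ot = Omega * params.tau
    if params.lag_sign == LagSign.VISUAL_LEADS:
        A = kappa * math.cos(phi1)
        B = kappa * math.cos(phi2 - ot)
        C = kappa * math.cos(phi2 + ot)
        L0 = np.array([[-A, 0.0, A], [0.0, -B, 0.0], [A, 0.0, -A - C]])
        L1 = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, B], [0.0, C, 0.0]])
    else:
        A = kappa * math.cos(phi2)
        B = kappa * math.cos(phi1 - ot)
        C = kappa * math.cos(phi1 + ot)
        L0 = np.array([[-B, 0.0, 0.0], [0.0, -A, A], [0.0, A, -A - C]])
        L1 = np.array([[0.0, 0.0, B], [0.0, 0.0, 0.0], [C, 0.0, 0.0]])
    return L0, L1, (A, B, C)


def _chebyshev_diff(m: int) -> Tuple[np.ndarray, np.ndarray]:
    """Chebyshev differentiation matrix and nodes on [-1, 1] (Trefethen)."""
    x = np.cos(np.pi * np.arange(m + 1) / m)
    c = np.ones(m + 1)
    c[0] = c[-1] = 2.0
    c *= (-1.0) ** np.arange(m + 1)
    X = np.tile(x, (m + 1, 1)).T
    dX = X - X.T
    D = np.outer(c, 1.0 / c) / (dX + np.eye(m + 1))
    D -= np.diag(D.sum(axis=1))
    return D, x


def _spectral_eigs(
    L0: np.ndarray, L1: np.ndarray, tau: float, m: int = 32
) -> np.ndarray:
    """Characteristic roots of xdot = L0 x(t) + L1 x(t - tau).

    Pseudospectral collocation of the solution-operator generator on m+1
    Chebyshev nodes over [-tau, 0]; the rightmost roots (the ones that
    decide stability) converge spectrally fast in m.
    """
    n = L0.shape[0]
    if tau == 0.0:
        return np.linalg.eigvals(L0 + L1)
    D, _ = _chebyshev_diff(m)
    D = D * (2.0 / tau)  # map [-1, 1] -> [-tau, 0]
    M = np.kron(D, np.eye(n))
    M[:n, :] = 0.0
    M[:n, :n] = L0
    M[:n, -n:] = L1
    return np.linalg.eigvals(M)


def stability(
    Omega: float,
    phi1: float,
    phi2: float,
    params: NetworkParams,
    mode: str = "spectral",
    n_cheb: int = 32,
) -> Tuple[Tuple[complex, ...], bool]:
    """Linear stability of a locked state (see module docstring for modes).

    Returns ``(eigenvalues, stable)``.  Raises ValueError if (Omega, phi1,
    phi2) is not a fixed point (residual >= 1e-6).
    """
    res = fixed_point_residual(Omega, phi1, phi2, params)
    if res >= _FP_TOL:
        raise ValueError(
            f"(Omega, phi1, phi2) is not a fixed point: residual {res:.3g} >= {_FP_TOL}"
        )
    L0, L1, (A, B, C) = _linearization_matrices(Omega, phi1, phi2, params)
    if mode == "cubic":
        lam = np.roots([1.0, 2.0 * A + B + C, A * (2.0 * B + C)])
        eigs = tuple(complex(v) for v in lam) + (0j,)
    elif mode == "spectral":
        eigs = tuple(
            complex(v) for v in _spectral_eigs(L0, L1, params.tau, m=n_cheb)
        )
    else:
        raise ValueError(f"unknown stability mode {mode!r}")
    # exclude the structural zero mode (global phase invariance): the single
    # root closest to the origin, which must itself be numerically zero
    mags = [abs(v) for v in eigs]
    izero = int(np.argmin(mags))
    rest = [v for i, v in enumerate(eigs) if i != izero]
    stable = all(v.real <= _ZERO_MODE_TOL for v in rest)
    return eigs, stable


def closed_form_R(phi1: float, phi2: float) -> float:
    """Order parameter of a locked configuration with phase shifts phi1, phi2."""
    return abs(1.0 + cmath.exp(-1j * phi1) + cmath.exp(-1j * phi2)) / 3.0


def enumerate_branches(
    params: NetworkParams,
    omega_bracket: Optional[Tuple[float, float]] = None,
    n_grid: int = 2000,
    stability_mode: str = "spectral",
) -> List[SynchronizedBranch]:
    """All synchronized fixed points (stable and unstable).

    Pipeline: collective-frequency roots -> all four arcsin-branch
    combinations of (phi1, phi2) -> full fixed-point filter -> stability.
    Duplicate fixed points (phase shifts equal mod 2*pi) are merged.
    """
    out: List[SynchronizedBranch] = []
    seen = []
    for Omega in collective_frequencies(params, omega_bracket, n_grid):
        try:
            cands = phase_shift_candidates(Omega, params)
        except BranchDoesNotExistError:
            continue
        for p1, p2, bidx in cands:
            if fixed_point_residual(Omega, p1, p2, params) >= 1e-9:
                continue
            key = (
                round(Omega, 8),
                round(p1 % (2.0 * math.pi), 8),
                round(p2 % (2.0 * math.pi), 8),
            )
            if key in seen:
                continue
            seen.append(key)
            eigs, stab = stability(Omega, p1, p2, params, mode=stability_mode)
            out.append(
                SynchronizedBranch(
                    Omega=Omega,
                    phi1=p1,
                    phi2=p2,
                    eigenvalues=eigs,
                    stable=stab,
                    R=closed_form_R(p1, p2),
                    lag_sign=params.lag_sign,
                    arcsin_branches=bidx,
                )
            )
    return out


def stable_branches(
    params: NetworkParams,
    omega_bracket: Optional[Tuple[float, float]] = None,
    n_grid: int = 2000,
    stability_mode: str = "spectral",
) -> List[SynchronizedBranch]:
    """The stable synchronized branches (full analytic pipeline)."""
    return [
        b
        for b in enumerate_branches(params, omega_bracket, n_grid, stability_mode)
        if b.stable
    ]


def locked_initial_state(branch: SynchronizedBranch) -> Tuple[np.ndarray, np.ndarray]:
    """Initial phases and history rates that seed the DDE at this branch.

    Returns ``(theta0, history_rates)`` with theta0 = (-phi1, -phi2, 0) and
    all history rates equal to Omega, so the linear initial history is the
    locked solution itself.
    """
    theta0 = np.array([-branch.phi1, -branch.phi2, 0.0])
    rates = np.full(3, branch.Omega)
    return theta0, rates
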