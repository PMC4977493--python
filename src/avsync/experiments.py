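"""Sweep and scan drivers: coupling/delay sweeps, multistability, critical delay.

Conventions shared by all drivers:

* "Negative lag" conditions run the auditory-leads equations with a
  positive delay magnitude; results can be plotted on a mirrored tau axis.
* Every run's initial phases come from a seeded generator; per-run seeds
  are derived from the sweep seed and the run's grid indices, so a sweep is
  reproducible row-for-row regardless of execution order.
* Steady-state summaries discard the first 75% of the horizon as transient.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .branches import SynchronizedBranch, locked_initial_state
from .integrator import DEFAULT_HORIZON, Trajectory, integrate
from .metrics import order_parameter, steady_state
from .model import LagSign, NetworkParams

__all__ = [
    "SweepResult",
    "run_single",
    "sweep_balanced",
    "sweep_unbalanced",
    "multistability_scan",
    "critical_delay",
    "CriticalDelayResult",
    "island_size",
    "hysteresis_trace",
    "perturbation_decay",
    "cluster_levels",
    "default_tau_grid",
]

#: Default delay grid for theta-band frequencies (3, 4, 5): covers both
#: printed transitions.
DEFAULT_TAU_MAX = 1.5
DEFAULT_TAU_STEP = 0.01
DEFAULT_N_IC = 24


def default_tau_grid(
    tau_max: float = DEFAULT_TAU_MAX, step: float = DEFAULT_TAU_STEP
) -> np.ndarray:
    return np.round(np.arange(0.0, tau_max + step / 2, step), 10)


def _run_seed(seed: int, *indices: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *indices]))


@dataclass
class SweepResult:
    """Tidy sweep table plus the provenance needed to re-run it."""

    df: pd.DataFrame
    config: dict
    seed: int

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def sidecar(self) -> dict:
        from . import __version__

        return {
            "config": self.config,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": __version__,
        }

    def write(self, csv_path, sidecar_path=None) -> None:
        self.df.to_csv(csv_path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.sidecar(), fh, indent=2, default=str)


def run_single(
    params: NetworkParams,
    initial_phases: Sequence[float],
    horizon: float = DEFAULT_HORIZON,
    tail_fraction: float = 0.25,
    history_rates: Optional[Sequence[float]] = None,
) -> dict:
    """Integrate one condition and summarize its steady state as a row."""
    traj = integrate(params, initial_phases, horizon=horizon, history_rates=history_rates)
    ss = steady_state(order_parameter(traj), traj, tail_fraction=tail_fraction)
    th0 = np.asarray(initial_phases, float)
    return {
        "kappa1": params.kappa1,
        "kappa2": params.kappa2,
        "tau": params.tau,
        "lag_sign": params.lag_sign.value,
        "theta0_1": th0[0],
        "theta0_2": th0[1],
        "theta0_3": th0[2],
        "R_ss": ss.R_ss,
        "R_sd": ss.R_sd,
        "synchronized": ss.synchronized,
        "Omega_hat": ss.Omega_hat,
    }


def _sweep(
    kappa_pairs: Sequence[Tuple[float, float]],
    taus: Sequence[float],
    omegas: Tuple[float, float, float],
    lag_signs: Sequence[LagSign],
    n_ic: int,
    seed: int,
    horizon: float,
    config: dict,
) -> SweepResult:
    rows = []
    for ik, (k1, k2) in enumerate(kappa_pairs):
        for isg, sign in enumerate(lag_signs):
            for it, tau in enumerate(taus):
                params = NetworkParams(*omegas, k1, k2, float(tau), sign)
                for ic in range(n_ic):
                    rng = _run_seed(seed, ik, isg, it, ic)
                    th0 = rng.uniform(0.0, 2.0 * np.pi, 3)
                    row = run_single(params, th0, horizon=horizon)
                    row.update(ic_index=ic, seed=seed)
                    rows.append(row)
    return SweepResult(df=pd.DataFrame(rows), config=config, seed=seed)


def sweep_balanced(
    kappas: Sequence[float],
    taus: Optional[Sequence[float]] = None,
    omegas: Tuple[float, float, float] = (3.0, 4.0, 5.0),
    lag_signs: Sequence[LagSign | str] = (LagSign.VISUAL_LEADS, LagSign.AUDITORY_LEADS),
    n_ic: int = DEFAULT_N_IC,
    seed: int = 0,
    horizon: float = DEFAULT_HORIZON,
) -> SweepResult:
    """Balanced-coupling sweep: R_ss(tau; kappa) from random initial phases.

    For theta-band frequencies (3, 4, 5) this reproduces the two-plateau
    structure: one synchronized level near R = 1 and a partially
    synchronized level near R = 0.33, separated by a critical delay.
    """
    if len(kappas) == 0:
        raise ValueError("kappa list is empty")
    taus = default_tau_grid() if taus is None else np.asarray(taus, float)
    signs = [LagSign.coerce(s) for s in lag_signs]
    config = {
        "kind": "balanced",
        "kappas": list(map(float, kappas)),
        "taus": [float(t) for t in taus],
        "omegas": list(omegas),
        "lag_signs": [s.value for s in signs],
        "n_ic": n_ic,
        "horizon": horizon,
    }
    return _sweep(
        [(float(k), float(k)) for k in kappas],
        taus, omegas, signs, n_ic, seed, horizon, config,
    )


def sweep_unbalanced(
    fixed: Tuple[str, float],
    varied: Sequence[float],
    taus: Optional[Sequence[float]] = None,
    omegas: Tuple[float, float, float] = (3.0, 4.0, 5.0),
    lag_signs: Sequence[LagSign | str] = (LagSign.VISUAL_LEADS, LagSign.AUDITORY_LEADS),
    n_ic: int = DEFAULT_N_IC,
    seed: int = 0,
    horizon: float = DEFAULT_HORIZON,
) -> SweepResult:
    """Unbalanced sweep: one coupling fixed, the other varied over a grid.

    ``fixed`` is ``("kappa1", value)`` or ``("kappa2", value)``.
    """
    name, fval = fixed
    if name not in ("kappa1", "kappa2"):
        raise ValueError("fixed must name 'kappa1' or 'kappa2'")
    if len(varied) == 0:
        raise ValueError("varied coupling grid is empty")
    taus = default_tau_grid() if taus is None else np.asarray(taus, float)
    signs = [LagSign.coerce(s) for s in lag_signs]
    pairs = [
        (float(fval), float(v)) if name == "kappa1" else (float(v), float(fval))
        for v in varied
    ]
    config = {
        "kind": "unbalanced",
        "fixed": [name, float(fval)],
        "varied": list(map(float, varied)),
        "taus": [float(t) for t in taus],
        "omegas": list(omegas),
        "lag_signs": [s.value for s in signs],
        "n_ic": n_ic,
        "horizon": horizon,
    }
    return _sweep(pairs, taus, omegas, signs, n_ic, seed, horizon, config)


def cluster_levels(
    values: Sequence[float], radius: float = 0.02
) -> List[Tuple[float, int]]:
    """Greedy 1-D clustering of steady-state levels.

    Sorted values join the current cluster while within ``radius`` of its
    running mean; returns ``[(center, count), ...]`` sorted by center.
    """
    vals = sorted(float(v) for v in values)
    clusters: List[List[float]] = []
    for v in vals:
        if clusters and abs(v - np.mean(clusters[-1])) <= radius:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    return [(float(np.mean(c)), len(c)) for c in clusters]


def multistability_scan(
    params: NetworkParams,
    taus: Sequence[float],
    n_ic: int = DEFAULT_N_IC,
    seed: int = 0,
    cluster_radius: float = 0.02,
    horizon: float = DEFAULT_HORIZON,
) -> Tuple[Dict[float, List[Tuple[float, int]]], pd.DataFrame]:
    """Distinct locked steady-state levels per delay, over random initial phases.

    For each tau, integrates ``n_ic`` seeded random initial conditions,
    keeps the frequency-locked runs and clusters their R_ss values.
    Returns ``(levels, rows)`` where ``levels[tau]`` is a list of
    ``(center, basin_count)``; unlocked runs are excluded, so an uncoupled
    system reports no clusters.
    """
    if n_ic < 20:
        raise ValueError("n_ic >= 20 required for meaningful basin sampling")
    rows = []
    levels: Dict[float, List[Tuple[float, int]]] = {}
    for it, tau in enumerate(taus):
        p = params.replace(tau=float(tau))
        locked = []
        for ic in range(n_ic):
            rng = _run_seed(seed, it, ic)
            th0 = rng.uniform(0.0, 2.0 * np.pi, 3)
            row = run_single(p, th0, horizon=horizon)
            row.update(ic_index=ic, seed=seed)
            rows.append(row)
            if row["synchronized"]:
                locked.append(row["R_ss"])
        levels[float(tau)] = cluster_levels(locked, cluster_radius)
    return levels, pd.DataFrame(rows)


@dataclass
class CriticalDelayResult:
    """Critical delay per lag sign.

    ``tau_c[sign]`` is the smallest grid delay at which the in-phase-like
    state's R_ss drops below the threshold, or None when the threshold is
    never crossed within the grid (open-ended synchronization island).
    """

    taus: np.ndarray
    R_threshold: float
    tau_c: Dict[LagSign, Optional[float]]
    R_curves: Dict[LagSign, np.ndarray] = field(repr=False, default_factory=dict)

    def open_ended(self, sign: LagSign) -> bool:
        return self.tau_c[sign] is None


def _inphase_R_curve(
    params: NetworkParams, taus: Sequence[float], horizon: float
) -> np.ndarray:
    out = np.empty(len(taus))
    for i, tau in enumerate(taus):
        p = params.replace(tau=float(tau))
        row = run_single(p, np.zeros(3), horizon=horizon)
        out[i] = row["R_ss"] if row["synchronized"] else 0.0
    return out


def critical_delay(
    params: NetworkParams,
    R_threshold: float = 0.9,
    taus: Optional[Sequence[float]] = None,
    horizon: float = DEFAULT_HORIZON,
) -> CriticalDelayResult:
    """Edge of the synchronization island for both lag signs.

    The in-phase-like branch is tracked by integrating from in-phase
    initial conditions at every delay; the critical delay is where its
    steady R first drops below ``R_threshold``.  The transition value need
    not coincide for positive and negative lags, because the intrinsic
    frequencies differ.
    """
    if not (0.0 < R_threshold < 1.0):
        raise ValueError("R_threshold must lie in (0, 1)")
    taus = default_tau_grid() if taus is None else np.asarray(taus, float)
    tau_c: Dict[LagSign, Optional[float]] = {}
    curves: Dict[LagSign, np.ndarray] = {}
    for sign in (LagSign.VISUAL_LEADS, LagSign.AUDITORY_LEADS):
        p = params.replace(lag_sign=sign)
        R = _inphase_R_curve(p, taus, horizon)
        curves[sign] = R
        below = np.nonzero(R < R_threshold)[0]
        tau_c[sign] = float(taus[below[0]]) if below.size else None
    return CriticalDelayResult(
        taus=np.asarray(taus, float), R_threshold=R_threshold,
        tau_c=tau_c, R_curves=curves,
    )


def island_size(result: CriticalDelayResult, sign: LagSign) -> float:
    """Width (in delay units) of the synchronization island around zero lag.

    Counts the contiguous run of grid delays, starting from the smallest,
    over which the in-phase-like state keeps R_ss at or above the
    threshold; re-entrant synchronized windows at larger delays are not
    part of the island.  Assumes a uniform grid.
    """
    taus = result.taus
    dt = float(taus[1] - taus[0]) if taus.size > 1 else 1.0
    above = result.R_curves[sign] >= result.R_threshold
    n = 0
    for ok in above:
        if not ok:
            break
        n += 1
    return float(n * dt)


def hysteresis_trace(
    params: NetworkParams,
    taus: Sequence[float],
    direction: str = "up",
    initial_phases: Optional[Sequence[float]] = None,
    horizon: float = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """Continuation sweep: each delay starts from the previous final state.

    Stepping the delay up or down while reusing the attained state as the
    next initial condition exposes hysteresis between coexisting branches.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    order = np.asarray(taus, float)
    order = np.sort(order) if direction == "up" else np.sort(order)[::-1]
    th0 = np.zeros(3) if initial_phases is None else np.asarray(initial_phases, float)
    rows = []
    for tau in order:
        p = params.replace(tau=float(tau))
        traj = integrate(p, th0, horizon=horizon)
        ss = steady_state(order_parameter(traj), traj)
        rows.append(
            {"tau": float(tau), "R_ss": ss.R_ss, "synchronized": ss.synchronized,
             "Omega_hat": ss.Omega_hat}
        )
        # keep phases bounded; only phase differences matter to the dynamics
        th0 = np.mod(traj.theta[:, -1], 2.0 * np.pi)
    return pd.DataFrame(rows).sort_values("tau").reset_index(drop=True)


def perturbation_decay(
    branch: SynchronizedBranch,
    params: NetworkParams,
    eps: float = 1e-3,
    horizon: float = 60.0,
    seed: int = 0,
) -> Tuple[float, float]:
    """Deviation of a perturbed locked state from the exact locked solution.

    Seeds the integrator at the branch's locked configuration (linear
    history at the collective frequency) plus an ``eps``-sized random
    kick, and returns ``(initial_deviation, final_deviation)`` of the
    relative phases, wrapped to (-pi, pi].  Decay of the deviation is the
    direct dynamical counterpart of the linear stability verdict.
    """
    theta0, rates = locked_initial_state(branch)
    rng = np.random.default_rng(seed)
    kick = eps * rng.standard_normal(3)
    traj = integrate(params, theta0 + kick, horizon=horizon, history_rates=rates)

    def deviation(col: np.ndarray) -> float:
        rel = np.array([col[0] - col[2] + branch.phi1, col[1] - col[2] + branch.phi2])
        rel = np.mod(rel + np.pi, 2.0 * np.pi) - np.pi
        return float(np.linalg.norm(rel))

    return deviation(traj.theta[:, 0]), deviation(traj.theta[:, -1])
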