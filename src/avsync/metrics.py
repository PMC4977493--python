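"""Synchronization metrics: Kuramoto order parameter and steady-state summaries.

The complex order parameter of N oscillators is

    Z(t) = (1/N) sum_n exp(i * theta_n(t)) = R(t) * exp(i * Phi(t)),

with coherence amplitude R in [0, 1] (R = 1: all phases equal; R = 0:
maximally dispersed) and mean phase Phi.  Steady-state values are tail
averages rather than final samples, to damp residual numerical ripple; the
tail standard deviation is reported so callers can detect non-stationary
(unlocked) tails, where R oscillates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .integrator import Trajectory

__all__ = [
    "OrderParameterSeries",
    "SteadyStateSummary",
    "order_parameter",
    "instantaneous_frequencies",
    "steady_state",
    "LOCK_TOL",
]

#: Frequency-lock tolerance: max pairwise difference of tail-mean
#: instantaneous frequencies (model units) below which the three
#: oscillators are declared synchronized.
LOCK_TOL = 1e-3


@dataclass
class OrderParameterSeries:
    """R(t) and mean phase Phi(t) on the trajectory's time grid."""

    t: np.ndarray
    R: np.ndarray
    Phi: np.ndarray

    def __len__(self) -> int:
        return self.t.size


@dataclass
class SteadyStateSummary:
    """Tail summary of a run.

    ``Omega_hat`` is the common tail-mean frequency if all three
    oscillators' tail-mean frequencies agree within ``LOCK_TOL``
    (``synchronized`` records that verdict), else None.
    """

    R_ss: float
    R_sd: float
    Omega_hat: Optional[float]
    synchronized: bool


def order_parameter(traj: Trajectory) -> OrderParameterSeries:
    """Kuramoto order parameter of the three phases at every time point."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    Z = np.exp(1j * traj.theta).mean(axis=0)
    return OrderParameterSeries(t=traj.t, R=np.abs(Z), Phi=np.angle(Z))


def instantaneous_frequencies(traj: Trajectory) -> np.ndarray:
    """Centered finite-difference frequencies, shape (3, len(t)).

    Endpoints use one-sided differences.  Phases are stored unwrapped, so
    no unwrapping correction is needed.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 time points")
    return np.gradient(traj.theta, traj.t, axis=1)


def steady_state(
    series: OrderParameterSeries,
    traj: Trajectory,
    tail_fraction: float = 0.25,
) -> SteadyStateSummary:
    """Summarize the final ``tail_fraction`` of a run.

    Raises if the tail holds fewer than 10 samples.
    """
    if not (0 < tail_fraction < 1):
        raise ValueError(f"tail_fraction must be in (0, 1), got {tail_fraction}")
    n = len(series)
    i0 = int(np.floor(n * (1 - tail_fraction)))
    if n - i0 < 10:
        raise ValueError(
            f"tail of {n - i0} samples is too short (< 10); "
            "integrate longer or enlarge tail_fraction"
        )
    R_tail = series.R[i0:]
    freqs = instantaneous_frequencies(traj)[:, i0:]
    fmean = freqs.mean(axis=1)
    spread = fmean.max() - fmean.min()
    synchronized = bool(spread < LOCK_TOL)
    return SteadyStateSummary(
        R_ss=float(R_tail.mean()),
        R_sd=float(R_tail.std()),
        Omega_hat=float(fmean.mean()) if synchronized else None,
        synchronized=synchronized,
    )
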