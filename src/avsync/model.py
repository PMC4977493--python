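"""Three-oscillator delayed Kuramoto network for audiovisual integration.

The network has an auditory node A (phase ``theta1``), a visual node V
(``theta2``) and a multisensory node AV (``theta3``).  A and V are each
coupled bidirectionally to AV through sines of phase differences; there is
no direct A-V link.  The experimental audiovisual onset asynchrony is
modelled as a transmission delay ``tau`` on exactly one of the two edges:

* ``visual_leads`` (positive AV lag): the V-AV edge is delayed in both
  directions, the A-AV edge is instantaneous.
* ``auditory_leads`` (negative AV lag): the A-AV edge is delayed, the
  V-AV edge is instantaneous.

``tau`` is always non-negative; the sign of the experimental lag is carried
by ``lag_sign`` only, because the present dynamics may not depend on the
future.  Phases are kept unwrapped (plain reals, never reduced mod 2*pi) so
instantaneous frequencies are finite differences without unwrapping
artifacts.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, asdict
from typing import Tuple

__all__ = [
    "LagSign",
    "NetworkParams",
    "rhs_visual_leads",
    "rhs_auditory_leads",
]


class LagSign(str, enum.Enum):
    """Which unisensory stream leads, i.e. which edge carries the delay."""

    VISUAL_LEADS = "visual_leads"
    AUDITORY_LEADS = "auditory_leads"

    @classmethod
    def coerce(cls, value: "LagSign | str") -> "LagSign":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ValueError(
                f"lag_sign must be 'visual_leads' or 'auditory_leads', got {value!r}"
            ) from None


@dataclass(frozen=True)
class NetworkParams:
    """Full parameterization of the three-oscillator delayed network.

    Parameters
    ----------
    omega1, omega2, omega3 : float
        Intrinsic frequencies of A, V and AV (radians per model time unit).
    kappa1 : float
        A-AV coupling strength (dimensionless, >= 0).
    kappa2 : float
        V-AV coupling strength (>= 0).
    tau : float
        Coupling delay magnitude (model time units, >= 0).
    lag_sign : LagSign or str
        Which edge is delayed (see module docstring).
    """

    omega1: float
    omega2: float
    omega3: float
    kappa1: float
    kappa2: float
    tau: float
    lag_sign: LagSign = LagSign.VISUAL_LEADS

    def __post_init__(self) -> None:
        object.__setattr__(self, "lag_sign", LagSign.coerce(self.lag_sign))
        for name in ("omega1", "omega2", "omega3", "kappa1", "kappa2", "tau"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            object.__setattr__(self, name, float(v))
        if self.kappa1 < 0 or self.kappa2 < 0:
            raise ValueError("coupling strengths kappa1, kappa2 must be >= 0")
        if self.tau < 0:
            raise ValueError(
                "tau must be >= 0; select the delayed edge with lag_sign instead "
                "of using a negative delay"
            )

    @property
    def omegas(self) -> Tuple[float, float, float]:
        return (self.omega1, self.omega2, self.omega3)

    @property
    def balanced(self) -> bool:
        return self.kappa1 == self.kappa2

    def replace(self, **changes) -> "NetworkParams":
        d = self.to_dict()
        d.update(changes)
        return NetworkParams(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lag_sign"] = self.lag_sign.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        return cls(**d)


def _check_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"non-finite phase encountered: {v!r} (corrupted state)")


def rhs_visual_leads(
    current: Tuple[float, float, float],
    delayed_theta2: float,
    delayed_theta3: float,
    params: NetworkParams,
) -> Tuple[float, float, float]:
    """Phase velocities for positive AV lag (visual stream leads).

    The V-AV edge is delayed in both directions: AV sees ``theta2(t - tau)``
    and V sees ``theta3(t - tau)``.  The A-AV edge is instantaneous.

    Returns ``(dtheta1/dt, dtheta2/dt, dtheta3/dt)``.
    """
    t1, t2, t3 = current
    _check_finite(t1, t2, t3, delayed_theta2, delayed_theta3)
    p = params
    d1 = p.omega1 + p.kappa1 * math.sin(t3 - t1)
    d2 = p.omega2 + p.kappa2 * math.sin(delayed_theta3 - t2)
    d3 = (
        p.omega3
        + p.kappa1 * math.sin(t1 - t3)
        + p.kappa2 * math.sin(delayed_theta2 - t3)
    )
    return (d1, d2, d3)


def rhs_auditory_leads(
    current: Tuple[float, float, float],
    delayed_theta1: float,
    delayed_theta3: float,
    params: NetworkParams,
) -> Tuple[float, float, float]:
    """Phase velocities for negative AV lag (auditory stream leads).

    Mirror of :func:`rhs_visual_leads` with the A-AV edge delayed and the
    V-AV edge instantaneous.  The two systems are similar in form but not
    mirror images, because the intrinsic frequencies differ.
    """
    t1, t2, t3 = current
    _check_finite(t1, t2, t3, delayed_theta1, delayed_theta3)
    p = params
    d1 = p.omega1 + p.kappa1 * math.sin(delayed_theta3 - t1)
    d2 = p.omega2 + p.kappa2 * math.sin(t3 - t2)
    d3 = (
        p.omega3
        + p.kappa1 * math.sin(delayed_theta1 - t3)
        + p.kappa2 * math.sin(t2 - t3)
    )
    return (d1, d2, d3)
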