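"""Closed-form and semi-analytic results for motor-cluster transport.

This module implements the force-velocity laws, the steady-state
distributions of the number of bound motors (with unlimited or limited
binding sites), the birth-death master-equation solver used as an internal
cross-check, the binding-averaged cluster velocity and the stall forces.

Model summary
-------------
A cluster of ``n`` bound motors pulls a cargo against a dimensionless force
``f``; the whole load acts on the leading motor, whose stepping rates are
Boltzmann-weighted, ``p1 = p exp(-f delta)`` and ``q1 = q exp(f (1-delta))``.
The resulting cluster velocity (in steps/s) is

    V_n = p (1 - e^f r^n)(1 - r) / [ e^(f delta) (1 - r) + e^f (r - r^n) ],

with ``r = q/p``.  Non-processive motors bind and unbind; at steady state
the number bound follows a binomial-type distribution, and the average
cluster velocity conditions on at least one motor being bound:

    Vbar = sum_{n>=1} P_n V_n / (1 - P_0).

All distribution weights are accumulated in log space so that clusters of
hundreds of motors do not overflow factorial ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from .parameters import LoadSpec, MeanFieldParameters, MotorParameters

__all__ = [
    "BoundMotorDistribution",
    "mean_field_velocity",
    "leading_motor_rates",
    "leading_motor_velocity",
    "bound_distribution_unlimited",
    "bound_distribution_limited",
    "master_equation_steady_state",
    "average_cluster_velocity",
    "stall_force",
    "force_to_piconewtons",
    "NeverBoundError",
]

_NORM_TOL = 1e-12


class NeverBoundError(ValueError):
    """Raised when the cluster is never bound (P_0 = 1) and a conditional
    average over bound states is requested."""


@dataclass(frozen=True)
class BoundMotorDistribution:
    """Probabilities ``P_0 .. P_N`` of having n motors bound."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 1 or probs.size < 1:
            raise ValueError("probs must be a non-empty 1-d sequence")
        if np.any(probs < -_NORM_TOL):
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > _NORM_TOL:
            raise ValueError("probabilities must sum to 1 within 1e-12")

    @property
    def N(self) -> int:
        return self.probs.size - 1

    @property
    def p0(self) -> float:
        return float(self.probs[0])

    def mean(self) -> float:
        return float(np.arange(self.probs.size) @ self.probs)

    def peak_index(self) -> int:
        return int(np.argmax(self.probs))

    def total_variation(self, other: "BoundMotorDistribution") -> float:
        a, b = self.probs, other.probs
        m = max(a.size, b.size)
        a = np.pad(a, (0, m - a.size))
        b = np.pad(b, (0, m - b.size))
        return float(0.5 * np.abs(a - b).sum())

    @classmethod
    def from_log_weights(cls, logw: np.ndarray) -> "BoundMotorDistribution":
        logw = np.asarray(logw, dtype=float)
        finite = np.isfinite(logw)
        probs = np.zeros_like(logw)
        probs[finite] = np.exp(logw[finite] - logsumexp(logw[finite]))
        probs /= probs.sum()
        return cls(probs)


def mean_field_velocity(mf: MeanFieldParameters, F: float, n: int) -> float:
    """Velocity (nm/s) under equal load sharing: ``v (1 - (F/(Fs n))^w)``.

    ``F`` is the physical load (pN) shared by ``n`` bound motors.  The
    result is negative beyond the collective stall ``F > Fs * n``.
    """
    if n < 1:
        raise ValueError("number of bound motors must be >= 1")
    if F < 0:
        raise ValueError("load force must be non-negative")
    return mf.v * (1.0 - (F / (mf.Fs * n)) ** mf.w)


def leading_motor_rates(params: MotorParameters, f: float) -> tuple[float, float]:
    """Stepping rates of the loaded leading motor, ``(p1, q1)``."""
    if not np.isfinite(f):
        raise ValueError("dimensionless force must be finite")
    p1 = params.p * np.exp(-f * params.delta)
    q1 = params.q * np.exp(f * (1.0 - params.delta))
    return float(p1), float(q1)


def leading_motor_velocity(params: MotorParameters, f: float, n: int) -> float:
    """Average velocity (steps/s) of a cluster of ``n`` bound motors under a
    leading-motor load ``f``.

    For unidirectional motors (``q = 0``) this reduces to ``p exp(-f delta)``.
    The root in ``f`` is at ``f = n ln(p/q)``, the cluster stall force.
    """
    if n < 1:
        raise ValueError("number of bound motors must be >= 1")
    if not np.isfinite(f):
        raise ValueError("dimensionless force must be finite")
    p, q, delta = params.p, params.q, params.delta
    if p == 0.0 and q == 0.0:
        return 0.0
    if p == 0.0:
        raise ValueError("model assumes forward-biased stepping (p > 0)")
    if q == 0.0:
        return float(p * np.exp(-f * delta))
    r = q / p
    if r == 1.0:
        # continuous limit p -> q taken by a symmetric nudge
        r = 1.0 - 1e-12
    rn = r**n
    num = p * (1.0 - np.exp(f) * rn) * (1.0 - r)
    den = np.exp(f * delta) * (1.0 - r) + np.exp(f) * (r - rn)
    return float(num / den)


def bound_distribution_unlimited(params: MotorParameters, N: int) -> BoundMotorDistribution:
    """Steady-state distribution of the number bound, unlimited sites.

    ``P_n`` is proportional to ``C(N, n) (k_on/k_off)^n``: each motor is an
    independent two-state system.  ``k_off = 0`` with ``k_on > 0`` is treated
    as the all-bound limit (all mass at ``n = N``).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    kon, koff = params.k_on, params.k_off
    if kon + koff <= 0:
        raise ValueError("k_on + k_off must be positive")
    n = np.arange(N + 1)
    if koff == 0.0:
        probs = np.zeros(N + 1)
        probs[-1] = 1.0
        return BoundMotorDistribution(probs)
    if kon == 0.0:
        probs = np.zeros(N + 1)
        probs[0] = 1.0
        return BoundMotorDistribution(probs)
    logw = gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1) + n * np.log(kon / koff)
    return BoundMotorDistribution.from_log_weights(logw)


def bound_distribution_limited(params: MotorParameters, N: int, M: int) -> BoundMotorDistribution:
    """Steady-state distribution of the number bound with ``M`` binding sites.

    ``P_n`` is proportional to ``N! M! / (n! (N-n)! (M-n)!) (k_on^s/k_off)^n``
    with the per-site rate ``k_on^s = k_on / M``; entries beyond
    ``min(N, M)`` vanish.  Weights are accumulated in log space (exact to
    1e-12 relative for N, M up to a few hundred).
    """
    if N < 1 or M < 1:
        raise ValueError("N and M must be >= 1")
    kon, koff = params.k_on, params.k_off
    if kon + koff <= 0:
        raise ValueError("k_on + k_off must be positive")
    nmax = min(N, M)
    n = np.arange(N + 1)
    if koff == 0.0:
        probs = np.zeros(N + 1)
        probs[nmax] = 1.0
        return BoundMotorDistribution(probs)
    if kon == 0.0:
        probs = np.zeros(N + 1)
        probs[0] = 1.0
        return BoundMotorDistribution(probs)
    kons = kon / M
    logw = np.full(N + 1, -np.inf)
    nn = n[: nmax + 1]
    logw[: nmax + 1] = (
        gammaln(N + 1)
        - gammaln(nn + 1)
        - gammaln(N - nn + 1)
        + gammaln(M + 1)
        - gammaln(M - nn + 1)
        + nn * np.log(kons / koff)
    )
    return BoundMotorDistribution.from_log_weights(logw)


def master_equation_steady_state(
    params: MotorParameters, N: int, M: Optional[int] = None
) -> BoundMotorDistribution:
    """Numerical steady state of the bound-count birth-death chain.

    Solves ``dP_n/dt = 0`` for the chain with in-rate
    ``(N-n)(M-n) k_on/M`` (or ``(N-n) k_on`` when unlimited) and out-rate
    ``n k_off`` by a direct linear solve; serves as an independent check on
    the closed-form distributions and satisfies detailed balance.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if M is not None and M < 1:
        raise ValueError("M must be >= 1")
    kon, koff = params.k_on, params.k_off
    if kon + koff <= 0:
        raise ValueError("singular chain: all rates are zero")
    nmax = N if M is None else min(N, M)
    if koff == 0.0:
        probs = np.zeros(N + 1)
        probs[nmax] = 1.0
        return BoundMotorDistribution(probs)
    if kon == 0.0:
        probs = np.zeros(N + 1)
        probs[0] = 1.0
        return BoundMotorDistribution(probs)

    n = np.arange(N + 1)
    if M is None:
        up = (N - n) * kon
    else:
        up = (N - n) * np.maximum(M - n, 0) * (kon / M)
    down = n * koff
    # generator (columns sum to zero); replace one balance row with
    # normalization to pin the stationary vector
    A = np.zeros((N + 2, N + 1))
    for i in range(N + 1):
        A[i, i] = -(up[i] + down[i])
        if i > 0:
            A[i, i - 1] = up[i - 1]
        if i < N:
            A[i, i + 1] = down[i + 1]
    A[N + 1, :] = 1.0
    b = np.zeros(N + 2)
    b[N + 1] = 1.0
    probs, *_ = np.linalg.lstsq(A, b, rcond=None)
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    return BoundMotorDistribution(probs)


def _bound_distribution(
    params: MotorParameters, N: int, M: Optional[int]
) -> BoundMotorDistribution:
    if M is None:
        return bound_distribution_unlimited(params, N)
    return bound_distribution_limited(params, N, M)


def average_cluster_velocity(
    params: MotorParameters, f: float, N: int, M: Optional[int] = None
) -> float:
    """Binding-averaged cluster velocity (steps/s), conditioned on >= 1 bound.

    ``Vbar = sum_{n=1..N} P_n V_n / (1 - P_0)`` with the leading-motor
    velocity ``V_n`` and the unlimited (``M=None``) or limited bound-number
    distribution.
    """
    if params.k_on <= 0:
        raise NeverBoundError("k_on = 0: the cluster never binds")
    dist = _bound_distribution(params, N, M)
    p0 = dist.p0
    if 1.0 - p0 <= 1e-300:
        raise NeverBoundError("P_0 = 1 within tolerance: the cluster never binds")
    vn = np.array([leading_motor_velocity(params, f, n) for n in range(1, N + 1)])
    return float(dist.probs[1:] @ vn / (1.0 - p0))


def stall_force(
    params: MotorParameters,
    N: int,
    processive: bool = True,
    M: Optional[int] = None,
) -> float:
    """Dimensionless stall force of a cluster of ``N`` motors.

    Processive clusters stall at ``f_s(N) = N ln(p/q)`` exactly (linear in
    N).  For non-processive clusters the root of the binding-averaged
    velocity is bracketed on ``[0, N ln(p/q)]`` and found to 1e-8; it lies
    at or below the processive value because the cluster spends time with
    fewer than N motors bound.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if params.q == 0.0:
        raise ValueError("no finite stall force for unidirectional motors (q = 0)")
    if params.p <= params.q:
        raise ValueError("finite forward-biased stall requires p > q > 0")
    fs_proc = N * np.log(params.p / params.q)
    if processive:
        return float(fs_proc)
    if N == 1:
        # a single motor's conditional velocity is V_1: binding drops out
        return float(np.log(params.p / params.q))
    return float(
        brentq(
            lambda f: average_cluster_velocity(params, f, N, M),
            0.0,
            fs_proc,
            xtol=1e-8,
        )
    )


def force_to_piconewtons(load: LoadSpec, dx: float) -> float:
    """Convert a dimensionless force to pN: ``F = f kBT / dx``."""
    if dx <= 0:
        raise ValueError("dx must be positive")
    return load.f * load.kBT / dx
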