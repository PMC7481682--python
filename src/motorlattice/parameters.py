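"""Parameter records for motor clusters and the load they pull against.

A motor species is described by its forward/backward stepping rates ``p`` and
``q`` (s^-1), a load-distribution exponent ``delta`` that splits the
Boltzmann force factor between the forward and backward rates of the loaded
leading motor, binding/unbinding rates ``k_on``/``k_off`` (s^-1, with
``k_on`` quoted in the unlimited-binding-site convention) and the lattice
step size ``dx`` (nm).  Force enters the model in dimensionless form
``f = F * dx / (kB*T)``.

The module also holds the named presets used throughout the package:
kinesin-1 (processive), Ncd (kinesin-14, non-processive) and a weakly
non-processive axonal kinesin-1 parameterization.  All presets keep the
conventional forward/backward ratio ``p = 10 q``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "MotorParameters",
    "LoadSpec",
    "ClusterSpec",
    "MeanFieldParameters",
    "PRESETS",
    "get_preset",
    "preset_names",
]

#: thermal energy at 310 K (physiological temperature), pN nm
KBT_310K = 4.28


@dataclass(frozen=True)
class MotorParameters:
    """Kinetic constants of one motor species.

    Parameters
    ----------
    p, q
        Forward and backward stepping rates of an unloaded motor (s^-1).
    delta
        Load-distribution exponent in [0, 1]; the loaded leading motor steps
        forward at ``p * exp(-f*delta)`` and backward at
        ``q * exp(f*(1-delta))``.
    k_on, k_off
        Binding and unbinding rates (s^-1).  ``k_on`` uses the
        unlimited-binding-site convention; with a binding window of M sites
        the per-site rate is ``k_on / M``.  ``k_on == k_off == 0`` encodes a
        fully processive motor.
    dx
        Motor step size / lattice spacing (nm).
    """

    p: float
    q: float
    delta: float = 0.5
    k_on: float = 0.0
    k_off: float = 0.0
    dx: float = 8.0

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0:
            raise ValueError("stepping rates p, q must be non-negative")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("binding rates k_on, k_off must be non-negative")
        if self.dx <= 0:
            raise ValueError("step size dx must be positive")

    @property
    def processive(self) -> bool:
        """True when the motor never exchanges with solution."""
        return self.k_on == 0.0 and self.k_off == 0.0

    def with_(self, **kwargs) -> "MotorParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LoadSpec:
    """Dimensionless load force and the thermal energy used to convert it.

    The physical force is ``F = f * kBT / dx`` (pN for kBT in pN nm and dx
    in nm).
    """

    f: float
    kBT: float = KBT_310K

    def __post_init__(self) -> None:
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")


@dataclass(frozen=True)
class ClusterSpec:
    """A cluster of ``N`` motors with an optional binding-site limit ``M``.

    ``M=None`` is the unlimited-binding-site convention.
    """

    N: int
    M: Optional[int] = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("cluster must contain at least one motor")
        if self.M is not None and self.M < 1:
            raise ValueError("binding-site limit M must be >= 1")

    @property
    def limited(self) -> bool:
        return self.M is not None

    def k_on_per_site(self, k_on: float) -> float:
        """Per-site binding rate ``k_on / M`` (``k_on`` when unlimited)."""
        if self.M is None:
            return k_on
        return k_on / self.M


@dataclass(frozen=True)
class MeanFieldParameters:
    """Parameters of the equal-load-sharing force-velocity law.

    ``v`` is the unloaded velocity (nm/s), ``Fs`` the single-motor stall
    force (pN) and ``w`` the nonlinearity exponent.
    """

    v: float
    Fs: float
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("unloaded velocity must be non-negative")
        if self.Fs <= 0:
            raise ValueError("stall force must be positive")
        if self.w <= 0:
            raise ValueError("exponent w must be positive")


PRESETS: dict[str, MotorParameters] = {
    # processive kinesin-1, multi-motor stepping rates
    "kinesin1-processive": MotorParameters(p=100.0, q=10.0, delta=0.5, dx=8.0),
    # single kinesin-1 steps slightly faster than in an assembly
    "kinesin1-single": MotorParameters(p=110.0, q=11.0, delta=0.5, dx=8.0),
    # Ncd (kinesin-14), strongly non-processive
    "ncd": MotorParameters(p=22.0, q=2.2, delta=0.5, k_on=20.0, k_off=10.0, dx=8.0),
    # single Ncd steps more slowly than coupled Ncd
    "ncd-single": MotorParameters(p=11.0, q=1.1, delta=0.5, k_on=20.0, k_off=10.0, dx=8.0),
    # axonal kinesin-1: weakly non-processive, used for in vivo comparison
    "kinesin1-axonal": MotorParameters(p=100.0, q=10.0, delta=0.5, k_on=5.0, k_off=1.0, dx=8.0),
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str) -> MotorParameters:
    """Look up a named motor parameter preset.

    Raises ``KeyError`` listing the available names when unknown.
    """
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(preset_names())}"
        ) from None


def _check_preset_ratio() -> None:
    for name, prm in PRESETS.items():
        assert math.isclose(prm.p, 10 * prm.q), name


_check_preset_ratio()
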