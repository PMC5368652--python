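"""Circular statistics used by the spike-entrainment and coupling analyses."""

from __future__ import annotations

import numpy as np
from scipy import special

from .core import InsufficientDataError, wrap_phase

__all__ = [
    "resultant_length",
    "circular_mean",
    "rayleigh_test",
    "vonmises_R",
]


def resultant_length(phases: np.ndarray) -> float:
    """Mean resultant length R of a sample of angles.

    R = |mean(exp(i*phi))|; 0 for a uniform spread of phases, 1 when all
    phases coincide.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise InsufficientDataError("no phases supplied")
    return float(np.abs(np.exp(1j * phases).mean()))


def circular_mean(phases: np.ndarray) -> float:
    """Circular mean direction in [-pi, pi)."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise InsufficientDataError("no phases supplied")
    return float(wrap_phase(np.angle(np.exp(1j * phases).mean())))


def rayleigh_test(phases: np.ndarray) -> tuple[float, float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(R, z, p)`` with ``z = n * R**2`` and the standard closed-form
    approximation ``p = exp(sqrt(1 + 4n + 4(n^2 - (nR)^2)) - (1 + 2n))``
    (accurate for n >= 10; callers enforce the spike-count floor).
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n == 0:
        raise InsufficientDataError("Rayleigh test needs at least one phase")
    R = resultant_length(phases)
    z = n * R**2
    nR = n * R
    p = float(np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - nR**2)) - (1 + 2 * n)))
    return R, float(z), min(p, 1.0)


def vonmises_R(kappa: float) -> float:
    """Population mean resultant length of a von Mises distribution,
    I1(kappa)/I0(kappa)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))
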