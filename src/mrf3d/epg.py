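"""Extended phase graph (EPG) simulation primitives.

The EPG formalism represents the magnetization of a voxel as a ladder of
configuration states: transverse states ``F+_k`` / ``F-_k`` over integer
dephasing orders ``k`` and longitudinal states ``Z_k``.  Each RF pulse mixes
the three states at every order through a 3x3 rotation, an unbalanced
gradient moment shifts the transverse ladders by one order, and free
precession relaxes the states with T1/T2.  This gives an exact and fast
simulation of multi-pulse gradient-echo sequences under the ideal-spoiling
assumptions used for fingerprint dictionaries.

Phase convention
----------------
A transverse state is ``F = Mx + i*My`` and RF phase 0 means rotation about
the +x axis of the rotating frame (right-handed).  ``f_minus[k]`` stores the
complex conjugate of the ``F_{-k}`` state, so ``f_minus[0] == conj(f_plus[0])``
always holds for physically consistent states.

Spin-lock (T1rho) preparation is modeled as mono-exponential rotating-frame
decay of the stored longitudinal magnetization with perfect composite-pulse
compensation: the balanced, phase-alternated spin-lock cluster with paired
180+-x refocusing pulses is designed precisely so that B0/B1 imperfections
inside the preparation cancel, which is what justifies collapsing it to
``Z -> Z * exp(-TSL/T1rho)`` followed by a crusher.  The spin-lock amplitude
(nominally 500 Hz) is carried as sequence metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPGState",
    "TissueParams",
    "epg_rf",
    "epg_grad_shift",
    "epg_relax",
    "t1rho_prep",
    "inversion",
    "epg_norm",
    "rf_matrix",
]


@dataclass
class EPGState:
    """Configuration-state ladders of one isochromat ensemble.

    Attributes
    ----------
    f_plus, f_minus, z
        Complex vectors over dephasing orders ``k = 0..max_order``.
        ``f_minus[k]`` holds ``conj(F_{-k})``.
    max_order
        Highest retained dephasing order ``K``; states shifted beyond it
        are truncated (their energy is negligible for T2-damped trains).
    """

    f_plus: np.ndarray
    f_minus: np.ndarray
    z: np.ndarray
    max_order: int

    def __post_init__(self) -> None:
        n = self.max_order + 1
        for name in ("f_plus", "f_minus", "z"):
            v = np.asarray(getattr(self, name), dtype=np.complex128)
            if v.shape != (n,):
                raise ValueError(
                    f"{name} must have length max_order+1={n}, got {v.shape}"
                )
            setattr(self, name, v)

    @classmethod
    def equilibrium(cls, max_order: int = 250) -> "EPGState":
        """Thermal equilibrium: ``Z_0 = 1``, everything else zero."""
        n = max_order + 1
        z = np.zeros(n, dtype=np.complex128)
        z[0] = 1.0
        return cls(
            f_plus=np.zeros(n, dtype=np.complex128),
            f_minus=np.zeros(n, dtype=np.complex128),
            z=z,
            max_order=max_order,
        )

    def copy(self) -> "EPGState":
        return EPGState(
            self.f_plus.copy(), self.f_minus.copy(), self.z.copy(), self.max_order
        )

    @property
    def signal(self) -> complex:
        """Observable transverse magnetization ``F_0 = Mx + i*My``."""
        return complex(self.f_plus[0])


@dataclass(frozen=True)
class TissueParams:
    """Relaxation and scaling parameters of one tissue.

    t1, t2, t1rho are in milliseconds; pd is an arbitrary proton-density
    scale; b1_scale multiplies every nominal flip angle (transmit-field
    inhomogeneity).  ``t2 <= t1`` is enforced unless ``validate=False``
    (useful only for stress tests).
    """

    t1: float
    t2: float
    t1rho: float
    pd: float = 1.0
    b1_scale: float = 1.0
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("t1", "t2", "t1rho"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.pd < 0:
            raise ValueError(f"pd must be >= 0, got {self.pd}")
        if not (self.b1_scale > 0):
            raise ValueError(f"b1_scale must be > 0, got {self.b1_scale}")
        if self.validate and self.t2 > self.t1:
            raise ValueError(f"t2={self.t2} exceeds t1={self.t1}")


def rf_matrix(flip_deg: float, phase_deg: float) -> np.ndarray:
    """3x3 EPG rotation matrix acting on ``(F+_k, F-_k, Z_k)`` at every order.

    Phase 0 is rotation about +x; the matrix follows the ``F = Mx + i*My``
    convention stated in the module docstring.
    """
    a = math.radians(flip_deg)
    p = math.radians(phase_deg)
    ca, sa = math.cos(a), math.sin(a)
    c2 = math.cos(a / 2.0) ** 2
    s2 = math.sin(a / 2.0) ** 2
    eip = complex(math.cos(p), math.sin(p))
    eim = eip.conjugate()
    return np.array(
        [
            [c2, eip * eip * s2, -1j * eip * sa],
            [eim * eim * s2, c2, 1j * eim * sa],
            [-0.5j * eim * sa, 0.5j * eip * sa, ca],
        ],
        dtype=np.complex128,
    )


def epg_rf(state: EPGState, flip_deg: float, phase_deg: float) -> EPGState:
    """Apply an instantaneous RF rotation to every configuration order."""
    if not (math.isfinite(flip_deg) and math.isfinite(phase_deg)):
        raise ValueError("flip/phase must be finite")
    if flip_deg < 0:
        raise ValueError(f"flip_deg must be >= 0, got {flip_deg}")
    r = rf_matrix(flip_deg, phase_deg)
    stacked = np.vstack([state.f_plus, state.f_minus, state.z])
    out = r @ stacked
    return EPGState(out[0], out[1], out[2], state.max_order)


def epg_grad_shift(state: EPGState) -> EPGState:
    """One unit of unbalanced gradient dephasing.

    ``F+`` shifts up one order, ``F-`` shifts down one order; the state
    crossing k=0 reappears conjugated on the other ladder.  Z is unaffected.
    Orders beyond ``max_order`` are truncated.
    """
    fp = np.empty_like(state.f_plus)
    fm = np.empty_like(state.f_minus)
    fp[1:] = state.f_plus[:-1]
    fm[:-1] = state.f_minus[1:]
    fm[-1] = 0.0
    fp[0] = np.conj(fm[0])
    return EPGState(fp, fm, state.z.copy(), state.max_order)


def epg_relax(state: EPGState, dt: float, params: TissueParams) -> EPGState:
    """Free relaxation for ``dt`` ms: T2 decay of F states, T1 decay and
    recovery of Z (only ``Z_0`` recovers toward equilibrium)."""
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    e1 = math.exp(-dt / params.t1)
    e2 = math.exp(-dt / params.t2)
    z = state.z * e1
    z[0] += 1.0 - e1
    return EPGState(state.f_plus * e2, state.f_minus * e2, z, state.max_order)


def t1rho_prep(state: EPGState, tsl: float, params: TissueParams) -> EPGState:
    """Spin-lock preparation of duration ``tsl`` ms.

    Longitudinal states decay mono-exponentially with T1rho (the composite
    tip-back / balanced spin-lock / tip-up cluster is assumed perfectly
    compensated); residual transverse magnetization is crushed.
    """
    if tsl < 0:
        raise ValueError(f"tsl must be >= 0, got {tsl}")
    att = math.exp(-tsl / params.t1rho)
    return EPGState(
        np.zeros_like(state.f_plus),
        np.zeros_like(state.f_minus),
        state.z * att,
        state.max_order,
    )


def inversion(state: EPGState, efficiency: float = 1.0) -> EPGState:
    """Adiabatic inversion: Z negated and scaled by ``efficiency``,
    transverse states crushed.  Relaxation during the pulse is handled by
    the schedule, not here."""
    if not (0.0 <= efficiency <= 1.0):
        raise ValueError(f"efficiency must be in [0, 1], got {efficiency}")
    return EPGState(
        np.zeros_like(state.f_plus),
        np.zeros_like(state.f_minus),
        state.z * (-efficiency),
        state.max_order,
    )


def epg_norm(state: EPGState) -> float:
    """Magnitude of the state under the EPG inner product.

    Equals the isochromat-ensemble RMS magnetization magnitude; preserved
    exactly by RF rotations and contracted by relaxation (toward the
    equilibrium fixed point).
    """
    return math.sqrt(
        0.5 * (np.vdot(state.f_plus, state.f_plus).real
               + np.vdot(state.f_minus, state.f_minus).real)
        + np.vdot(state.z, state.z).real
    )
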