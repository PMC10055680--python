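"""Brute-force isochromat Bloch oracle.

Simulates an ensemble of isochromats whose intra-voxel gradient-dephasing
phases uniformly span one gradient cycle, replaying the same compiled event
table the EPG engine consumes.  Shares the EPG module's phase convention
(F = Mx + i*My, RF phase 0 = rotation about +x, right-handed rotations)
but none of its code path: rotations act on 3-vectors, dephasing is an
explicit per-spin phase, and the observed signal is the ensemble mean of
Mx + i*My.  Independence from the configuration-state algebra is the point.
"""

from __future__ import annotations

import numpy as np

from mrf3d._kernel import (
    OP_GRAD,
    OP_INVERSION,
    OP_RELAX,
    OP_RF,
    OP_SAMPLE,
    OP_SPOIL,
    OP_T1RHO,
)


def rotation_about_xy_axis(flip_deg: float, phase_deg: float) -> np.ndarray:
    """Right-handed rotation by flip about the axis at angle phase from +x
    in the transverse plane: Rz(phase) @ Rx(flip) @ Rz(-phase)."""
    a = np.deg2rad(flip_deg)
    p = np.deg2rad(phase_deg)
    ca, sa = np.cos(a), np.sin(a)
    cp, sp = np.cos(p), np.sin(p)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    rz = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]])
    return rz @ rx @ rz.T


def bloch_fingerprint(schedule, t1, t2, t1rho, b1=1.0, n_spins=2048):
    """Signal at each sample event for one tissue, from n_spins isochromats."""
    ops, a1, a2 = schedule.ops, schedule.a1, schedule.a2
    m = np.zeros((3, n_spins))
    m[2] = 1.0
    # per-spin dephasing increment per gradient event: one full cycle across the ensemble
    theta = 2.0 * np.pi * np.arange(n_spins) / n_spins
    ct, st = np.cos(theta), np.sin(theta)
    out = np.zeros(schedule.n_readouts, dtype=np.complex128)
    ridx = 0
    for e in range(len(ops)):
        op = ops[e]
        if op == OP_RF:
            r = rotation_about_xy_axis(a1[e] * b1, a2[e])
            m = r @ m
        elif op == OP_RELAX:
            dt = a1[e]
            e1, e2 = np.exp(-dt / t1), np.exp(-dt / t2)
            m[0] *= e2
            m[1] *= e2
            m[2] = m[2] * e1 + (1.0 - e1)
        elif op == OP_GRAD:
            mx = m[0] * ct - m[1] * st
            my = m[0] * st + m[1] * ct
            m[0], m[1] = mx, my
        elif op == OP_SAMPLE:
            out[ridx] = np.mean(m[0]) + 1j * np.mean(m[1])
            ridx += 1
        elif op == OP_SPOIL:
            m[0] = 0.0
            m[1] = 0.0
        elif op == OP_T1RHO:
            m[0] = 0.0
            m[1] = 0.0
            m[2] *= np.exp(-a1[e] / t1rho)
        elif op == OP_INVERSION:
            m[0] = 0.0
            m[1] = 0.0
            m[2] *= -a1[e]
    return out
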