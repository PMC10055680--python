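"""Acquisition schedule of the 3D-MRF sequence and fingerprint simulation.

The default schedule reproduces the published sequence design: a 10 ms
adiabatic inversion, a T1/T2 module of two FISP segments (250 excitations
each, flip-angle ramps peaking at 20 deg and 60 deg, 50 ms recovery delay
between segments), a T1/B1 module of two RF-spoiled FLASH segments with the
same flip-angle patterns, and a T1rho module of six spin-lock preparations
with lock durations spanning 2-45 ms, each followed by 125 excitations
(ramp to 20 deg) and a 500 ms magnetization recovery delay.  TR = 7.5 ms,
TE = 3.5 ms, one readout per excitation: 1750 readouts in total.

FISP segments apply one unit of unbalanced gradient dephasing per TR;
FLASH segments are modeled with ideal spoiling (transverse magnetization
destroyed every TR), which is dictionary-equivalent to RF phase cycling and
much cheaper.  The exact six spin-lock durations are not prescribed beyond
their 2-45 ms span; the default places them log-uniformly on that interval.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernel
from ._kernel import (
    OP_GRAD,
    OP_INVERSION,
    OP_RELAX,
    OP_RF,
    OP_SAMPLE,
    OP_SPOIL,
    OP_T1RHO,
)
from .epg import TissueParams

__all__ = [
    "SequenceConfig",
    "SequenceEvent",
    "SequenceSchedule",
    "Fingerprint",
    "flip_angle_train",
    "build_schedule",
    "simulate_fingerprint",
    "simulate_fingerprints",
]


def _default_tsl_list() -> tuple:
    # six lock durations log-spaced over the published 2-45 ms span
    return tuple(np.round(np.geomspace(2.0, 45.0, 6), 3))


@dataclass(frozen=True)
class SequenceConfig:
    """All tunable sequence parameters (times in ms, angles in degrees)."""

    tr: float = 7.5
    te: float = 3.5
    n_exc_fisp: int = 250
    fa_max_fisp1: float = 20.0
    fa_max_fisp2: float = 60.0
    inter_segment_delay: float = 50.0
    n_exc_flash: int = 250
    fa_max_flash1: float = 20.0
    fa_max_flash2: float = 60.0
    tsl_list: tuple = field(default_factory=_default_tsl_list)
    n_exc_per_tsl: int = 125
    fa_max_t1rho: float = 20.0
    recovery_delay: float = 500.0
    inversion_duration: float = 10.0
    inversion_efficiency: float = 1.0
    spin_lock_freq_hz: float = 500.0  # metadata only; not used by the model
    ramp_shape: str = "half-sine"
    max_order: int = 250

    def __post_init__(self) -> None:
        if self.te <= 0 or self.tr <= self.te:
            raise ValueError("require 0 < te < tr")
        for name in ("inter_segment_delay", "recovery_delay", "inversion_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.inversion_efficiency <= 1.0):
            raise ValueError("inversion_efficiency must be in [0, 1]")
        tsl = tuple(float(t) for t in self.tsl_list)
        if any(t < 0 for t in tsl):
            raise ValueError("tsl values must be >= 0")
        if list(tsl) != sorted(tsl):
            raise ValueError("tsl_list must be sorted ascending")
        object.__setattr__(self, "tsl_list", tsl)
        if self.ramp_shape not in ("half-sine", "linear"):
            raise ValueError(f"unknown ramp_shape {self.ramp_shape!r}")
        for name in ("n_exc_fisp", "n_exc_flash", "n_exc_per_tsl"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tsl_list"] = list(self.tsl_list)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceConfig":
        d = dict(d)
        if "tsl_list" in d:
            d["tsl_list"] = tuple(d["tsl_list"])
        return cls(**d)


@dataclass(frozen=True)
class SequenceEvent:
    """One entry of the human-readable event list."""

    kind: str  # inversion | excitation | delay | t1rho_prep | readout
    time_offset: float  # ms from train start
    flip_deg: float = 0.0
    phase_deg: float = 0.0
    tsl: float = 0.0
    te: float = 0.0


@dataclass
class SequenceSchedule:
    """Built schedule: typed event list plus the compiled event table the
    EPG kernel replays.  ``schedule_hash`` fingerprints the generating
    configuration so dictionaries and signals cannot be mixed across
    schedules."""

    config: SequenceConfig
    events: list
    ops: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    n_readouts: int
    schedule_hash: str

    @property
    def readout_times(self) -> np.ndarray:
        return np.array(
            [e.time_offset for e in self.events if e.kind == "readout"]
        )

    def segment_slices(self) -> dict:
        """Readout-index slices of the named sequence modules."""
        c = self.config
        n_fisp = 2 * c.n_exc_fisp
        n_flash = 2 * c.n_exc_flash
        n_t1rho = len(c.tsl_list) * c.n_exc_per_tsl
        return {
            "fisp": slice(0, n_fisp),
            "flash": slice(n_fisp, n_fisp + n_flash),
            "t1rho": slice(n_fisp + n_flash, n_fisp + n_flash + n_t1rho),
        }


@dataclass
class Fingerprint:
    """Complex signal series, one entry per readout event."""

    values: np.ndarray
    schedule_hash: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fingerprint contains non-finite entries")


def flip_angle_train(n: int, fa_max: float, ramp_shape: str = "half-sine") -> np.ndarray:
    """Flip-angle ramp of one segment: starts at 0, peaks at ``fa_max``.

    ``half-sine`` (default): FA_i = fa_max * sin(pi * i / (n-1)), the
    smooth lobe conventionally used for FISP fingerprinting trains;
    ``linear``: straight ramp 0 -> fa_max.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if fa_max < 0 or not math.isfinite(fa_max):
        raise ValueError("fa_max must be finite and >= 0")
    i = np.arange(n)
    if ramp_shape == "half-sine":
        lobe = np.sin(np.pi * i / (n - 1))
        peak = lobe.max()  # rescale so the train peaks exactly at fa_max
        return fa_max * lobe / (peak if peak > 0 else 1.0)
    if ramp_shape == "linear":
        return fa_max * i / (n - 1)
    raise ValueError(f"unknown ramp_shape {ramp_shape!r}")


def _schedule_hash(config: SequenceConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_schedule(config: SequenceConfig | None = None) -> SequenceSchedule:
    """Compile a :class:`SequenceConfig` into an ordered event list.

    Layout: inversion -> FISP seg 1 -> delay -> FISP seg 2 -> delay ->
    FLASH seg 1 -> delay -> FLASH seg 2 -> [for each TSL: spin-lock prep,
    excitation block, recovery delay].  Every excitation is followed by one
    readout at TE; relaxation splits each TR into [TE, TR-TE] around it.
    """
    if config is None:
        config = SequenceConfig()
    c = config
    events: list[SequenceEvent] = []
    ops: list[int] = []
    a1: list[float] = []
    a2: list[float] = []
    t = 0.0

    def emit(op: int, x1: float = 0.0, x2: float = 0.0) -> None:
        ops.append(op)
        a1.append(x1)
        a2.append(x2)

    def run_segment(n_exc: int, fa_max: float, spoiled: bool) -> None:
        nonlocal t
        fas = flip_angle_train(n_exc, fa_max, c.ramp_shape)
        for fa in fas:
            events.append(SequenceEvent("excitation", t, flip_deg=float(fa)))
            events.append(SequenceEvent("readout", t + c.te, te=c.te))
            emit(OP_RF, float(fa), 0.0)
            emit(OP_RELAX, c.te)
            emit(OP_SAMPLE)
            emit(OP_RELAX, c.tr - c.te)
            emit(OP_SPOIL if spoiled else OP_GRAD)
            t += c.tr

    def run_delay(dt: float) -> None:
        nonlocal t
        if dt > 0:
            events.append(SequenceEvent("delay", t, tsl=0.0, te=0.0))
            emit(OP_RELAX, dt)
            t += dt

    # inversion module
    events.append(SequenceEvent("inversion", t))
    emit(OP_INVERSION, c.inversion_efficiency)
    emit(OP_RELAX, c.inversion_duration)
    t += c.inversion_duration

    # T1/T2 module: two FISP segments
    run_segment(c.n_exc_fisp, c.fa_max_fisp1, spoiled=False)
    run_delay(c.inter_segment_delay)
    run_segment(c.n_exc_fisp, c.fa_max_fisp2, spoiled=False)
    run_delay(c.inter_segment_delay)

    # T1/B1 module: two ideally spoiled FLASH segments (spoiler at entry
    # clears FISP residue before the first spoiled readout)
    emit(OP_SPOIL)
    run_segment(c.n_exc_flash, c.fa_max_flash1, spoiled=True)
    run_delay(c.inter_segment_delay)
    run_segment(c.n_exc_flash, c.fa_max_flash2, spoiled=True)

    # T1rho module
    for tsl in c.tsl_list:
        events.append(SequenceEvent("t1rho_prep", t, tsl=float(tsl)))
        emit(OP_T1RHO, float(tsl))
        t += float(tsl)
        run_segment(c.n_exc_per_tsl, c.fa_max_t1rho, spoiled=False)
        run_delay(c.recovery_delay)

    n_readouts = sum(1 for e in events if e.kind == "readout")
    return SequenceSchedule(
        config=c,
        events=events,
        ops=np.asarray(ops, dtype=np.int64),
        a1=np.asarray(a1, dtype=np.float64),
        a2=np.asarray(a2, dtype=np.float64),
        n_readouts=n_readouts,
        schedule_hash=_schedule_hash(c),
    )


def simulate_fingerprints(
    schedule: SequenceSchedule,
    t1: np.ndarray,
    t2: np.ndarray,
    t1rho: np.ndarray,
    b1: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Simulate fingerprints for a batch of parameter sets.

    Returns a complex array of shape ``(n_atoms, n_readouts)``; rows are the
    unscaled (PD = 1) signal series.
    """
    t1 = np.atleast_1d(np.asarray(t1, dtype=np.float64))
    t2 = np.atleast_1d(np.asarray(t2, dtype=np.float64))
    t1rho = np.atleast_1d(np.asarray(t1rho, dtype=np.float64))
    b1 = np.broadcast_to(np.asarray(b1, dtype=np.float64), t1.shape).copy()
    if not (t1.shape == t2.shape == t1rho.shape == b1.shape):
        raise ValueError("parameter arrays must share a common shape")
    if np.any(t1 <= 0) or np.any(t2 <= 0) or np.any(t1rho <= 0):
        raise ValueError("relaxation times must be positive")
    return _kernel.run_epg_batch(
        schedule.ops,
        schedule.a1,
        schedule.a2,
        t1,
        t2,
        t1rho,
        b1,
        schedule.config.max_order,
        schedule.n_readouts,
    )


def simulate_fingerprint(schedule: SequenceSchedule, params: TissueParams) -> Fingerprint:
    """Simulate the fingerprint of a single tissue (scaled by its PD)."""
    sig = simulate_fingerprints(
        schedule,
        np.array([params.t1]),
        np.array([params.t2]),
        np.array([params.t1rho]),
        np.array([params.b1_scale]),
    )[0]
    return Fingerprint(values=params.pd * sig, schedule_hash=schedule.schedule_hash)
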