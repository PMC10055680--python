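"""Parameter grids, dictionary simulation, and SVD subspace compression.

The dictionary covers T1 50-3000 ms, T2 2-200 ms and T1rho 2-200 ms, each
axis a geometric progression in 6% steps, with physically implausible
combinations (T2 > T1, and by default T1rho > T1) removed.  Each atom's
fingerprint is simulated with the EPG kernel and stored unit-L2-normalized
together with its original norm, so matching reduces to a normalized inner
product and the proton-density scale can be recovered.

Compression projects fingerprints onto the top right-singular-vector
subspace of the atom-by-timepoint matrix; matching in the rank-r space is
near-lossless once the retained energy is high (>= 99.9%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .sequence import SequenceSchedule, simulate_fingerprints

__all__ = [
    "ParameterGrid",
    "Dictionary",
    "CompressedDictionary",
    "geometric_axis",
    "build_grid",
    "default_grid",
    "build_dictionary",
    "compress",
    "save_dictionary",
    "load_dictionary",
]


def geometric_axis(vmin: float, vmax: float, step_fraction: float = 0.06) -> np.ndarray:
    """Geometric progression ``vmin * (1+step)^k`` for all k with value <= vmax."""
    if step_fraction <= 0:
        raise ValueError("step_fraction must be > 0")
    if not (0 < vmin <= vmax):
        raise ValueError("require 0 < vmin <= vmax")
    # tolerance absorbs log/pow roundoff at exact endpoints
    kmax = int(np.floor(np.log(vmax / vmin) / np.log1p(step_fraction) + 1e-9))
    return vmin * (1.0 + step_fraction) ** np.arange(kmax + 1)


@dataclass
class ParameterGrid:
    """Cartesian (T1, T2, T1rho, B1) grid after feasibility filtering.

    ``atoms`` is an (n, 4) array ordered lexicographically by
    (t1, t2, t1rho, b1); ``indices`` holds the per-axis index of each atom.
    """

    t1_values: np.ndarray
    t2_values: np.ndarray
    t1rho_values: np.ndarray
    b1_values: np.ndarray
    atoms: np.ndarray
    indices: np.ndarray
    step_fraction: float = 0.06

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    def axis_lengths(self) -> tuple:
        return (
            len(self.t1_values),
            len(self.t2_values),
            len(self.t1rho_values),
            len(self.b1_values),
        )


def build_grid(
    t1_values: np.ndarray,
    t2_values: np.ndarray,
    t1rho_values: np.ndarray,
    b1_values: np.ndarray | None = None,
    enforce_t2_le_t1: bool = True,
    enforce_t1rho_le_t1: bool = True,
    step_fraction: float = 0.06,
) -> ParameterGrid:
    """Cartesian product of axes with plausibility filters applied."""
    axes = []
    for name, v in (
        ("t1_values", t1_values),
        ("t2_values", t2_values),
        ("t1rho_values", t1rho_values),
    ):
        v = np.asarray(v, dtype=np.float64)
        if v.size == 0:
            raise ValueError(f"{name} is empty")
        if np.any(v <= 0) or np.any(np.diff(v) <= 0) and v.size > 1:
            raise ValueError(f"{name} must be positive and strictly ascending")
        axes.append(v)
    b1 = np.asarray(
        [1.0] if b1_values is None else b1_values, dtype=np.float64
    )
    if b1.size == 0 or np.any(b1 <= 0):
        raise ValueError("b1_values must be nonempty and positive")
    t1v, t2v, trv = axes

    i1, i2, ir, ib = np.meshgrid(
        np.arange(len(t1v)),
        np.arange(len(t2v)),
        np.arange(len(trv)),
        np.arange(len(b1)),
        indexing="ij",
    )
    idx = np.stack([i1.ravel(), i2.ravel(), ir.ravel(), ib.ravel()], axis=1)
    atoms = np.column_stack(
        [t1v[idx[:, 0]], t2v[idx[:, 1]], trv[idx[:, 2]], b1[idx[:, 3]]]
    )
    keep = np.ones(len(atoms), dtype=bool)
    if enforce_t2_le_t1:
        keep &= atoms[:, 1] <= atoms[:, 0]
    if enforce_t1rho_le_t1:
        keep &= atoms[:, 2] <= atoms[:, 0]
    return ParameterGrid(
        t1_values=t1v,
        t2_values=t2v,
        t1rho_values=trv,
        b1_values=b1,
        atoms=atoms[keep],
        indices=idx[keep],
        step_fraction=step_fraction,
    )


def default_grid(
    t1_range=(50.0, 3000.0),
    t2_range=(2.0, 200.0),
    t1rho_range=(2.0, 200.0),
    step_fraction: float = 0.06,
    b1_values=None,
    **kwargs,
) -> ParameterGrid:
    """Published dictionary ranges in geometric steps (default 6%).

    The B1 axis is off (single value 1.0) by default; pass e.g.
    ``b1_values=np.arange(0.7, 1.31, 0.1)`` to enable it.
    """
    return build_grid(
        geometric_axis(*t1_range, step_fraction),
        geometric_axis(*t2_range, step_fraction),
        geometric_axis(*t1rho_range, step_fraction),
        b1_values=b1_values,
        step_fraction=step_fraction,
        **kwargs,
    )


@dataclass
class Dictionary:
    """Unit-normalized fingerprints (atoms x timepoints) with their norms."""

    grid: ParameterGrid
    fingerprints: np.ndarray
    norms: np.ndarray
    schedule_hash: str
    ramp_shape: str = "half-sine"
    meta: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.fingerprints.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.fingerprints.shape[1]


def build_dictionary(
    grid: ParameterGrid,
    schedule: SequenceSchedule,
    chunk_size: int = 1024,
) -> Dictionary:
    """Simulate one fingerprint per atom, in chunks, and normalize rows.

    Chunking bounds peak memory to one ``chunk_size x n_readouts`` block of
    raw fingerprints; build time is linear in the atom count.
    """
    if np.any(grid.atoms[:, 1] > grid.atoms[:, 0]):
        raise RuntimeError("grid contains t2 > t1 atoms; filter before building")
    n = grid.n_atoms
    fps = np.empty((n, schedule.n_readouts), dtype=np.complex128)
    norms = np.empty(n, dtype=np.float64)
    for lo in range(0, n, chunk_size):
        hi = min(lo + chunk_size, n)
        block = simulate_fingerprints(
            schedule,
            grid.atoms[lo:hi, 0],
            grid.atoms[lo:hi, 1],
            grid.atoms[lo:hi, 2],
            grid.atoms[lo:hi, 3],
        )
        nb = np.linalg.norm(block, axis=1)
        if np.any(nb == 0):
            raise RuntimeError("zero-norm fingerprint encountered")
        fps[lo:hi] = block / nb[:, None]
        norms[lo:hi] = nb
    return Dictionary(
        grid=grid,
        fingerprints=fps,
        norms=norms,
        schedule_hash=schedule.schedule_hash,
        ramp_shape=schedule.config.ramp_shape,
        meta={
            "tr": schedule.config.tr,
            "te": schedule.config.te,
            "spin_lock_freq_hz": schedule.config.spin_lock_freq_hz,
        },
    )


@dataclass
class CompressedDictionary:
    """Rank-r SVD subspace representation of a dictionary.

    ``basis`` (timepoints x r) has orthonormal columns; ``projected``
    (atoms x r) are the fingerprint coordinates in that subspace.  Grid and
    norms are carried along so compressed matching is self-contained.
    """

    basis: np.ndarray
    projected: np.ndarray
    singular_values: np.ndarray
    energy_retained: float
    grid: ParameterGrid
    norms: np.ndarray
    schedule_hash: str

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    @property
    def n_atoms(self) -> int:
        return self.projected.shape[0]


def _svd_right_vectors(fps: np.ndarray, gram_chunk: int = 2048):
    """Singular values and right singular vectors of the atom matrix.

    For tall matrices (atoms >> timepoints) the timepoint Gram matrix is
    accumulated in chunks and eigendecomposed — mathematically identical to
    a thin SVD and far cheaper at dictionary scale.
    """
    n_atoms, n_t = fps.shape
    if n_atoms >= 2 * n_t:
        g = np.zeros((n_t, n_t), dtype=np.complex128)
        for lo in range(0, n_atoms, gram_chunk):
            blk = fps[lo : lo + gram_chunk]
            g += blk.conj().T @ blk
        w, v = np.linalg.eigh(g)
        order = np.argsort(w)[::-1]
        s = np.sqrt(np.clip(w[order], 0.0, None))
        return s, v[:, order]
    _, s, vh = np.linalg.svd(fps, full_matrices=False)
    return s, vh.conj().T


def compress(
    dictionary: Dictionary,
    rank: int | None = None,
    energy: float | None = None,
) -> CompressedDictionary:
    """SVD compression to an explicit rank, or to the smallest rank whose
    cumulative squared singular values retain at least ``energy``."""
    if (rank is None) == (energy is None):
        raise ValueError("specify exactly one of rank or energy")
    s, v = _svd_right_vectors(dictionary.fingerprints)
    total = float(np.sum(s**2))
    cum = np.cumsum(s**2) / total
    if rank is None:
        if not (0.0 < energy <= 1.0):
            raise ValueError("energy must be in (0, 1]")
        rank = int(np.searchsorted(cum, energy - 1e-12) + 1)
        rank = min(rank, len(s))
    if not (1 <= rank <= len(s)):
        raise ValueError(f"rank must be in [1, {len(s)}], got {rank}")
    basis = np.ascontiguousarray(v[:, :rank])
    return CompressedDictionary(
        basis=basis,
        projected=dictionary.fingerprints @ basis,
        singular_values=s,
        energy_retained=float(cum[rank - 1]),
        grid=dictionary.grid,
        norms=dictionary.norms,
        schedule_hash=dictionary.schedule_hash,
    )


def save_dictionary(dictionary: Dictionary, path, compressed: CompressedDictionary | None = None) -> None:
    """Write a dictionary (and optionally its SVD subspace) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("fingerprints", data=dictionary.fingerprints)
        f.create_dataset("norms", data=dictionary.norms)
        g = f.create_group("grid")
        g.create_dataset("t1", data=dictionary.grid.t1_values)
        g.create_dataset("t2", data=dictionary.grid.t2_values)
        g.create_dataset("t1rho", data=dictionary.grid.t1rho_values)
        g.create_dataset("b1", data=dictionary.grid.b1_values)
        g.create_dataset("atoms", data=dictionary.grid.atoms)
        g.create_dataset("indices", data=dictionary.grid.indices)
        g.attrs["step_fraction"] = dictionary.grid.step_fraction
        f.attrs["schedule_hash"] = dictionary.schedule_hash
        f.attrs["ramp_shape"] = dictionary.ramp_shape
        for k, v in dictionary.meta.items():
            f.attrs[k] = v
        if compressed is not None:
            sv = f.create_group("svd")
            sv.create_dataset("basis", data=compressed.basis)
            sv.create_dataset("projected", data=compressed.projected)
            sv.create_dataset("singular_values", data=compressed.singular_values)
            sv.attrs["energy_retained"] = compressed.energy_retained


def load_dictionary(path) -> tuple:
    """Read a dictionary archive; returns (Dictionary, CompressedDictionary | None)."""
    with h5py.File(path, "r") as f:
        g = f["grid"]
        grid = ParameterGrid(
            t1_values=g["t1"][:],
            t2_values=g["t2"][:],
            t1rho_values=g["t1rho"][:],
            b1_values=g["b1"][:],
            atoms=g["atoms"][:],
            indices=g["indices"][:],
            step_fraction=float(g.attrs["step_fraction"]),
        )
        meta = {
            k: f.attrs[k]
            for k in f.attrs
            if k not in ("schedule_hash", "ramp_shape")
        }
        d = Dictionary(
            grid=grid,
            fingerprints=f["fingerprints"][:],
            norms=f["norms"][:],
            schedule_hash=str(f.attrs["schedule_hash"]),
            ramp_shape=str(f.attrs["ramp_shape"]),
            meta=meta,
        )
        comp = None
        if "svd" in f:
            sv = f["svd"]
            basis = sv["basis"][:]
            comp = CompressedDictionary(
                basis=basis,
                projected=sv["projected"][:],
                singular_values=sv["singular_values"][:],
                energy_retained=float(sv.attrs["energy_retained"]),
                grid=grid,
                norms=d.norms,
                schedule_hash=d.schedule_hash,
            )
    return d, comp
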