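"""Dictionary pattern matching: signals -> quantitative parameter maps.

Each voxel's complex signal series is matched to the dictionary atom that
maximizes the magnitude of the normalized inner product with the
(conjugated) unit-norm atom fingerprint.  Maximizing the magnitude rather
than the real part makes matching invariant to the arbitrary global phase
a simulated or reconstructed acquisition carries; proton density is the
inner-product magnitude divided by the atom's stored norm.  Ties are broken
by the lowest atom index so noiseless matching is bit-reproducible.

With a compressed dictionary, signals are first projected onto the SVD
basis and all inner products are computed in the rank-r subspace.

The optional refinement pass (the iterative stage of matching) evaluates
the two grid neighbors of the best atom along each of T1/T2/T1rho and fits
a parabola to the scores in log-parameter space, yielding sub-grid-step
estimates; the refined value is confined to one grid step around the
matched atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary import CompressedDictionary, Dictionary

__all__ = ["ParameterMaps", "match_voxel", "match_volume"]

NO_DATA = np.nan


@dataclass
class ParameterMaps:
    """Voxelwise quantitative maps: the pipeline's product.

    ``pd`` is in arbitrary units, ``t1``/``t2``/``t1rho`` in ms, ``b1`` is
    dimensionless, ``match_score`` is the normalized inner product in
    [0, 1].  Masked voxels carry NaN.
    """

    pd: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    t1rho: np.ndarray
    b1: np.ndarray
    match_score: np.ndarray
    mask: np.ndarray
    atom_index: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 3.0)
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "pd": self.pd,
            "t1": self.t1,
            "t2": self.t2,
            "t1rho": self.t1rho,
            "b1": self.b1,
            "score": self.match_score,
        }


def _inner_products(signals, dictionary, chunk):
    """|<atom, signal>| argmax over atoms, chunked over atoms.

    Returns (best index, best |ip|) per signal row.  Ties resolve to the
    lowest atom index (np.argmax convention on the first maximum).
    """
    n_sig = signals.shape[0]
    best_idx = np.zeros(n_sig, dtype=np.int64)
    best_val = np.full(n_sig, -1.0)
    if isinstance(dictionary, CompressedDictionary):
        atoms_mat = dictionary.projected
        sig_mat = signals @ dictionary.basis
    else:
        atoms_mat = dictionary.fingerprints
        sig_mat = signals
    for lo in range(0, atoms_mat.shape[0], chunk):
        blk = atoms_mat[lo : lo + chunk]
        ips = np.abs(sig_mat @ blk.conj().T)
        idx = np.argmax(ips, axis=1)
        val = ips[np.arange(n_sig), idx]
        # strict > keeps the earliest atom on exact ties across chunks
        better = val > best_val
        best_idx[better] = idx[better] + lo
        best_val[better] = val[better]
    return best_idx, best_val


def match_voxel(signal: np.ndarray, dictionary: Dictionary | CompressedDictionary):
    """Match one signal series; returns ``(atom_index, pd, score)``."""
    signal = np.asarray(signal, dtype=np.complex128)
    if signal.ndim != 1:
        raise ValueError("signal must be a 1-D complex series")
    _check_length(signal.shape[0], dictionary)
    nrm = np.linalg.norm(signal)
    if nrm == 0:
        raise ValueError("all-zero signal cannot be matched (mask it)")
    idx, val = _inner_products(signal[None, :], dictionary, chunk=4096)
    i = int(idx[0])
    pd = float(val[0] / dictionary.norms[i])
    score = float(min(val[0] / nrm, 1.0))
    return i, pd, score


def _check_length(n: int, dictionary) -> None:
    if isinstance(dictionary, CompressedDictionary):
        expected = dictionary.basis.shape[0]
    else:
        expected = dictionary.n_timepoints
    if n != expected:
        raise ValueError(
            f"signal has {n} timepoints but dictionary (schedule "
            f"{dictionary.schedule_hash}) expects {expected}"
        )


_NBR_OFFSETS = np.array(
    [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
)


def _refine(grid, atom_idx, signals, dictionary, scores):
    """Sub-grid refinement from the 3x3x3 (t1, t2, t1rho) neighborhood.

    Fits a full quadratic (with cross terms, capturing e.g. the T1-T1rho
    score coupling) to the inner-product magnitudes over the neighborhood in
    log-parameter offsets and moves to its stationary point, clamped to one
    grid step per axis.  Edge atoms with an incomplete neighborhood are left
    unrefined.
    """
    key = {tuple(ix): j for j, ix in enumerate(grid.indices)}
    if isinstance(dictionary, CompressedDictionary):
        atoms_mat = dictionary.projected
        sig_mat = signals @ dictionary.basis
    else:
        atoms_mat = dictionary.fingerprints
        sig_mat = signals
    # design matrix of the 10-term quadratic over the 27 offsets (shared)
    p = _NBR_OFFSETS.astype(float)
    design = np.column_stack(
        [
            np.ones(27),
            p,
            p**2,
            p[:, 0] * p[:, 1],
            p[:, 0] * p[:, 2],
            p[:, 1] * p[:, 2],
        ]
    )
    solver = np.linalg.pinv(design)
    log_step = np.log1p(grid.step_fraction)
    refined = [grid.atoms[atom_idx, a].astype(float).copy() for a in range(3)]
    for v, j in enumerate(atom_idx):
        ix0 = grid.indices[j]
        nbrs = np.full(27, -1, dtype=np.int64)
        for q, (dx, dy, dz) in enumerate(_NBR_OFFSETS):
            nbrs[q] = key.get((ix0[0] + dx, ix0[1] + dy, ix0[2] + dz, ix0[3]), -1)
        if np.any(nbrs < 0):
            continue
        s = np.abs(atoms_mat[nbrs].conj() @ sig_mat[v])
        c = solver @ s
        gvec = c[1:4]
        h = np.array(
            [
                [2.0 * c[4], c[7], c[8]],
                [c[7], 2.0 * c[5], c[9]],
                [c[8], c[9], 2.0 * c[6]],
            ]
        )
        try:
            x = -np.linalg.solve(h, gvec)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(x)):
            continue
        x = np.clip(x, -1.0, 1.0)
        for a in range(3):
            refined[a][v] *= np.exp(x[a] * log_step)
    return refined


def match_volume(
    signals: np.ndarray,
    dictionary: Dictionary | CompressedDictionary,
    refine: bool = False,
    mask: np.ndarray | None = None,
    mask_fraction: float = 0.01,
    chunk: int = 2048,
    voxel_size: tuple = (1.0, 1.0, 3.0),
) -> ParameterMaps:
    """Match every voxel of a ``(... , timepoints)`` signal array.

    Voxels whose signal norm falls below ``mask_fraction`` times the 99th
    percentile of all norms (or outside an explicit ``mask``) are excluded
    and carry NaN in every output map.
    """
    signals = np.asarray(signals, dtype=np.complex128)
    spatial = signals.shape[:-1]
    _check_length(signals.shape[-1], dictionary)
    flat = signals.reshape(-1, signals.shape[-1])
    norms = np.linalg.norm(flat, axis=1)
    if mask is None:
        ref = np.percentile(norms, 99)
        keep = norms > mask_fraction * ref
    else:
        keep = np.asarray(mask, dtype=bool).reshape(-1) & (norms > 0)
    grid = dictionary.grid

    n_vox = flat.shape[0]
    out = {
        k: np.full(n_vox, NO_DATA)
        for k in ("pd", "t1", "t2", "t1rho", "b1", "score")
    }
    atom_index = np.full(n_vox, -1, dtype=np.int64)
    if np.any(keep):
        sel = flat[keep]
        idx, val = _inner_products(sel, dictionary, chunk)
        atom_index[keep] = idx
        out["pd"][keep] = val / dictionary.norms[idx]
        out["score"][keep] = np.minimum(val / norms[keep], 1.0)
        out["t1"][keep] = grid.atoms[idx, 0]
        out["t2"][keep] = grid.atoms[idx, 1]
        out["t1rho"][keep] = grid.atoms[idx, 2]
        out["b1"][keep] = grid.atoms[idx, 3]
        if refine:
            r_t1, r_t2, r_t1rho = _refine(grid, idx, sel, dictionary, val)
            out["t1"][keep] = r_t1
            out["t2"][keep] = r_t2
            out["t1rho"][keep] = r_t1rho
    return ParameterMaps(
        pd=out["pd"].reshape(spatial),
        t1=out["t1"].reshape(spatial),
        t2=out["t2"].reshape(spatial),
        t1rho=out["t1rho"].reshape(spatial),
        b1=out["b1"].reshape(spatial),
        match_score=out["score"].reshape(spatial),
        mask=keep.reshape(spatial),
        atom_index=atom_index.reshape(spatial),
        voxel_size=voxel_size,
        meta={"schedule_hash": dictionary.schedule_hash, "refined": refine},
    )
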