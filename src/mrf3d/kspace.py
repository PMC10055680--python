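"""Radial stack-of-stars k-space model.

In-plane encoding is radial: each readout samples one diameter spoke of the
2-D k-plane at a golden-angle azimuth; the through-plane (kz) dimension is
Cartesian and acquired center-out.  The forward model here is an exact
non-uniform discrete Fourier transform evaluated by direct summation —
adequate for the grid sizes this package simulates, and exactly adjoint by
construction, which the reconstruction tests rely on.

Reconstruction is density-compensated adjoint gridding: a ramp (|k|)
density compensation function with an area-matched weight at the spoke
center, followed by the exact adjoint NUDFT.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "spoke_kcoords",
    "radial_forward",
    "radial_adjoint",
    "radial_dcf",
    "recon_radial_2d",
    "center_out_order",
]


def spoke_kcoords(angle_deg: float, n_samples: int) -> np.ndarray:
    """(n_samples, 2) k-space coordinates of one diameter spoke, in
    cycles/pixel, spanning [-0.5, 0.5)."""
    r = (np.arange(n_samples) - n_samples // 2) / n_samples
    th = np.deg2rad(angle_deg)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _encoding_matrix(angles_deg, n_samples, shape):
    nx, ny = shape
    x, y = np.meshgrid(np.arange(nx) - nx // 2, np.arange(ny) - ny // 2, indexing="ij")
    xy = np.column_stack([x.ravel(), y.ravel()])
    ks = np.concatenate([spoke_kcoords(a, n_samples) for a in np.atleast_1d(angles_deg)])
    return np.exp(-2j * np.pi * (ks @ xy.T))


def radial_forward(image: np.ndarray, angles_deg, n_samples: int) -> np.ndarray:
    """Sample a 2-D image along diameter spokes; returns (n_spokes, n_samples)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    e = _encoding_matrix(angles_deg, n_samples, image.shape)
    data = e @ image.astype(np.complex128).ravel()
    return data.reshape(len(np.atleast_1d(angles_deg)), n_samples)


def radial_adjoint(data: np.ndarray, angles_deg, shape) -> np.ndarray:
    """Exact adjoint of :func:`radial_forward` (no density compensation)."""
    data = np.asarray(data, dtype=np.complex128)
    angles = np.atleast_1d(angles_deg)
    if data.shape[0] != len(angles):
        raise ValueError("data rows must equal number of spokes")
    e = _encoding_matrix(angles, data.shape[1], shape)
    img = e.conj().T @ data.ravel()
    return img.reshape(shape)


def radial_dcf(n_samples: int, n_spokes: int) -> np.ndarray:
    """Ramp density compensation for full-diameter spokes.

    Weight |k| dk dtheta per sample, with the k=0 sample weighted by the
    area of the disk of radius dk/2 shared across all spokes.
    """
    dk = 1.0 / n_samples
    r = np.abs(np.arange(n_samples) - n_samples // 2) * dk
    w = r * dk * np.pi / n_spokes
    w[n_samples // 2] = np.pi * (dk / 2.0) ** 2 / n_spokes
    return w


def recon_radial_2d(data: np.ndarray, angles_deg, shape) -> np.ndarray:
    """Density-compensated adjoint reconstruction of one 2-D frame."""
    w = radial_dcf(data.shape[1], data.shape[0])
    return radial_adjoint(data * w[None, :], angles_deg, shape)


def center_out_order(nz: int) -> np.ndarray:
    """kz partition ordering from the k-space center outward.

    Ties between +/- offsets resolve to the lower partition index first;
    the result is a permutation covering every partition exactly once.
    """
    center = nz // 2
    idx = np.arange(nz)
    return idx[np.lexsort((idx, np.abs(idx - center)))]
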