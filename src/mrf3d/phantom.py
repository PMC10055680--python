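"""Digital phantoms and simulated acquisitions.

Two phantom families emulate the validation experiments the sequence was
designed for:

* a system-phantom analogue — 14 disjoint spheres on a circular layout with
  relaxation times spanning T1 200-2500 ms, T2 up to 600 ms and T1rho up to
  450 ms (geometrically spaced; the short end is clamped at 5 ms so every
  sphere is simulable);
* a brain-like phantom — elliptical CSF/GM/WM compartments with optional
  focal lesions whose T1/T2/T1rho are elevated relative to white matter,
  mirroring the qualitative lesion-versus-NAWM contrast of demyelinating
  disease.

Acquisition simulation supports a ``direct`` mode (per-voxel fingerprints
plus i.i.d. complex Gaussian noise; multi-shot acquisitions are complex
averages of independently noisy shots, so noise SD falls as 1/sqrt(n)) and
a ``kspace`` mode (golden-angle radial stack-of-stars sampling of the
per-frame images through the exact NUDFT in :mod:`mrf3d.kspace`).
Voxels sharing a tissue label share one EPG simulation, which keeps
phantom-scale runs fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kspace as ksp
from .epg import TissueParams
from .sequence import SequenceSchedule, simulate_fingerprints

__all__ = [
    "DigitalPhantom",
    "AcquisitionConfig",
    "SimulatedSignals",
    "KSpaceData",
    "GOLDEN_ANGLE_DEG",
    "make_nist_like_phantom",
    "make_brain_like_phantom",
    "golden_angle_spokes",
    "simulate_acquisition",
    "recon_frames",
    "sigma_for_snr",
]

GOLDEN_ANGLE_DEG = 180.0 * (np.sqrt(5.0) - 1.0) / 2.0  # 111.246117975...


@dataclass
class DigitalPhantom:
    """Labeled voxel grid with per-region tissue parameters."""

    label_map: np.ndarray
    region_params: dict
    voxel_size: tuple = (1.0, 1.0, 3.0)
    name: str = "phantom"

    def __post_init__(self) -> None:
        labels = set(np.unique(self.label_map)) - {0}
        missing = labels - set(self.region_params)
        if missing:
            raise ValueError(f"labels without parameters: {sorted(missing)}")

    @property
    def labels(self) -> list:
        return sorted(set(np.unique(self.label_map)) - {0})

    def region_mask(self, label: int) -> np.ndarray:
        return self.label_map == label

    def ground_truth(self, param: str) -> np.ndarray:
        """Volume of the true value of ``param`` (0 in background)."""
        out = np.zeros(self.label_map.shape)
        for lab in self.labels:
            out[self.label_map == lab] = getattr(self.region_params[lab], param)
        return out


def _sphere_mask(shape, center_mm, radius_mm, voxel_size):
    coords = [
        (np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_size)
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    d2 = (
        (x - center_mm[0]) ** 2
        + (y - center_mm[1]) ** 2
        + (z - center_mm[2]) ** 2
    )
    return d2 <= radius_mm**2


def make_nist_like_phantom(
    shape=(64, 64, 8),
    n_spheres: int = 14,
    t1_range=(200.0, 2500.0),
    t2_range=(5.0, 600.0),
    t1rho_range=(5.0, 450.0),
    sphere_radius_mm: float = 5.0,
    voxel_size=(1.0, 1.0, 3.0),
) -> DigitalPhantom:
    """System-phantom analogue: disjoint spheres on a circle, relaxation
    times geometrically spaced across the published sphere ranges."""
    if n_spheres < 1:
        raise ValueError("n_spheres must be >= 1")
    if n_spheres == 1:
        t1s = [float(np.sqrt(t1_range[0] * t1_range[1]))]
        t2s = [float(np.sqrt(t2_range[0] * t2_range[1]))]
        t1rs = [float(np.sqrt(t1rho_range[0] * t1rho_range[1]))]
    else:
        t1s = np.geomspace(*t1_range, n_spheres)
        t2s = np.geomspace(*t2_range, n_spheres)
        t1rs = np.geomspace(*t1rho_range, n_spheres)
    fov = (shape[0] * voxel_size[0], shape[1] * voxel_size[1], shape[2] * voxel_size[2])
    ring_r = 0.5 * min(fov[0], fov[1]) - sphere_radius_mm - 1.0
    if ring_r <= 0 or 2 * sphere_radius_mm > fov[2]:
        raise ValueError("spheres do not fit in the volume")
    if n_spheres > 1:
        spacing = 2.0 * np.pi * ring_r / n_spheres
        if spacing < 2.0 * sphere_radius_mm:
            raise ValueError("spheres on the ring would overlap")
    label_map = np.zeros(shape, dtype=np.int32)
    params = {}
    cz = fov[2] / 2.0
    for i in range(n_spheres):
        th = 2.0 * np.pi * i / max(n_spheres, 1)
        cx = fov[0] / 2.0 + (ring_r if n_spheres > 1 else 0.0) * np.cos(th)
        cy = fov[1] / 2.0 + (ring_r if n_spheres > 1 else 0.0) * np.sin(th)
        m = _sphere_mask(shape, (cx, cy, cz), sphere_radius_mm, voxel_size)
        label_map[m] = i + 1
        # t2 <= t1 can be violated at the top of the sphere ranges (long-T2
        # spheres); keep those parameters unvalidated, as the phantom may
        # deliberately exceed the dictionary's physiologic envelope
        params[i + 1] = TissueParams(
            t1=float(t1s[i]),
            t2=float(t2s[i]),
            t1rho=float(t1rs[i]),
            pd=1.0,
            validate=False,
        )
    return DigitalPhantom(label_map, params, tuple(voxel_size), name="nist_like")


# literature-plausible 3T relaxation parameters for the brain compartments
BRAIN_TISSUES = {
    "wm": TissueParams(t1=850.0, t2=70.0, t1rho=90.0, pd=0.75),
    "gm": TissueParams(t1=1400.0, t2=90.0, t1rho=110.0, pd=0.85),
    "csf": TissueParams(t1=3000.0, t2=500.0, t1rho=400.0, pd=1.0),
}
LABEL_CSF, LABEL_GM, LABEL_WM = 1, 2, 3
LESION_LABEL_START = 10


@dataclass(frozen=True)
class LesionSpec:
    """Focal lesion: center (voxels, in-plane), radius (mm), and the factor
    by which T1/T2/T1rho are elevated over white matter."""

    center: tuple
    radius_mm: float = 3.0
    factor: float = 1.3


def make_brain_like_phantom(
    shape=(64, 64, 8),
    lesion_specs=None,
    tissues: dict | None = None,
    voxel_size=(1.0, 1.0, 3.0),
) -> DigitalPhantom:
    """Concentric elliptical CSF / GM / WM compartments plus optional
    lesions; every lesion must lie inside white matter."""
    tissues = dict(BRAIN_TISSUES if tissues is None else tissues)
    nx, ny, nz = shape
    x, y = np.meshgrid(
        (np.arange(nx) - nx / 2 + 0.5) / (nx / 2),
        (np.arange(ny) - ny / 2 + 0.5) / (ny / 2),
        indexing="ij",
    )
    r2 = (x / 0.9) ** 2 + (y / 0.95) ** 2
    plane = np.zeros((nx, ny), dtype=np.int32)
    plane[r2 <= 1.0] = LABEL_CSF
    plane[r2 <= 0.88] = LABEL_GM
    plane[r2 <= 0.55] = LABEL_WM
    label_map = np.repeat(plane[:, :, None], nz, axis=2)
    params = {
        LABEL_CSF: tissues["csf"],
        LABEL_GM: tissues["gm"],
        LABEL_WM: tissues["wm"],
    }
    wm = tissues["wm"]
    for i, spec in enumerate(lesion_specs or []):
        cx, cy = spec.center
        cz = nz * voxel_size[2] / 2.0
        m = _sphere_mask(
            shape,
            ((cx + 0.5) * voxel_size[0], (cy + 0.5) * voxel_size[1], cz),
            spec.radius_mm,
            voxel_size,
        )
        if np.any(label_map[m] != LABEL_WM):
            raise ValueError(f"lesion {i} extends outside white matter")
        lab = LESION_LABEL_START + i
        label_map[m] = lab
        params[lab] = TissueParams(
            t1=wm.t1 * spec.factor,
            t2=wm.t2 * spec.factor,
            t1rho=wm.t1rho * spec.factor,
            pd=wm.pd,
        )
    return DigitalPhantom(label_map, params, tuple(voxel_size), name="brain_like")


def golden_angle_spokes(n_frames: int, n_shots: int = 1) -> np.ndarray:
    """Spoke azimuth table, shape (n_shots, n_frames), degrees in [0, 360).

    Within a shot the azimuth advances by the golden angle each frame; shot
    s starts from the offset s * 180 / n_shots.
    """
    if n_frames < 1 or n_shots < 1:
        raise ValueError("n_frames and n_shots must be >= 1")
    k = np.arange(n_frames)
    shots = np.arange(n_shots)
    return (shots[:, None] * 180.0 / n_shots + k[None, :] * GOLDEN_ANGLE_DEG) % 360.0


@dataclass(frozen=True)
class AcquisitionConfig:
    """Simulated-acquisition settings.

    ``noise_sigma`` is the SD of the complex Gaussian noise added per
    sample and per shot (per-shot noise is independent); ``mode`` selects
    per-voxel signals (``direct``) or radial stack-of-stars sampling
    (``kspace``).
    """

    n_shots: int = 1
    noise_sigma: float = 0.0
    seed: int = 0
    mode: str = "direct"
    spokes_per_frame: int = 1
    readout_samples: int = 64

    def __post_init__(self) -> None:
        if self.n_shots < 1:
            raise ValueError("n_shots must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.mode not in ("direct", "kspace"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def shot_offset_deg(self) -> float:
        return 180.0 / self.n_shots


@dataclass
class SimulatedSignals:
    """Foreground-packed voxel signal series from a direct-mode acquisition."""

    signals: np.ndarray  # (n_voxels, n_readouts) complex, shot-averaged
    voxel_index: np.ndarray  # (n_voxels, 3) grid coordinates
    shape: tuple
    labels: np.ndarray  # (n_voxels,) phantom label per row
    schedule_hash: str
    noise_sigma: float
    n_shots: int
    seed: int

    def volume(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter per-voxel values back onto the phantom grid."""
        out = np.full(self.shape, fill, dtype=np.asarray(values).dtype)
        out[tuple(self.voxel_index.T)] = values
        return out


@dataclass
class KSpaceData:
    """Golden-angle radial stack-of-stars samples.

    ``samples`` has shape (n_frames, n_spokes, readout_samples, nz) with kz
    stored in acquisition (center-out) order.
    """

    samples: np.ndarray
    angles_deg: np.ndarray  # (n_frames, n_spokes)
    kz_order: np.ndarray
    shape: tuple
    schedule_hash: str
    noise_sigma: float
    seed: int


def sigma_for_snr(signals: np.ndarray, snr: float) -> float:
    """Noise SD giving the requested per-sample SNR (RMS signal magnitude
    over RMS complex-noise magnitude) for the supplied noiseless signals."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    return float(np.sqrt(np.mean(np.abs(signals) ** 2)) / snr)


def _region_fingerprints(phantom: DigitalPhantom, schedule: SequenceSchedule):
    labels = phantom.labels
    t1 = np.array([phantom.region_params[l].t1 for l in labels])
    t2 = np.array([phantom.region_params[l].t2 for l in labels])
    t1r = np.array([phantom.region_params[l].t1rho for l in labels])
    b1 = np.array([phantom.region_params[l].b1_scale for l in labels])
    pd = np.array([phantom.region_params[l].pd for l in labels])
    fps = simulate_fingerprints(schedule, t1, t2, t1r, b1) * pd[:, None]
    return labels, fps


def _complex_noise(rng, shape, sigma):
    # total complex variance sigma^2 (sigma/sqrt(2) per component)
    return (sigma / np.sqrt(2.0)) * (
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    )


def simulate_acquisition(
    phantom: DigitalPhantom,
    schedule: SequenceSchedule,
    acq: AcquisitionConfig,
):
    """Simulate the acquisition of a phantom.

    direct mode: every foreground voxel receives its region's fingerprint
    scaled by PD plus independent complex Gaussian noise per shot; shots
    are complex-averaged.  kspace mode: each frame's image is sampled along
    that frame's golden-angle spokes (one per shot) at every kz partition.
    """
    labels, fps = _region_fingerprints(phantom, schedule)
    rng = np.random.default_rng(acq.seed)
    if acq.mode == "direct":
        fg = phantom.label_map > 0
        vidx = np.argwhere(fg)
        vox_labels = phantom.label_map[fg]
        row_of = {lab: i for i, lab in enumerate(labels)}
        rows = np.array([row_of[l] for l in vox_labels])
        clean = fps[rows]
        acc = np.zeros_like(clean)
        for _ in range(acq.n_shots):
            acc += clean + _complex_noise(rng, clean.shape, acq.noise_sigma)
        return SimulatedSignals(
            signals=acc / acq.n_shots,
            voxel_index=vidx,
            shape=phantom.label_map.shape,
            labels=vox_labels,
            schedule_hash=schedule.schedule_hash,
            noise_sigma=acq.noise_sigma,
            n_shots=acq.n_shots,
            seed=acq.seed,
        )

    # kspace mode: exact NUDFT sampling, frame by frame
    nx, ny, nz = phantom.label_map.shape
    n_frames = schedule.n_readouts
    angles = golden_angle_spokes(n_frames, acq.n_shots)  # (shots, frames)
    kz_order = ksp.center_out_order(nz)
    row_vol = np.zeros((nx, ny, nz), dtype=np.int64)
    for i, lab in enumerate(labels):
        row_vol[phantom.label_map == lab] = i + 1
    pd_vol = phantom.ground_truth("pd")
    samples = np.zeros(
        (n_frames, acq.n_shots, acq.readout_samples, nz), dtype=np.complex128
    )
    for t in range(n_frames):
        frame = np.zeros((nx, ny, nz), dtype=np.complex128)
        for i in range(len(labels)):
            frame[row_vol == i + 1] = fps[i, t]
        frame *= pd_vol
        kz_stack = np.fft.fftshift(
            np.fft.fft(np.fft.ifftshift(frame, axes=2), axis=2), axes=2
        )
        for s in range(acq.n_shots):
            for zi, kz in enumerate(kz_order):
                samples[t, s, :, zi] = ksp.radial_forward(
                    kz_stack[:, :, kz], angles[s, t], acq.readout_samples
                )[0]
    samples += _complex_noise(rng, samples.shape, acq.noise_sigma)
    return KSpaceData(
        samples=samples,
        angles_deg=angles.T.copy(),
        kz_order=kz_order,
        shape=(nx, ny, nz),
        schedule_hash=schedule.schedule_hash,
        noise_sigma=acq.noise_sigma,
        seed=acq.seed,
    )


def recon_frames(kdata: KSpaceData, grid_shape=None) -> np.ndarray:
    """Density-compensated adjoint reconstruction of every frame.

    Returns a complex series (nx, ny, nz, n_frames) aligned to the phantom
    grid; kz is inverse-FFT'd after undoing the center-out ordering.
    """
    nx, ny, nz = kdata.shape if grid_shape is None else grid_shape
    n_frames, n_spokes, n_samp, nz_k = kdata.samples.shape
    if nz_k != nz:
        raise ValueError("kz partition count does not match grid shape")
    out = np.zeros((nx, ny, nz, n_frames), dtype=np.complex128)
    kz_stack = np.empty((nx, ny, nz), dtype=np.complex128)
    for t in range(n_frames):
        kz_stack[:] = 0.0
        for zi, kz in enumerate(kdata.kz_order):
            kz_stack[:, :, kz] = ksp.recon_radial_2d(
                kdata.samples[t, :, :, zi], kdata.angles_deg[t], (nx, ny)
            )
        out[:, :, :, t] = np.fft.fftshift(
            np.fft.ifft(np.fft.ifftshift(kz_stack, axes=2), axis=2), axes=2
        )
    return out
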