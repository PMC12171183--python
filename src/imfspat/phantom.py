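"""Synthetic fat-fraction phantoms with ground-truth IMF masks.

Each phantom is an elliptic-cylinder "muscle" along the slice axis filled with
low fat-fraction background (truncated normal, default 0.03 +/- 0.01 clipped
below 0.05 so background is always accepted by the median-threshold growth
condition). High-FF structures are planted inside a safety margin (one pixel
beyond the extraction erosion) so the eroded ROI never clips them:

* branch-like tubes — persistent in-plane random walks along the muscle long
  axis, emulating the branching IMF morphology seen in gastrocnemius;
* diffuse spherical clusters — multiple focal blobs, the soleus-like mode;
* sub-threshold noise singletons — isolated high-FF voxels placed away from
  every true cluster; they emulate imaging artifacts and must be removed by
  the small-cluster filter.

Presets "young" (sparse branches) and "old" (3x branch count, denser
clustering) mimic the age-group morphologies; "sol_diffuse" the multi-focal
soleus pattern. The ``proximal_gradient`` biases branch placement toward the
proximal (100 %) end of the muscle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .extraction import erode_slice_roi
from .volumes import FFVolume, MuscleMask

_MARGIN = 3  # pixels between planted structures and the muscle boundary


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom (all defaults documented above)."""

    shape: tuple[int, int, int] = (44, 44, 28)
    spacing: tuple[float, float, float] = (1.1, 1.1, 2.0)
    slice_axis: int = 2
    muscle_semiaxes: tuple[float, float] = (17.0, 14.0)
    background_ff: float = 0.03
    background_sd: float = 0.01
    background_max: float = 0.05
    n_branches: int = 4
    branch_step_sd: float = 1.1          # mm per slice, in-plane tortuosity
    branch_radius: float = 1.0           # in-plane stamp radius, pixels
    branch_ff: tuple[float, float] = (0.25, 0.60)
    branch_length_frac: float = 0.7      # fraction of slices spanned
    n_diffuse_clusters: int = 0
    diffuse_radius: float = 2.0          # voxels
    n_noise_singletons: int = 8
    singleton_ff: float = 0.45
    proximal_gradient: float = 1.0       # weight slope of branch starts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branches < 0 or self.n_diffuse_clusters < 0 or self.n_noise_singletons < 0:
            raise ValueError("structure counts must be non-negative")
        if not 0 < self.background_max < 2 * self.background_ff + 1e-9:
            raise ValueError("background_max must keep background below twice its mean")
        if self.branch_ff[0] <= self.background_max * 2:
            raise ValueError("branch FF must be well above the background threshold")


@dataclass
class Phantom:
    """Generated phantom: FF volume, muscle mask, ground truth and noise."""

    ff: FFVolume
    muscle: MuscleMask
    truth: np.ndarray          # planted IMF clusters (each component >= 4 voxels)
    singletons: np.ndarray     # planted sub-threshold noise voxels (not truth)
    spec: PhantomSpec


def preset(name: str) -> PhantomSpec:
    """Named parameter sets mimicking the observed group morphologies."""
    presets = {
        "young": PhantomSpec(n_branches=4),
        "old": PhantomSpec(n_branches=12),
        "sol_diffuse": PhantomSpec(n_branches=2, n_diffuse_clusters=6),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]


def _ellipse_mask(shape2d: tuple[int, int], semiaxes: tuple[float, float]) -> np.ndarray:
    a, b = semiaxes
    cx, cy = (shape2d[0] - 1) / 2.0, (shape2d[1] - 1) / 2.0
    x, y = np.meshgrid(np.arange(shape2d[0]), np.arange(shape2d[1]), indexing="ij")
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


def _stamp_disk(mask2d: np.ndarray, center: tuple[float, float], radius: float,
                limit: np.ndarray) -> None:
    r_int = int(np.ceil(radius))
    cx, cy = center
    x0, x1 = int(np.floor(cx)) - r_int, int(np.floor(cx)) + r_int + 1
    y0, y1 = int(np.floor(cy)) - r_int, int(np.floor(cy)) + r_int + 1
    for x in range(max(x0, 0), min(x1, mask2d.shape[0])):
        for y in range(max(y0, 0), min(y1, mask2d.shape[1])):
            if (x - round(cx)) ** 2 + (y - round(cy)) ** 2 <= radius ** 2 and limit[x, y]:
                mask2d[x, y] = True


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one phantom, deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    if spec.slice_axis != 2:
        raise ValueError("phantom generation assumes slice_axis=2")
    ellipse = _ellipse_mask((nx, ny), spec.muscle_semiaxes)
    safe2d = erode_slice_roi(ellipse, _MARGIN)
    if not safe2d.any():
        raise ValueError("muscle too small for the safety margin")
    muscle = np.repeat(ellipse[:, :, None], nz, axis=2)

    # background: truncated normal, bounded below twice its median by design
    ff = np.zeros(spec.shape, dtype=float)
    bg = rng.normal(spec.background_ff, spec.background_sd, size=spec.shape)
    ff[muscle] = np.clip(bg, 0.0, spec.background_max)[muscle]

    truth = np.zeros(spec.shape, dtype=bool)
    safe_idx = np.argwhere(safe2d)

    # branch-like tubes: persistent random walks along the slice axis
    z_weights = 1.0 + spec.proximal_gradient * np.arange(nz) / max(nz - 1, 1)
    z_weights /= z_weights.sum()
    step_px = spec.branch_step_sd / spec.spacing[0]
    length = max(2, int(round(spec.branch_length_frac * nz)))
    for _ in range(spec.n_branches):
        z0 = int(rng.choice(nz, p=z_weights))
        start = safe_idx[rng.integers(len(safe_idx))]
        cx, cy = float(start[0]), float(start[1])
        for z in range(z0, min(z0 + length, nz)):
            _stamp_disk(truth[:, :, z], (cx, cy), spec.branch_radius, safe2d)
            cx += rng.normal(0.0, step_px)
            cy += rng.normal(0.0, step_px)
            if not safe2d[int(np.clip(round(cx), 0, nx - 1)),
                          int(np.clip(round(cy), 0, ny - 1))]:
                # walked out of the safe region: snap back to nearest safe pixel
                d2 = ((safe_idx[:, 0] - cx) ** 2 + (safe_idx[:, 1] - cy) ** 2)
                cx, cy = map(float, safe_idx[int(np.argmin(d2))])

    # diffuse spherical clusters (soleus-like multi-focal mode)
    for _ in range(spec.n_diffuse_clusters):
        c2d = safe_idx[rng.integers(len(safe_idx))]
        zc = int(rng.integers(_MARGIN, nz - _MARGIN))
        r = spec.diffuse_radius
        ri = int(np.ceil(r))
        for dx in range(-ri, ri + 1):
            for dy in range(-ri, ri + 1):
                for dz in range(-ri, ri + 1):
                    if dx * dx + dy * dy + dz * dz <= r * r:
                        x, y, z = c2d[0] + dx, c2d[1] + dy, zc + dz
                        if 0 <= z < nz and 0 <= x < nx and 0 <= y < ny and safe2d[x, y]:
                            truth[x, y, z] = True

    if (spec.n_branches or spec.n_diffuse_clusters) and not truth.any():
        raise ValueError("planted ground truth is empty")

    # drop any truth fragment below the 4-voxel cluster threshold so truth
    # equals what a correct extraction should retain
    labels, n = ndimage.label(truth, structure=ndimage.generate_binary_structure(3, 3))
    if n:
        sizes = np.bincount(labels.ravel())[1:]
        small = np.flatnonzero(sizes < 4) + 1
        if small.size:
            truth[np.isin(labels, small)] = False

    ff[truth] = rng.uniform(*spec.branch_ff, size=int(truth.sum()))

    # noise singletons: >= 2 voxels (Chebyshev) from truth and from each other
    singles = np.zeros(spec.shape, dtype=bool)
    forbidden = ndimage.binary_dilation(truth, structure=np.ones((5, 5, 5), bool))
    placed = 0
    attempts = 0
    while placed < spec.n_noise_singletons and attempts < 10000:
        attempts += 1
        p2d = safe_idx[rng.integers(len(safe_idx))]
        z = int(rng.integers(0, nz))
        if forbidden[p2d[0], p2d[1], z]:
            continue
        singles[p2d[0], p2d[1], z] = True
        forbidden[max(p2d[0] - 2, 0):p2d[0] + 3,
                  max(p2d[1] - 2, 0):p2d[1] + 3,
                  max(z - 2, 0):z + 3] = True
        placed += 1
    ff[singles] = spec.singleton_ff

    ffvol = FFVolume(ff, spec.spacing, spec.slice_axis, True)
    mask = MuscleMask(muscle, spec.spacing, "phantom", spec.slice_axis, True)
    return Phantom(ffvol, mask, truth, singles, spec)


def cohort_specs(
    n_young: int, n_old: int, base_seed: int = 0
) -> list[tuple[str, PhantomSpec]]:
    """Specs for a simulated cohort: per-participant seeds off a base seed."""
    out = []
    for i in range(n_young):
        out.append(("young", replace(preset("young"), seed=base_seed + i)))
    for i in range(n_old):
        out.append(("older", replace(preset("old"), seed=base_seed + 1000 + i)))
    return out
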