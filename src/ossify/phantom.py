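"""Synthetic two-channel cryo-FIB-SEM phantoms with exact ground truth.

The generator emulates the imaged scene of forming embryonic bone: one or
more cells (each with a nucleus) containing spherical membrane-bounded
vesicles; dense amorphous-mineral precursor granules packed inside a subset
of the vesicles at a controlled volume filling factor; a brighter
mineralized matrix slab perforated by darker canaliculi (~300 nm) and a
nanochannel network (~40 nm, a fixed fraction of the mineral volume);
additive Gaussian noise and optional FIB curtaining (vertical striping).

Every voxel has a known class label, and the per-vesicle ground-truth table
is derived from the voxelized labels themselves, so downstream morphometry
can be validated to the voxel.

Geometry works in voxel units with the voxel-corner convention: voxel ``i``
spans ``[i, i+1)`` and has its center at ``i + 0.5``; spheres are voxelized
by a center-in-sphere test (±1 voxel-shell quantization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import DENSITY, STRUCTURE, ImageStack, LabelVolume
from .morphometry import CellRecord, VesicleRecord


class PackingError(RuntimeError):
    """Requested density/geometry cannot be realized without overlaps."""


@dataclass
class VolumeLaw:
    """Distribution of vesicle volumes in µm³.

    ``lognormal``: parameterized by the arithmetic mean and the natural-log
    standard deviation.  The default (mean 0.65 µm³, σ_log 0.9) is a
    right-skewed law placing ≈82 % of vesicles below 1 µm³ and spanning
    diameters ≈0.3–2.8 µm — the closest lognormal can come to the observed
    80 %-below-1 µm³ quantile at that mean.  ``fixed`` yields a constant
    volume (useful for controlled tests).
    """

    family: str = "lognormal"
    mean: float = 0.65
    sigma_log: float = 0.9

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "fixed"):
            raise ValueError(f"unknown volume law family {self.family!r}")
        if not self.mean > 0:
            raise ValueError("mean vesicle volume must be positive")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")

    def sample(self, rng: np.random.Generator, n: int, v_min: float = 0.0) -> np.ndarray:
        """Draw ``n`` volumes, resampling any draw below ``v_min`` (µm³)."""
        if self.family == "fixed":
            if self.mean < v_min:
                raise PackingError(
                    f"fixed vesicle volume {self.mean} µm³ below the minimum "
                    f"hostable volume {v_min:.3g} µm³")
            return np.full(n, self.mean)
        mu = math.log(self.mean) - 0.5 * self.sigma_log**2
        out = rng.lognormal(mu, self.sigma_log, size=n)
        for _ in range(100):
            low = out < v_min
            if not low.any():
                return out
            out[low] = rng.lognormal(mu, self.sigma_log, size=int(low.sum()))
        raise PackingError("vesicle volume law produces only sub-granule vesicles")


@dataclass
class PhantomParams:
    """Full parameter set of the phantom scene.

    Defaults follow the imaged system: 8 nm isotropic voxels, 0.037
    precursor-bearing vesicles per µm³ of cell volume, mean vesicle volume
    0.65 µm³, 9 % mean filling factor, 80 nm precursor granules, 40 nm
    nanochannels occupying 14 % of the mineral volume, 300 nm canaliculi.
    """

    volume_shape: tuple[int, int, int] = (256, 256, 256)
    voxel_size: float = 0.008          # µm
    n_cells: int = 1
    vesicle_density: float = 0.037     # precursor-bearing vesicles per µm³ cell
    vesicle_volume_law: VolumeLaw = field(default_factory=VolumeLaw)
    filling_factor_mean: float = 0.09
    filling_factor_sd: float = 0.01
    granule_diameter: float = 0.080    # µm
    frac_empty_vesicles: float = 0.30
    matrix_gray_levels: tuple[float, float, float] = (60.0, 180.0, 220.0)
    noise_sd: float = 5.0              # gray levels
    striping_amplitude: float = 0.0    # gray levels
    nanochannel_fraction: float = 0.14
    nanochannel_diameter: float = 0.040  # µm
    canaliculus_diameter: float = 0.300  # µm
    matrix_fraction: float = 0.25      # fraction of the y extent that is matrix
    cell_radius: float | None = None   # µm; None = auto-fit to the cell region
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.volume_shape)
        if len(shape) != 3 or min(shape) < 1:
            raise ValueError("volume_shape must be 3 positive ints")
        self.volume_shape = shape
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not 0 < self.filling_factor_mean <= 1:
            raise ValueError("filling_factor_mean must be in (0, 1]")
        if self.filling_factor_sd < 0:
            raise ValueError("filling_factor_sd must be non-negative")
        if not 0 <= self.frac_empty_vesicles <= 1:
            raise ValueError("frac_empty_vesicles must be in [0, 1]")
        unm, mino, prec = self.matrix_gray_levels
        if not mino > unm:
            raise ValueError("mineralized gray mean must exceed unmineralized "
                             "(backscatter contrast ordering)")
        for name in ("granule_diameter", "nanochannel_diameter", "canaliculus_diameter"):
            if getattr(self, name) < 2 * self.voxel_size:
                raise ValueError(f"{name} must be at least two voxels "
                                 f"({2 * self.voxel_size:.4g} µm)")
        if self.vesicle_density < 0:
            raise ValueError("vesicle_density must be non-negative")
        if not 0 <= self.nanochannel_fraction < 1:
            raise ValueError("nanochannel_fraction must be in [0, 1)")
        if not 0 <= self.matrix_fraction < 0.95:
            raise ValueError("matrix_fraction must be in [0, 0.95)")
        if self.noise_sd < 0 or self.striping_amplitude < 0:
            raise ValueError("noise_sd and striping_amplitude must be non-negative")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")


@dataclass
class PhantomOutput:
    """Phantom channels, per-class ground-truth labels and truth tables."""

    density_channel: ImageStack
    structure_channel: ImageStack
    truth: dict[str, LabelVolume]
    truth_table: list[VesicleRecord]
    cell_table: list[CellRecord]
    params: PhantomParams

    @property
    def mineralized_fraction(self) -> float:
        """Ground-truth fraction of voxels that are mineral (matrix minus channels)."""
        lab = self.truth["matrix"].labels
        return float(np.count_nonzero(lab)) / lab.size


# -- sphere rasterization ----------------------------------------------------

def _ball(shape, center, radius, shell: bool = False):
    """Bounding-box slices + boolean mask of voxel centers inside a sphere.

    With ``shell=True`` return the one-voxel surface shell instead.
    """
    lo = [max(int(math.floor(c - radius - 1.0)), 0) for c in center]
    hi = [min(int(math.ceil(c + radius + 1.0)) + 1, s) for c, s in zip(center, shape)]
    if any(l >= h for l, h in zip(lo, hi)):
        return None, None
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = sum(((g + 0.5) - c) ** 2 for g, c in zip(grids, center))
    if shell:
        inner = max(radius - 1.0, 0.0)
        mask = (d2 <= radius * radius) & (d2 > inner * inner)
    else:
        mask = d2 <= radius * radius
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return sl, mask


def _sample_in_ball(rng, center, radius):
    """Uniform point inside a sphere (voxel coordinates)."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    r = radius * rng.uniform() ** (1.0 / 3.0)
    return np.asarray(center) + direction * r


# -- scene construction ------------------------------------------------------

def _place_cells(params: PhantomParams, rng, y_limit: int):
    """Choose non-overlapping cell centers/radii inside the unmineralized region."""
    nz, ny, nx = params.volume_shape
    if params.n_cells == 0:
        return []
    if params.cell_radius is not None:
        r_vox = params.cell_radius / params.voxel_size
    else:
        avail = min(nz, y_limit, nx)
        r_vox = 0.42 * avail / math.ceil(params.n_cells ** (1.0 / 3.0))
    if r_vox < 2:
        raise PackingError("cell radius below two voxels; enlarge the volume "
                           "or coarsen the voxels")
    if min(nz, nx) - 2 * (r_vox + 1) <= 0 or y_limit - 2 * (r_vox + 1) <= 0:
        raise PackingError(
            f"cell radius {r_vox * params.voxel_size:.3g} µm does not fit the "
            "unmineralized region; shrink cell_radius or matrix_fraction")
    lo = np.array([r_vox + 1] * 3)
    hi = np.array([nz - r_vox - 1, y_limit - r_vox - 1, nx - r_vox - 1])

    def _try_random():
        cells = []
        for _ in range(params.n_cells):
            for _attempt in range(3000):
                c = rng.uniform(lo, hi)
                if all(np.linalg.norm(c - c0) > r_vox + r0 + 1 for c0, r0 in cells):
                    cells.append((c, r_vox))
                    break
            else:
                return None
        return cells

    def _try_anchors():
        # corners (+ center) of the admissible box are maximally separated;
        # deterministic fallback for packings too tight for rejection sampling
        anchors = [np.where(np.array(bits), hi, lo).astype(float)
                   for bits in np.ndindex(2, 2, 2)] + [(lo + hi) / 2.0]
        rng.shuffle(anchors)
        cells = []
        for anchor in anchors:
            if len(cells) == params.n_cells:
                break
            c = np.clip(anchor + rng.uniform(-2, 2, size=3), lo, hi)
            if all(np.linalg.norm(c - c0) > r_vox + r0 + 1 for c0, r0 in cells):
                cells.append((c, r_vox))
        return cells if len(cells) == params.n_cells else None

    cells = _try_random() or _try_anchors()
    if cells is None:
        raise PackingError(
            f"could not place {params.n_cells} cells of radius "
            f"{r_vox * params.voxel_size:.3g} µm in the unmineralized region")
    return cells


def _carve_canaliculi(matrix: np.ndarray, y0: int, params: PhantomParams, rng):
    """Carve cylindrical canaliculi running from the matrix surface inward."""
    nz, ny, nx = matrix.shape
    can = np.zeros_like(matrix, dtype=np.uint16)
    radius = 0.5 * params.canaliculus_diameter / params.voxel_size
    depth = ny - y0
    if depth < 2 * radius:
        return can
    n_can = max(2, 2 * params.n_cells)
    for cid in range(1, n_can + 1):
        z_entry = rng.uniform(radius + 1, nz - radius - 1) if nz > 2 * radius + 2 else nz / 2
        x_entry = rng.uniform(radius + 1, nx - radius - 1) if nx > 2 * radius + 2 else nx / 2
        tilt = rng.uniform(-0.3, 0.3, size=2)
        for y in range(y0, ny):
            t = y - y0
            cz, cx = z_entry + tilt[0] * t, x_entry + tilt[1] * t
            zlo = max(int(math.floor(cz - radius - 1)), 0)
            zhi = min(int(math.ceil(cz + radius + 1)) + 1, nz)
            xlo = max(int(math.floor(cx - radius - 1)), 0)
            xhi = min(int(math.ceil(cx + radius + 1)) + 1, nx)
            if zlo >= zhi or xlo >= xhi:
                continue
            zz, xx = np.ogrid[zlo:zhi, xlo:xhi]
            disk = ((zz + 0.5) - cz) ** 2 + ((xx + 0.5) - cx) ** 2 <= radius**2
            sub = can[zlo:zhi, y, xlo:xhi]
            sub[disk & matrix[zlo:zhi, y, xlo:xhi]] = cid
    return can


def _nanochannel_mask(mineral: np.ndarray, params: PhantomParams, rng):
    """Correlated random field thresholded to the target volume fraction.

    Explicit 40 nm tubes at a 14 % fraction would need tens of thousands of
    segments; a Gaussian random field with correlation length equal to the
    channel diameter reproduces the volume fraction and gray-level structure
    that downstream stages consume (network topology is out of scope).
    """
    target = params.nanochannel_fraction
    if target <= 0 or not mineral.any():
        return np.zeros_like(mineral)
    sigma = max(params.nanochannel_diameter / (2 * params.voxel_size), 0.5)
    noise = rng.standard_normal(mineral.shape)
    fld = ndimage.gaussian_filter(noise, sigma=sigma)
    vals = fld[mineral]
    k = int(round(target * vals.size))
    if k == 0:
        return np.zeros_like(mineral)
    cutoff = np.partition(vals, vals.size - k)[vals.size - k]
    return mineral & (fld >= cutoff)


def generate_phantom(params: PhantomParams) -> PhantomOutput:
    """Generate a deterministic two-channel phantom with ground truth.

    Raises
    ------
    PackingError
        If the requested vesicle density, cell count or cell radius cannot
        be realized without overlaps (never silently truncated).
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = shape = params.volume_shape
    vs = params.voxel_size
    voxel_volume = vs**3

    # -- mineralized slab along +y, carved by canaliculi and nanochannels
    y0 = int(round(ny * (1.0 - params.matrix_fraction)))
    slab = np.zeros(shape, dtype=bool)
    if params.matrix_fraction > 0 and y0 < ny:
        slab[:, y0:, :] = True
    canaliculus = _carve_canaliculi(slab, y0, params, rng) if slab.any() \
        else np.zeros(shape, dtype=np.uint16)
    mineral = slab & (canaliculus == 0)
    nanochannel = _nanochannel_mask(mineral, params, rng)
    mineral &= ~nanochannel

    # -- cells and nuclei in the unmineralized region
    y_limit = y0 - 2 if slab.any() else ny
    cells = _place_cells(params, rng, y_limit)
    cell_lab = np.zeros(shape, dtype=np.uint16)
    nucleus_lab = np.zeros(shape, dtype=np.uint16)
    nuclei = []
    for cid, (center, radius) in enumerate(cells, start=1):
        sl, mask = _ball(shape, center, radius)
        cell_lab[sl][mask] = cid
        n_r = 0.35 * radius
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        n_c = center + direction * 0.3 * radius
        sl, mask = _ball(shape, n_c, n_r)
        nucleus_lab[sl][mask] = cid
        nuclei.append((n_c, n_r))

    cell_voxel_counts = np.bincount(cell_lab.ravel(), minlength=len(cells) + 1)[1:]
    total_cell_volume = float(cell_voxel_counts.sum()) * voxel_volume

    # -- vesicle census: density counts precursor-bearing vesicles only
    n_filled = int(round(params.vesicle_density * total_cell_volume))
    if params.frac_empty_vesicles >= 1.0:
        if n_filled > 0:
            raise ValueError("frac_empty_vesicles = 1 is inconsistent with a "
                             "positive vesicle density of precursor-bearing vesicles")
        n_empty = 0
    else:
        fe = params.frac_empty_vesicles
        n_empty = int(round(n_filled * fe / (1.0 - fe)))
    n_total = n_filled + n_empty

    granule_r_vox = 0.5 * params.granule_diameter / vs
    # smallest vesicle that can host one granule plus a margin voxel
    v_min = (4.0 / 3.0) * math.pi * ((granule_r_vox + 1.5) * vs) ** 3
    volumes = params.vesicle_volume_law.sample(rng, n_total, v_min=v_min) \
        if n_total else np.empty(0)
    if n_total and volumes.sum() > 0.35 * total_cell_volume:
        raise PackingError(
            f"requested vesicles occupy {volumes.sum():.3g} µm³, more than 35 % of "
            f"the {total_cell_volume:.3g} µm³ cell volume — density too high")

    is_filled = np.zeros(n_total, dtype=bool)
    is_filled[:n_filled] = True
    rng.shuffle(is_filled)

    # place largest first for packing headroom; labels follow placement order
    order = np.argsort(volumes)[::-1]
    vesicle_lab = np.zeros(shape, dtype=np.uint32)
    ves_centers: list[np.ndarray] = []
    ves_radii: list[float] = []
    ves_cell: list[int] = []
    ves_filled: list[bool] = []
    membrane = np.zeros(shape, dtype=bool)
    if n_total:
        if not cells:
            raise PackingError("vesicles requested but no cells to host them")
        weights = cell_voxel_counts / cell_voxel_counts.sum()
        placed_by_cell: dict[int, list[tuple[np.ndarray, float]]] = {}
        next_label = 1
        for idx in order:
            r_ves = max((3.0 * volumes[idx] / (4.0 * math.pi)) ** (1.0 / 3.0) / vs, 1.0)
            cid = int(rng.choice(len(cells), p=weights)) + 1
            c_center, c_radius = cells[cid - 1]
            n_c, n_r = nuclei[cid - 1]
            max_r = c_radius - r_ves - 1.0
            if max_r <= 0:
                raise PackingError(
                    f"vesicle of radius {r_ves * vs:.3g} µm does not fit in cell of "
                    f"radius {c_radius * vs:.3g} µm")
            for _attempt in range(2000):
                pos = _sample_in_ball(rng, c_center, max_r)
                if np.linalg.norm(pos - n_c) < n_r + r_ves + 1.0:
                    continue
                if any(np.linalg.norm(pos - p) < r + r_ves + 1.0
                       for p, r in placed_by_cell.get(cid, [])):
                    continue
                break
            else:
                raise PackingError("vesicle packing failed; reduce vesicle_density "
                                   "or the vesicle volumes")
            placed_by_cell.setdefault(cid, []).append((pos, r_ves))
            sl, mask = _ball(shape, pos, r_ves)
            vesicle_lab[sl][mask] = next_label
            sl, shell = _ball(shape, pos, r_ves, shell=True)
            membrane[sl] |= shell
            ves_centers.append(pos)
            ves_radii.append(r_ves)
            ves_cell.append(cid)
            ves_filled.append(bool(is_filled[idx]))
            next_label += 1

    # -- precursor granules packed to the drawn filling factor
    precursor_lab = np.zeros(shape, dtype=np.uint32)
    ves_voxel_counts = np.bincount(vesicle_lab.ravel(), minlength=n_total + 1)
    granule_id = 0
    for label, (pos, r_ves, filled) in enumerate(
            zip(ves_centers, ves_radii, ves_filled), start=1):
        if not filled:
            continue
        f_target = params.filling_factor_mean if params.filling_factor_sd == 0 \
            else rng.normal(params.filling_factor_mean, params.filling_factor_sd)
        f_target = float(np.clip(f_target, 1e-6, 1.0))
        target_vox = f_target * ves_voxel_counts[label]
        placed: list[np.ndarray] = []
        prec_vox = 0
        free_r = r_ves - granule_r_vox - 0.5
        while prec_vox < target_vox:
            for _attempt in range(500):
                g = _sample_in_ball(rng, pos, max(free_r, 0.0))
                if all(np.linalg.norm(g - q) >= 2 * granule_r_vox for q in placed):
                    break
            else:
                break  # vesicle saturated below target; truth table records reality
            granule_id += 1
            placed.append(g)
            sl, mask = _ball(shape, g, granule_r_vox)
            mask = mask & (precursor_lab[sl] == 0)
            precursor_lab[sl][mask] = granule_id
            prec_vox += int(mask.sum())

    # -- ground-truth tables straight from the voxel labels
    prec_per_ves = np.bincount(vesicle_lab[precursor_lab > 0].ravel(),
                               minlength=n_total + 1)
    boundary_ids = set()
    for axis in range(3):
        for face in (0, -1):
            boundary_ids.update(np.unique(np.take(vesicle_lab, face, axis=axis)))
    truth_table = []
    filled_per_cell = np.zeros(len(cells) + 1, dtype=int)
    for label in range(1, len(ves_centers) + 1):
        p_vox = int(prec_per_ves[label])
        if p_vox == 0:
            continue
        v_vox = int(ves_voxel_counts[label])
        cid = ves_cell[label - 1]
        filled_per_cell[cid] += 1
        centroid_idx = ves_centers[label - 1] - 0.5  # mean voxel index of a ball
        truth_table.append(VesicleRecord(
            vesicle_id=label,
            cell_id=cid,
            vesicle_volume=v_vox * voxel_volume,
            precursor_volume=p_vox * voxel_volume,
            filling_factor=p_vox / v_vox,
            centroid=tuple(float(c) * vs for c in centroid_idx),
            touches_boundary=label in boundary_ids,
        ))
    cell_table = [
        CellRecord(cell_id=cid,
                   imaged_cell_volume=float(cell_voxel_counts[cid - 1]) * voxel_volume,
                   n_vesicles=int(filled_per_cell[cid]),
                   vesicle_density=float(filled_per_cell[cid])
                   / (float(cell_voxel_counts[cid - 1]) * voxel_volume))
        for cid in range(1, len(cells) + 1)
    ]

    # -- compose gray levels and corrupt
    unm, mino, prec_gray = params.matrix_gray_levels
    density = np.full(shape, unm, dtype=np.float64)
    density[mineral] = mino
    density[precursor_lab > 0] = prec_gray
    structure = np.full(shape, 90.0, dtype=np.float64)
    structure[cell_lab > 0] = 110.0
    structure[nucleus_lab > 0] = 130.0
    structure[vesicle_lab > 0] = 70.0
    structure[membrane] = 200.0
    structure[precursor_lab > 0] = 170.0
    structure[mineral] = 150.0
    structure[(canaliculus > 0) | nanochannel] = 40.0

    def _to_stack(arr, channel):
        return ImageStack(voxels=np.clip(np.rint(arr), 0, 255).astype(np.uint8),
                          voxel_size=vs, channel=channel, bit_depth=8)

    density_stack = corrupt_stack(_to_stack(density, DENSITY), params.noise_sd,
                                  params.striping_amplitude,
                                  seed=int(rng.integers(2**31)))
    structure_stack = corrupt_stack(_to_stack(structure, STRUCTURE), params.noise_sd,
                                    params.striping_amplitude,
                                    seed=int(rng.integers(2**31)))

    truth = {
        "cell": LabelVolume(cell_lab, "cell", vs),
        "nucleus": LabelVolume(nucleus_lab, "nucleus", vs),
        "vesicle": LabelVolume(vesicle_lab, "vesicle", vs),
        "precursor": LabelVolume(precursor_lab, "precursor", vs),
        "matrix": LabelVolume(mineral.astype(np.uint8), "matrix", vs),
        "canaliculus": LabelVolume(canaliculus, "canaliculus", vs),
        "nanochannel": LabelVolume(nanochannel.astype(np.uint8), "nanochannel", vs),
    }
    return PhantomOutput(density_channel=density_stack,
                         structure_channel=structure_stack,
                         truth=truth, truth_table=truth_table,
                         cell_table=cell_table, params=params)


def corrupt_stack(stack: ImageStack, noise_sd: float, striping_amplitude: float,
                  seed: int) -> ImageStack:
    """Add Gaussian noise and column-wise striping (FIB curtaining) to a stack.

    With both amplitudes zero the voxels are returned unchanged.  The output
    is clipped to the stack's intensity range and keeps its dtype; within a
    slice the striping offset is constant along each image column.
    """
    if noise_sd < 0 or striping_amplitude < 0:
        raise ValueError("noise_sd and striping_amplitude must be non-negative")
    if noise_sd == 0 and striping_amplitude == 0:
        return replace(stack, voxels=stack.voxels.copy())
    rng = np.random.default_rng(seed)
    nz, ny, nx = stack.shape
    arr = stack.voxels.astype(np.float64)
    if noise_sd > 0:
        arr += rng.normal(0.0, noise_sd, size=stack.shape)
    if striping_amplitude > 0:
        offsets = rng.uniform(-striping_amplitude, striping_amplitude, size=(nz, nx))
        arr += offsets[:, None, :]
    top = 2**stack.bit_depth - 1
    out = np.clip(np.rint(arr), 0, top).astype(stack.voxels.dtype)
    return replace(stack, voxels=out)
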