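"""3D vesicle morphometry: labelling, per-vesicle volumes and filling
factors, per-cell vesicle densities, allometric (power-law) scaling of
precursor cargo with vesicle size, and per-stack summary tables.

Counting rule: only vesicles that contain electron-dense mineral precursor
enter the record table — vesicles without cargo are excluded from all
statistics, and precursor voxels found outside any vesicle are reported as
an anomaly (none are expected; the vesicles are exclusively intracellular).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .io import LabelVolume

#: default minimum vesicle volume: a 40 nm-diameter sphere, below the
#: smallest structure of interest (µm³)
MIN_VESICLE_VOLUME = (4.0 / 3.0) * math.pi * 0.020**3

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class VesicleRecord:
    """Morphometry of one precursor-bearing vesicle (volumes in µm³)."""

    vesicle_id: int
    cell_id: int
    vesicle_volume: float
    precursor_volume: float
    filling_factor: float
    centroid: tuple[float, float, float]  # µm, (z, y, x)
    touches_boundary: bool = False


@dataclass
class CellRecord:
    """Per-cell vesicle census; density in vesicles per µm³."""

    cell_id: int
    imaged_cell_volume: float
    n_vesicles: int
    vesicle_density: float


@dataclass
class AllometricFit:
    """Power-law fit P = a·V^b on log10–log10 axes (b = ``exponent``)."""

    exponent: float
    log_prefactor: float
    exponent_se: float
    n: int


@dataclass
class StackSummary:
    """Per-stack aggregate of the vesicle census (volumes in µm³).

    ``filling_factor`` is the unweighted mean of per-vesicle ratios;
    ``filling_factor_total`` is the ratio of summed precursor volume to
    summed vesicle volume — two distinct statistics, both reported.
    ``precursor_per_vesicle`` is the product mean volume × mean filling
    factor (an identity that holds to float precision).
    """

    stack_id: str
    volume_imaged: float
    volume_mineralized_bone: float
    n_cells: int
    n_vesicles: int
    mean_vesicle_volume: float
    filling_factor: float
    precursor_per_vesicle: float
    filling_factor_total: float = float("nan")


@dataclass
class MorphometryQC:
    """Anomaly counts produced while building vesicle records."""

    orphan_precursor_voxels: int   # precursor voxels outside any vesicle
    n_excluded_no_precursor: int   # vesicles without cargo (not recorded)
    n_excluded_below_min: int
    n_outside_cell: int            # recorded vesicles not inside any cell


def label_components(mask, connectivity: int = 26, voxel_size: float = 1.0,
                     class_name: str = "") -> LabelVolume:
    """Label maximal connected components of a binary volume.

    ``connectivity`` is 6 (faces), 18 (+edges) or 26 (+corners); labels are
    assigned 1..K in array scan order.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    mask = np.asarray(mask).astype(bool)
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    labels, _ = ndimage.label(mask, structure=structure)
    return LabelVolume(labels=labels.astype(np.int32), class_name=class_name,
                       voxel_size=voxel_size)


def _majority_assignment(component_labels, host_labels, include_background=False):
    """For each positive component id, the host id covering most of its voxels.

    Ties break to the lower host id.  With ``include_background=False`` a
    component with any positive-host overlap is assigned to the best such
    host; with ``include_background=True`` the background competes, so a
    component lying mostly outside every host gets id 0.  Also returns the
    total count of component voxels lying on background.
    """
    comp = component_labels.ravel()
    host = host_labels.ravel()
    sel = comp > 0
    comp, host = comp[sel], host[sel]
    n_comp = int(comp.max()) if comp.size else 0
    n_host = int(host.max()) if host.size else 0
    pair = comp.astype(np.int64) * (n_host + 1) + host
    counts = np.bincount(pair, minlength=(n_comp + 1) * (n_host + 1))
    counts = counts.reshape(n_comp + 1, n_host + 1)
    on_background = int(counts[1:, 0].sum())
    if include_background or n_host == 0:
        assignment = np.argmax(counts, axis=1)  # argmax ties -> lowest id
    else:
        positive = counts[:, 1:]
        best = np.argmax(positive, axis=1) + 1
        assignment = np.where(positive.max(axis=1) > 0, best, 0)
    return assignment, on_background


def build_vesicle_records(vesicle_labels: LabelVolume, precursor_labels: LabelVolume,
                          cell_labels: LabelVolume,
                          min_volume: float = MIN_VESICLE_VOLUME,
                          ) -> tuple[list[VesicleRecord], MorphometryQC]:
    """Per-vesicle morphometry from aligned label volumes.

    A record is produced for every vesicle label with positive precursor
    overlap and volume ≥ ``min_volume``.  Precursor components are assigned
    whole to the vesicle covering the majority of their voxels (ties to the
    lower vesicle id); precursor voxels outside any vesicle are counted as
    an anomaly in the QC report rather than silently dropped.
    """
    for other in (precursor_labels, cell_labels):
        if other.shape != vesicle_labels.shape:
            raise ValueError("label volumes must share one shape "
                             f"({other.class_name}: {other.shape} vs "
                             f"{vesicle_labels.shape})")
        if not np.isclose(other.voxel_size, vesicle_labels.voxel_size):
            raise ValueError("label volumes must share one voxel size")
    v = vesicle_labels.labels
    voxel_volume = vesicle_labels.voxel_volume
    n_ves = int(v.max())
    ves_counts = np.bincount(v.ravel(), minlength=n_ves + 1)

    # whole-component precursor assignment by majority overlap
    prec_assign, orphan_voxels = _majority_assignment(precursor_labels.labels, v)
    prec_counts = np.bincount(precursor_labels.labels.ravel())
    prec_per_ves = np.zeros(n_ves + 1, dtype=np.int64)
    for comp_id in range(1, len(prec_assign)):
        prec_per_ves[prec_assign[comp_id]] += prec_counts[comp_id]

    cell_assign, _ = _majority_assignment(v, cell_labels.labels,
                                          include_background=True)

    boundary_ids = set()
    for axis in range(3):
        for face in (0, -1):
            boundary_ids.update(int(i) for i in np.unique(np.take(v, face, axis=axis)))

    ids = np.arange(1, n_ves + 1)
    centroids = ndimage.center_of_mass(np.ones_like(v, dtype=np.uint8), v, ids) \
        if n_ves else []

    records: list[VesicleRecord] = []
    n_no_prec = n_small = n_outside = 0
    for label in range(1, n_ves + 1):
        vol = ves_counts[label] * voxel_volume
        p_vol = prec_per_ves[label] * voxel_volume
        if p_vol <= 0:
            n_no_prec += 1
            continue
        if vol < min_volume:
            n_small += 1
            continue
        cid = int(cell_assign[label]) if label < len(cell_assign) else 0
        if cid == 0:
            n_outside += 1
        records.append(VesicleRecord(
            vesicle_id=label,
            cell_id=cid,
            vesicle_volume=float(vol),
            precursor_volume=float(p_vol),
            # ratio of voxel counts: exact, independent of the voxel volume
            filling_factor=float(prec_per_ves[label] / ves_counts[label]),
            centroid=tuple(float(c) * vesicle_labels.voxel_size
                           for c in centroids[label - 1]),
            touches_boundary=label in boundary_ids,
        ))
    qc = MorphometryQC(orphan_precursor_voxels=orphan_voxels,
                       n_excluded_no_precursor=n_no_prec,
                       n_excluded_below_min=n_small,
                       n_outside_cell=n_outside)
    return records, qc


def build_cell_records(cell_labels: LabelVolume,
                       records: list[VesicleRecord]) -> list[CellRecord]:
    """Per-cell imaged volumes and vesicle counts from labels + records."""
    counts = np.bincount(cell_labels.labels.ravel())
    per_cell = {}
    for rec in records:
        per_cell[rec.cell_id] = per_cell.get(rec.cell_id, 0) + 1
    cells = []
    for cid in range(1, len(counts)):
        vol = float(counts[cid]) * cell_labels.voxel_volume
        n = per_cell.get(cid, 0)
        cells.append(CellRecord(cell_id=cid, imaged_cell_volume=vol, n_vesicles=n,
                                vesicle_density=n / vol if vol > 0 else 0.0))
    return cells


def stack_summary(records: list[VesicleRecord], cells: list[CellRecord],
                  volume_imaged: float, volume_mineralized: float,
                  stack_id: str = "stack") -> StackSummary:
    """Aggregate a stack's records into a summary row (volumes in µm³)."""
    if not records:
        raise ValueError("stack_summary requires at least one vesicle record")
    vols = np.array([r.vesicle_volume for r in records])
    precs = np.array([r.precursor_volume for r in records])
    fills = np.array([r.filling_factor for r in records])
    mean_v = float(vols.mean())
    fill = float(fills.mean())
    return StackSummary(
        stack_id=stack_id,
        volume_imaged=float(volume_imaged),
        volume_mineralized_bone=float(volume_mineralized),
        n_cells=len(cells),
        n_vesicles=len(records),
        mean_vesicle_volume=mean_v,
        filling_factor=fill,
        precursor_per_vesicle=mean_v * fill,
        filling_factor_total=float(precs.sum() / vols.sum()),
    )


def pooled_stats(summaries: list[StackSummary]) -> tuple[float, float, float]:
    """Vesicle-count-weighted pooling across stacks.

    Returns (pooled mean vesicle volume µm³, pooled filling factor,
    pooled precursor volume per vesicle µm³ = product of the first two).
    """
    if not summaries:
        raise ValueError("pooled_stats requires at least one summary")
    n = np.array([s.n_vesicles for s in summaries], dtype=float)
    if n.sum() <= 0:
        raise ValueError("pooled_stats requires a positive total vesicle count")
    v = np.array([s.mean_vesicle_volume for s in summaries])
    f = np.array([s.filling_factor for s in summaries])
    pooled_v = float((n * v).sum() / n.sum())
    pooled_f = float((n * f).sum() / n.sum())
    return pooled_v, pooled_f, pooled_v * pooled_f


def allometric_fit(records: list[VesicleRecord]) -> AllometricFit:
    """OLS power-law fit of precursor volume against vesicle volume.

    Fits log10(precursor) = b·log10(vesicle) + a; an exponent b ≈ 1 means a
    size-independent filling factor with prefactor 10^a.
    """
    if len(records) < 3:
        raise ValueError("allometric_fit requires at least 3 records")
    x = np.log10([r.vesicle_volume for r in records])
    y = np.log10([r.precursor_volume for r in records])
    if np.ptp(x) == 0:
        raise ValueError("allometric_fit: vesicle volumes are all equal "
                         "(degenerate x-variance)")
    fit = stats.linregress(x, y)
    return AllometricFit(exponent=float(fit.slope),
                         log_prefactor=float(fit.intercept),
                         exponent_se=float(fit.stderr), n=len(records))


def vesicle_density(cells: list[CellRecord]) -> tuple[float, list[float]]:
    """Pooled vesicle density (total vesicles / total imaged cell volume,
    per µm³) together with the per-cell densities."""
    if not cells:
        raise ValueError("vesicle_density requires at least one cell")
    total_volume = sum(c.imaged_cell_volume for c in cells)
    if total_volume <= 0:
        raise ValueError("total imaged cell volume must be positive")
    total_n = sum(c.n_vesicles for c in cells)
    return total_n / total_volume, [c.vesicle_density for c in cells]
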