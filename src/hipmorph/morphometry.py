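"""Muscle volume, per-slice cross-sectional area and fat-infiltration profiles.

Volume is per-slice cross-sectional area (voxel count x in-plane voxel area)
summed and multiplied by slice thickness, which is exact for orthogonal
grids. Per-slice MFI is the pooled proportion of fat signal to total signal,
``sum(fat) / (sum(fat) + sum(water))``, over the labelled voxels of that
axial slice. The slice-wise MFI series is normalised onto 101 nodes over the
muscle's superior-inferior span (proximal = most superior = node 0) with a
cubic interpolating spline (linear when fewer than 4 slices are observed).

Gluteus medius is additionally analysed as three subregions (anterior,
middle, posterior) and gluteus minimus as two (anterior, posterior),
partitioned per slice into equal-extent bins along the world
anterior-posterior axis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .dixon_io import DixonVolume, LabelMask, UnknownLabelError

__all__ = [
    "MuscleProfile",
    "VolumeRecord",
    "ProfileError",
    "N_PROFILE_NODES",
    "slice_csa",
    "muscle_volume",
    "slice_mfi",
    "mfi_profile",
    "split_subregions",
    "SUBREGION_SCHEMES",
]

log = logging.getLogger(__name__)

N_PROFILE_NODES = 101

SUBREGION_SCHEMES: dict[str, tuple[str, ...]] = {
    "Gmed": ("anterior", "middle", "posterior"),
    "Gmin": ("anterior", "posterior"),
}


class ProfileError(ValueError):
    """A muscle does not support profile construction (e.g. too few slices)."""


@dataclass
class VolumeRecord:
    muscle: str
    side: str
    volume_mm3: float
    csa_mm2: np.ndarray  # indexed by axial slice over the full stack
    participant_id: str | None = None

    def __post_init__(self) -> None:
        if self.volume_mm3 < 0:
            raise ValueError("volume must be non-negative")


@dataclass
class MuscleProfile:
    """101-node fat-infiltration curve; node 0 proximal, node 100 distal."""

    muscle: str
    side: str
    nodes: np.ndarray
    n_slices_observed: int
    subregion: str | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.shape != (N_PROFILE_NODES,):
            raise ValueError(f"profile must have {N_PROFILE_NODES} nodes")
        if (self.nodes < 0).any() or (self.nodes > 1).any():
            raise ValueError("MFI values must lie in [0, 1]")


def _check_label(mask: LabelMask, label: int) -> None:
    if int(label) not in mask.label_map:
        raise UnknownLabelError(f"label {label} not in label map")


def _inplane_area(mask: LabelMask) -> float:
    ax = mask.axial_axis
    vs = mask.voxel_size
    return float(np.prod([vs[a] for a in range(3) if a != ax]))


def _axial_slice(arr: np.ndarray, axial_axis: int, index: int) -> np.ndarray:
    sl = [slice(None)] * 3
    sl[axial_axis] = index
    return arr[tuple(sl)]


def slice_csa(mask: LabelMask, label: int, slice_index: int) -> float:
    """Cross-sectional area (mm^2) of one label on one axial slice."""
    _check_label(mask, label)
    ax = mask.axial_axis
    if not 0 <= slice_index < mask.shape[ax]:
        raise IndexError(f"slice {slice_index} outside axial extent")
    count = int((_axial_slice(mask.labels, ax, slice_index) == label).sum())
    return count * _inplane_area(mask)


def muscle_volume(
    mask: LabelMask, label: int, participant_id: str | None = None
) -> VolumeRecord:
    """Muscle volume as the sum over axial slices of CSA x slice thickness."""
    _check_label(mask, label)
    ax = mask.axial_axis
    thickness = mask.voxel_size[ax]
    other = tuple(a for a in range(3) if a != ax)
    counts = (mask.labels == label).sum(axis=other)
    csa = counts * _inplane_area(mask)
    muscle, side = mask.label_map[int(label)]
    return VolumeRecord(
        muscle=muscle, side=side,
        volume_mm3=float(csa.sum() * thickness),
        csa_mm2=np.asarray(csa, dtype=float),
        participant_id=participant_id,
    )


def slice_mfi(
    dixon: DixonVolume, mask: LabelMask, label: int, slice_index: int
) -> float:
    """Pooled fat fraction sum(fat)/(sum(fat)+sum(water)) over the labelled
    voxels of one axial slice; NaN marks a missing value (no labelled voxels
    or zero total signal), never silently zero."""
    _check_label(mask, label)
    if not mask.same_grid(dixon):
        raise ValueError("mask and Dixon volume are on different grids")
    ax = mask.axial_axis
    in_label = _axial_slice(mask.labels, ax, slice_index) == label
    if not in_label.any():
        return float("nan")
    f = float(_axial_slice(dixon.fat, ax, slice_index)[in_label].sum())
    w = float(_axial_slice(dixon.water, ax, slice_index)[in_label].sum())
    if f + w == 0.0:
        return float("nan")
    return f / (f + w)


def mfi_profile(dixon: DixonVolume, mask: LabelMask, label: int) -> MuscleProfile:
    """Normalise the slice-wise MFI series of one muscle onto 101 nodes from
    proximal (0%) to distal (100%) of its observed superior-inferior span.

    Interior slices with missing MFI are bridged by the interpolant with a
    logged warning; fewer than 2 valid slices is an error.
    """
    _check_label(mask, label)
    ax = mask.axial_axis
    n_slices = mask.shape[ax]
    other = tuple(a for a in range(3) if a != ax)
    occupied = np.where((mask.labels == label).sum(axis=other) > 0)[0]
    if occupied.size == 0:
        raise ProfileError(f"label {label} is empty")

    s_coord = np.array([mask.slice_superior_coord(i) for i in occupied])
    order = np.argsort(-s_coord)  # proximal (most superior) first
    occupied, s_coord = occupied[order], s_coord[order]

    values = np.array([slice_mfi(dixon, mask, label, int(i)) for i in occupied])
    valid = ~np.isnan(values)
    if valid.sum() < 2:
        raise ProfileError(
            f"label {label}: need >= 2 slices with valid MFI, got {int(valid.sum())}"
        )
    if (~valid).any():
        log.warning(
            "label %d: %d slice(s) with missing MFI bridged by interpolation",
            label, int((~valid).sum()),
        )

    span = s_coord[0] - s_coord[-1]
    frac = (s_coord[0] - s_coord) / span if span > 0 else np.zeros_like(s_coord)
    x, y = frac[valid], values[valid]
    grid = np.linspace(0.0, 1.0, N_PROFILE_NODES)
    if x.size >= 4:
        interp = CubicSpline(x, y)
        nodes = interp(grid)
    else:
        nodes = np.interp(grid, x, y)
    nodes = np.clip(nodes, 0.0, 1.0)

    muscle, side = mask.label_map[int(label)]
    return MuscleProfile(
        muscle=muscle, side=side, nodes=nodes,
        n_slices_observed=int(valid.sum()),
    )


def split_subregions(mask: LabelMask, label: int, scheme: str | None = None) -> LabelMask:
    """Partition a Gmed (thirds) or Gmin (halves) label slice-by-slice along
    the world anterior-posterior axis into equal-extent subregions.

    The partition is exhaustive and disjoint: on every axial slice the union
    of the subregion voxel sets equals the original labelled set. The
    returned mask contains only the subregion labels (1..n, proximal naming
    anterior-first), each mapped to ``("<Muscle>_<subregion>", side)``.
    """
    _check_label(mask, label)
    muscle, side = mask.label_map[int(label)]
    scheme_name = scheme or muscle
    if scheme_name not in SUBREGION_SCHEMES:
        raise ValueError(
            f"no subregion scheme for {scheme_name!r} (only {sorted(SUBREGION_SCHEMES)})"
        )
    names = SUBREGION_SCHEMES[scheme_name]
    nseg = len(names)

    ax = mask.axial_axis
    out = np.zeros(mask.shape, dtype=np.int16)
    in_label = mask.labels == label
    ii, jj, kk = np.where(in_label)
    if ii.size:
        homog = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).astype(float)
        a_coord = (mask.affine @ homog)[1]  # world anterior coordinate
        axial_idx = (ii, jj, kk)[ax]
        for z in np.unique(axial_idx):
            on_slice = axial_idx == z
            a = a_coord[on_slice]
            amin, amax = a.min(), a.max()
            if amax > amin:
                # fraction measured from the anterior (largest +A) edge
                fa = (amax - a) / (amax - amin)
                seg = np.minimum((fa * nseg).astype(int), nseg - 1)
            else:
                seg = np.zeros(a.shape, dtype=int)
            out[ii[on_slice], jj[on_slice], kk[on_slice]] = seg + 1

    label_map = {i + 1: (f"{muscle}_{name}", side) for i, name in enumerate(names)}
    return LabelMask(labels=out, affine=mask.affine.copy(), label_map=label_map)
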