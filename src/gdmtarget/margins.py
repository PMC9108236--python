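"""Geometry deformation margin (GDM) construction and target volumes.

From the per-phase marker–target deformation vectors the workflow builds:

* the GDM — an anisotropic six-direction margin taking, per anatomical
  direction, the maximum deformation component observed across all
  motion-sampling series (negative maxima clamp to zero: the margin guards
  against underdose only, it never shrinks the target);
* ``ITV_GDM`` — the CTV expanded by the GDM (Minkowski sum with an
  axis-aligned box kernel, which guarantees every observed shifted CTV copy
  is contained);
* ``ITV_GDM-SUM`` — the union of the CTV with one translated copy per
  deformation vector (the subvolume-merging alternative, generally smaller);
* PTVs — each ITV expanded by an isotropic residual-uncertainty margin
  (default 2 mm, chosen to cover registration observer variability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    AnatomicalMargin,
    BinaryStructure,
    DeformationVector,
    _round_half_away,
    translate_structure,
)

__all__ = [
    "TargetSet",
    "gdm_margin",
    "expand_anisotropic",
    "itv_gdm_sum",
    "expand_isotropic",
    "build_target_set",
]


def gdm_margin(vectors: list[DeformationVector]) -> AnatomicalMargin:
    """Six-direction margin from deformation vectors (componentwise maxima).

    Each direction takes the largest deformation component pointing that
    way over all series; directions never observed stay at zero.
    """
    if not vectors:
        raise ValueError("gdm_margin needs at least one deformation vector")
    d = np.array([v.as_array() for v in vectors])
    pos = np.maximum(d, 0.0).max(axis=0)  # +x=L, +y=P, +z=S
    neg = np.maximum(-d, 0.0).max(axis=0)  # -x=R, -y=A, -z=I
    return AnatomicalMargin(
        left=pos[0], right=neg[0],
        posterior=pos[1], anterior=neg[1],
        superior=pos[2], inferior=neg[2],
    )


#: sub-voxel tolerance when voxelising margin extents (absorbs float dust)
EXTENT_TOL_VOX = 1e-6


def _extent_voxels(margin_mm: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Directed margin extents in whole voxels, rounded up (never clipped)."""
    return np.ceil(np.asarray(margin_mm) / spacing - EXTENT_TOL_VOX).astype(int)


def _check_room(mask: np.ndarray, low_vox: np.ndarray, high_vox: np.ndarray) -> None:
    """Error if expanding ``mask`` by the given voxel extents leaves the grid."""
    if not mask.any():
        raise ValueError("cannot expand an empty structure")
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    shape = np.asarray(mask.shape)
    if np.any(lo - low_vox < 0) or np.any(hi + high_vox > shape - 1):
        raise ValueError(
            "expansion exceeds the grid: structure bounding box "
            f"{lo.tolist()}..{hi.tolist()} with voxel extents -{low_vox.tolist()}"
            f"/+{high_vox.tolist()} leaves shape {shape.tolist()}; "
            "pad the grid before expanding"
        )


def _shift_or(acc: np.ndarray, src: np.ndarray, offset) -> None:
    """acc |= src shifted by integer voxel ``offset`` (out-of-grid dropped)."""
    slc_src, slc_dst = [], []
    for ax in range(3):
        k = int(offset[ax])
        n = src.shape[ax]
        if k >= 0:
            slc_src.append(slice(0, n - k))
            slc_dst.append(slice(k, n))
        else:
            slc_src.append(slice(-k, n))
            slc_dst.append(slice(0, n + k))
    acc[tuple(slc_dst)] |= src[tuple(slc_src)]


def expand_anisotropic(
    ctv: BinaryStructure, margin: AnatomicalMargin, kernel: str = "box"
) -> BinaryStructure:
    """CTV → ITV_GDM: Minkowski sum with the anisotropic GDM kernel.

    The default ``box`` kernel spans [−right, +left] × [−anterior,
    +posterior] × [−inferior, +superior] mm in LPS.  On the voxel grid each
    directed extent is rounded *up* to whole voxels (a 1e-6-voxel tolerance
    absorbs floating-point dust): the margin exists to guard against target
    underdose, so voxelisation must never clip it, and upward rounding also
    keeps every nearest-voxel-shifted CTV copy contained even when the
    margin estimate carries sub-voxel registration error.  The box kernel
    is separable, so the sum is realised as three 1-D dilations.

    ``kernel="ellipsoid"`` instead uses a per-octant quasi-ellipsoid (each
    octant bounded by the ellipsoid through that octant's three directed
    margins), the rounded kernel some planning systems apply.  It does not
    guarantee containment of the translated CTV copies; use it only for
    comparison studies.
    """
    if kernel not in ("box", "ellipsoid"):
        raise ValueError(f"kernel must be 'box' or 'ellipsoid', got {kernel!r}")
    low_mm, high_mm = margin.low_high_mm()
    spacing = np.asarray(ctv.grid.spacing)
    low_vox = _extent_voxels(low_mm, spacing)
    high_vox = _extent_voxels(high_mm, spacing)
    _check_room(ctv.mask, low_vox, high_vox)

    if kernel == "ellipsoid":
        acc = np.zeros_like(ctv.mask)
        for kx in range(-int(low_vox[0]), int(high_vox[0]) + 1):
            for ky in range(-int(low_vox[1]), int(high_vox[1]) + 1):
                for kz in range(-int(low_vox[2]), int(high_vox[2]) + 1):
                    rho = 0.0
                    ok = True
                    for ax, k in enumerate((kx, ky, kz)):
                        if k == 0:
                            continue
                        m = high_mm[ax] if k > 0 else low_mm[ax]
                        if m == 0:
                            ok = False
                            break
                        rho += (k * spacing[ax] / m) ** 2
                    if ok and rho <= 1.0 + 1e-12:
                        _shift_or(acc, ctv.mask, (kx, ky, kz))
        return ctv.with_mask(acc, label="ITV_GDM")

    out = ctv.mask.copy()
    for ax in range(3):
        lo, hi = int(low_vox[ax]), int(high_vox[ax])
        if lo == 0 and hi == 0:
            continue
        acc = np.zeros_like(out)
        n = out.shape[ax]
        for k in range(-lo, hi + 1):
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if k >= 0:
                src[ax], dst[ax] = slice(0, n - k), slice(k, n)
            else:
                src[ax], dst[ax] = slice(-k, n), slice(0, n + k)
            acc[tuple(dst)] |= out[tuple(src)]
        out = acc
    return ctv.with_mask(out, label="ITV_GDM")


def itv_gdm_sum(ctv: BinaryStructure, vectors: list[DeformationVector]) -> BinaryStructure:
    """CTV → ITV_GDM-SUM: union of the CTV with its per-vector translated copies.

    The untranslated (expiration) copy is always included since the CTV is
    defined on the expiration series.  A copy losing voxels off the grid is
    an error — a silently clipped target would defeat the purpose.
    """
    if ctv.is_empty():
        raise ValueError("cannot build ITV_GDM-SUM from an empty CTV")
    out = ctv.mask.copy()
    n_ctv = ctv.voxel_count
    for v in vectors:
        shifted = translate_structure(ctv, v.as_array())
        if shifted.voxel_count != n_ctv:
            raise ValueError(
                f"deformation vector {v.d} for series {v.series_id!r} pushes the "
                "CTV outside the grid; pad the grid before building ITV_GDM-SUM"
            )
        out |= shifted.mask
    return ctv.with_mask(out, label="ITV_GDM-SUM")


def expand_isotropic(itv: BinaryStructure, r_mm: float) -> BinaryStructure:
    """ITV → PTV: spherical expansion by ``r_mm`` via Euclidean distance transform.

    Keeps every voxel whose centre lies within ``r_mm`` of an ITV voxel
    centre, in physical mm (anisotropic spacing respected).
    """
    if r_mm < 0:
        raise ValueError(f"isotropic margin must be >= 0, got {r_mm}")
    if r_mm == 0:
        return itv.with_mask(itv.mask.copy(), label=f"{itv.label}+0mm")
    spacing = np.asarray(itv.grid.spacing)
    reach = np.ceil(r_mm / spacing).astype(int)
    _check_room(itv.mask, reach, reach)
    dist = ndimage.distance_transform_edt(~itv.mask, sampling=tuple(spacing))
    return itv.with_mask(dist <= r_mm, label=f"{itv.label}+{r_mm:g}mm")


@dataclass
class TargetSet:
    """All structures of one GDM workflow run, with their containment chain."""

    ctv: BinaryStructure
    itv_gdm: BinaryStructure
    itv_gdm_sum: BinaryStructure
    ptv_gdm: BinaryStructure
    ptv_gdm_sum: BinaryStructure
    margin: AnatomicalMargin
    iso_margin_mm: float

    def containment_ok(self) -> bool:
        """Voxelwise check of ctv ⊆ itv_gdm_sum ⊆ itv_gdm ⊆ ptv_gdm (and the
        SUM branch)."""
        chain = (
            (self.ctv, self.itv_gdm_sum),
            (self.itv_gdm_sum, self.itv_gdm),
            (self.itv_gdm, self.ptv_gdm),
            (self.itv_gdm_sum, self.ptv_gdm_sum),
        )
        return all(not np.any(inner.mask & ~outer.mask) for inner, outer in chain)


def build_target_set(
    ctv: BinaryStructure,
    vectors: list[DeformationVector],
    iso_margin_mm: float = 2.0,
    kernel: str = "box",
) -> TargetSet:
    """Run the full margin construction: GDM, both ITVs, both PTVs.

    The containment chain is only guaranteed (and asserted) for the
    default box kernel.
    """
    if vectors:
        margin = gdm_margin(vectors)
        itv = expand_anisotropic(ctv, margin, kernel=kernel)
        itv_sum = itv_gdm_sum(ctv, vectors)
    else:
        margin = AnatomicalMargin()
        itv = ctv.with_mask(ctv.mask.copy(), label="ITV_GDM")
        itv_sum = ctv.with_mask(ctv.mask.copy(), label="ITV_GDM-SUM")
    ptv = expand_isotropic(itv, iso_margin_mm)
    ptv.label = "PTV_GDM"
    ptv_sum = expand_isotropic(itv_sum, iso_margin_mm)
    ptv_sum.label = "PTV_GDM-SUM"
    ts = TargetSet(
        ctv=ctv,
        itv_gdm=itv,
        itv_gdm_sum=itv_sum,
        ptv_gdm=ptv,
        ptv_gdm_sum=ptv_sum,
        margin=margin,
        iso_margin_mm=float(iso_margin_mm),
    )
    if kernel == "box":
        assert ts.containment_ok(), "containment chain violated (internal error)"
    return ts
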