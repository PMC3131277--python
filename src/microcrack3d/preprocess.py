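"""Pre-processing: ring-artifact removal and intensity normalisation.

Reconstructed tomographic slices carry two slowly varying nuisances that
must be corrected before crack enhancement: concentric ring artifacts
(non-uniform detector response, fixed in the polar angle about the rotation
axis) and low-frequency global intensity variations.  Both corrections run
before the planarity filter.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume_io import GreyVolume

__all__ = ["remove_ring_artifacts", "normalize_intensity", "ConfigError"]


class ConfigError(ValueError):
    pass


def _binned_median(sorted_v, bounds, n_radii):
    med = np.full(n_radii, np.nan)
    for k in range(n_radii):
        seg = sorted_v[bounds[k] : bounds[k + 1]]
        if seg.size:
            med[k] = np.median(seg)
    return med


def _ring_profile(
    sl: np.ndarray,
    r_int: np.ndarray,
    n_radii: int,
    radial_smooth_vox: float,
    bone_threshold: float | None,
) -> np.ndarray:
    """Per-radius ring offset of one slice.

    The angular median per integer radius estimates the slice's radial
    grey profile; rings live in its high radial frequencies while genuine
    anatomy trends live in the low ones, so the ring estimate is the
    median profile minus its radial Gaussian low-pass.  Where possible the
    median is taken over sub-threshold (marrow/pore) pixels only, so that
    trabeculae crossing a radius band do not masquerade as rings; radii
    with too little marrow coverage fall back to the all-pixel median.
    """
    flat = sl.ravel()
    rr = r_int.ravel()

    def profile(select):
        v = flat[select]
        r = rr[select]
        order = np.argsort(r, kind="stable")
        bounds = np.searchsorted(r[order], np.arange(n_radii + 1))
        med = _binned_median(v[order], bounds, n_radii)
        counts = np.diff(bounds)
        return med, counts

    def highpass(med):
        if np.isnan(med).all():
            return np.zeros(n_radii)
        valid = ~np.isnan(med)
        filled = np.interp(np.arange(n_radii), np.nonzero(valid)[0], med[valid])
        low = ndimage.gaussian_filter1d(filled, radial_smooth_vox, mode="nearest")
        return filled - low

    everything = np.ones(flat.size, dtype=bool)
    med_all, n_all = profile(everything)
    ring = highpass(med_all)
    if bone_threshold is not None:
        # Per-phase profiles: a level-consistent profile per phase keeps
        # bone/marrow steps out of the high-pass, so trabeculae crossing a
        # radius band cannot masquerade as rings.
        marrow = flat < bone_threshold
        med_m, n_m = profile(marrow)
        med_b, n_b = profile(~marrow)
        ring_m = highpass(med_m)
        ring_b = highpass(med_b)
        enough_m = n_m >= np.maximum(16, 0.25 * n_all)
        enough_b = n_b >= np.maximum(16, 0.25 * n_all)
        ring = np.where(enough_m, ring_m, np.where(enough_b, ring_b, ring))
    # The innermost radii hold too few pixels for a stable median.
    ring[:4] = 0.0
    return ring


def remove_ring_artifacts(
    vol: GreyVolume,
    center_xy: tuple[float, float] | None = None,
    angular_bins: int | None = None,
    radial_smooth_um: float = 28.0,
) -> GreyVolume:
    """Subtract the concentric ring pattern from every slice.

    Per slice, pixels are binned by integer radius about the rotation-axis
    centre (default: the slice centre); the ring offset is the high-radial-
    frequency part of the angular median profile and is subtracted at each
    pixel's (continuous) radius.  The slice mean is preserved.  Constant
    slices are returned unchanged.

    ``angular_bins`` is accepted for API compatibility; the median is taken
    over *all* pixels at a radius, which is the dense limit of angular
    binning.
    """
    data = np.asarray(vol.data, dtype=np.float32)
    nz, ny, nx = data.shape
    if center_xy is None:
        center_xy = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    cx, cy = center_xy
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(xx - cx, yy - cy)
    r_int = np.rint(r).astype(np.int32)
    n_radii = int(r_int.max()) + 1
    smooth_vox = max(radial_smooth_um / vol.voxel_size_um, 1.0)

    # A global bone level (when the histogram supports one) lets the ring
    # estimator work per phase.  Only accept the split when the two phases
    # are well separated relative to their internal spread — otherwise the
    # "phases" are just the bright/dark halves of the ring pattern itself.
    try:
        from .segmentation import segment_bone

        _, bone_threshold = segment_bone(data, "auto")
        lo = data[data < bone_threshold]
        hi = data[data >= bone_threshold]
        spread = max(
            np.median(np.abs(lo - np.median(lo))),
            np.median(np.abs(hi - np.median(hi))),
            1e-9,
        )
        if (hi.mean() - lo.mean()) < 4.0 * 1.4826 * spread:
            bone_threshold = None
    except Exception:
        bone_threshold = None

    out = np.empty_like(data)
    for z in range(nz):
        sl = data[z]
        if np.ptp(sl) == 0:
            out[z] = sl
            continue
        # Estimate-and-subtract a few times: the profile estimator is not a
        # projection (interpolation leaves a small radially coherent
        # residue), so iterating makes the correction idempotent.
        corrected = sl
        for _ in range(3):
            ring = _ring_profile(corrected, r_int, n_radii, smooth_vox, bone_threshold)
            correction = np.interp(r.ravel(), np.arange(n_radii), ring).reshape(ny, nx)
            corrected = corrected - correction
        corrected += sl.mean() - corrected.mean()
        out[z] = corrected
    return GreyVolume(out, vol.voxel_size_um, vol.origin_um)


def normalize_intensity(
    vol: GreyVolume,
    window_um: float = 200.0,
    mode: str = "subtract",
    bone_mask: np.ndarray | None = None,
) -> GreyVolume:
    """Remove low-frequency intensity variations.

    A bias field is estimated by heavy Gaussian smoothing (sigma =
    ``window_um``); when a bone mask is given, the field is estimated from
    bone-phase voxels only (normalised convolution), so marrow regions do
    not drag it down.  ``mode="subtract"`` removes the zero-mean part of the
    field; ``mode="divide"`` divides by the field rescaled to unit mean.
    The global mean is preserved.
    """
    sigma_vox = window_um / vol.voxel_size_um
    if sigma_vox < 3:
        raise ConfigError(
            f"normalisation window {window_um} um is under 3 voxels at "
            f"{vol.voxel_size_um} um/voxel"
        )
    data = np.asarray(vol.data, dtype=np.float32)
    if np.ptp(data) == 0:
        return GreyVolume(data.copy(), vol.voxel_size_um, vol.origin_um)
    if bone_mask is not None:
        m = np.asarray(bone_mask, dtype=np.float32)
        num = ndimage.gaussian_filter(data * m, sigma_vox, mode="nearest")
        den = ndimage.gaussian_filter(m, sigma_vox, mode="nearest")
        field = np.where(den > 1e-6, num / np.maximum(den, 1e-6), data.mean())
    else:
        field = ndimage.gaussian_filter(data, sigma_vox, mode="nearest")
    if mode == "subtract":
        out = data - (field - field.mean())
    elif mode == "divide":
        scale = field / field.mean()
        out = data / np.maximum(scale, 1e-3)
        out *= data.mean() / out.mean()
    else:
        raise ConfigError(f"unknown normalisation mode {mode!r}")
    return GreyVolume(out.astype(np.float32), vol.voxel_size_um, vol.origin_um)
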