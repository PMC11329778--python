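"""Collagen fiber detection, orientation statistics and coverage analysis.

The pipeline mirrors the classic SHG (second-harmonic generation) workflow
for fibrillar collagen: maximum-intensity projection of a shallow z-range,
Hessian-based ridge ("tubeness") enhancement of bright curvilinear
structures, automatic thresholding into a fiber mask, a local-gradient
orientation histogram over the masked pixels, and the Shannon entropy H' of
that orientation distribution.  Higher H' means a more disordered
("de-tensioned") fiber field.  A separate coverage analysis thresholds the
image and counts connected particles above a minimum calibrated area,
returning the collagen-covered area fraction.

Conventions: pixel indices are 0-based row-major; orientations are axial
angles in degrees on the half-open interval [-90, +90) with 0 deg along the
image x-axis and positive angles counter-clockwise (rows are treated as a
downward y-axis, so the vertical gradient component is negated before
computing angles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask

__all__ = [
    "ImageStack",
    "RidgeResponse",
    "FiberMask",
    "OrientationDistribution",
    "EntropyResult",
    "CoverageResult",
    "FiberAnalysisConfig",
    "FiberAnalysisResult",
    "max_intensity_projection",
    "tubeness_filter",
    "isodata_threshold",
    "segment_fibers",
    "orientation_histogram",
    "orientation_entropy",
    "coverage_fraction",
    "analyze_fiber_image",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageStack:
    """Calibrated grayscale image data, 2D ``(y, x)`` or 3D ``(y, x, z)``.

    Parameters
    ----------
    voxels
        Non-negative intensity array.
    pixel_size_um
        Lateral calibration, micrometres per pixel (same for x and y).
    z_step_um
        Micrometres per slice; required for 3D stacks, ``None`` for 2D.
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_step_um: float | None = None

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        object.__setattr__(self, "voxels", vox)
        if vox.ndim not in (2, 3):
            raise ValueError("voxels must be 2D (y,x) or 3D (y,x,z)")
        if vox.shape[0] < 16 or vox.shape[1] < 16:
            raise ValueError("image must be at least 16x16 pixels")
        if np.any(vox < 0):
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if vox.ndim == 3:
            if self.z_step_um is None or not self.z_step_um > 0:
                raise ValueError("3D stacks require z_step_um > 0")

    @property
    def is_3d(self) -> bool:
        return self.voxels.ndim == 3

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2] if self.is_3d else 1


@dataclass(frozen=True)
class RidgeResponse:
    """Per-pixel bright-ridge strength from the Hessian tubeness filter."""

    values: np.ndarray
    scale_um: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2:
            raise ValueError("ridge response must be 2D")
        if np.any(vals < 0):
            raise ValueError("ridge response must be non-negative")


@dataclass(frozen=True)
class FiberMask:
    """Binary fiber mask plus the provenance of the threshold that made it."""

    pixels: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("mask must be 2D")


@dataclass(frozen=True)
class OrientationDistribution:
    """Normalized axial orientation histogram over [-90, +90) degrees."""

    bin_edges_deg: np.ndarray
    p: np.ndarray
    weight_total: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_deg, dtype=np.float64)
        p = np.asarray(self.p, dtype=np.float64)
        object.__setattr__(self, "bin_edges_deg", edges)
        object.__setattr__(self, "p", p)
        if p.size < 2:
            raise ValueError("need at least 2 orientation bins")
        if edges.size != p.size + 1:
            raise ValueError("bin_edges_deg must have len(p)+1 entries")
        widths = np.diff(edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0]):
            raise ValueError("bins must be increasing and equal-width")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.p.size

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])


@dataclass(frozen=True)
class EntropyResult:
    """Shannon orientation entropy H' in nats, with the bin count used."""

    H_nats: float
    n_bins: int


@dataclass(frozen=True)
class CoverageResult:
    """Collagen-covered area fraction after minimum-particle-size filtering."""

    fraction: float
    n_particles: int
    min_particle_area_um2: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def max_intensity_projection(stack: ImageStack, depth_um: float) -> np.ndarray:
    """Maximum-intensity z-projection over the first ``depth_um`` of a stack.

    The number of projected slices is ``round(depth_um / z_step_um)``,
    at least 1.  Used to flatten the superficial endometrial collagen layer
    (13 um in the reference workflow) before 2D fiber analysis.
    """
    if not stack.is_3d:
        raise ValueError("projection requires a stack")
    if not depth_um > 0:
        raise ValueError("depth_um must be positive")
    assert stack.z_step_um is not None
    total_depth = stack.n_slices * stack.z_step_um
    if depth_um > total_depth + 1e-9:
        raise ValueError(
            f"depth_um={depth_um} exceeds stack depth {total_depth}"
        )
    n = max(1, int(round(depth_um / stack.z_step_um)))
    n = min(n, stack.n_slices)
    return stack.voxels[:, :, :n].max(axis=2)


def _hessian_eigen_min(smoothed: np.ndarray) -> np.ndarray:
    """More-negative eigenvalue of the 2x2 Hessian of a smoothed image.

    Second derivatives are central finite differences (one-sided at the
    borders), identical stencils to :func:`numpy.gradient`.
    """
    gy, gx = np.gradient(smoothed)
    gyy, gyx = np.gradient(gy)
    gxy_, gxx = np.gradient(gx)
    gxy = 0.5 * (gyx + gxy_)
    # closed-form eigenvalues of [[gyy, gxy], [gxy, gxx]]
    half_trace = 0.5 * (gxx + gyy)
    root = np.sqrt((0.5 * (gxx - gyy)) ** 2 + gxy**2)
    return half_trace - root


def tubeness_filter(
    image: np.ndarray, scale_um: float, pixel_size_um: float
) -> RidgeResponse:
    """Single-scale Hessian ridge enhancement for bright curvilinear fibers.

    The image is Gaussian-smoothed at sigma = ``scale_um / pixel_size_um``
    pixels; per pixel the 2x2 Hessian is formed and, with lambda2 its
    more-negative eigenvalue, the response is ``max(0, -lambda2)`` —
    the bright-ridge convention (SHG collagen is bright on dark).
    """
    if not scale_um > 0:
        raise ValueError("scale_um must be positive")
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("tubeness_filter expects a 2D image")
    sigma_px = scale_um / pixel_size_um
    smoothed = ndimage.gaussian_filter(img, sigma_px, mode="nearest")
    lam2 = _hessian_eigen_min(smoothed)
    response = np.maximum(0.0, -lam2)
    return RidgeResponse(values=response, scale_um=scale_um)


def isodata_threshold(values: np.ndarray, max_iter: int = 500) -> float:
    """IsoData (iterative intermeans) threshold on raw values.

    Iterates ``t <- (mean(values < t) + mean(values >= t)) / 2`` from the
    global mean until a fixed point.  This is the "Default" auto-threshold
    of common image-analysis tools, applied to the continuous values rather
    than a binned histogram.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = v.min(), v.max()
    if lo == hi:
        raise ValueError("constant input has no isodata threshold")
    t = v.mean()
    for _ in range(max_iter):
        low = v[v < t]
        high = v[v >= t]
        if low.size == 0 or high.size == 0:
            break
        t_new = 0.5 * (low.mean() + high.mean())
        if t_new == t:
            break
        t = t_new
    return float(t)


def segment_fibers(
    response: RidgeResponse,
    method: Literal["isodata", "fixed"] = "isodata",
    fixed_threshold: float | None = None,
) -> FiberMask:
    """Threshold a ridge response into a binary fiber mask.

    ``isodata`` uses the iterative-intermeans fixed point; ``fixed``
    requires an explicit threshold.  Pixels with response >= threshold are
    foreground.  An all-zero response with ``isodata`` yields an empty mask
    with a warning (no fibers present).
    """
    vals = response.values
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method 'fixed' requires fixed_threshold")
        thr = float(fixed_threshold)
    elif method == "isodata":
        if vals.max() == vals.min():
            warnings.warn("ridge response is constant: no fibers detected")
            return FiberMask(
                pixels=np.zeros(vals.shape, dtype=bool),
                provenance={"method": "isodata", "threshold": None},
            )
        thr = isodata_threshold(vals)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return FiberMask(
        pixels=vals >= thr,
        provenance={"method": method, "threshold": thr},
    )


def _fold_axial_deg(angles_deg: np.ndarray) -> np.ndarray:
    """Fold angles into the axial interval [-90, +90) degrees (mod 180)."""
    return (np.asarray(angles_deg) + 90.0) % 180.0 - 90.0


def orientation_histogram(
    image: np.ndarray,
    mask: FiberMask,
    n_bins: int = 180,
    smoothing_scale_um: float = 1.0,
    pixel_size_um: float = 1.0,
    exclude_border: bool = True,
) -> OrientationDistribution:
    """Local-gradient orientation histogram over masked fiber pixels.

    Gradients are Gaussian-derivative filters at the smoothing scale; the
    local fiber orientation is the gradient direction rotated by 90 deg and
    folded into the axial interval [-90, +90).  Each masked pixel
    contributes its squared gradient magnitude as weight, so strong clean
    edges dominate and flat regions contribute nothing.  By default a
    border margin of 3 sigma, where the derivative filters are truncated
    by the frame, is excluded.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    img = np.asarray(image, dtype=np.float64)
    if mask.pixels.shape != img.shape:
        raise ValueError("mask shape must match image shape")
    sigma_px = smoothing_scale_um / pixel_size_um
    m = mask.pixels
    if exclude_border:
        # drop pixels whose Gaussian-derivative support is truncated by the
        # frame: their gradients are boundary artifacts, not fiber signal
        margin = int(np.ceil(3.0 * sigma_px)) + 1
        if 2 * margin < min(img.shape):
            m = m.copy()
            m[:margin, :] = False
            m[-margin:, :] = False
            m[:, :margin] = False
            m[:, -margin:] = False
    if not m.any():
        raise ValueError("no oriented structure (empty mask)")
    gx = ndimage.gaussian_filter(img, sigma_px, order=(0, 1), mode="nearest")
    gy = ndimage.gaussian_filter(img, sigma_px, order=(1, 0), mode="nearest")
    # rows grow downward: negate the row-derivative for a CCW-positive angle
    gy_math = -gy
    w = gx**2 + gy**2
    w_masked = np.where(m, w, 0.0)
    total = w_masked.sum()
    if total <= 0:
        raise ValueError("no oriented structure (all-zero gradients)")
    grad_dir_deg = np.degrees(np.arctan2(gy_math, gx))
    theta = _fold_axial_deg(grad_dir_deg + 90.0)
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    sel = m & (w > 0)
    counts, _ = np.histogram(theta[sel], bins=edges, weights=w[sel])
    return OrientationDistribution(
        bin_edges_deg=edges, p=counts / counts.sum(), weight_total=float(total)
    )


def fourier_orientation_histogram(
    image: np.ndarray,
    n_bins: int = 180,
) -> OrientationDistribution:
    """Fourier-sector orientation histogram (alternative estimator).

    Sums the windowed power spectrum in angular sectors; spectral energy at
    angle phi corresponds to stripes oriented at phi + 90 deg in the image.
    Provided as a mask-free alternative to the local-gradient method.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    win = np.outer(np.hanning(h), np.hanning(w))
    f = np.fft.fftshift(np.fft.fft2((img - img.mean()) * win))
    power = np.abs(f) ** 2
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h // 2, w // 2
    fy = -(yy - cy)  # spatial-frequency y axis points up
    fx = xx - cx
    r2 = fx**2 + fy**2
    valid = (r2 > 4) & (r2 < (min(h, w) // 2) ** 2)
    phi = np.degrees(np.arctan2(fy, fx))
    theta = _fold_axial_deg(phi + 90.0)
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    counts, _ = np.histogram(theta[valid], bins=edges, weights=power[valid])
    if counts.sum() <= 0:
        raise ValueError("no oriented structure (flat spectrum)")
    return OrientationDistribution(
        bin_edges_deg=edges,
        p=counts / counts.sum(),
        weight_total=float(power[valid].sum()),
    )


def orientation_entropy(dist: OrientationDistribution) -> EntropyResult:
    """Shannon index H' = -sum_i p_i ln p_i of an orientation distribution.

    Natural logarithm (nats); the empty-bin convention 0 ln 0 = 0 applies.
    H' ranges from 0 (all mass in one bin) to ln(n_bins) (uniform).
    """
    p = dist.p[dist.p > 0]
    h = float(-(p * np.log(p)).sum())
    # guard against tiny negative round-off on near-degenerate distributions
    return EntropyResult(H_nats=max(0.0, h), n_bins=dist.n_bins)


def coverage_fraction(
    image: np.ndarray,
    mask_or_threshold: FiberMask | float | Literal["isodata"] = "isodata",
    min_particle_area_um2: float = 0.172,
    pixel_size_um: float = 1.0,
    roi: Sequence[tuple[float, float]] | None = None,
) -> CoverageResult:
    """Collagen-covered area fraction via particle analysis.

    Thresholds the image (unless a mask is given), restricts to an optional
    polygonal ROI, labels 8-connected components and discards particles
    smaller than ``min_particle_area_um2`` (the 0.172-to-infinity particle
    filter of the reference workflow, interpreted in um^2).  Returns the
    retained area divided by the ROI (or whole-image) area.

    ``roi`` is a polygon as (x, y) pixel-coordinate vertices.
    """
    if min_particle_area_um2 < 0:
        raise ValueError("min_particle_area_um2 must be >= 0")
    img = np.asarray(image, dtype=np.float64)
    if isinstance(mask_or_threshold, FiberMask):
        binary = mask_or_threshold.pixels
        if binary.shape != img.shape:
            raise ValueError("mask shape must match image shape")
    elif mask_or_threshold == "isodata":
        binary = img >= isodata_threshold(img)
    else:
        binary = img >= float(mask_or_threshold)

    if roi is not None:
        verts = np.asarray(roi, dtype=np.float64)
        x, y = verts[:, 0], verts[:, 1]
        shoelace = 0.5 * abs(
            np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
        )
        if shoelace == 0:
            raise ValueError("ROI polygon has zero area")
        # polygon2mask expects (row, col) = (y, x)
        roi_mask = polygon2mask(img.shape, verts[:, ::-1])
        if not roi_mask.any():
            raise ValueError("ROI polygon has zero area")
    else:
        roi_mask = np.ones(img.shape, dtype=bool)

    binary = binary & roi_mask
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    labels, n_comp = ndimage.label(binary, structure=structure)
    px_area_um2 = pixel_size_um**2
    kept_px = 0
    kept_n = 0
    if n_comp:
        areas = np.bincount(labels.ravel())[1:]
        keep = areas * px_area_um2 >= min_particle_area_um2
        kept_n = int(keep.sum())
        kept_px = int(areas[keep].sum())
    return CoverageResult(
        fraction=kept_px / int(roi_mask.sum()),
        n_particles=kept_n,
        min_particle_area_um2=min_particle_area_um2,
    )


# ---------------------------------------------------------------------------
# Composed pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FiberAnalysisConfig:
    """Parameters for the full entropy + coverage fiber analysis."""

    pixel_size_um: float = 0.5
    projection_depth_um: float = 13.0
    tubeness_scale_um: float = 1.0
    gradient_scale_um: float = 1.0
    n_bins: int = 180
    circular_fov: bool = False
    orientation_method: Literal["gradient", "fourier"] = "gradient"
    orientation_mask: Literal["tubeness_positive", "isodata"] = "tubeness_positive"
    threshold_method: Literal["isodata", "fixed"] = "isodata"
    fixed_threshold: float | None = None
    min_particle_area_um2: float = 0.172

    def as_dict(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "projection_depth_um": self.projection_depth_um,
            "tubeness_scale_um": self.tubeness_scale_um,
            "gradient_scale_um": self.gradient_scale_um,
            "n_bins": self.n_bins,
            "circular_fov": self.circular_fov,
            "orientation_method": self.orientation_method,
            "orientation_mask": self.orientation_mask,
            "threshold_method": self.threshold_method,
            "fixed_threshold": self.fixed_threshold,
            "min_particle_area_um2": self.min_particle_area_um2,
        }


@dataclass(frozen=True)
class FiberAnalysisResult:
    """All artifacts of one fiber-image analysis, kept for audit."""

    projected: np.ndarray
    ridge: RidgeResponse
    mask: FiberMask
    distribution: OrientationDistribution
    entropy: EntropyResult
    coverage: CoverageResult
    config: FiberAnalysisConfig


def analyze_fiber_image(
    stack: ImageStack, config: FiberAnalysisConfig | None = None
) -> FiberAnalysisResult:
    """Full deterministic fiber pipeline on one image or stack.

    3D stacks are max-projected over ``projection_depth_um`` first; then
    tubeness -> isodata mask -> orientation histogram -> entropy.  Coverage
    is computed independently from an isodata threshold of the projected
    image, matching the density-analysis recipe.
    """
    cfg = config or FiberAnalysisConfig(pixel_size_um=stack.pixel_size_um)
    img = (
        max_intensity_projection(stack, cfg.projection_depth_um)
        if stack.is_3d
        else stack.voxels
    )
    ridge = tubeness_filter(img, cfg.tubeness_scale_um, cfg.pixel_size_um)
    if cfg.orientation_mask == "tubeness_positive":
        # permissive mask for the orientation histogram: every pixel the
        # ridge filter highlights at all.  A hard auto-threshold keeps the
        # brightest (often overlapping) ridges and drops the flanks of
        # isolated fibers, which skews the orientation distribution; the
        # |grad|^2 weighting already suppresses background pixels.
        floor = 1e-4 * ridge.values.max()
        mask = FiberMask(
            pixels=ridge.values > floor,
            provenance={"method": "tubeness_positive", "threshold": floor},
        )
    else:
        mask = segment_fibers(
            ridge,
            method=cfg.threshold_method,
            fixed_threshold=cfg.fixed_threshold,
        )
    if cfg.circular_fov:
        # restrict orientation analysis to the inscribed disc: chords of a
        # square frame over-represent frame-aligned fibers (longer chords),
        # a disc is isotropic and removes that orientation bias
        h_, w_ = mask.pixels.shape
        yy, xx = np.ogrid[0:h_, 0:w_]
        r = min(h_, w_) / 2.0
        disc = (yy - (h_ - 1) / 2.0) ** 2 + (xx - (w_ - 1) / 2.0) ** 2 <= r**2
        mask = FiberMask(
            pixels=mask.pixels & disc,
            provenance={**mask.provenance, "circular_fov": True},
        )
    if cfg.orientation_method == "fourier":
        dist = fourier_orientation_histogram(img, n_bins=cfg.n_bins)
    else:
        dist = orientation_histogram(
            img,
            mask,
            n_bins=cfg.n_bins,
            smoothing_scale_um=cfg.gradient_scale_um,
            pixel_size_um=cfg.pixel_size_um,
        )
    ent = orientation_entropy(dist)
    cov = coverage_fraction(
        img,
        "isodata",
        min_particle_area_um2=cfg.min_particle_area_um2,
        pixel_size_um=cfg.pixel_size_um,
    )
    return FiberAnalysisResult(
        projected=img,
        ridge=ridge,
        mask=mask,
        distribution=dist,
        entropy=ent,
        coverage=cov,
        config=cfg,
    )
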