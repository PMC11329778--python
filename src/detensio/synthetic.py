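"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators, each deterministic under a fixed seed and each emitting
its ground truth alongside the data:

* :func:`render_fiber_image` — fiber phantoms emulating SHG micrographs:
  bright anti-aliased strokes on a dark background, axial orientations
  drawn from a von Mises distribution on doubled angles (the standard
  axial construction, since fiber orientation is defined mod 180 deg),
  optional sinusoidal waviness, Gaussian PSF blur and additive/Poisson
  noise.  Low concentration kappa gives loosely packed, disordered fields;
  high kappa gives well-aligned ones.

* :func:`simulate_kinetics` — two-parameter linear contrast kinetics
  C_t = C_blood * (fBV + PS * t) + noise.

* :func:`simulate_proteome` — spiked log-normal protein intensity tables
  (null proteins at log2fc 0, substrates shifted by a known effect) plus
  an in-silico tryptic digest of a parent protein with planted
  semi-tryptic cleavages after Leu/Ile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .degradomics import DigestRule, IntensityTable, cleavage_sites, digest
from .fiber import ImageStack, OrientationDistribution
from .perfusion import EnhancementSeries

__all__ = [
    "FiberFieldSpec",
    "FiberGroundTruth",
    "KineticsSpec",
    "ProteomeSpec",
    "render_fiber_image",
    "simulate_kinetics",
    "simulate_proteome",
    "sample_axial_vonmises_deg",
    "bin_axial_angles",
    "axial_vonmises_bin_probs",
    "binned_entropy_nats",
]


# ---------------------------------------------------------------------------
# Fiber phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FiberFieldSpec:
    """Parameters of a synthetic SHG-like fiber field.

    Defaults describe a realistic tiled two-photon field of view:
    1440 x 1440 px at 0.5 um/px (720 um square), 210 fibers spanning the
    frame, 1 um stroke width, 0.4 um PSF blur, noise off.
    ``fiber_length_um=None`` draws fibers as chords through the whole
    frame (endpoints outside the field, as for long collagen fibers); a
    finite length gives short segments.  ``kappa=0`` means uniform axial
    orientations.
    """

    image_size_px: tuple[int, int] = (1440, 1440)
    pixel_size_um: float = 0.5
    n_fibers: int = 210
    mean_angle_deg: float = 0.0
    kappa: float = 8.0
    fiber_length_um: float | None = None
    waviness_amp_um: float = 0.0
    waviness_period_um: float = 40.0
    fiber_width_um: float = 1.0
    psf_sigma_um: float = 0.4
    noise_sigma: float = 0.0
    poisson_scale: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        for name in ("pixel_size_um", "fiber_width_um", "waviness_period_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.fiber_length_um is not None and not self.fiber_length_um > 0:
            raise ValueError("fiber_length_um must be positive")
        if self.n_fibers < 1:
            raise ValueError("need at least one fiber")


@dataclass(frozen=True)
class FiberGroundTruth:
    """Exact generator truth for one rendered fiber field."""

    angles_deg: np.ndarray
    distribution: OrientationDistribution
    entropy_nats: float
    mask: np.ndarray


def sample_axial_vonmises_deg(
    rng: np.random.Generator,
    n: int,
    mean_angle_deg: float,
    kappa: float,
) -> np.ndarray:
    """Axial (mod 180 deg) von Mises angles via the doubled-angle trick."""
    if kappa == 0:
        theta = rng.uniform(-90.0, 90.0, size=n)
    else:
        doubled = rng.vonmises(np.radians(2.0 * mean_angle_deg), kappa, size=n)
        theta = np.degrees(doubled) / 2.0
    return (theta + 90.0) % 180.0 - 90.0


def bin_axial_angles(
    angles_deg: np.ndarray, n_bins: int = 180
) -> OrientationDistribution:
    """Exact binned histogram of sampled axial angles, normalized."""
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    counts, _ = np.histogram(angles_deg, bins=edges)
    n = counts.sum()
    if n == 0:
        raise ValueError("no angles to bin")
    return OrientationDistribution(
        bin_edges_deg=edges, p=counts / n, weight_total=float(n)
    )


def binned_entropy_nats(dist: OrientationDistribution) -> float:
    p = dist.p[dist.p > 0]
    return float(-(p * np.log(p)).sum())


def axial_vonmises_bin_probs(
    kappa: float, mean_angle_deg: float = 0.0, n_bins: int = 180
) -> np.ndarray:
    """Analytic bin probabilities of the axial von Mises distribution.

    Integrates the doubled-angle von Mises density over each axial bin by
    a fine trapezoidal rule; used to check that the generator's target
    entropy decreases with concentration kappa.
    """
    edges = np.radians(np.linspace(-90.0, 90.0, n_bins + 1))
    mu2 = np.radians(2.0 * mean_angle_deg)
    if kappa == 0:
        return np.full(n_bins, 1.0 / n_bins)

    def pdf_theta(theta: np.ndarray) -> np.ndarray:
        # density of theta = (wrapped von Mises on 2*theta) / 2
        return np.exp(kappa * np.cos(2.0 * theta - mu2)) / (
            np.pi * special.i0(kappa)
        )

    probs = np.empty(n_bins)
    for i in range(n_bins):
        grid = np.linspace(edges[i], edges[i + 1], 64)
        probs[i] = np.trapezoid(pdf_theta(grid), grid)
    return probs / probs.sum()


def _deposit_bilinear(
    canvas: np.ndarray, xs: np.ndarray, ys: np.ndarray, w: float
) -> None:
    """Accumulate unit-weight sub-pixel points onto a canvas bilinearly."""
    h, wd = canvas.shape
    inside = (xs >= 0) & (xs < wd - 1) & (ys >= 0) & (ys < h - 1)
    xs, ys = xs[inside], ys[inside]
    x0 = np.floor(xs).astype(np.intp)
    y0 = np.floor(ys).astype(np.intp)
    fx = xs - x0
    fy = ys - y0
    np.add.at(canvas, (y0, x0), w * (1 - fx) * (1 - fy))
    np.add.at(canvas, (y0, x0 + 1), w * fx * (1 - fy))
    np.add.at(canvas, (y0 + 1, x0), w * (1 - fx) * fy)
    np.add.at(canvas, (y0 + 1, x0 + 1), w * fx * fy)


def render_fiber_image(
    spec: FiberFieldSpec, truth_n_bins: int = 180
) -> tuple[ImageStack, FiberGroundTruth]:
    """Render a fiber field and return it with its exact ground truth.

    Fibers are drawn as sub-pixel-sampled strokes along straight (or
    sinusoidally perturbed) centerlines, blurred by the stroke width and
    PSF, normalized to unit peak, then degraded by the configured noise.
    The ground-truth orientation distribution is the exact binned
    histogram of the sampled fiber angles.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    ps = spec.pixel_size_um
    canvas = np.zeros((h, w), dtype=np.float64)

    angles = sample_axial_vonmises_deg(
        rng, spec.n_fibers, spec.mean_angle_deg, spec.kappa
    )
    if spec.fiber_length_um is None:
        half_len_px = 0.5 * float(np.hypot(h, w)) + 2.0
    else:
        half_len_px = 0.5 * spec.fiber_length_um / ps
    step_px = 0.35
    t = np.arange(-half_len_px, half_len_px + step_px, step_px)
    amp_px = spec.waviness_amp_um / ps
    period_px = spec.waviness_period_um / ps

    for theta in angles:
        rad = np.radians(theta)
        dx, dy = np.cos(rad), -np.sin(rad)  # row axis points down
        nx, ny = -dy, dx
        for _attempt in range(50):
            cx = rng.uniform(0, w - 1)
            cy = rng.uniform(0, h - 1)
            if amp_px > 0:
                phase = rng.uniform(0, 2 * np.pi)
                off = amp_px * np.sin(2 * np.pi * t / period_px + phase)
            else:
                off = 0.0
            xs = cx + t * dx + off * nx
            ys = cy + t * dy + off * ny
            in_frame = (xs >= 0) & (xs < w - 1) & (ys >= 0) & (ys < h - 1)
            if in_frame.any():
                _deposit_bilinear(canvas, xs, ys, step_px)
                break
        else:
            raise RuntimeError("could not place fiber inside the frame")

    sigma_px = float(
        np.hypot(0.5 * spec.fiber_width_um / ps, spec.psf_sigma_um / ps)
    )
    clean = ndimage.gaussian_filter(canvas, sigma_px, mode="nearest")
    peak = clean.max()
    if peak > 0:
        clean = clean / peak
    mask = clean > 0.05

    image = clean
    if spec.poisson_scale is not None:
        image = rng.poisson(image * spec.poisson_scale) / spec.poisson_scale
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, None)

    dist = bin_axial_angles(angles, n_bins=truth_n_bins)
    truth = FiberGroundTruth(
        angles_deg=angles,
        distribution=dist,
        entropy_nats=binned_entropy_nats(dist),
        mask=mask,
    )
    return ImageStack(voxels=image, pixel_size_um=ps), truth


# ---------------------------------------------------------------------------
# Contrast kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticsSpec:
    """Linear enhancement kinetics C_t = C_blood * (fBV + PS * t) + noise.

    Defaults: fBV 0.05, PS 0.003 /min (mid-range physiological values for
    implantation-site imaging), one sample per minute over the 15-min
    fitting window, noise off.
    """

    fbv_true: float = 0.05
    ps_true_per_min: float = 0.003
    c_blood: float = 1.0
    t_samples_min: tuple[float, ...] = tuple(float(t) for t in range(1, 16))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_blood > 0:
            raise ValueError("c_blood must be positive")
        t = np.asarray(self.t_samples_min)
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_samples_min must be strictly increasing")


def simulate_kinetics(
    spec: KineticsSpec,
) -> tuple[EnhancementSeries, tuple[float, float]]:
    """Simulate one enhancement series; returns it with (fBV, PS) truth."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.t_samples_min, dtype=np.float64)
    c_t = spec.c_blood * (spec.fbv_true + spec.ps_true_per_min * t)
    if spec.noise_sd > 0:
        c_t = c_t + rng.normal(0.0, spec.noise_sd, size=t.size)
    series = EnhancementSeries(t_min=t, c_t=c_t, c_blood=spec.c_blood)
    return series, (spec.fbv_true, spec.ps_true_per_min)


# ---------------------------------------------------------------------------
# Spiked proteome with in-silico digest
# ---------------------------------------------------------------------------

#: Rough vertebrate amino-acid frequencies for random parent proteins.
_AA_FREQ = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.053, "C": 0.022,
    "Q": 0.041, "E": 0.062, "G": 0.074, "H": 0.026, "I": 0.053,
    "L": 0.091, "K": 0.058, "M": 0.023, "F": 0.039, "P": 0.050,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.063,
}


@dataclass(frozen=True)
class ProteomeSpec:
    """Spiked proteome-table parameters.

    Defaults emulate a label-free ex vivo supernatant comparison: 200
    proteins, 10 true substrates shifted by log2fc = 1 (2-fold release),
    6 replicates per group, log2-scale replicate noise SD 0.3, and 3
    planted Leu/Ile cleavage events in the digested parent protein.
    """

    n_proteins: int = 200
    n_true_substrates: int = 10
    true_log2fc: float = 1.0
    n_per_group: int = 6
    lognormal_sd: float = 0.3
    proteins_fasta: tuple[tuple[str, str], ...] | None = None
    n_planted_cleavages: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_substrates > self.n_proteins:
            raise ValueError("n_true_substrates must be <= n_proteins")
        if self.n_per_group < 2:
            raise ValueError("need >= 2 replicates per group")
        if not self.lognormal_sd >= 0:
            raise ValueError("lognormal_sd must be >= 0")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aas = list(_AA_FREQ)
    probs = np.array([_AA_FREQ[a] for a in aas])
    probs = probs / probs.sum()
    return "".join(rng.choice(aas, size=length, p=probs))


def _plantable_sites(
    protein_seq: str, rule: DigestRule
) -> list[tuple[int, int, int]]:
    """(pep_start, pep_end, cut_after_pos) candidates for L/I cleavages.

    Candidates are internal Leu/Ile positions of fully-tryptic 0-missed
    peptides such that the resulting C-terminal fragment has length >= 5
    and a non-tryptic N-terminal boundary.
    """
    sites = cleavage_sites(protein_seq, rule)
    bounds = [0] + [i + 1 for i in sites] + [len(protein_seq)]
    out = []
    for j in range(len(bounds) - 1):
        start, end = bounds[j] + 1, bounds[j + 1]  # 1-based inclusive
        for pos in range(start + 1, end - 4):  # cut after pos (1-based)
            if protein_seq[pos - 1] in ("L", "I"):
                out.append((start, end, pos))
    return out


def simulate_proteome(
    spec: ProteomeSpec,
) -> tuple[IntensityTable, pd.DataFrame, dict]:
    """Spiked intensity table + digested peptide table + truth labels.

    Returns ``(table, peptides, truth)`` where ``peptides`` has columns
    ``peptide, protein_id, start, end, planted`` (1-based inclusive
    coordinates in the parent protein) and ``truth`` carries the substrate
    indicator, the parent sequences and the planted cleavage positions.
    """
    rng = np.random.default_rng(spec.seed)
    rule = DigestRule()

    proteins = [f"P{i + 1:04d}" for i in range(spec.n_proteins)]
    is_substrate = np.zeros(spec.n_proteins, dtype=bool)
    idx = rng.choice(spec.n_proteins, size=spec.n_true_substrates, replace=False)
    is_substrate[idx] = True

    base = rng.uniform(20.0, 30.0, size=spec.n_proteins)
    n = spec.n_per_group
    treated_cols = [f"treated_{i + 1}" for i in range(n)]
    vehicle_cols = [f"vehicle_{i + 1}" for i in range(n)]
    log2 = np.empty((spec.n_proteins, 2 * n))
    noise = rng.normal(0.0, spec.lognormal_sd, size=(spec.n_proteins, 2 * n))
    log2[:, :n] = base[:, None] + noise[:, :n]
    log2[:, :n] += np.where(is_substrate, spec.true_log2fc, 0.0)[:, None]
    log2[:, n:] = base[:, None] + noise[:, n:]
    abundance = pd.DataFrame(
        2.0**log2, index=proteins, columns=treated_cols + vehicle_cols
    )
    groups = pd.Series(
        {**{c: "treated" for c in treated_cols},
         **{c: "vehicle" for c in vehicle_cols}}
    )
    table = IntensityTable(abundance=abundance, groups=groups)

    # parent sequences for the digest
    if spec.proteins_fasta is not None:
        parents = list(spec.proteins_fasta)
    else:
        for _ in range(100):
            seq = _random_protein(rng, 250)
            if len(_plantable_sites(seq, rule)) >= spec.n_planted_cleavages:
                break
        else:
            raise RuntimeError("could not generate a plantable parent protein")
        parents = [("DCN_LIKE", seq)]

    pep_rows = []
    planted_positions: list[tuple[str, int, int]] = []
    for pid, seq in parents:
        spans = digest(seq, rule)
        if not spans:
            import warnings

            warnings.warn(f"protein {pid} too short to digest; skipped")
            continue
        for start, end in spans:
            pep_rows.append(
                {
                    "peptide": seq[start - 1 : end],
                    "protein_id": pid,
                    "start": start,
                    "end": end,
                    "planted": False,
                }
            )
    # plant semi-tryptic cleavages after L/I in the first parent
    if spec.n_planted_cleavages > 0 and parents:
        pid, seq = parents[0]
        candidates = _plantable_sites(seq, rule)
        if len(candidates) < spec.n_planted_cleavages:
            raise ValueError(
                "parent protein has too few Leu/Ile sites to plant"
            )
        chosen = rng.choice(
            len(candidates), size=spec.n_planted_cleavages, replace=False
        )
        for k in sorted(chosen):
            _pstart, pend, cut = candidates[k]
            frag_start = cut + 1  # N-term right after the L/I cut
            pep_rows.append(
                {
                    "peptide": seq[frag_start - 1 : pend],
                    "protein_id": pid,
                    "start": frag_start,
                    "end": pend,
                    "planted": True,
                }
            )
            planted_positions.append((pid, frag_start, pend))

    peptides = pd.DataFrame(
        pep_rows, columns=["peptide", "protein_id", "start", "end", "planted"]
    )
    truth = {
        "is_substrate": pd.Series(is_substrate, index=proteins),
        "true_log2fc": spec.true_log2fc,
        "parents": dict(parents),
        "planted_peptides": planted_positions,
        "n_planted": len(planted_positions),
    }
    return table, peptides, truth
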