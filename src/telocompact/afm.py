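"""AFM / DREEM quantitative analyses for protein-DNA complex tables.

Re-implements the statistics applied to single-molecule AFM measurements of
TRF2-DNA complexes: Gaussian-mixture fits of volume and height histograms,
contour-length comparisons between complex size classes, the linear relation
between complex volume and the amount of DNA compacted inside it, a pluggable
volume-to-molecular-weight calibration, and per-complex DREEM signal
contrasts (bound minus free DNA) with the enhanced-fraction cohort summary.
A small pseudo-AFM renderer bridges simulation frames to the same pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .electrostatics import NM_PER_BP

__all__ = [
    "VOLUME_CLASS_THRESHOLD_NM3",
    "AFMTable",
    "DreemTrace",
    "MixtureFit",
    "fit_gaussian_mixture",
    "compare_contour_lengths",
    "VolumeCompactionFit",
    "fit_volume_compaction",
    "Calibration",
    "PolynomialCalibration",
    "IdentityCalibration",
    "mw_to_volume",
    "DreemResult",
    "dreem_contrast",
    "render_pseudo_afm",
    "measure_volume",
]

#: AFM-volume threshold separating small and large complexes (nm^3)
VOLUME_CLASS_THRESHOLD_NM3 = 500.0

#: canonical column names of a per-complex AFM measurement table
AFM_COLUMNS = ["volume_nm3", "height_nm", "dna_contour_length_nm", "size_class", "complexes_per_molecule"]


def AFMTable(rows: pd.DataFrame | dict) -> pd.DataFrame:
    """Validate / coerce a per-complex AFM measurement table.

    Columns: volume_nm3, height_nm, dna_contour_length_nm, size_class
    ("SMALL"/"LARGE"), complexes_per_molecule.  The size class is derived
    from the 500 nm^3 threshold and checked for consistency.
    """
    df = pd.DataFrame(rows).copy()
    missing = [c for c in AFM_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"AFM table missing columns: {missing}")
    if (df["volume_nm3"] <= 0).any():
        raise ValueError("volumes must be positive")
    derived = np.where(df["volume_nm3"] > VOLUME_CLASS_THRESHOLD_NM3, "LARGE", "SMALL")
    if "size_class" in df.columns:
        if not (df["size_class"] == derived).all():
            raise ValueError("size_class inconsistent with the 500 nm^3 threshold")
    else:
        df["size_class"] = derived
    if "complexes_per_molecule" not in df.columns:
        df["complexes_per_molecule"] = 1
    return df[AFM_COLUMNS]


@dataclass
class DreemTrace:
    """Signal samples along a traced DNA contour with per-sample labels.

    ``labels`` entries are "DNA_FREE" or "DNA_BOUND"; a usable trace carries
    at least 10 samples of each.
    """

    samples: np.ndarray
    labels: np.ndarray
    complex_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels)
        if len(self.samples) != len(self.labels):
            raise ValueError("samples and labels length mismatch")

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        free = self.samples[self.labels == "DNA_FREE"]
        bound = self.samples[self.labels == "DNA_BOUND"]
        if len(free) < 10 or len(bound) < 10:
            raise ValueError(
                f"trace {self.complex_id}: need >= 10 samples of each label "
                f"(free {len(free)}, bound {len(bound)})"
            )
        return bound, free


# ---------------------------------------------------------------------------
# Gaussian mixture fits on histograms
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """Least-squares sum-of-Gaussians fit to a histogram.

    R^2 follows the convention of AFM figure captions: computed on
    histogram counts against the fitted curve, not on raw samples.
    ``overlapping`` flags component pairs closer than the sum of their
    widths (a sign that K was chosen too large).
    """

    K: int
    means: np.ndarray
    sds: np.ndarray
    amplitudes: np.ndarray
    r_squared: float
    bin_width: float
    overlapping: bool = False
    bin_centers: np.ndarray = field(default=None, repr=False)
    counts: np.ndarray = field(default=None, repr=False)


def _gauss_sum(x, *params):
    k = len(params) // 3
    out = np.zeros_like(x, dtype=float)
    for i in range(k):
        a, mu, sd = params[3 * i : 3 * i + 3]
        out += a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return out


def fit_gaussian_mixture(values: Sequence[float], K: int, bin_width: float) -> MixtureFit:
    """Fit a K-component Gaussian mixture and score it on the histogram.

    Parameters are estimated by maximum likelihood (EM on the raw sample -
    histogram least squares is badly multimodal for overlapping components
    at these sample sizes); the reported R^2 compares the implied mixture
    curve with the histogram counts at ``bin_width``, the figure-caption
    convention.  Components are returned sorted by mean.  A singular fit
    (empty histogram, collapsed width) raises ``RuntimeError``.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 30:
        raise ValueError("need at least 30 values for a histogram fit")
    if K not in (1, 2):
        raise ValueError("K must be 1 or 2")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < K + 1:
        raise RuntimeError("singular fit: too few occupied histogram bins")
    from sklearn.mixture import GaussianMixture

    try:
        gm = GaussianMixture(n_components=K, random_state=0, n_init=5).fit(
            values.reshape(-1, 1)
        )
    except ValueError as exc:
        raise RuntimeError(f"singular mixture fit: {exc}") from exc
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    if np.any(sds <= 0) or not np.all(np.isfinite(sds)):
        raise RuntimeError("singular mixture fit: collapsed component width")
    weights = gm.weights_[order]
    amps = weights * len(values) * bin_width / (sds * np.sqrt(2.0 * np.pi))
    # predicted counts = expected bin occupancy (exact bin integrals, which
    # stays correct even for components much narrower than a bin)
    pred = np.zeros_like(centers, dtype=float)
    for w, m, s in zip(weights, means, sds):
        pred += w * len(values) * (
            stats.norm.cdf(edges[1:], m, s) - stats.norm.cdf(edges[:-1], m, s)
        )
    ss_res = float(np.sum((counts - pred) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    overlapping = bool(K == 2 and abs(means[1] - means[0]) < (sds[0] + sds[1]))
    return MixtureFit(K, means, sds, amps, r2, bin_width, overlapping, centers, counts)


def compare_contour_lengths(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[tuple[float, float], tuple[float, float], float]:
    """Per-group mean +/- sd and a Welch two-sample p-value.

    Used to test whether DNA bound by large complexes is significantly
    shorter than free DNA (compaction draws contour length into the
    complex).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 measurements")
    if np.std(a) == 0 and np.std(b) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return (
        (float(np.mean(a)), float(np.std(a, ddof=1))),
        (float(np.mean(b)), float(np.std(b, ddof=1))),
        float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# volume vs compacted length
# ---------------------------------------------------------------------------


@dataclass
class VolumeCompactionFit:
    intercept: float
    slope: float  # nm^3 per bp
    r_squared: float
    binned_intercept: float
    binned_slope: float
    binned_r_squared: float
    bin_bp: float


def fit_volume_compaction(
    table: pd.DataFrame,
    baseline_contour_nm: float,
    bin_bp: float = 100.0,
    nm_per_bp: float = NM_PER_BP,
) -> VolumeCompactionFit:
    """Ordinary least squares of complex volume on compacted DNA length.

    The compacted length L_c (bp) of each complex is the shortfall of its
    measured DNA contour from the free-DNA baseline, converted at
    ``nm_per_bp`` (0.32 nm/bp).  Returns both the raw fit and the fit after
    averaging volume in ``bin_bp`` windows of L_c (the binned fit trades
    scatter for fewer points and typically a higher R^2).
    """
    df = table[table["size_class"] == "LARGE"] if "size_class" in table else table
    if len(df) < 10:
        raise ValueError("need at least 10 rows")
    lc_bp = (baseline_contour_nm - df["dna_contour_length_nm"].to_numpy()) / nm_per_bp
    vol = df["volume_nm3"].to_numpy()
    keep = lc_bp > 0
    lc_bp, vol = lc_bp[keep], vol[keep]
    res = stats.linregress(lc_bp, vol)
    edges = np.arange(0.0, lc_bp.max() + bin_bp, bin_bp)
    idx = np.digitize(lc_bp, edges)
    centers, means = [], []
    for k in np.unique(idx):
        centers.append(edges[k - 1] + bin_bp / 2.0)
        means.append(vol[idx == k].mean())
    if len(centers) < 2:
        raise ValueError("fewer than 2 occupied length bins")
    bres = stats.linregress(centers, means)
    return VolumeCompactionFit(
        float(res.intercept),
        float(res.slope),
        float(res.rvalue**2),
        float(bres.intercept),
        float(bres.slope),
        float(bres.rvalue**2),
        bin_bp,
    )


# ---------------------------------------------------------------------------
# volume <-> molecular weight calibration (pluggable)
# ---------------------------------------------------------------------------


class Calibration:
    """Monotone volume(MW) calibration with an inverse.

    The AFM volume-to-molecular-weight curve is instrument-dependent, so no
    default coefficients are hard-coded; supply anchors or coefficients.
    """

    def volume(self, mw_kda: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def mw(self, volume_nm3: float) -> float:
        """Invert the calibration on its monotone-increasing branch."""
        from scipy.optimize import brentq

        grid = np.geomspace(1e-3, 1e5, 4000)
        vals = np.array([self.volume(m) for m in grid])
        # restrict to the increasing branch from the left
        end = int(np.argmax(vals)) + 1
        grid, vals = grid[:end], vals[:end]
        k = int(np.searchsorted(vals, volume_nm3))
        if k == 0 or k >= len(grid):
            raise ValueError("volume outside the calibration's monotone range")
        return float(
            brentq(lambda m: self.volume(m) - volume_nm3, grid[k - 1], grid[k])
        )


class IdentityCalibration(Calibration):
    def volume(self, mw_kda: float) -> float:
        if mw_kda <= 0:
            raise ValueError("molecular weight must be positive")
        return float(mw_kda)


@dataclass
class PolynomialCalibration(Calibration):
    """Polynomial volume(MW) calibration, e.g. fitted through measured
    (MW, volume) anchor points with ``from_anchors``."""

    coefficients: np.ndarray

    def volume(self, mw_kda: float) -> float:
        if mw_kda <= 0:
            raise ValueError("molecular weight must be positive")
        return float(np.polyval(self.coefficients, mw_kda))

    @classmethod
    def from_anchors(cls, anchors: Sequence[tuple[float, float]]) -> "PolynomialCalibration":
        mw = np.array([a[0] for a in anchors], dtype=float)
        vol = np.array([a[1] for a in anchors], dtype=float)
        coeff = np.polyfit(mw, vol, deg=len(anchors) - 1)
        return cls(coeff)


def mw_to_volume(mw_kda: float, calibration: Calibration) -> float:
    """Expected AFM volume (nm^3) of a particle of the given mass."""
    return calibration.volume(mw_kda)


# ---------------------------------------------------------------------------
# DREEM signal contrast
# ---------------------------------------------------------------------------


@dataclass
class DreemResult:
    deltas: np.ndarray  # per-complex bound - free mean signal
    sds: np.ndarray
    classes: list[str]  # ENHANCED / REDUCED / NULL
    enhanced_fraction: float
    ci_low: float
    ci_high: float


def dreem_contrast(traces: Sequence[DreemTrace], alpha: float = 0.05) -> DreemResult:
    """Per-complex DREEM signal difference (DNA bound - DNA alone) and the
    cohort's enhanced fraction.

    A complex is ENHANCED when its bound-segment signal is significantly
    above its free-DNA signal (Welch test, p < alpha), REDUCED when
    significantly below, NULL otherwise.  The enhanced fraction carries a
    95% binomial (Wilson) confidence interval.
    """
    deltas, sds, classes = [], [], []
    for trace in traces:
        bound, free = trace.split()
        delta = float(np.mean(bound) - np.mean(free))
        deltas.append(delta)
        sds.append(float(np.sqrt(np.var(bound, ddof=1) + np.var(free, ddof=1))))
        if np.std(bound) == 0 and np.std(free) == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(bound, free, equal_var=False).pvalue)
        if p < alpha and delta > 0:
            classes.append("ENHANCED")
        elif p < alpha and delta < 0:
            classes.append("REDUCED")
        else:
            classes.append("NULL")
    n = len(classes)
    k = classes.count("ENHANCED")
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="wilson")
    return DreemResult(
        np.array(deltas), np.array(sds), classes, k / n, float(ci.low), float(ci.high)
    )


# ---------------------------------------------------------------------------
# pseudo-AFM rendering of simulation frames
# ---------------------------------------------------------------------------


def render_pseudo_afm(
    points: np.ndarray,
    pixel_nm: float = 0.25,
    tip_radius_nm: float = 0.0,
    bead_radius_nm: float = 0.5,
    pad_nm: float = 3.0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Topographic height field of beads resting on a substrate plane.

    Each bead is rendered as a sphere (height = z_center + sqrt(r^2 - d^2)
    above the z = 0 substrate); the image is the maximum over beads, then
    dilated by a spherical tip of ``tip_radius_nm`` (grayscale dilation with
    a spherical structuring element), mimicking tip convolution.  Returns
    (grid, (x0, y0)) with the grid origin in nm.
    """
    if pixel_nm > 1.0:
        raise ValueError("pixel_nm must be <= 1 nm for faithful volumes")
    if tip_radius_nm < 0:
        raise ValueError("tip radius must be non-negative")
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty frame")
    x0, y0 = pts[:, 0].min() - pad_nm, pts[:, 1].min() - pad_nm
    nx = int(np.ceil((pts[:, 0].max() + pad_nm - x0) / pixel_nm)) + 1
    ny = int(np.ceil((pts[:, 1].max() + pad_nm - y0) / pixel_nm)) + 1
    grid = np.zeros((ny, nx))
    r = bead_radius_nm
    span = int(np.ceil(r / pixel_nm))
    for px, py, pz in pts:
        cx = int(round((px - x0) / pixel_nm))
        cy = int(round((py - y0) / pixel_nm))
        for iy in range(max(cy - span, 0), min(cy + span + 1, ny)):
            for ix in range(max(cx - span, 0), min(cx + span + 1, nx)):
                dx = x0 + ix * pixel_nm - px
                dy = y0 + iy * pixel_nm - py
                d2 = dx * dx + dy * dy
                if d2 <= r * r:
                    h = pz + np.sqrt(r * r - d2)
                    if h > grid[iy, ix]:
                        grid[iy, ix] = h
    if tip_radius_nm > 0:
        t = int(np.ceil(tip_radius_nm / pixel_nm))
        yy, xx = np.mgrid[-t : t + 1, -t : t + 1]
        d2 = (xx * pixel_nm) ** 2 + (yy * pixel_nm) ** 2
        inside = d2 <= tip_radius_nm**2
        profile = np.full(d2.shape, -np.inf)
        profile[inside] = np.sqrt(tip_radius_nm**2 - d2[inside]) - tip_radius_nm
        grid = ndimage.grey_dilation(grid, structure=profile)
        grid[grid < 0] = 0.0
    return grid, (x0, y0)


def measure_volume(grid: np.ndarray, pixel_nm: float, height_floor: float = 0.05) -> float:
    """Particle volume from a height field: sum of (height - floor) over
    pixels above the floor, times the pixel area (the standard AFM grain
    volume estimate)."""
    above = grid > height_floor
    return float(np.sum(grid[above] - height_floor) * pixel_nm**2)
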