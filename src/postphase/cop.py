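"""Center-of-pressure stabilometry: displacement conversion, smoothing,
and the 35-feature sway battery.

Raw platform output is a pair of sensor percentages in [−1, 1]
(StaticVR_ML, StaticVR_AP); displacement in centimeters is
``dimension × 0.5 × percentage`` per axis.  The stabilogram is smoothed
with a Savitzky–Golay filter (window 7, polynomial order 3) and all
features are computed on mean-centered axes, which makes every battery
member invariant under constant translation of the trajectory.

The battery follows the standard posturography measure set (mean/RMS
distances, sway path, mean velocity, ranges, 95 % confidence-ellipse and
confidence-circle areas, sway area, frequency-domain measures, fractal
dimensions) plus the step-direction Shannon entropy; 35 features named
``COP__<feature>``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import chi2

from .segmentation import PhaseSegment
from .spectral import median_frequency, spectral_edge, welch_psd

SAVGOL_WINDOW = 7
SAVGOL_ORDER = 3
EPS = 1e-12

#: z and chi-square quantiles for the 95 % confidence circle / ellipse.
_Z95 = 1.644853626951472
_CHI2_95_2 = float(chi2.ppf(0.95, df=2))


@dataclass(frozen=True)
class PlatformGeometry:
    """Force-platform dimensions: ``x_cm`` along ML, ``y_cm`` along AP."""

    x_cm: float = 50.0
    y_cm: float = 50.0

    def __post_init__(self) -> None:
        if self.x_cm <= 0 or self.y_cm <= 0:
            raise ValueError("platform dimensions must be positive")


@dataclass
class Stabilogram:
    """CoP trajectory in centimeters: ``ml`` and ``ap`` series at ``fs`` Hz."""

    ml: np.ndarray
    ap: np.ndarray
    fs: float = 90.0

    def __post_init__(self) -> None:
        self.ml = np.asarray(self.ml, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        if self.ml.shape != self.ap.shape or self.ml.ndim != 1:
            raise ValueError("ml and ap must be equal-length 1-D arrays")
        if not (np.isfinite(self.ml).all() and np.isfinite(self.ap).all()):
            raise ValueError("stabilogram contains non-finite values")

    @property
    def n(self) -> int:
        return self.ml.size


def read_stabilogram(path) -> Stabilogram:
    """Read a two-column (ML, AP) text file with a ``# fs: <Hz>`` header."""
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# fs:"):
        raise ValueError("stabilogram file must start with a '# fs: <Hz>' header")
    fs = float(lines[0].split(":", 1)[1])
    data = np.loadtxt(lines[1:], ndmin=2)
    return Stabilogram(ml=data[:, 0], ap=data[:, 1], fs=fs)


def write_stabilogram(stab: Stabilogram, path) -> None:
    np.savetxt(path, np.column_stack([stab.ml, stab.ap]), fmt="%.8g",
               header=f" fs: {stab.fs}", comments="#")


def to_displacement(cop_raw: np.ndarray, geometry: PlatformGeometry,
                    fs: float = 90.0) -> Stabilogram:
    """Sensor percentages → centimeters: disp = dimension × 0.5 × percentage."""
    cop_raw = np.asarray(cop_raw, dtype=float)
    if cop_raw.ndim != 2 or cop_raw.shape[0] != 2:
        raise ValueError("cop_raw must be a 2 × N array (ML row, AP row)")
    if np.abs(cop_raw).max(initial=0.0) > 1.0:
        raise ValueError("sensor percentages must lie in [-1, 1]")
    return Stabilogram(ml=geometry.x_cm * 0.5 * cop_raw[0],
                       ap=geometry.y_cm * 0.5 * cop_raw[1], fs=fs)


def smooth_stabilogram(stab: Stabilogram,
                       window: int = SAVGOL_WINDOW,
                       order: int = SAVGOL_ORDER) -> Stabilogram:
    """Savitzky–Golay smoothing per axis; exact on polynomials ≤ order."""
    if stab.n < window:
        raise ValueError(f"need at least {window} samples, got {stab.n}")
    return Stabilogram(
        ml=signal.savgol_filter(stab.ml, window, order),
        ap=signal.savgol_filter(stab.ap, window, order),
        fs=stab.fs,
    )


# -- elementary sway measures ----------------------------------------------

def rdist(series: np.ndarray) -> float:
    """RMS distance of the mean-centered series (population SD)."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("rdist requires at least 2 samples")
    return float(np.sqrt(np.mean((series - series.mean()) ** 2)))


def total_excursion(series: np.ndarray) -> float:
    """Sway path length along one axis: Σ |x_{i+1} − x_i|."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("total_excursion requires at least 2 samples")
    return float(np.sum(np.abs(np.diff(series))))


def direction_entropy(stab: Stabilogram, n_bins: int = 36) -> float:
    """Shannon entropy (bits) of the step-direction histogram.

    Step angles atan2(Δap, Δml) over (−π, π], zero-length steps discarded;
    maximum is log2(n_bins) for an isotropic walk, 0 for straight-line
    motion.
    """
    if stab.n < 2:
        raise ValueError("direction_entropy requires at least 2 samples")
    dml, dap = np.diff(stab.ml), np.diff(stab.ap)
    nonzero = (dml != 0) | (dap != 0)
    if not nonzero.any():
        raise ValueError("all steps are zero: direction undefined")
    theta = np.arctan2(dap[nonzero], dml[nonzero])
    counts, _ = np.histogram(theta, bins=n_bins, range=(-np.pi, np.pi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _planar_diameter(ml: np.ndarray, ap: np.ndarray) -> float:
    """Largest distance between any two trajectory points (via convex hull)."""
    pts = np.column_stack([ml, ap])
    try:
        hull = pts[ConvexHull(pts).vertices]
    except QhullError:  # degenerate (collinear / constant) trajectories
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        return float(np.hypot(*(hi - lo)))
    d2 = ((hull[:, None, :] - hull[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


# -- battery ---------------------------------------------------------------

def _battery_values(stab: Stabilogram) -> dict[str, float]:
    fs, n = stab.fs, stab.n
    t = (n - 1) / fs
    ml = stab.ml - stab.ml.mean()
    ap = stab.ap - stab.ap.mean()
    rd = np.hypot(ml, ap)

    mdist_ml, mdist_ap = float(np.mean(np.abs(ml))), float(np.mean(np.abs(ap)))
    mdist = float(np.mean(rd))
    rdist_ml, rdist_ap = rdist(ml), rdist(ap)
    rdist_r = float(np.sqrt(np.mean(rd ** 2)))
    sd_ml = float(np.std(ml, ddof=1))
    sd_ap = float(np.std(ap, ddof=1))
    sd_rd = float(np.std(rd, ddof=1))

    totex_ml, totex_ap = total_excursion(ml), total_excursion(ap)
    totex = float(np.sum(np.hypot(np.diff(ml), np.diff(ap))))
    mvelo, mvelo_ml, mvelo_ap = totex / t, totex_ml / t, totex_ap / t

    range_ml = float(ml.max() - ml.min())
    range_ap = float(ap.max() - ap.min())
    range_r = _planar_diameter(ml, ap)

    # 95 % confidence circle (mean + z·SD of resultant distance) and
    # 95 % confidence ellipse (chi-square scaling of the 2-D covariance).
    area_cc = float(np.pi * (mdist + _Z95 * sd_rd) ** 2)
    cov = np.cov(ml, ap, ddof=1)
    area_ce = float(np.pi * _CHI2_95_2 * np.sqrt(max(np.linalg.det(cov), 0.0)))
    # Sway area: summed triangle areas swept per unit time.
    area_sw = float(np.abs(ml[:-1] * ap[1:] - ml[1:] * ap[:-1]).sum() / (2.0 * t))

    # Rotational mean frequency: sway-path velocity against mean distance.
    mfreq = mvelo / (2.0 * np.pi * mdist + EPS)
    mfreq_ml = mvelo_ml / (4.0 * np.sqrt(2.0) * mdist_ml + EPS)
    mfreq_ap = mvelo_ap / (4.0 * np.sqrt(2.0) * mdist_ap + EPS)

    def fd(diameter: float) -> float:
        return float(np.log(n) / (np.log(n * diameter / (totex + EPS) + EPS) + EPS))

    fd_pd = fd(range_r)
    fd_cc = fd(2.0 * np.sqrt(area_cc / np.pi))
    fd_ce = fd(2.0 * np.sqrt(area_ce / np.pi + EPS))

    freqs_ml, psd_ml = welch_psd(ml, fs)
    freqs_ap, psd_ap = welch_psd(ap, fs)
    centroid = lambda f, p: float((f * p).sum() / (p.sum() + EPS))

    return {
        "MDIST": mdist, "MDIST_AP": mdist_ap, "MDIST_ML": mdist_ml,
        "RDIST": rdist_r, "RDIST_AP": rdist_ap, "RDIST_ML": rdist_ml,
        "SD_AP": sd_ap, "SD_ML": sd_ml, "SD_RD": sd_rd,
        "TOTEX": totex, "TOTEX_AP": totex_ap, "TOTEX_ML": totex_ml,
        "MVELO": mvelo, "MVELO_AP": mvelo_ap, "MVELO_ML": mvelo_ml,
        "RANGE": range_r, "RANGE_AP": range_ap, "RANGE_ML": range_ml,
        "AREA_CC": area_cc, "AREA_CE": area_ce, "AREA_SW": area_sw,
        "MFREQ": mfreq, "MFREQ_AP": mfreq_ap, "MFREQ_ML": mfreq_ml,
        "FD_PD": fd_pd, "FD_CC": fd_cc, "FD_CE": fd_ce,
        "DIRECTION_ENTROPY": direction_entropy(stab),
        "MEDFREQ_AP": median_frequency(freqs_ap, psd_ap),
        "MEDFREQ_ML": median_frequency(freqs_ml, psd_ml),
        "F95_AP": spectral_edge(freqs_ap, psd_ap, 0.95),
        "F95_ML": spectral_edge(freqs_ml, psd_ml, 0.95),
        "CFREQ_AP": centroid(freqs_ap, psd_ap),
        "CFREQ_ML": centroid(freqs_ml, psd_ml),
        "SWAY_RATIO_ML_AP": rdist_ml / (rdist_ap + EPS),
    }


COP_FEATURE_NAMES: tuple[str, ...] = (
    "MDIST", "MDIST_AP", "MDIST_ML", "RDIST", "RDIST_AP", "RDIST_ML",
    "SD_AP", "SD_ML", "SD_RD", "TOTEX", "TOTEX_AP", "TOTEX_ML",
    "MVELO", "MVELO_AP", "MVELO_ML", "RANGE", "RANGE_AP", "RANGE_ML",
    "AREA_CC", "AREA_CE", "AREA_SW", "MFREQ", "MFREQ_AP", "MFREQ_ML",
    "FD_PD", "FD_CC", "FD_CE", "DIRECTION_ENTROPY",
    "MEDFREQ_AP", "MEDFREQ_ML", "F95_AP", "F95_ML", "CFREQ_AP", "CFREQ_ML",
    "SWAY_RATIO_ML_AP",
)
assert len(COP_FEATURE_NAMES) == 35


def cop_feature_vector(stab: Stabilogram) -> dict[str, float]:
    """The full 35-feature vector, named ``COP__<feature>``."""
    values = _battery_values(stab)
    out: dict[str, float] = {}
    for name in COP_FEATURE_NAMES:
        v = values[name]
        if not np.isfinite(v):
            raise ValueError(f"CoP operator {name!r} produced non-finite value {v}")
        out[f"COP__{name}"] = float(v)
    return out


def cop_phase_features(segment: PhaseSegment,
                       geometry: PlatformGeometry | None = None) -> dict[str, float]:
    """Raw sensor segment → displacement → smoothing → 35 features."""
    geometry = geometry or PlatformGeometry()
    stab = to_displacement(segment.data, geometry, fs=segment.fs)
    return cop_feature_vector(smooth_stabilogram(stab))
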