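"""Synthetic microscopy benchmark generator for bacterial membrane-potential assays.

Real DiBAC4(3) experiments produce paired brightfield/FITC micrographs of
rod-shaped bacteria in which depolarized cells fluoresce more brightly than
polarized ones.  This module generates such data with known ground truth so
that every downstream stage (segmentation, intensity profiling, clustered
population statistics) can be scored against the truth:

* :func:`sample_population` places non-overlapping capsule-shaped cells (plus
  out-of-size-range debris) in a frame and assigns each cell a polarization
  class and a true fluorescence intensity drawn from a two-component
  log-normal mixture.
* :func:`render_image_pair` rasterizes a scene into a 16-bit brightfield /
  fluorescence image pair (dark rods on a bright background; uniform emission
  blurred by a Gaussian PSF plus read noise).
* :func:`generate_cell_table` bypasses imaging and directly emits per-cell
  measurement rows with biological-replicate clustering of the depolarization
  probability on the logit scale — the fast path for statistics tests.
* :func:`generate_growth_curve` produces logistic OD600 trajectories with
  multiplicative noise.

All operations are deterministic given their explicit ``seed`` argument; no
global random state is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

__all__ = [
    "PopulationSpec",
    "ImagingSpec",
    "GrowthCurveSpec",
    "SceneGroundTruth",
    "ImagePair",
    "GrowthSeries",
    "SceneTooDenseError",
    "sample_population",
    "render_image_pair",
    "generate_cell_table",
    "generate_dose_response_table",
    "generate_growth_curve",
]

GROUND_TRUTH_COLUMNS = [
    "object_id",
    "cx",
    "cy",
    "length_px",
    "width_px",
    "orientation_rad",
    "class",
    "true_mean_intensity",
]

#: Fraction of the brightfield background level that cell interiors drop to.
BRIGHTFIELD_CELL_CONTRAST = 0.35

#: Realistic per-condition depolarized fractions for preset experiments.
#: These mirror the percent-depolarized levels reported in single-cell DiBAC
#: studies of the corresponding designs (KCl calibration series, growth-time
#: series and neurotransmitter exposure, for B. subtilis and L. reuteri).
#: They parameterize the generator only — simulated imagery cannot stand in
#: for the original micrographs.
CONDITION_PRESETS: dict[str, dict[str, float]] = {
    "bsubtilis_kcl": {
        "Control": 0.2103,
        "Val+KCl15": 0.2613,
        "Val+KCl60": 0.3759,
        "Val+KCl300": 0.4738,
    },
    "bsubtilis_growth": {"t3h": 0.3815, "t5h": 0.4104, "t7h": 0.5702},
    "bsubtilis_neurotransmitter": {
        "Control": 0.4895,
        "Glutamate": 0.2846,
        "GABA": 0.2371,
    },
    "lreuteri_kcl": {
        "Control": 0.2230,
        "Val+KCl15": 0.3093,
        "Val+KCl60": 0.3502,
        "Val+KCl300": 0.3998,
    },
    "lreuteri_neurotransmitter": {
        "Control": 0.3989,
        "Glutamate": 0.2756,
        "GABA": 0.2498,
    },
}


class SceneTooDenseError(RuntimeError):
    """Raised when rejection sampling cannot place all objects without overlap."""


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of a two-class (polarized / depolarized) cell population.

    Intensities are log-normal per class: ``mu_*`` and ``sigma_*`` are the
    location and scale of ``log(intensity)`` in arbitrary fluorescence units.
    The defaults put the polarized mode near 10 a.u. and the depolarized mode
    near 18 a.u., so that a mixed control population has a pooled mean close
    to the ~13.7 a.u. depolarization thresholds typical of DiBAC assays of
    *B. subtilis* in exponential phase.

    ``replicate_sd`` is the standard deviation of a biological-replicate
    random effect added to the logit of the depolarization probability; it is
    what makes cells within a replicate correlated.
    """

    n_cells: int = 300
    frac_depolarized: float = 0.21
    mu_pol: float = math.log(10.0)
    sigma_pol: float = 0.35
    mu_depol: float = math.log(18.0)
    sigma_depol: float = 0.35
    replicate_sd: float = 0.1
    n_debris_small: int = 0
    n_debris_large: int = 0
    # capsule geometry ranges (pixels); rods ~4 um x 0.8 um at 40x
    cell_length_range: tuple[float, float] = (18.0, 30.0)
    cell_width_range: tuple[float, float] = (4.0, 7.0)

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_debris_small < 0 or self.n_debris_large < 0:
            raise ValueError("object counts must be non-negative")
        if not 0.0 <= self.frac_depolarized <= 1.0:
            raise ValueError("frac_depolarized must lie in [0, 1]")
        if self.sigma_pol <= 0 or self.sigma_depol <= 0:
            raise ValueError("intensity scales must be positive")
        if self.mu_depol <= self.mu_pol:
            raise ValueError(
                "mu_depol must exceed mu_pol: the dye enters depolarized cells, "
                "so their fluorescence is brighter"
            )
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be non-negative")
        lo_l, hi_l = self.cell_length_range
        lo_w, hi_w = self.cell_width_range
        if not (0 < lo_w <= hi_w and 0 < lo_l <= hi_l):
            raise ValueError("geometry ranges must be positive and ordered")

    def class_means(self) -> tuple[float, float]:
        """Expected intensity of the polarized and depolarized class (log-normal mean)."""
        m_pol = math.exp(self.mu_pol + 0.5 * self.sigma_pol**2)
        m_dep = math.exp(self.mu_depol + 0.5 * self.sigma_depol**2)
        return m_pol, m_dep

    def mixture_mean(self, frac: float | None = None) -> float:
        """Expected intensity of a cell drawn from the mixture."""
        f = self.frac_depolarized if frac is None else frac
        m_pol, m_dep = self.class_means()
        return (1.0 - f) * m_pol + f * m_dep

    def mixture_tail(self, threshold: float, frac: float | None = None) -> float:
        """P(intensity > threshold) under the mixture — the analytic depolarized
        fraction recovered by thresholding at ``threshold``."""
        f = self.frac_depolarized if frac is None else frac
        if threshold <= 0:
            return 1.0
        z_pol = (math.log(threshold) - self.mu_pol) / self.sigma_pol
        z_dep = (math.log(threshold) - self.mu_depol) / self.sigma_depol
        from scipy.stats import norm

        return f * norm.sf(z_dep) + (1.0 - f) * norm.sf(z_pol)

    def median_cell_area(self) -> float:
        """Capsule area at median length/width — used to derive size-filter bounds."""
        length = 0.5 * sum(self.cell_length_range)
        width = 0.5 * sum(self.cell_width_range)
        return _capsule_area(length, width)


@dataclass(frozen=True)
class ImagingSpec:
    """Raster geometry and acquisition noise of the simulated microscope.

    The noise model is deliberately simple (uniform emission, Gaussian PSF,
    additive Gaussian read noise); it carries the statistical structure the
    analysis needs, not the optics of any particular instrument.
    """

    width_px: int = 512
    height_px: int = 512
    background_bf: float = 3000.0
    background_fl: float = 2.0
    read_noise_sd: float = 1.0
    psf_sigma_px: float = 0.8
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.background_bf < 0 or self.background_fl < 0:
            raise ValueError("backgrounds must be non-negative")
        if self.read_noise_sd < 0 or self.psf_sigma_px < 0:
            raise ValueError("noise and PSF scales must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass(frozen=True)
class GrowthCurveSpec:
    """Logistic OD600 growth model: N(t) = K / (1 + ((K-N0)/N0) exp(-r_max t)).

    ``r_max`` is the maximum specific growth rate in min^-1; exponential-phase
    *B. subtilis* grows at roughly 0.011 min^-1 (doubling time ~64 min).
    """

    N0: float = 0.01
    K: float = 1.4
    r_max: float = 0.011
    noise_sd: float = 0.0
    times_min: tuple[float, ...] = tuple(float(t) for t in range(0, 481, 30))

    def __post_init__(self) -> None:
        if not 0 < self.N0 < self.K:
            raise ValueError("need 0 < N0 < K")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        t = np.asarray(self.times_min, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("sampling times must be non-negative and strictly increasing")

    def mean_od(self, t: np.ndarray | float) -> np.ndarray | float:
        a = (self.K - self.N0) / self.N0
        return self.K / (1.0 + a * np.exp(-self.r_max * np.asarray(t, dtype=float)))


@dataclass
class SceneGroundTruth:
    """True composition of a synthetic field: one row per object.

    ``table`` columns: object_id, cx, cy (0-based pixel coordinates of the
    centroid), length_px, width_px, orientation_rad, class (polarized /
    depolarized / debris), true_mean_intensity.
    """

    table: pd.DataFrame
    frame_shape: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        missing = set(GROUND_TRUTH_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"ground-truth table missing columns: {sorted(missing)}")

    @property
    def cells(self) -> pd.DataFrame:
        return self.table[self.table["class"] != "debris"]

    @property
    def n_cells(self) -> int:
        return int(len(self.cells))

    def to_csv(self, path) -> None:
        self.table[GROUND_TRUTH_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_shape: tuple[int, int]) -> "SceneGroundTruth":
        return cls(pd.read_csv(path), frame_shape)


@dataclass
class ImagePair:
    """A paired brightfield / fluorescence acquisition of one field."""

    brightfield: np.ndarray
    fluorescence: np.ndarray
    scene_id: str = "scene"

    def write_tiffs(self, out_dir) -> tuple[str, str]:
        """Write `<scene_id>_BF.tif` and `<scene_id>_FITC.tif` into *out_dir*."""
        import os

        import tifffile

        bf_path = os.path.join(str(out_dir), f"{self.scene_id}_BF.tif")
        fl_path = os.path.join(str(out_dir), f"{self.scene_id}_FITC.tif")
        tifffile.imwrite(bf_path, self.brightfield)
        tifffile.imwrite(fl_path, self.fluorescence)
        return bf_path, fl_path


@dataclass
class GrowthSeries:
    """An OD600 time series (times in minutes)."""

    times_min: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times_min.shape != self.od600.shape:
            raise ValueError("times and OD must have the same length")
        if self.times_min.size and np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.times_min, "od600": self.od600}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "GrowthSeries":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(), df["od600"].to_numpy())


# ---------------------------------------------------------------------------
# geometry helpers

def _capsule_area(length: float, width: float) -> float:
    r = width / 2.0
    return width * (length - width) + math.pi * r * r


def _segment_endpoints(cx, cy, length, width, theta):
    """Endpoints of the central segment of a capsule (half-length minus cap radius)."""
    half = np.maximum(length - width, 0.0) / 2.0
    dx, dy = np.cos(theta) * half, np.sin(theta) * half
    return cx - dx, cy - dy, cx + dx, cy + dy


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between two 2-D segments p1-p2 and q1-q2."""
    p1, p2, q1, q2 = (np.asarray(v, dtype=float) for v in (p1, p2, q1, q2))
    d1 = p2 - p1
    d2 = q2 - q1
    r = p1 - q1
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    if a <= 1e-12 and e <= 1e-12:
        return float(np.linalg.norm(r))
    if a <= 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= 1e-12:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest = (p1 + s * d1) - (q1 + t * d2)
    return float(np.linalg.norm(closest))


def capsules_overlap(row_a, row_b, gap: float = 1.0) -> bool:
    """True when two capsule objects come closer than the sum of radii plus *gap*."""
    ax1, ay1, ax2, ay2 = _segment_endpoints(
        row_a["cx"], row_a["cy"], row_a["length_px"], row_a["width_px"], row_a["orientation_rad"]
    )
    bx1, by1, bx2, by2 = _segment_endpoints(
        row_b["cx"], row_b["cy"], row_b["length_px"], row_b["width_px"], row_b["orientation_rad"]
    )
    d = _segment_distance((ax1, ay1), (ax2, ay2), (bx1, by1), (bx2, by2))
    return d < (row_a["width_px"] + row_b["width_px"]) / 2.0 + gap


# ---------------------------------------------------------------------------
# operations

_MAX_ATTEMPTS_PER_OBJECT = 200


def sample_population(
    spec: PopulationSpec, imaging: ImagingSpec, seed: int
) -> SceneGroundTruth:
    """Sample a ground-truth field of cells and debris.

    Cell classes are i.i.d. Bernoulli(``frac_depolarized``); intensities are
    drawn from the class log-normal.  Capsules are placed by rejection
    sampling so that no two objects overlap and every object lies fully
    inside the frame.

    Raises
    ------
    SceneTooDenseError
        if an object cannot be placed after a bounded number of attempts.
    """
    rng = np.random.default_rng(seed)
    records: list[dict] = []

    n = spec.n_cells
    depolarized = rng.random(n) < spec.frac_depolarized
    log_int = np.where(
        depolarized,
        rng.normal(spec.mu_depol, spec.sigma_depol, size=n),
        rng.normal(spec.mu_pol, spec.sigma_pol, size=n),
    )
    intensities = np.exp(log_int)

    def place(length, width, cls, intensity, object_id):
        margin = length / 2.0 + 1.0
        if (
            imaging.width_px <= 2 * margin or imaging.height_px <= 2 * margin
        ):
            raise SceneTooDenseError(
                f"frame {imaging.width_px}x{imaging.height_px} too small for an "
                f"object of length {length:.1f}px"
            )
        for _ in range(_MAX_ATTEMPTS_PER_OBJECT):
            cand = {
                "object_id": object_id,
                "cx": rng.uniform(margin, imaging.width_px - margin),
                "cy": rng.uniform(margin, imaging.height_px - margin),
                "length_px": length,
                "width_px": width,
                "orientation_rad": rng.uniform(0.0, math.pi),
                "class": cls,
                "true_mean_intensity": intensity,
            }
            if all(not capsules_overlap(cand, other) for other in records):
                records.append(cand)
                return
        raise SceneTooDenseError(
            f"could not place object {object_id} after "
            f"{_MAX_ATTEMPTS_PER_OBJECT} attempts: scene too dense"
        )

    oid = 0
    for i in range(n):
        length = rng.uniform(*spec.cell_length_range)
        width = rng.uniform(*spec.cell_width_range)
        cls = "depolarized" if depolarized[i] else "polarized"
        place(length, width, cls, float(intensities[i]), oid)
        oid += 1

    # sub-range specks: a few pixels across, non-fluorescent
    for _ in range(spec.n_debris_small):
        size = rng.uniform(1.5, 3.0)
        place(size, size, "debris", 0.0, oid)
        oid += 1
    # super-range blobs: larger than any cell, dimly autofluorescent
    m_pol, _ = spec.class_means()
    max_len = spec.cell_length_range[1]
    for _ in range(spec.n_debris_large):
        diameter = rng.uniform(1.3 * max_len, 1.8 * max_len)
        place(diameter, diameter, "debris", 0.15 * m_pol, oid)
        oid += 1

    table = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS)
    return SceneGroundTruth(table=table, frame_shape=(imaging.height_px, imaging.width_px))


def _paint_capsules(shape: tuple[int, int], truth: SceneGroundTruth):
    """Yield (rows, cols) index arrays of the pixels inside each object's capsule."""
    H, W = shape
    for _, row in truth.table.iterrows():
        half_l = row["length_px"] / 2.0
        r = row["width_px"] / 2.0
        x1, y1, x2, y2 = _segment_endpoints(
            row["cx"], row["cy"], row["length_px"], row["width_px"], row["orientation_rad"]
        )
        lo_x = max(int(math.floor(row["cx"] - half_l - 2)), 0)
        hi_x = min(int(math.ceil(row["cx"] + half_l + 2)), W - 1)
        lo_y = max(int(math.floor(row["cy"] - half_l - 2)), 0)
        hi_y = min(int(math.ceil(row["cy"] + half_l + 2)), H - 1)
        yy, xx = np.mgrid[lo_y : hi_y + 1, lo_x : hi_x + 1]
        # distance from each pixel centre to the capsule's central segment
        px = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
        a = np.array([x1, y1])
        b = np.array([x2, y2])
        ab = b - a
        denom = float(ab @ ab)
        if denom < 1e-12:
            t = np.zeros(len(px))
        else:
            t = np.clip((px - a) @ ab / denom, 0.0, 1.0)
        nearest = a + t[:, None] * ab
        dist = np.linalg.norm(px - nearest, axis=1)
        inside = dist <= r
        yield row, yy.ravel()[inside], xx.ravel()[inside]


def render_image_pair(
    truth: SceneGroundTruth, imaging: ImagingSpec, seed: int, scene_id: str = "scene"
) -> ImagePair:
    """Rasterize a ground-truth scene into a 16-bit brightfield/FITC pair.

    Brightfield: bright uniform background with objects darkened to
    ``BRIGHTFIELD_CELL_CONTRAST`` of the background.  Fluorescence: uniform
    per-object emission at ``true_mean_intensity`` on top of
    ``background_fl``, convolved with a Gaussian PSF, plus additive Gaussian
    read noise on both channels.  Values exceeding the bit depth are clipped
    with a warning.
    """
    H, W = truth.frame_shape
    if (H, W) != (imaging.height_px, imaging.width_px):
        raise ValueError("truth frame_shape disagrees with imaging spec")
    rng = np.random.default_rng(seed)

    bf = np.full((H, W), imaging.background_bf, dtype=float)
    fl = np.full((H, W), imaging.background_fl, dtype=float)
    cell_level = BRIGHTFIELD_CELL_CONTRAST * imaging.background_bf
    for row, rr, cc in _paint_capsules((H, W), truth):
        bf[rr, cc] = cell_level
        fl[rr, cc] += row["true_mean_intensity"]

    if imaging.psf_sigma_px > 0:
        fl = gaussian_filter(fl, imaging.psf_sigma_px, mode="nearest")
        bf = gaussian_filter(bf, imaging.psf_sigma_px, mode="nearest")
    if imaging.read_noise_sd > 0:
        bf = bf + rng.normal(0.0, imaging.read_noise_sd, size=bf.shape)
        fl = fl + rng.normal(0.0, imaging.read_noise_sd, size=fl.shape)

    out = []
    for chan in (bf, fl):
        if chan.max() > imaging.max_value:
            warnings.warn(
                "rendered intensities exceed the sensor bit depth; clipping",
                RuntimeWarning,
                stacklevel=2,
            )
        q = np.clip(np.rint(chan), 0, imaging.max_value)
        out.append(q.astype(np.uint16 if imaging.bit_depth == 16 else np.uint8))
    return ImagePair(brightfield=out[0], fluorescence=out[1], scene_id=scene_id)


def generate_cell_table(
    spec: PopulationSpec,
    design: list[tuple[str, int, int]],
    seed: int,
    frac_by_condition: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Directly generate per-cell measurement rows with replicate clustering.

    ``design`` rows are ``(condition, n_replicates, n_cells_per_replicate)``.
    Within replicate *j* of a condition with target fraction *f*, cells are
    depolarized with probability ``expit(logit(f) + b_j)`` where
    ``b_j ~ Normal(0, replicate_sd^2)`` — the same logit-scale heterogeneity
    a multilevel logistic model assumes.  Intensities come from the class
    log-normals; imaging is bypassed entirely.

    Returns a table with columns
    ``condition,replicate,image_id,cell_id,area_px,mean_intensity,true_class``.
    """
    if not design:
        raise ValueError("design must contain at least one row")
    for row in design:
        if len(row) != 3:
            raise ValueError("design rows must be (condition, n_replicates, n_cells)")
        _, n_rep, n_cell = row
        if n_rep < 1:
            raise ValueError("every design row needs n_replicates >= 1")
        if n_cell < 0:
            raise ValueError("n_cells_per_replicate must be non-negative")

    rng = np.random.default_rng(seed)
    frames = []
    area = int(round(spec.median_cell_area()))
    for condition, n_rep, n_cell in design:
        f = (frac_by_condition or {}).get(condition, spec.frac_depolarized)
        for j in range(1, n_rep + 1):
            b_j = rng.normal(0.0, spec.replicate_sd) if spec.replicate_sd > 0 else 0.0
            if f in (0.0, 1.0):
                p = f  # degenerate fractions are not perturbed
            else:
                p = float(expit(logit(f) + b_j))
            depol = rng.random(n_cell) < p
            log_int = np.where(
                depol,
                rng.normal(spec.mu_depol, spec.sigma_depol, size=n_cell),
                rng.normal(spec.mu_pol, spec.sigma_pol, size=n_cell),
            )
            frames.append(
                pd.DataFrame(
                    {
                        "condition": condition,
                        "replicate": f"R{j}",
                        "image_id": f"{condition}_R{j}_sim",
                        "cell_id": np.arange(1, n_cell + 1),
                        "area_px": area,
                        "mean_intensity": np.exp(log_int),
                        "true_class": np.where(depol, "depolarized", "polarized"),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_dose_response_table(
    doses: list[float],
    beta0: float,
    beta1: float,
    n_replicates: int,
    n_cells_per_replicate_dose: int,
    replicate_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate a clustered dose–response experiment on the logit scale.

    Each biological replicate *j* spans every dose (the clustering structure
    of a KCl calibration series) and carries one random intercept
    ``b_j ~ Normal(0, replicate_sd^2)``:
    ``P(depolarized | dose x, replicate j) = expit(beta0 + beta1 * x + b_j)``.

    Returns columns ``x`` (dose), ``y`` (0/1 depolarized), ``replicate``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(1, n_replicates + 1):
        b_j = rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0
        for x in doses:
            p = expit(beta0 + beta1 * x + b_j)
            y = (rng.random(n_cells_per_replicate_dose) < p).astype(int)
            rows.append(
                pd.DataFrame({"x": float(x), "y": y, "replicate": f"R{j}"})
            )
    return pd.concat(rows, ignore_index=True)


def generate_growth_curve(spec: GrowthCurveSpec, seed: int) -> GrowthSeries:
    """Sample a logistic OD600 trajectory with multiplicative log-normal noise."""
    rng = np.random.default_rng(seed)
    t = np.asarray(spec.times_min, dtype=float)
    mean = np.asarray(spec.mean_od(t), dtype=float)
    if spec.noise_sd > 0:
        mean = mean * np.exp(rng.normal(0.0, spec.noise_sd, size=mean.shape))
    return GrowthSeries(times_min=t, od600=mean)
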