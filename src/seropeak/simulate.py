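"""Synthetic two-group serum-spectrum cohorts with known ground truth.

Emulates the study design the classifier targets: two groups of sera
(default 29 vs 17), three profile spectra per sample over m/z 400-2000,
~160 occupied unit-m/z bins of which ~110 carry a between-group fold
change. Peak areas are log-normal across samples (serum ion intensities
are strictly positive and right-skewed), group effects are multiplicative
(a log2 fold change applied before replicate noise), and replicate noise is
multiplicative Gaussian on the log scale with a configurable CV.

Because downstream normalization rescales every 10-m/z window to a fixed
sum, a fold change is only observable relative to co-window mass: the
generator therefore clusters peaks (up to 4 per occupied window) and keeps
at least one non-discriminative anchor bin in every occupied window
whenever the configuration allows, and places no peak on a window boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocess import RawSpectrum

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_cohort_matrix",
    "render_profile",
]

_SEGMENT = 10.0  # m/z width of a normalization window
_PEAKS_PER_SEGMENT = 4


@dataclass
class SimulationConfig:
    """Parameters of a synthetic two-group triplicate cohort.

    Defaults mirror the study conditions the package is exercised on:
    29 vs 17 sera, m/z 400-2000, 160 occupied unit-m/z bins with 110
    discriminative ones, a 2.0 log2 fold change, and demographics matching
    the published cohort table (66% vs 41% male; ages 26.9 (7.2) vs
    34.0 (9.2) years).
    """

    n_group1: int = 29
    n_group2: int = 17
    mz_min: float = 400.0
    mz_max: float = 2000.0
    n_peaks: int = 160
    n_discriminative: int = 110
    effect_log2: float = 2.0
    base_sigma_log: float = 0.8
    replicate_cv: float = 0.08
    sex_ratio_g1: float = 0.66
    sex_ratio_g2: float = 0.41
    age_mean_g1: float = 26.9
    age_sd_g1: float = 7.2
    age_mean_g2: float = 34.0
    age_sd_g2: float = 9.2
    seed: int = 0
    group1_label: str = "disease"
    group2_label: str = "control"
    n_replicates: int = field(default=3, init=False)  # triplicate spectra, fixed
    peak_width: float = 0.15  # Gaussian sigma of a rendered ion, m/z
    grid_step: float = 0.05  # profile sampling step, m/z

    def __post_init__(self) -> None:
        if self.n_discriminative > self.n_peaks:
            raise ValueError("n_discriminative cannot exceed n_peaks")
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be below mz_max")
        for name in ("n_group1", "n_group2", "n_peaks", "n_discriminative"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_segments = int((self.mz_max - self.mz_min) // _SEGMENT)
        if math.ceil(self.n_peaks / _PEAKS_PER_SEGMENT) > n_segments:
            raise ValueError("n_peaks too large for the m/z range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("n_replicates", None)
        return d


@dataclass
class GroundTruth:
    """Which bins carry the simulated effect and which group sits higher."""

    discriminative_bins: np.ndarray  # unit-m/z bin labels
    direction: list  # per bin: group label with the higher mean

    def __post_init__(self) -> None:
        self.discriminative_bins = np.asarray(self.discriminative_bins, dtype=float)
        if len(self.discriminative_bins) != len(self.direction):
            raise ValueError("one direction per discriminative bin required")
        if len(set(self.discriminative_bins.tolist())) != len(self.discriminative_bins):
            raise ValueError("discriminative bins must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mz_bin": self.discriminative_bins, "direction": self.direction}
        )


def render_profile(
    peak_areas: dict[float, float],
    peak_width: float = 0.15,
    grid_step: float = 0.05,
    mz_min: float = 400.0,
    mz_max: float = 2000.0,
    sample_id: str = "synthetic",
    replicate_index: int = 1,
) -> RawSpectrum:
    """Render a position -> area map as a profile trace of Gaussian ions.

    Each entry becomes a symmetric Gaussian of standard deviation
    ``peak_width`` centered on the given m/z, scaled so its numeric integral
    equals the requested area. ``peak_width`` must stay below 1 m/z so
    unit-spaced ions remain valley-separated, and ``grid_step`` must
    undersample the peak (grid_step < peak_width).
    """
    if not 0 < peak_width < 1:
        raise ValueError("peak_width must lie in (0, 1) m/z")
    if grid_step >= peak_width:
        raise ValueError("grid_step must be smaller than peak_width")
    n = int(round((mz_max - mz_min) / grid_step)) + 1
    mz = mz_min + np.arange(n) * grid_step
    y = np.zeros(n)
    norm = 1.0 / (peak_width * math.sqrt(2.0 * math.pi))
    half = int(math.ceil(6 * peak_width / grid_step))
    for center, area in peak_areas.items():
        if area == 0:
            continue
        c = int(round((center - mz_min) / grid_step))
        lo, hi = max(c - half, 0), min(c + half, n - 1)
        z = (mz[lo : hi + 1] - center) / peak_width
        y[lo : hi + 1] += area * norm * np.exp(-0.5 * z * z)
    return RawSpectrum(sample_id, replicate_index, mz, y)


def _place_bins(cfg: SimulationConfig, rng: np.random.Generator):
    """Choose occupied unit-m/z bins clustered inside normalization windows
    and split them into discriminative and anchor bins.

    Offsets 1-8 within each 10-m/z window are used so no ion (rendered at
    the bin center) nears a window boundary; one bin per window is
    protected as an anchor and the
    discriminative set is drawn from the rest (spilling into protected bins
    only when the configuration leaves no alternative).
    """
    n_segments = int((cfg.mz_max - cfg.mz_min) // _SEGMENT)
    n_seg = max(1, math.ceil(cfg.n_peaks / _PEAKS_PER_SEGMENT)) if cfg.n_peaks else 0
    seg_starts = cfg.mz_min + _SEGMENT * rng.choice(n_segments, size=n_seg, replace=False)
    counts = np.full(n_seg, cfg.n_peaks // n_seg) if n_seg else np.array([], int)
    if n_seg:
        counts[: cfg.n_peaks - counts.sum()] += 1
    bins, protected = [], []
    for start, cnt in zip(np.sort(seg_starts), counts):
        offsets = rng.choice(np.arange(1, 9), size=cnt, replace=False)
        seg_bins = np.sort(start + offsets)
        bins.extend(seg_bins.tolist())
        protected.append(seg_bins[rng.integers(len(seg_bins))])
    bins = np.asarray(bins)
    protected = set(np.asarray(protected).tolist())
    free = np.array([b for b in bins if b not in protected])
    rng.shuffle(free)
    if cfg.n_discriminative <= free.size:
        disc = free[: cfg.n_discriminative]
    else:
        extra = np.array(sorted(protected))
        rng.shuffle(extra)
        disc = np.concatenate([free, extra[: cfg.n_discriminative - free.size]])
    return np.sort(bins), np.sort(disc)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, list[RawSpectrum]], pd.DataFrame, GroundTruth]:
    """Simulate a two-group triplicate cohort.

    Returns the replicate profile spectra grouped by sample, the sample
    metadata table (sample_id, group, sex, age) and the ground truth.
    Identical configs (including seed) produce bit-identical cohorts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    bins, disc = _place_bins(cfg, rng)
    direction = rng.choice([cfg.group1_label, cfg.group2_label], size=disc.size)
    truth = GroundTruth(disc, list(direction))

    baseline = np.exp(rng.normal(math.log(50.0), 0.5, size=bins.size))
    is_disc = np.isin(bins, disc)
    up_g1 = np.zeros(bins.size, bool)
    up_g2 = np.zeros(bins.size, bool)
    d_idx = {b: g for b, g in zip(disc, direction)}
    for j, b in enumerate(bins):
        if is_disc[j]:
            (up_g1 if d_idx[b] == cfg.group1_label else up_g2)[j] = True
    fold = 2.0**cfg.effect_log2
    sigma_rep = math.sqrt(math.log(1.0 + cfg.replicate_cv**2))

    spectra: dict[str, list[RawSpectrum]] = {}
    meta_rows = []
    groups = [
        (cfg.group1_label, cfg.n_group1, up_g1, cfg.sex_ratio_g1, cfg.age_mean_g1, cfg.age_sd_g1),
        (cfg.group2_label, cfg.n_group2, up_g2, cfg.sex_ratio_g2, cfg.age_mean_g2, cfg.age_sd_g2),
    ]
    for label, n, up, sex_ratio, age_mean, age_sd in groups:
        for i in range(n):
            sid = f"{label}_{i + 1:03d}"
            true_area = baseline * np.exp(rng.normal(0.0, cfg.base_sigma_log, bins.size))
            true_area = np.where(up, true_area * fold, true_area)
            reps = []
            # ions sit at unit-bin centers (b + 0.5 under floor binning)
            positions = (bins + 0.5).tolist()
            for r in range(1, cfg.n_replicates + 1):
                rep = true_area * np.exp(rng.normal(0.0, sigma_rep, bins.size))
                reps.append(
                    render_profile(
                        dict(zip(positions, rep.tolist())),
                        peak_width=cfg.peak_width,
                        grid_step=cfg.grid_step,
                        mz_min=cfg.mz_min,
                        mz_max=cfg.mz_max,
                        sample_id=sid,
                        replicate_index=r,
                    )
                )
            spectra[sid] = reps
            meta_rows.append(
                {
                    "sample_id": sid,
                    "group": label,
                    "sex": "M" if rng.random() < sex_ratio else "F",
                    "age": round(float(np.clip(rng.normal(age_mean, age_sd), 5, 90)), 1),
                }
            )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return spectra, meta, truth


def generate_cohort_matrix(config: SimulationConfig):
    """Simulate a cohort and run it through the standard preprocessing
    pipeline; returns ``(PeakMatrix, GroundTruth)``."""
    from .preprocess import build_peak_matrix

    spectra, meta, truth = generate_cohort(config)
    matrix = build_peak_matrix(spectra, meta, anchor=config.mz_min)
    return matrix, truth
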