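"""Large-scale genomic alteration (LGA) calling from shallow-WGS copy ratios.

Pipeline, per sample: a binned linear copy-ratio profile (50 kb windows) is
segmented per chromosome by penalized least-squares change-point detection;
a per-profile minimal-CNA cutoff is estimated from the distribution of
pairwise level differences of large segments; adjacent segments closer than
the cutoff are merged; LGAs are counted per chromosome arm as breaks
between adjacent (gap < 3 Mb) retained segments (> 10 Mb each) whose levels
differ by at least the cutoff.  Samples with more than 20 LGAs are called
HRD, with fewer than 18 HRP, and 18-20 are flagged borderline for manual
review (never auto-resolved).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .genome import GenomeBuild, GenomicInterval, split_by_arm
from .segmentation import detect_breakpoints, estimate_noise_sd

HRD = "HRD"
HRP = "HRP"
BORDERLINE = "borderline"

DEFAULT_BIN_WIDTH = 50_000
DEFAULT_MIN_SEGMENT = 10_000_000
DEFAULT_MAX_GAP = 3_000_000

_BIN_COLUMNS = ["chrom", "start", "end", "ratio", "usable"]
_SEG_COLUMNS = ["chrom", "start", "end", "level", "n_bins"]


@dataclass
class BinnedProfile:
    """Ordered genomic bins of linear copy ratio for one sample."""

    sample_id: str
    bins: pd.DataFrame  # chrom, start, end, ratio, usable
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        missing = [c for c in _BIN_COLUMNS if c not in self.bins.columns]
        if missing:
            raise ValueError(f"binned profile missing columns: {missing}")
        self.bins = self.bins.reset_index(drop=True)
        usable = self.bins[self.bins["usable"].astype(bool)]
        if (usable["ratio"] <= 0).any():
            raise ValueError("usable bins must have ratio > 0")
        for _, grp in self.bins.groupby("chrom", sort=False):
            if not grp["start"].is_monotonic_increasing:
                raise ValueError("bins must be sorted by start within chromosome")
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError("bins overlap within chromosome")


@dataclass
class SegmentedProfile:
    """Piecewise-constant copy-ratio segments for one sample."""

    sample_id: str
    segments: pd.DataFrame  # chrom, start, end, level, n_bins
    residual_mad: float | None = None  # MAD of bin-level residuals, if known

    def __post_init__(self) -> None:
        missing = [c for c in _SEG_COLUMNS if c not in self.segments.columns]
        if missing:
            raise ValueError(f"segmented profile missing columns: {missing}")
        self.segments = self.segments.reset_index(drop=True)
        if (self.segments["n_bins"] < 1).any():
            raise ValueError("segments must contain at least one bin")
        if (self.segments["level"] <= 0).any():
            raise ValueError("segment levels must be > 0")


@dataclass(frozen=True)
class LevelCutoff:
    """Smallest copy-ratio difference regarded as a real copy-number change."""

    value: float
    method: str

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class LgaReport:
    sample_id: str
    per_arm: dict[str, int]
    lga_total: int
    classification: str
    parameters: dict = field(default_factory=dict)
    review_flag: str = ""  # free text, e.g. borderline/ploidy concerns

    def __post_init__(self) -> None:
        if self.lga_total != sum(self.per_arm.values()):
            raise ValueError("lga_total must equal the sum of per-arm counts")


def read_binned_profile(
    path: str | Path, sample_id: str | None = None, scale: str = "linear"
) -> BinnedProfile:
    """Read a binned-profile TSV (chrom, start, end, ratio, usable).

    ``scale="log2"`` declares log2 ratios in the file; they are converted to
    the linear scale on ingest (internal unit throughout).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if scale == "log2":
        df["ratio"] = 2.0 ** df["ratio"].astype(float)
    elif scale != "linear":
        raise ValueError("scale must be 'linear' or 'log2'")
    sid = sample_id or Path(path).stem
    return BinnedProfile(sid, df[_BIN_COLUMNS])


def write_segments(seg: SegmentedProfile, path: str | Path) -> None:
    out = seg.segments.copy()
    out.insert(0, "sample", seg.sample_id)
    out.to_csv(path, sep="\t", index=False)


def thin_probes(
    probes: pd.DataFrame, window: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Keep at most one probe per non-overlapping window per chromosome.

    ``probes`` has columns position, value and optionally chrom; positions
    must be sorted within each chromosome.  The retained probe is chosen
    uniformly at random within each window, reproducibly under ``seed``.
    Used to thin dense array profiles down to a sWGS-like density.
    """
    if probes.empty:
        return probes.copy()
    df = probes.copy()
    has_chrom = "chrom" in df.columns
    group_cols = ["chrom"] if has_chrom else []
    for _, grp in df.groupby("chrom", sort=False) if has_chrom else [(None, df)]:
        if not grp["position"].is_monotonic_increasing:
            raise ValueError("probes must be sorted by position within chromosome")
    rng = np.random.default_rng(seed)
    df["_win"] = df["position"] // window
    keep_idx = []
    for _, grp in df.groupby(group_cols + ["_win"], sort=False) if group_cols else df.groupby("_win", sort=False):
        keep_idx.append(grp.index[rng.integers(len(grp))])
    out = df.loc[sorted(keep_idx)].drop(columns="_win").reset_index(drop=True)
    return out


def _auto_penalty(values: np.ndarray) -> float:
    sigma = estimate_noise_sd(values)
    n = values.size
    return max(3.0 * sigma * sigma * np.log(max(n, 2)), 1e-9)


def segment_profile(
    profile: BinnedProfile, penalty: float | str = "auto"
) -> SegmentedProfile:
    """Segment each chromosome into piecewise-constant copy-ratio levels.

    ``penalty`` is the per-breakpoint cost of the least-squares objective;
    ``"auto"`` calibrates it from a robust noise estimate (3*sigma^2*log n).
    Chromosome boundaries are always breakpoints.
    """
    rows = []
    residuals = []
    for chrom, grp in profile.bins.groupby("chrom", sort=False):
        grp = grp[grp["usable"].astype(bool)]
        if grp.empty:
            continue
        vals = grp["ratio"].to_numpy(dtype=float)
        if isinstance(penalty, str):
            if penalty != "auto":
                raise ValueError("penalty must be a positive number or 'auto'")
            pen = _auto_penalty(vals)
        else:
            if penalty <= 0:
                raise ValueError("penalty must be positive")
            pen = float(penalty)
        bkps = detect_breakpoints(vals, pen)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        prev = 0
        for b in bkps:
            level = float(np.mean(vals[prev:b]))
            rows.append((chrom, int(starts[prev]), int(ends[b - 1]), level, b - prev))
            residuals.append(vals[prev:b] - level)
            prev = b
    seg = pd.DataFrame(rows, columns=_SEG_COLUMNS)
    if seg.empty:
        raise ValueError("profile has no usable bins")
    res = np.concatenate(residuals)
    mad = float(np.median(np.abs(res - np.median(res)))) if res.size else 0.0
    return SegmentedProfile(profile.sample_id, seg, residual_mad=mad)


def estimate_level_cutoff(
    seg: SegmentedProfile, large_segment: int = DEFAULT_MIN_SEGMENT
) -> LevelCutoff:
    """Estimate the per-profile minimal copy-number-change cutoff.

    Primary rule: the first local minimum of a kernel-density estimate of
    all pairwise level differences between large (>= 10 Mb) segments —
    the valley separating noise-scale differences from real CNA steps.
    Fallback when no usable valley exists: 3x the median absolute deviation
    of within-segment bin residuals.
    """
    segs = seg.segments
    if len(segs) < 2:
        raise ValueError(
            "cannot estimate a cutoff from a single segment; supply one explicitly"
        )
    large = segs[(segs["end"] - segs["start"]) >= large_segment]
    levels = large["level"].to_numpy(dtype=float)
    if levels.size >= 2:
        diffs = np.abs(levels[:, None] - levels[None, :])[
            np.triu_indices(levels.size, k=1)
        ]
        diffs = diffs[diffs >= 0]
        if np.ptp(diffs) > 0 and diffs.size >= 3:
            try:
                kde = gaussian_kde(diffs)
                grid = np.linspace(0.0, float(diffs.max()), 512)
                dens = kde(grid)
                for i in range(1, len(grid) - 1):
                    if dens[i] < dens[i - 1] and dens[i] <= dens[i + 1]:
                        if grid[i] > 0:
                            return LevelCutoff(float(grid[i]), "kde-valley")
                        break
            except np.linalg.LinAlgError:
                pass
    mad = seg.residual_mad if seg.residual_mad is not None else 0.0
    if mad <= 0:
        # last resort: scale of the smallest observed level difference
        lv = np.sort(segs["level"].to_numpy(dtype=float))
        gaps = np.diff(lv)
        gaps = gaps[gaps > 0]
        value = float(gaps.min()) / 2 if gaps.size else 1e-6
        return LevelCutoff(max(value, 1e-9), "min-gap-fallback")
    return LevelCutoff(3.0 * float(mad), "residual-mad")


def merge_segments(seg: SegmentedProfile, cutoff: LevelCutoff) -> SegmentedProfile:
    """Iteratively merge the closest adjacent same-chromosome segment pair.

    While any adjacent pair differs in level by less than the cutoff, the
    pair with the smallest difference is merged; the merged level is the
    n_bins-weighted mean.  Terminates at a fixed point.
    """
    out_rows = []
    for chrom, grp in seg.segments.groupby("chrom", sort=False):
        rows = [list(r) for r in grp[_SEG_COLUMNS].itertuples(index=False)]
        while len(rows) > 1:
            diffs = [abs(rows[i + 1][3] - rows[i][3]) for i in range(len(rows) - 1)]
            i = int(np.argmin(diffs))
            if diffs[i] >= cutoff.value:
                break
            a, b = rows[i], rows[i + 1]
            n = a[4] + b[4]
            level = (a[3] * a[4] + b[3] * b[4]) / n
            rows[i : i + 2] = [[chrom, a[1], b[2], level, n]]
        out_rows.extend(rows)
    merged = pd.DataFrame(out_rows, columns=_SEG_COLUMNS)
    return SegmentedProfile(seg.sample_id, merged, residual_mad=seg.residual_mad)


def classify_hrd(lga_total: int) -> str:
    """HRD if > 20 LGAs, HRP if < 18, borderline (manual review) in 18-20."""
    if lga_total < 0:
        raise ValueError("LGA count cannot be negative")
    if lga_total > 20:
        return HRD
    if lga_total < 18:
        return HRP
    return BORDERLINE


def call_lgas(
    seg: SegmentedProfile,
    genome: GenomeBuild,
    cutoff: LevelCutoff,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    max_gap: int = DEFAULT_MAX_GAP,
) -> LgaReport:
    """Count large-scale genomic alterations per chromosome arm.

    Per arm: segments are split at the centromere, arm-parts longer than
    ``min_segment`` (strict) are retained, and one LGA is counted for each
    consecutive retained pair whose genomic gap is below ``max_gap``
    (strict) and whose level difference reaches the cutoff.
    """
    arm_segs: dict[str, list[tuple[int, int, float]]] = {}
    for row in seg.segments.itertuples(index=False):
        if not genome.has_chromosome(row.chrom):
            raise ValueError(f"chromosome {row.chrom!r} absent from genome build")
        for arm, part in split_by_arm(
            GenomicInterval(row.chrom, int(row.start), int(row.end)), genome
        ):
            arm_segs.setdefault(arm, []).append((part.start, part.end, row.level))
    per_arm: dict[str, int] = {}
    for arm, parts in arm_segs.items():
        parts.sort()
        retained = [p for p in parts if p[1] - p[0] > min_segment]
        count = 0
        for (s0, e0, l0), (s1, e1, l1) in zip(retained, retained[1:]):
            if s1 - e0 < max_gap and abs(l1 - l0) >= cutoff.value:
                count += 1
        if count:
            per_arm[arm] = count
    total = sum(per_arm.values())
    cls = classify_hrd(total)
    flag = "manual review: borderline LGA count" if cls == BORDERLINE else ""
    return LgaReport(
        sample_id=seg.sample_id,
        per_arm=per_arm,
        lga_total=total,
        classification=cls,
        parameters={
            "min_segment": min_segment,
            "max_gap": max_gap,
            "cutoff": cutoff.value,
            "cutoff_method": cutoff.method,
        },
        review_flag=flag,
    )


def shallow_hrd_pipeline(
    profile: BinnedProfile,
    genome: GenomeBuild,
    penalty: float | str = "auto",
    cutoff: float | None = None,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[SegmentedProfile, LgaReport]:
    """Segment, estimate cutoff, merge, and call LGAs in one pass."""
    seg = segment_profile(profile, penalty=penalty)
    if cutoff is not None:
        cut = LevelCutoff(cutoff, "user")
    else:
        cut = estimate_level_cutoff(seg)
    merged = merge_segments(seg, cut)
    report = call_lgas(merged, genome, cut, min_segment=min_segment, max_gap=max_gap)
    return merged, report
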