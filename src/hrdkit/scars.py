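"""Allele-specific scar scores: LOH, TAI, LST and their sum.

Input is an allele-specific copy-number profile: ordered, non-overlapping
segments carrying total/major/minor copy number and a probe count.  After
smoothing away alterations shorter than 3 Mb:

* LOH   — number of loss-of-heterozygosity regions (minor copy number 0)
          spanning at least 15 Mb but less than the chromosome's assayed
          extent;
* TAI   — number of chromosome arms whose telomere-anchored segment run is
          allelically imbalanced over more than 500 probes while the
          segment adjacent to the centromere is balanced;
* LST   — number of allele-specific state changes between adjacent
          (gap < 3 Mb) segments of at least 10 Mb on the same arm.

The total (LOH + TAI + LST) is the array-based HRD scar score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genome import GenomeBuild, GenomicInterval, split_by_arm

DEFAULT_SMOOTH = 3_000_000
DEFAULT_LOH_MIN = 15_000_000
DEFAULT_LST_MIN = 10_000_000
DEFAULT_TAI_MIN_PROBES = 500


@dataclass(frozen=True)
class AllelicSegment:
    interval: GenomicInterval
    total_cn: int
    major_cn: int
    minor_cn: int
    n_probes: int

    def __post_init__(self) -> None:
        if not (self.major_cn >= self.minor_cn >= 0):
            raise ValueError("need major_cn >= minor_cn >= 0")
        if self.major_cn + self.minor_cn != self.total_cn:
            raise ValueError("major_cn + minor_cn must equal total_cn")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")

    @property
    def state(self) -> tuple[int, int]:
        return (self.major_cn, self.minor_cn)

    @property
    def balanced(self) -> bool:
        return self.major_cn == self.minor_cn

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class AllelicProfile:
    sample_id: str
    segments: list[AllelicSegment]

    def __post_init__(self) -> None:
        key = lambda s: (s.interval.chrom, s.interval.start)
        self.segments = sorted(self.segments, key=key)
        prev: AllelicSegment | None = None
        for s in self.segments:
            if prev is not None and prev.interval.chrom == s.interval.chrom:
                if s.interval.start < prev.interval.end:
                    raise ValueError(
                        f"overlapping segments on {s.interval.chrom} at {s.interval.start}"
                    )
            prev = s

    def by_chrom(self) -> dict[str, list[AllelicSegment]]:
        out: dict[str, list[AllelicSegment]] = {}
        for s in self.segments:
            out.setdefault(s.interval.chrom, []).append(s)
        return out


@dataclass(frozen=True)
class ScarScores:
    loh: int
    tai: int
    lst: int
    total: int

    def __post_init__(self) -> None:
        if min(self.loh, self.tai, self.lst) < 0:
            raise ValueError("scar components cannot be negative")
        if self.total != self.loh + self.tai + self.lst:
            raise ValueError("total must equal loh + tai + lst")


def read_allelic_profile(path: str | Path, sample_id: str | None = None) -> AllelicProfile:
    """Read an allelic-segment TSV: sample, chrom, start, end, total_cn, major_cn, minor_cn, n_probes."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if sample_id is not None and "sample" in df.columns:
        df = df[df["sample"] == sample_id]
    sid = sample_id or (str(df["sample"].iloc[0]) if "sample" in df.columns else Path(path).stem)
    segs = [
        AllelicSegment(
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            int(r.total_cn),
            int(r.major_cn),
            int(r.minor_cn),
            int(r.n_probes),
        )
        for r in df.itertuples(index=False)
    ]
    return AllelicProfile(sid, segs)


def smooth_small_alterations(
    profile: AllelicProfile, min_size: int = DEFAULT_SMOOTH
) -> AllelicProfile:
    """Drop segments shorter than ``min_size`` and fuse like-state flanks.

    Flanking segments with an identical (major, minor) state separated only
    by removed material or by gaps shorter than ``min_size`` are fused into
    one segment spanning the gap (probe counts summed).  Fusion runs both
    before removal (so a subdivided segment is first reassembled, keeping
    scores invariant under state-preserving splits) and after it.
    Idempotent.
    """

    def fuse(segs: list[AllelicSegment]) -> list[AllelicSegment]:
        fused: list[AllelicSegment] = []
        for s in segs:
            if fused:
                prev = fused[-1]
                gap = s.interval.start - prev.interval.end
                if prev.state == s.state and gap < min_size:
                    fused[-1] = AllelicSegment(
                        GenomicInterval(s.interval.chrom, prev.interval.start, s.interval.end),
                        prev.total_cn,
                        prev.major_cn,
                        prev.minor_cn,
                        prev.n_probes + s.n_probes,
                    )
                    continue
            fused.append(s)
        return fused

    out: list[AllelicSegment] = []
    for segs in profile.by_chrom().values():
        segs = fuse(segs)
        segs = [s for s in segs if s.length >= min_size]
        out.extend(fuse(segs))
    return AllelicProfile(profile.sample_id, out)


def score_loh(
    profile: AllelicProfile,
    genome: GenomeBuild,
    min_size: int = DEFAULT_LOH_MIN,
    contig_gap: int = DEFAULT_SMOOTH,
) -> int:
    """Count LOH regions >= ``min_size`` not covering the whole chromosome.

    A region is a maximal run of minor_cn = 0 segments with gaps below
    ``contig_gap``; its span is measured from the first to the last segment
    of the run.  Runs covering the chromosome's entire assayed extent are
    excluded.
    """
    count = 0
    for chrom, segs in profile.by_chrom().items():
        assayed_start = segs[0].interval.start
        assayed_end = segs[-1].interval.end
        runs: list[tuple[int, int]] = []
        cur: tuple[int, int] | None = None
        prev_end: int | None = None
        for s in segs:
            if s.minor_cn == 0:
                if cur is not None and prev_end is not None and s.interval.start - prev_end < contig_gap:
                    cur = (cur[0], s.interval.end)
                else:
                    if cur is not None:
                        runs.append(cur)
                    cur = (s.interval.start, s.interval.end)
                prev_end = s.interval.end
            else:
                if cur is not None:
                    runs.append(cur)
                    cur = None
                prev_end = None
        if cur is not None:
            runs.append(cur)
        for start, end in runs:
            if end - start >= min_size and not (start <= assayed_start and end >= assayed_end):
                count += 1
    return count


def _arm_segments(
    profile: AllelicProfile, genome: GenomeBuild
) -> dict[str, list[tuple[GenomicInterval, AllelicSegment]]]:
    """Segments split by arm; centromeric parts excised.  Keyed by arm id."""
    out: dict[str, list[tuple[GenomicInterval, AllelicSegment]]] = {}
    for s in profile.segments:
        for arm, part in split_by_arm(s.interval, genome):
            out.setdefault(arm, []).append((part, s))
    for parts in out.values():
        parts.sort(key=lambda t: t[0].start)
    return out


def score_tai(
    profile: AllelicProfile,
    genome: GenomeBuild,
    min_probes: int = DEFAULT_TAI_MIN_PROBES,
    contig_gap: int = DEFAULT_SMOOTH,
) -> int:
    """Count arms with telomeric allelic imbalance and centromeric balance.

    The telomere-anchored run is the maximal run of imbalanced segments
    containing the arm's outermost assayed segment (gaps < ``contig_gap``);
    it qualifies when its summed probe count exceeds ``min_probes``
    (strict) and the assayed segment nearest the centromere is balanced.
    Arms with no assayed segments are skipped.
    """
    count = 0
    for arm, parts in _arm_segments(profile, genome).items():
        if not parts:
            continue
        is_p = arm.endswith("p")
        # order from telomere inward: p arm telomere is position 0,
        # q arm telomere is the chromosome end
        ordered = parts if is_p else parts[::-1]
        # centromere-adjacent segment must be balanced
        if not ordered[-1][1].balanced:
            continue
        probes = 0
        prev_iv: GenomicInterval | None = None
        for iv, seg in ordered:
            if seg.balanced:
                break
            if prev_iv is not None:
                gap = (iv.start - prev_iv.end) if is_p else (prev_iv.start - iv.end)
                if gap >= contig_gap:
                    break
            probes += seg.n_probes
            prev_iv = iv
        if probes > min_probes:
            count += 1
    return count


def score_lst(
    profile: AllelicProfile,
    genome: GenomeBuild,
    min_segment: int = DEFAULT_LST_MIN,
    smooth: int = DEFAULT_SMOOTH,
    presmoothed: bool = False,
) -> int:
    """Count large-scale state transitions between adjacent >= 10 Mb segments.

    After smoothing alterations below ``smooth``, one LST is counted per
    consecutive pair of retained (>= ``min_segment``) arm segments whose
    gap is below ``smooth`` and whose (major, minor) states differ.
    """
    if not presmoothed:
        profile = smooth_small_alterations(profile, smooth)
    count = 0
    for arm, parts in _arm_segments(profile, genome).items():
        retained = [(iv, s) for iv, s in parts if iv.length >= min_segment]
        for (iv0, s0), (iv1, s1) in zip(retained, retained[1:]):
            if iv1.start - iv0.end < smooth and s0.state != s1.state:
                count += 1
    return count


def hrd_scar_score(
    profile: AllelicProfile,
    genome: GenomeBuild,
    loh_min: int = DEFAULT_LOH_MIN,
    tai_min_probes: int = DEFAULT_TAI_MIN_PROBES,
    lst_min: int = DEFAULT_LST_MIN,
    smooth: int = DEFAULT_SMOOTH,
) -> ScarScores:
    """Smooth once, compute LOH + TAI + LST on the same smoothed profile."""
    if not profile.segments:
        return ScarScores(0, 0, 0, 0)
    sm = smooth_small_alterations(profile, smooth)
    loh = score_loh(sm, genome, min_size=loh_min, contig_gap=smooth)
    tai = score_tai(sm, genome, min_probes=tai_min_probes, contig_gap=smooth)
    lst = score_lst(sm, genome, min_segment=lst_min, smooth=smooth, presmoothed=True)
    return ScarScores(loh, tai, lst, loh + tai + lst)
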