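"""LGA calling: probe thinning, cutoff estimation, merging, arm-break counts."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_segments
from hrdkit import synthetic
from hrdkit.genome import load_genome
from hrdkit.shallow_hrd import (
    BinnedProfile,
    LevelCutoff,
    SegmentedProfile,
    call_lgas,
    classify_hrd,
    estimate_level_cutoff,
    merge_segments,
    read_binned_profile,
    segment_profile,
    shallow_hrd_pipeline,
    thin_probes,
)

MB = 1_000_000


# ----------------------------------------------------------- probe thinning

def test_thin_probes_one_per_window():
    df = pd.DataFrame({"position": np.arange(10) * 500, "value": np.arange(10.0)})
    out = thin_probes(df, window=10_000, seed=1)
    assert len(out) == 1
    assert out["position"].iloc[0] in df["position"].values


def test_thin_probes_deterministic_under_seed():
    rng = np.random.default_rng(3)
    pos = np.sort(rng.integers(0, 500_000, 300))
    df = pd.DataFrame({"position": pos, "value": rng.normal(size=300)})
    a = thin_probes(df, seed=11)
    b = thin_probes(df, seed=11)
    pd.testing.assert_frame_equal(a, b)
    # windows respected: at most one probe per 10 kb
    assert (a["position"] // 10_000).is_unique


def test_thin_probes_empty_and_unsorted():
    empty = pd.DataFrame({"position": [], "value": []})
    assert thin_probes(empty, seed=0).empty
    bad = pd.DataFrame({"position": [100, 50], "value": [1.0, 2.0]})
    with pytest.raises(ValueError, match="sorted"):
        thin_probes(bad, seed=0)


# ------------------------------------------------------------- segmentation

def _profile_from_levels(levels_per_chrom, bin_width=50_000, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, levels in levels_per_chrom.items():
        vals = np.concatenate([np.full(n, lv) for lv, n in levels])
        vals = vals + rng.normal(0, noise, vals.size) if noise else vals
        starts = np.arange(vals.size) * bin_width
        for s, v in zip(starts, vals):
            rows.append((chrom, int(s), int(s + bin_width), float(v), 1))
    return BinnedProfile("t", pd.DataFrame(rows, columns=["chrom", "start", "end", "ratio", "usable"]))


def test_segment_profile_recovers_planted_steps():
    prof = _profile_from_levels({"1": [(1.0, 100), (1.5, 80), (1.0, 60), (2.0, 100)]})
    seg = segment_profile(prof)
    assert len(seg.segments) == 4
    assert list(seg.segments["n_bins"]) == [100, 80, 60, 100]
    assert np.allclose(seg.segments["level"], [1.0, 1.5, 1.0, 2.0])


def test_segment_profile_constant_per_chromosome():
    prof = _profile_from_levels({"1": [(1.0, 120)], "2": [(2.0, 90)]})
    seg = segment_profile(prof)
    assert len(seg.segments) == 2
    assert set(seg.segments["chrom"]) == {"1", "2"}


def test_segment_profile_rejects_bad_penalty():
    prof = _profile_from_levels({"1": [(1.0, 50)]})
    with pytest.raises(ValueError):
        segment_profile(prof, penalty=-1.0)


# --------------------------------------------------------- cutoff estimation

def test_cutoff_valley_between_noise_and_real_steps():
    # large segments at levels 1.0/1.5/2.0 with slight jitter
    rng = np.random.default_rng(5)
    rows = []
    pos = 0
    for i, base in enumerate([1.0, 1.5, 2.0] * 4):
        level = base + rng.normal(0, 0.02)
        rows.append(("1", pos, pos + 15 * MB, level, 300))
        pos += 15 * MB
    seg = SegmentedProfile("t", make_segments(rows), residual_mad=0.02)
    cut = estimate_level_cutoff(seg)
    assert 0.1 < cut.value < 0.5


def test_cutoff_cannot_exceed_only_gap():
    seg = SegmentedProfile(
        "t",
        make_segments([("1", 0, 20 * MB, 1.0, 400), ("1", 20 * MB, 40 * MB, 2.0, 400)]),
        residual_mad=0.01,
    )
    cut = estimate_level_cutoff(seg)
    assert cut.value <= 1.0


def test_cutoff_fallback_is_three_mad():
    seg = SegmentedProfile(
        "t",
        make_segments([("1", 0, 20 * MB, 1.0, 400), ("1", 20 * MB, 40 * MB, 1.0, 400)]),
        residual_mad=0.01,
    )
    cut = estimate_level_cutoff(seg)
    assert cut.method == "residual-mad"
    assert cut.value == pytest.approx(0.03)


def test_cutoff_requires_two_segments():
    seg = SegmentedProfile("t", make_segments([("1", 0, 20 * MB, 1.0, 400)]))
    with pytest.raises(ValueError, match="cutoff"):
        estimate_level_cutoff(seg)


# ------------------------------------------------------------------ merging

def test_merge_below_cutoff():
    seg = SegmentedProfile(
        "t", make_segments([("1", 0, MB, 1.00, 10), ("1", MB, 2 * MB, 1.02, 10)])
    )
    out = merge_segments(seg, LevelCutoff(0.1, "user"))
    assert len(out.segments) == 1
    assert out.segments["level"].iloc[0] == pytest.approx(1.01)
    assert out.segments["n_bins"].iloc[0] == 20


def test_merge_above_cutoff_unchanged():
    seg = SegmentedProfile(
        "t", make_segments([("1", 0, MB, 1.0, 10), ("1", MB, 2 * MB, 1.6, 10)])
    )
    out = merge_segments(seg, LevelCutoff(0.5, "user"))
    assert len(out.segments) == 2


def test_merge_chain_is_iterative_fixed_point():
    # iterative merging cascades: after fusing 1.00/1.02 the 1.01 mean is
    # still within the cutoff of 1.05, so the chain collapses fully
    seg = SegmentedProfile(
        "t",
        make_segments(
            [("1", 0, MB, 1.00, 10), ("1", MB, 2 * MB, 1.02, 10), ("1", 2 * MB, 3 * MB, 1.05, 10)]
        ),
    )
    out = merge_segments(seg, LevelCutoff(0.05, "user"))
    assert len(out.segments) == 1
    # whereas a wider chain stops once the weighted mean drifts out of range
    seg2 = SegmentedProfile(
        "t",
        make_segments(
            [("1", 0, MB, 1.00, 10), ("1", MB, 2 * MB, 1.04, 10), ("1", 2 * MB, 3 * MB, 1.08, 10)]
        ),
    )
    assert len(merge_segments(seg2, LevelCutoff(0.05, "user")).segments) == 2

    # brute force: every greedy merge order reaches the same segment count
    def brute(levels, nbins, cutoff):
        import itertools

        states = {tuple(zip(levels, nbins))}
        terminal = set()
        while states:
            st_ = states.pop()
            pairs = [
                i for i in range(len(st_) - 1) if abs(st_[i + 1][0] - st_[i][0]) < cutoff
            ]
            if not pairs:
                terminal.add(len(st_))
                continue
            for i in pairs:
                a, b = st_[i], st_[i + 1]
                n = a[1] + b[1]
                merged = ((a[0] * a[1] + b[0] * b[1]) / n, n)
                states.add(st_[:i] + (merged,) + st_[i + 2 :])
        return terminal

    assert brute([1.00, 1.02, 1.05], [10, 10, 10], 0.05) == {1}
    assert brute([1.00, 1.04, 1.08], [10, 10, 10], 0.05) == {2}


# ---------------------------------------------------------------- LGA calls

def _seg_profile(rows):
    return SegmentedProfile("t", make_segments(rows))


def test_two_qualifying_breaks(toy_genome):
    seg = _seg_profile(
        [("1", 0, 20 * MB, 2.0, 400), ("1", 20 * MB, 35 * MB, 3.0, 300), ("1", 35 * MB, 50 * MB, 2.0, 300)]
    )
    rep = call_lgas(seg, toy_genome, LevelCutoff(0.5, "user"))
    assert rep.lga_total == 2
    assert rep.per_arm == {"1p": 2}


def test_dropped_small_segment_opens_gap(toy_genome):
    seg = _seg_profile(
        [("1", 0, 20 * MB, 2.0, 400), ("1", 20 * MB, 28 * MB, 3.0, 160), ("1", 28 * MB, 45 * MB, 2.0, 340)]
    )
    rep = call_lgas(seg, toy_genome, LevelCutoff(0.5, "user"))
    assert rep.lga_total == 0


def test_break_below_cutoff_not_counted(toy_genome):
    seg = _seg_profile(
        [("1", 0, 20 * MB, 2.0, 400), ("1", 20 * MB, 40 * MB, 2.2, 400)]
    )
    assert call_lgas(seg, toy_genome, LevelCutoff(0.5, "user")).lga_total == 0


def test_missing_chromosome_raises(toy_genome):
    seg = _seg_profile([("9", 0, 20 * MB, 2.0, 400), ("9", 20 * MB, 40 * MB, 3.0, 400)])
    with pytest.raises(ValueError, match="'9'"):
        call_lgas(seg, toy_genome, LevelCutoff(0.5, "user"))


def _random_seg_profile(rng, genome):
    rows = []
    for chrom in genome.chromosomes:
        pos = 0
        while pos < chrom.length - 5 * MB:
            length = int(rng.integers(2 * MB, 30 * MB))
            end = min(pos + length, chrom.length)
            gap = int(rng.integers(0, 6 * MB)) if rng.random() < 0.3 else 0
            level = float(rng.choice([1.0, 1.5, 2.0, 2.5, 3.0]))
            rows.append((chrom.name, pos, end, level, max(1, (end - pos) // 50_000)))
            pos = end + gap
    return _seg_profile(rows)


def brute_force_lga(seg, genome, cutoff, min_segment=10 * MB, max_gap=3 * MB):
    """Independent reference: explicit per-arm double loop over retained pairs."""
    from hrdkit.genome import GenomicInterval, split_by_arm

    total = 0
    arms = {}
    for r in seg.segments.itertuples(index=False):
        for arm, part in split_by_arm(GenomicInterval(r.chrom, int(r.start), int(r.end)), genome):
            arms.setdefault(arm, []).append((part.start, part.end, float(r.level)))
    for arm, parts in arms.items():
        retained = sorted(p for p in parts if p[1] - p[0] > min_segment)
        for i in range(len(retained) - 1):
            j = i + 1
            gap = retained[j][0] - retained[i][1]
            if gap < max_gap and abs(retained[j][2] - retained[i][2]) >= cutoff:
                total += 1
    return total


def test_lga_scan_agrees_with_bruteforce_on_random_profiles(toy_genome):
    rng = np.random.default_rng(99)
    cutoff = LevelCutoff(0.4, "user")
    for _ in range(1000):
        seg = _random_seg_profile(rng, toy_genome)
        got = call_lgas(seg, toy_genome, cutoff).lga_total
        assert got == brute_force_lga(seg, toy_genome, 0.4)


def test_lga_invariant_under_chromosome_reordering(toy_genome):
    rng = np.random.default_rng(5)
    seg = _random_seg_profile(rng, toy_genome)
    shuffled = SegmentedProfile(
        "t", seg.segments.sample(frac=1.0, random_state=1).sort_values(["chrom", "start"]).reset_index(drop=True)
    )
    cut = LevelCutoff(0.4, "user")
    assert call_lgas(seg, toy_genome, cut).lga_total == call_lgas(shuffled, toy_genome, cut).lga_total


def test_lga_monotone_in_gap_and_min_segment(toy_genome):
    rng = np.random.default_rng(17)
    cut = LevelCutoff(0.4, "user")
    for _ in range(50):
        seg = _random_seg_profile(rng, toy_genome)
        base = call_lgas(seg, toy_genome, cut).lga_total
        assert call_lgas(seg, toy_genome, cut, max_gap=1 * MB).lga_total <= base
        assert call_lgas(seg, toy_genome, cut, min_segment=15 * MB).lga_total <= base


# ------------------------------------------------------------ classification

@pytest.mark.parametrize(
    "n,expected",
    [(0, "HRP"), (17, "HRP"), (18, "borderline"), (19, "borderline"),
     (20, "borderline"), (21, "HRD"), (30, "HRD")],
)
def test_classify_hrd_boundaries(n, expected):
    assert classify_hrd(n) == expected


def test_classify_hrd_rejects_negative():
    with pytest.raises(ValueError):
        classify_hrd(-1)


# ------------------------------------------------------------- end to end

def test_end_to_end_planted_breaks_recovered(toy_genome):
    rng = np.random.default_rng(2)
    breaks = synthetic.plan_lga_breaks(25, toy_genome, rng)
    profile, truth = synthetic.simulate_binned_profile(breaks, toy_genome, noise_sd=0.0, seed=4)
    _, report = shallow_hrd_pipeline(profile, toy_genome)
    assert report.lga_total == truth == 25
    assert report.classification == "HRD"


def test_log2_reader_roundtrip(tmp_path, toy_genome):
    prof = _profile_from_levels({"1": [(1.0, 50), (2.0, 50)]})
    df = prof.bins.copy()
    df["ratio"] = np.log2(df["ratio"])
    p = tmp_path / "bins.tsv"
    df.to_csv(p, sep="\t", index=False)
    back = read_binned_profile(p, scale="log2")
    assert np.allclose(back.bins["ratio"], prof.bins["ratio"])
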