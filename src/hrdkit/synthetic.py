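"""Synthetic-cohort generator with recorded ground truth.

The study data this pipeline was designed around are access-restricted,
so every input format the pipeline consumes can be generated here with
known truth: binned copy-ratio profiles with planted arm breaks, allelic
profiles with planted LOH/TAI/LST events, exponential tumour-growth
trajectories with category-specific treatment effects, RAD51 foci-count
mixtures, variant tables with per-rule violations, expression matrices
with planted deletions plus their fusion calls, and a linked annotation
table.  All randomness flows from one root seed via named substreams.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBuild, GenomicInterval
from .scars import AllelicProfile, AllelicSegment
from .shallow_hrd import BinnedProfile, classify_hrd

# geometry constants for planted events (bp)
_GAP = 3_500_000  # unassayed separator: breaks 3 Mb adjacency on both sides
_LEADER = 5_000_000  # balanced telomeric leader, prevents accidental TAI
_TAI_LEN = 30_000_000
_LOH_LEN = 20_000_000
_LST_LEN = 12_000_000  # per half; an LST block is two adjacent halves
_FILLER_MIN = 4_000_000
_PROBE_SPACING = 50_000


@dataclass
class CohortSpec:
    """Study-condition defaults for the simulated PDX cohort.

    Response probabilities and the HRD prevalence are calibrated so the
    expected marginals match the study cohort (55 models, 30 HRD, ~29
    responders including SD); LGA-count distributions place HRD models
    above and HRP models below the 18-20 borderline band.
    """

    n_models: int = 55
    hrd_prevalence: float = 30 / 55
    response_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "HRD": {"CR": 0.30, "PR": 0.17, "SD": 0.23, "PD": 0.30},
            "HRP": {"CR": 0.04, "PR": 0.0, "SD": 0.28, "PD": 0.68},
        }
    )
    # LGA counts: HRD shifted Poisson (min 21), HRP capped Poisson (max 17)
    lga_hrd_min: int = 21
    lga_hrd_poisson_mean: float = 9.0
    lga_hrp_poisson_mean: float = 8.0
    lga_hrp_max: int = 17
    # scar events scale with the planted LGA count (shared latent state)
    scar_per_lga: tuple[float, float, float] = (0.20, 0.15, 0.35)  # loh, tai, lst
    bin_width: int = 50_000
    profile_noise_sd: float = 0.05  # 10% of the 0.5 planted level step
    # growth model
    mice_per_arm: int = 8
    schedule_days: tuple[float, ...] = (0, 3, 7, 10, 14, 17, 21, 24, 28, 31, 35, 38, 42)
    measurement_cv: float = 0.10  # multiplicative lognormal noise
    ethical_volume: float = 2000.0
    v0_range: tuple[float, float] = (60.0, 200.0)
    # RAD51 foci mixtures
    cells_per_sample: int = 200
    foci_mean_deficient: float = 1.0
    foci_mean_proficient: float = 9.0
    treated_samples_per_model: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for state, probs in self.response_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"response probabilities for {state} must sum to 1")
        if not (0.0 <= self.hrd_prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")
        if not any(d >= 14 for d in self.schedule_days):
            raise ValueError("measurement schedule needs a day >= 14")


def _substream(seed: int, name: str) -> np.random.Generator:
    # stable across processes (unlike built-in str hashing)
    ss = np.random.SeedSequence([seed, zlib.crc32(name.encode()) % (2**31)])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------- LGA profiles

def plan_lga_breaks(total: int, genome: GenomeBuild, rng: np.random.Generator) -> dict[str, int]:
    """Distribute a requested LGA count over arms, respecting capacity.

    Capacity per arm: k breaks need k+1 retained segments of > 10 Mb.
    """
    arms = genome.arms()
    caps = {}
    for arm, iv in arms:
        cap = iv.length // 10_500_000 - 1
        caps[arm] = max(0, int(cap))
    if total > sum(caps.values()):
        raise ValueError(
            f"cannot plant {total} breaks: genome capacity is {sum(caps.values())}"
        )
    counts = {arm: 0 for arm, _ in arms}
    remaining = total
    while remaining > 0:
        open_arms = [a for a, _ in arms if counts[a] < caps[a]]
        counts[open_arms[int(rng.integers(len(open_arms)))]] += 1
        remaining -= 1
    return {a: c for a, c in counts.items() if c > 0}


def simulate_binned_profile(
    planted_breaks: dict[str, int],
    genome: GenomeBuild,
    bin_width: int = 50_000,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "sim",
) -> tuple[BinnedProfile, int]:
    """Piecewise-constant copy-ratio profile with planted qualifying breaks.

    Each arm with k planted breaks carries k+1 equal segments (> 10 Mb
    each, zero gap) alternating between levels 2.0 and 2.5; Gaussian noise
    of ``noise_sd`` is added per bin.  Centromeric bins are marked
    unusable.  Returns the profile and the planted truth count.
    """
    rng = np.random.default_rng(seed)
    arm_map = dict(genome.arms())
    for arm in planted_breaks:
        if arm not in arm_map:
            raise ValueError(f"unknown arm {arm!r}")
        cap = arm_map[arm].length // 10_500_000 - 1
        if planted_breaks[arm] > cap:
            raise ValueError(f"arm {arm}: {planted_breaks[arm]} breaks exceed capacity {cap}")
    rows = []
    for chrom in genome.chromosomes:
        n_bins = chrom.length // bin_width
        starts = np.arange(n_bins) * bin_width
        ends = starts + bin_width
        levels = np.full(n_bins, 2.0)
        usable = np.ones(n_bins, dtype=int)
        # centromere bins unusable
        in_cen = (starts < chrom.cen_end) & (ends > chrom.cen_start)
        usable[in_cen] = 0
        for arm_suffix, a_start, a_end in (
            ("p", 0, chrom.cen_start),
            ("q", chrom.cen_end, chrom.length),
        ):
            arm = f"{chrom.name}{arm_suffix}"
            k = planted_breaks.get(arm, 0)
            if k == 0:
                continue
            lo = int(np.ceil(a_start / bin_width))
            hi = int(a_end // bin_width)
            seg_bins = (hi - lo) // (k + 1)
            for j in range(k + 1):
                b0 = lo + j * seg_bins
                b1 = lo + (j + 1) * seg_bins if j < k else hi
                levels[b0:b1] = 2.0 if j % 2 == 0 else 2.5
        ratios = levels + (rng.normal(0.0, noise_sd, n_bins) if noise_sd > 0 else 0.0)
        ratios = np.clip(ratios, 1e-3, None)
        for i in range(n_bins):
            rows.append((chrom.name, int(starts[i]), int(ends[i]), float(ratios[i]), int(usable[i])))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "ratio", "usable"])
    return BinnedProfile(sample_id, bins, bin_width=bin_width), int(sum(planted_breaks.values()))


# ------------------------------------------------------------- allelic scars

def _probes(length: int) -> int:
    return max(1, length // _PROBE_SPACING)


def simulate_allelic_profile(
    loh: int,
    tai: int,
    lst: int,
    genome: GenomeBuild,
    seed: int = 0,
    sample_id: str = "sim",
    plant_decoys: bool = False,
) -> tuple[AllelicProfile, tuple[int, int, int]]:
    """Allelic profile where each planted event scores exactly once.

    Events are laid out arm by arm with >= 3 Mb unassayed separators so no
    event interferes with another's criterion: a balanced telomeric leader
    prevents accidental TAI, every arm ends in a balanced segment at the
    centromeric side, LOH regions are interior 20 Mb minor=0 segments, TAI
    events are telomere-anchored imbalanced 30 Mb segments, and LST events
    are adjacent balanced-state pairs.  Optional decoys plant sub-threshold
    events (10 Mb LOH, 300-probe TAI, 8 Mb LST pair) that must not score.
    """
    rng = np.random.default_rng(seed)
    need = {"tai": tai, "loh": loh, "lst": lst}
    decoys = {"loh": 1, "tai": 1, "lst": 1} if plant_decoys else {"loh": 0, "tai": 0, "lst": 0}
    segments: list[AllelicSegment] = []
    arms = genome.arms()
    order = rng.permutation(len(arms))
    for idx in order:
        arm, iv = arms[int(idx)]
        is_p = arm.endswith("p")
        # build blocks from telomere inward; each entry is a list of
        # (length, major, minor, n_probes) laid out contiguously
        blocks: list[list[tuple[int, int, int, int]]] = []
        budget = iv.length
        used = 0

        def fits(extra: int) -> bool:
            # room for blocks so far + candidate + trailing gap + filler
            return used + extra + _GAP + _FILLER_MIN <= budget

        # telomeric block: TAI event, TAI decoy, or balanced leader
        if need["tai"] > 0 and fits(_TAI_LEN + _GAP):
            blocks.append([(_TAI_LEN, 2, 1, _probes(_TAI_LEN))])
            used += _TAI_LEN + _GAP
            need["tai"] -= 1
        elif decoys["tai"] > 0 and fits(_TAI_LEN + _GAP):
            # imbalanced telomeric run with too few probes: must not score
            blocks.append([(_TAI_LEN, 2, 1, 300)])
            used += _TAI_LEN + _GAP
            decoys["tai"] -= 1
        else:
            blocks.append([(_LEADER, 1, 1, _probes(_LEADER))])
            used += _LEADER + _GAP
        # interior blocks
        while True:
            if need["lst"] > 0 and fits(2 * _LST_LEN + _GAP):
                blocks.append(
                    [
                        (_LST_LEN, 1, 1, _probes(_LST_LEN)),
                        (_LST_LEN, 2, 2, _probes(_LST_LEN)),
                    ]
                )
                used += 2 * _LST_LEN + _GAP
                need["lst"] -= 1
            elif need["loh"] > 0 and fits(_LOH_LEN + _GAP):
                blocks.append([(_LOH_LEN, 2, 0, _probes(_LOH_LEN))])
                used += _LOH_LEN + _GAP
                need["loh"] -= 1
            elif decoys["loh"] > 0 and fits(10_000_000 + _GAP):
                blocks.append([(10_000_000, 2, 0, _probes(10_000_000))])
                used += 10_000_000 + _GAP
                decoys["loh"] -= 1
            elif decoys["lst"] > 0 and fits(2 * 8_000_000 + _GAP):
                blocks.append(
                    [(8_000_000, 1, 1, _probes(8_000_000)), (8_000_000, 2, 2, _probes(8_000_000))]
                )
                used += 2 * 8_000_000 + _GAP
                decoys["lst"] -= 1
            else:
                break
        # balanced filler adjacent to the centromere
        filler = budget - used
        blocks.append([(filler, 1, 1, _probes(filler))])

        # lay out in coordinates: p arm from start forward, q arm from end back
        cursor = iv.start if is_p else iv.end
        for block in blocks:
            if is_p:
                for length, major, minor, probes in block:
                    seg_iv = GenomicInterval(iv.chrom, cursor, cursor + length)
                    segments.append(AllelicSegment(seg_iv, major + minor, major, minor, probes))
                    cursor += length
                cursor += _GAP
            else:
                for length, major, minor, probes in block:
                    seg_iv = GenomicInterval(iv.chrom, cursor - length, cursor)
                    segments.append(AllelicSegment(seg_iv, major + minor, major, minor, probes))
                    cursor -= length
                cursor -= _GAP
    if need["loh"] or need["tai"] or need["lst"]:
        raise ValueError(
            f"genome too small for requested events; left over: {need} "
            f"(requested loh={loh}, tai={tai}, lst={lst})"
        )
    return AllelicProfile(sample_id, segments), (loh, tai, lst)


# ------------------------------------------------------------- tumour growth

_CATEGORY_RATES = {
    # per-day exponential rates for treated arms; chosen so the noise-free
    # trajectory lands safely inside its category's classification box
    "CR": -0.28,
    "PR": None,  # plateau model below
    "SD": -0.005,
    "PD": 0.08,
}


def _treated_volume(category: str, v0: float, t: np.ndarray) -> np.ndarray:
    if category == "CR":
        return v0 * np.exp(_CATEGORY_RATES["CR"] * t)
    if category == "PR":
        # decay to ~30% of V0
        return v0 * (0.30 + 0.70 * np.exp(-0.25 * t))
    if category == "SD":
        return v0 * np.exp(_CATEGORY_RATES["SD"] * t)
    if category == "PD":
        return v0 * np.exp(_CATEGORY_RATES["PD"] * t)
    raise ValueError(f"unknown category {category!r}")


def simulate_growth_cohort(
    truth: pd.DataFrame, spec: CohortSpec, seed: int = 0
) -> pd.DataFrame:
    """Measurement table for a cohort with known per-model categories.

    ``truth`` needs columns pdx and response_category.  Control arms grow
    exponentially (lognormal rate across mice); treated arms follow
    category-specific trajectories with multiplicative measurement noise;
    mice are dropped from the schedule once they exceed the ethical
    volume (the over-limit measurement is kept, later ones are not).
    Volumes are emitted as perpendicular diameters (a_mm, b_mm) with
    b = 0.8 a, so V = a*b^2/2 reproduces the intended volume.
    """
    rng = _substream(seed, "growth")
    days = np.asarray(spec.schedule_days, dtype=float)
    rows = []
    for r in truth.itertuples(index=False):
        category = r.response_category
        for arm in ("control", "treated"):
            for m in range(spec.mice_per_arm):
                mouse = f"{r.pdx}_{arm}_{m}"
                v0 = rng.uniform(*spec.v0_range)
                if arm == "control":
                    rate = float(np.exp(rng.normal(np.log(0.07), 0.25)))
                    vols = v0 * np.exp(rate * days)
                else:
                    vols = _treated_volume(category, v0, days)
                noise = np.exp(rng.normal(0.0, spec.measurement_cv, days.size))
                noise[0] = 1.0  # V0 defines the baseline
                vols = vols * noise
                over = np.nonzero(vols > spec.ethical_volume)[0]
                last = over[0] if over.size else days.size - 1
                for i in range(last + 1):
                    a = (2.0 * vols[i] / 0.64) ** (1.0 / 3.0)
                    b = 0.8 * a
                    rows.append((r.pdx, mouse, arm, float(days[i]), a, b))
    return pd.DataFrame(rows, columns=["pdx", "mouse", "arm", "day", "a_mm", "b_mm"])


# -------------------------------------------------------------- cohort truth

def simulate_cohort_annotations(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Per-model truth: HRD state, planted LGA count, scar counts, category.

    This is the statistical core of the cohort (used directly for power
    studies); file-level generators consume it to emit concrete inputs.
    """
    rng = _substream(seed, "cohort")
    rows = []
    categories = ("CR", "PR", "SD", "PD")
    for i in range(spec.n_models):
        hrd = bool(rng.random() < spec.hrd_prevalence)
        state = "HRD" if hrd else "HRP"
        if hrd:
            lga = spec.lga_hrd_min + int(rng.poisson(spec.lga_hrd_poisson_mean))
        else:
            lga = min(int(rng.poisson(spec.lga_hrp_poisson_mean)), spec.lga_hrp_max)
        probs = [spec.response_probs[state][c] for c in categories]
        category = categories[int(rng.choice(len(categories), p=probs))]
        r_loh, r_tai, r_lst = spec.scar_per_lga
        loh = int(rng.poisson(r_loh * lga))
        tai = int(rng.poisson(r_tai * lga))
        lst = int(rng.poisson(r_lst * lga))
        # biomarkers conditional on state
        brca = bool(hrd and rng.random() < 0.43)
        meth_pct = 0.0
        if hrd and not brca and rng.random() < 0.8:
            meth_pct = float(rng.uniform(90, 100) if rng.random() < 0.65 else rng.uniform(40, 60))
        rad51_deficient = bool(
            rng.random() < (0.75 if hrd else 0.05)
        )
        responder = category in ("CR", "PR", "SD")
        surv_scale = 2000.0 if responder else 600.0
        survival = float(max(30.0, rng.exponential(surv_scale)))
        death = bool(rng.random() < 0.6)
        rows.append(
            (
                f"PDX{i + 1:03d}", state, lga, classify_hrd(lga), loh, tai, lst,
                loh + tai + lst, category, int(brca), meth_pct,
                "HR-deficient" if rad51_deficient else "HR-proficient",
                survival, int(death),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pdx", "true_state", "lga_planted", "hrd_class_planted",
            "loh_planted", "tai_planted", "lst_planted", "scar_total_planted",
            "response_category", "brca_mutated_loh", "methylation_percent",
            "rad51_status", "survival_days", "death_event",
        ],
    )


# ---------------------------------------------------------------- aux tables

def simulate_foci_table(truth: pd.DataFrame, spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Per-cell RAD51 foci counts from state-conditional Poisson mixtures."""
    rng = _substream(seed, "foci")
    rows = []
    for r in truth.itertuples(index=False):
        deficient = r.rad51_status == "HR-deficient"
        for arm in ("control", "treated"):
            for s in range(spec.treated_samples_per_model):
                sample = f"{r.pdx}_{arm}_{s}"
                if arm == "treated" and not deficient:
                    mean = spec.foci_mean_proficient
                else:
                    mean = spec.foci_mean_deficient
                counts = rng.poisson(mean, spec.cells_per_sample)
                for cell, fc in enumerate(counts):
                    rows.append((r.pdx, sample, arm, cell, 1, int(fc)))
    return pd.DataFrame(
        rows, columns=["pdx", "sample", "arm", "cell_id", "marker_positive", "foci_count"]
    )


_RULE_VIOLATIONS = (
    "none", "min_alt_depth", "min_alt_freq", "clinsig_benign", "synonymous",
    "func_class", "pop_freq", "predictor_vote",
)


def simulate_variant_table(seed: int = 0, n_per_rule: int = 3) -> pd.DataFrame:
    """Variant rows each violating exactly one WES rule (or none).

    The ``truth_violation`` column records the planted verdict; a
    recurrent key planted across 5 samples carries ``recurrent``.
    """
    rng = _substream(seed, "variants")
    rows = []
    pos = 1_000_000
    damaging = {"SIFT": "Deleterious", "Polyphen2_HDIV": "Probably_damaging",
                "MutationAssessor": "High", "MetaSVM": "Damaging", "FATHMM": "Damaging"}

    def base(sample, gene, p, **kw):
        d = dict(
            sample=sample, gene=gene, chrom="17", pos=p, ref="C", alt="T",
            total_depth=120, alt_depth=48, alt_freq=0.40, func_class="exonic",
            exonic_class="nonsynonymous_SNV", clinsig="", popfreq_1000g=0.0,
            popfreq_gnomad=0.0,
        )
        d.update({f"pred_{k}": v for k, v in damaging.items()})
        d.update(kw)
        return d

    for rule in _RULE_VIOLATIONS:
        for i in range(n_per_rule):
            pos += 1000 + int(rng.integers(100))
            sample = f"S{i + 1}"
            gene = "BRCA1"
            if rule == "none":
                d = base(sample, gene, pos)
            elif rule == "min_alt_depth":
                d = base(sample, gene, pos, alt_depth=1, total_depth=2, alt_freq=0.5)
            elif rule == "min_alt_freq":
                d = base(sample, gene, pos, alt_depth=10, alt_freq=0.10)
            elif rule == "clinsig_benign":
                d = base(sample, gene, pos, clinsig="Benign")
            elif rule == "synonymous":
                d = base(sample, gene, pos, exonic_class="synonymous_SNV")
            elif rule == "func_class":
                d = base(sample, gene, pos, func_class="intronic")
            elif rule == "pop_freq":
                d = base(sample, gene, pos, popfreq_gnomad=0.01)
            elif rule == "predictor_vote":
                d = base(sample, gene, pos, pred_SIFT="Tolerated",
                         pred_Polyphen2_HDIV="Possibly_damaging", pred_MetaSVM="Neutral")
            d["truth_violation"] = rule
            rows.append(d)
    # one recurrent key across 5 samples
    pos += 5000
    for i in range(5):
        d = base(f"S{i + 1}", "TP53", pos)
        d["truth_violation"] = "recurrent"
        rows.append(d)
    return pd.DataFrame(rows)


def simulate_expression_with_deletion(
    n_samples: int = 30,
    n_genes: int = 50,
    seed: int = 0,
    deleted_sample: str = "S01",
    depletion: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Counts matrix with one planted deletion plus its fusion call.

    Genes sit on chromosome 14 at 100 kb spacing; the deletion spans six
    genes (among them a DDR gene) between the fusion partners, whose
    counts are scaled by ``depletion`` in the deleted sample.  The region
    is kept several genes wide because the expression verdict is
    rank-based: a sample lands at or below the 10th percentile of every
    region gene by chance with probability ~0.1^k, so specificity rests
    on k.  Returns (counts, gene bed, fusion table, deleted genes).
    """
    rng = _substream(seed, "expression")
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    genes = [f"G{i:03d}" for i in range(n_genes)]
    # place the fusion partners and the spanned DDR gene mid-chromosome
    gene_names = list(genes)
    i_a, i_b = 20, 27  # partners; genes 21-26 are inside the region
    gene_names[i_a] = "APOPT1"
    gene_names[i_b] = "ZFYVE21"
    gene_names[21] = "XRCC3"
    base = rng.uniform(200, 2000, n_genes)
    counts = rng.poisson(base[:, None], (n_genes, n_samples)).astype(float)
    counts = pd.DataFrame(counts, index=gene_names, columns=samples)
    starts = 20_000_000 + np.arange(n_genes) * 100_000
    bed = pd.DataFrame(
        {"chrom": "14", "start": starts, "end": starts + 50_000, "gene": gene_names}
    )
    deleted = gene_names[i_a + 1 : i_b]
    counts.loc[deleted, deleted_sample] *= depletion
    fusion = pd.DataFrame(
        [
            {
                "sample": deleted_sample,
                "geneA": "APOPT1", "chromA": "14", "posA": int(starts[i_a] + 50_000),
                "geneB": "ZFYVE21", "chromB": "14", "posB": int(starts[i_b]),
                "junction_reads": 25,
            }
        ]
    )
    return counts, bed, fusion, deleted


# ---------------------------------------------------------------- full runs

def null_spec(spec: CohortSpec | None = None) -> CohortSpec:
    """Copy of a spec with identical response probabilities in both states
    (biomarker independent of response): the size-control condition."""
    spec = spec or CohortSpec()
    pooled = {
        c: spec.hrd_prevalence * spec.response_probs["HRD"][c]
        + (1 - spec.hrd_prevalence) * spec.response_probs["HRP"][c]
        for c in ("CR", "PR", "SD", "PD")
    }
    total = sum(pooled.values())
    pooled = {c: v / total for c, v in pooled.items()}
    return dataclasses.replace(spec, response_probs={"HRD": dict(pooled), "HRP": dict(pooled)})
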