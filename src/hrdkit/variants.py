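"""Somatic-variant filter cascades and VAF-based LOH inference.

Two filter profiles are implemented:

* WES cohort cascade — minimum alternative depth (2) and frequency (0.25),
  benign clinical significance, synonymous and non-exonic/splicing
  exclusion, cohort recurrence (seen in >= 5 distinct tumours), population
  frequency (> 0.001 in any of the annotation databases) and a benign
  vote among 5 effect predictors (> 2 benign labels excludes).
* Targeted panel — low VAF (< 5%), low coverage (< 100x), or elevated
  1000 Genomes frequency (> 0.1%).

Every rejection records the full ordered list of failed rules, so the
partition kept + rejected always reconstructs the input.  Gene-list
restriction (cancer-census or DNA-damage-response lists) and LOH inference
from elevated VAF round out the module.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

PREDICTORS = ("SIFT", "Polyphen2_HDIV", "MutationAssessor", "MetaSVM", "FATHMM")
BENIGN_LABELS = frozenset(
    {"benign", "tolerated", "possibly damaging", "low", "medium", "neutral"}
)
BENIGN_CLINSIG = frozenset({"benign", "likely benign", "benign/likely benign"})
KEPT_FUNC_CLASSES = frozenset({"exonic", "splicing"})

# rejection-reason vocabulary
R_MIN_ALT_DEPTH = "min_alt_depth"
R_MIN_ALT_FREQ = "min_alt_freq"
R_MIN_DEPTH_AND_FREQ = "min_depth_and_freq"
R_CLINSIG = "clinsig_benign"
R_SYNONYMOUS = "synonymous"
R_FUNC_CLASS = "func_class"
R_RECURRENT = "recurrent"
R_POP_FREQ = "pop_freq"
R_PREDICTOR = "predictor_vote"
R_LOW_VAF = "low_vaf"
R_LOW_COVERAGE = "low_coverage"
R_POP_FREQ_1000G = "pop_freq_1000g"
R_GENE_LIST = "gene_list"

KEY_1000G = "1000g"


@dataclass
class VariantRecord:
    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    alt_freq: float
    func_class: str = "exonic"
    exonic_class: str = ""
    clinsig: str = ""
    pop_freqs: dict[str, float] = field(default_factory=dict)
    predictor_calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.alt_freq <= 1.0):
            raise ValueError(f"{self.key()}: alt_freq must be in [0, 1]")
        if self.alt_depth > self.total_depth:
            raise ValueError(f"{self.key()}: alt_depth exceeds total_depth")

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FilterResult:
    kept: list[VariantRecord]
    rejected: list[tuple[VariantRecord, list[str]]]

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)

    def reasons_flat(self) -> list[str]:
        return [r for _, reasons in self.rejected for r in reasons]


@dataclass(frozen=True)
class GeneList:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene list must be non-empty")

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


def load_gene_list(path_or_builtin: str | Path) -> GeneList:
    """Load a one-symbol-per-line gene list, or a bundled built-in.

    Built-ins ``"cgc"`` and ``"ddr"`` are small synthetic placeholder lists
    (the licensed COSMIC census and the GO-derived DDR list cannot be
    redistributed); replace them with full lists for real analyses.
    """
    name = str(path_or_builtin)
    if name in ("cgc", "ddr"):
        ref = importlib.resources.files("hrdkit.data").joinpath(
            f"{name}_genes_synthetic.txt"
        )
        lines = ref.read_text().splitlines()
    else:
        lines = Path(path_or_builtin).read_text().splitlines()
        name = Path(path_or_builtin).stem
    genes = frozenset(
        ln.strip().upper() for ln in lines if ln.strip() and not ln.startswith("#")
    )
    return GeneList(name, genes)


def _norm_label(label: str) -> str:
    return label.strip().lower().replace("_", " ")


def _benign_votes(rec: VariantRecord) -> int:
    votes = 0
    for name in PREDICTORS:
        call = rec.predictor_calls.get(name)
        if call is None or str(call).strip() == "":
            continue  # missing predictions are not benign votes
        if _norm_label(str(call)) in BENIGN_LABELS:
            votes += 1
    return votes


def filter_wes_cohort(
    variants: list[VariantRecord],
    min_alt_depth: int = 2,
    min_alt_freq: float = 0.25,
    max_pop_freq: float = 0.001,
    max_recurrence: int = 4,
    max_benign_votes: int = 2,
    rule1_conjunctive: bool = False,
) -> FilterResult:
    """Apply the WES cohort filter cascade, recording every failed rule.

    The recurrence rule needs the whole cohort: a (chrom, pos, ref, alt)
    key observed in more than ``max_recurrence`` distinct tumours is
    treated as an artefact/germline leak and removed.  By default the
    depth and frequency minima are independent filters;
    ``rule1_conjunctive=True`` removes a variant only when it fails both.
    """
    key_samples: dict[tuple, set[str]] = {}
    for v in variants:
        key_samples.setdefault(v.key(), set()).add(v.sample_id)

    kept, rejected = [], []
    for v in variants:
        reasons: list[str] = []
        if rule1_conjunctive:
            if v.alt_depth < min_alt_depth and v.alt_freq < min_alt_freq:
                reasons.append(R_MIN_DEPTH_AND_FREQ)
        else:
            if v.alt_depth < min_alt_depth:
                reasons.append(R_MIN_ALT_DEPTH)
            if v.alt_freq < min_alt_freq:
                reasons.append(R_MIN_ALT_FREQ)
        if _norm_label(v.clinsig) in BENIGN_CLINSIG:
            reasons.append(R_CLINSIG)
        if _norm_label(v.exonic_class) == "synonymous snv":
            reasons.append(R_SYNONYMOUS)
        if v.func_class.strip().lower() not in KEPT_FUNC_CLASSES:
            reasons.append(R_FUNC_CLASS)
        if len(key_samples[v.key()]) > max_recurrence:
            reasons.append(R_RECURRENT)
        if any(f > max_pop_freq for f in v.pop_freqs.values()):
            reasons.append(R_POP_FREQ)
        if _benign_votes(v) > max_benign_votes:
            reasons.append(R_PREDICTOR)
        if reasons:
            rejected.append((v, reasons))
        else:
            kept.append(v)
    return FilterResult(kept, rejected)


def filter_targeted(
    variants: list[VariantRecord],
    vaf_min: float = 0.05,
    cov_min: int = 100,
    popfreq_max: float = 0.001,
    conjunctive_popfreq: bool = False,
) -> FilterResult:
    """Targeted-panel exclusion: low VAF, low coverage, high 1000G frequency.

    Default reading is disjunctive (any condition rejects);
    ``conjunctive_popfreq=True`` uses the literal "(low VAF or low
    coverage) and high 1000G frequency" reading.  A missing 1000 Genomes
    frequency is treated as 0 with a warning.
    """
    kept, rejected = [], []
    for v in variants:
        if KEY_1000G not in v.pop_freqs:
            warnings.warn(
                f"{v.sample_id} {v.key()}: missing 1000 Genomes frequency, assuming 0",
                stacklevel=2,
            )
        g1000 = v.pop_freqs.get(KEY_1000G, 0.0)
        low_vaf = v.alt_freq < vaf_min
        low_cov = v.total_depth < cov_min
        high_pop = g1000 > popfreq_max
        reasons: list[str] = []
        if conjunctive_popfreq:
            if (low_vaf or low_cov) and high_pop:
                if low_vaf:
                    reasons.append(R_LOW_VAF)
                if low_cov:
                    reasons.append(R_LOW_COVERAGE)
                reasons.append(R_POP_FREQ_1000G)
        else:
            if low_vaf:
                reasons.append(R_LOW_VAF)
            if low_cov:
                reasons.append(R_LOW_COVERAGE)
            if high_pop:
                reasons.append(R_POP_FREQ_1000G)
        if reasons:
            rejected.append((v, reasons))
        else:
            kept.append(v)
    return FilterResult(kept, rejected)


def restrict_to_genes(variants: list[VariantRecord], gene_list: GeneList) -> FilterResult:
    """Keep variants whose gene symbol is in the list (case-normalized)."""
    kept, rejected = [], []
    for v in variants:
        if v.gene.upper() in gene_list.genes:
            kept.append(v)
        else:
            rejected.append((v, [R_GENE_LIST]))
    return FilterResult(kept, rejected)


def infer_loh_from_vaf(variant: VariantRecord, vaf_loh_threshold: float = 0.7) -> bool:
    """LOH of the locus inferred from an elevated variant allele frequency.

    True iff alt_freq >= threshold (inclusive).  The default 0.7 is this
    package's choice of a conservative cutoff for ~pure tumour samples.
    """
    return variant.alt_freq >= vaf_loh_threshold


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV: one row per variant per sample.

    Fixed columns sample, gene, chrom, pos, ref, alt, total_depth,
    alt_depth, alt_freq, func_class, exonic_class, clinsig; any
    ``popfreq_<db>`` column feeds pop_freqs and any ``pred_<name>`` column
    feeds predictor_calls.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    pop_cols = [c for c in df.columns if c.startswith("popfreq_")]
    pred_cols = [c for c in df.columns if c.startswith("pred_")]
    records = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        pop = {
            c[len("popfreq_"):]: float(d[c])
            for c in pop_cols
            if str(d[c]).strip() != ""
        }
        preds = {c[len("pred_"):]: str(d[c]) for c in pred_cols if str(d[c]).strip() != ""}
        records.append(
            VariantRecord(
                sample_id=str(d["sample"]),
                gene=str(d["gene"]),
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                total_depth=int(d["total_depth"]),
                alt_depth=int(d["alt_depth"]),
                alt_freq=float(d["alt_freq"]),
                func_class=str(d.get("func_class", "exonic")),
                exonic_class=str(d.get("exonic_class", "")),
                clinsig=str(d.get("clinsig", "")),
                pop_freqs=pop,
                predictor_calls=preds,
            )
        )
    return records
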