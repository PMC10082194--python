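"""RAD51 foci scoring and functional HR-status classification.

Foci counts arrive as a per-cell table (image analysis is upstream).  A
marker-positive (geminin/EdU/DAPI-gated) cell is RAD51-positive when it
shows more than ``foci_threshold`` foci (default 5, strict).  A PDX is
HR-deficient when the mean percentage of RAD51-positive cells across its
cisplatin-treated samples is below 10% (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

DEFAULT_FOCI_THRESHOLD = 5
DEFAULT_PERCENT_THRESHOLD = 10.0
MIN_CELLS = 100

HR_DEFICIENT = "HR-deficient"
HR_PROFICIENT = "HR-proficient"


@dataclass(frozen=True)
class SampleFociScore:
    sample_id: str
    arm: str  # "control" or "treated"
    n_cells: int  # marker-positive cells scored
    percent_positive: float


@dataclass(frozen=True)
class HrStatusCall:
    pdx_id: str
    mean_treated_percent: float
    status: str


def score_sample(
    cells: pd.DataFrame,
    sample_id: str | None = None,
    arm: str = "treated",
    foci_threshold: int = DEFAULT_FOCI_THRESHOLD,
    inclusive: bool = False,
) -> SampleFociScore:
    """Percent of marker-positive cells with more than ``foci_threshold`` foci.

    ``cells`` needs columns marker_positive (0/1) and foci_count.  Marker-
    negative cells are ignored entirely.  ``inclusive=True`` counts cells
    with exactly the threshold as positive (>= instead of >).  Warns below
    the recommended minimum of 100 cells per condition.
    """
    pos = cells[cells["marker_positive"].astype(bool)]
    if pos.empty:
        raise ValueError("no marker-positive cells to score")
    if sample_id is None:
        sample_id = str(pos["sample"].iloc[0]) if "sample" in pos.columns else "?"
    if len(pos) < MIN_CELLS:
        warnings.warn(
            f"sample {sample_id}: only {len(pos)} marker-positive cells "
            f"(minimum {MIN_CELLS} recommended)",
            stacklevel=2,
        )
    counts = pos["foci_count"]
    hits = (counts >= foci_threshold) if inclusive else (counts > foci_threshold)
    pct = 100.0 * int(hits.sum()) / len(pos)
    return SampleFociScore(sample_id, arm, len(pos), pct)


def classify_hr(
    pdx_id: str,
    treated_scores: list[SampleFociScore],
    percent_threshold: float = DEFAULT_PERCENT_THRESHOLD,
    weight_by_cells: bool = False,
) -> HrStatusCall:
    """HR-deficient iff the mean treated-arm percent positive is < threshold.

    Aggregation over treated xenografts is an unweighted mean by default;
    ``weight_by_cells=True`` weights by scored cell counts.
    """
    if not treated_scores:
        raise ValueError(f"PDX {pdx_id}: no treated-arm scores")
    if weight_by_cells:
        total = sum(s.n_cells for s in treated_scores)
        mean = sum(s.percent_positive * s.n_cells for s in treated_scores) / total
    else:
        mean = sum(s.percent_positive for s in treated_scores) / len(treated_scores)
    status = HR_DEFICIENT if mean < percent_threshold else HR_PROFICIENT
    return HrStatusCall(pdx_id, mean, status)


def score_foci_table(
    foci: pd.DataFrame,
    foci_threshold: int = DEFAULT_FOCI_THRESHOLD,
    percent_threshold: float = DEFAULT_PERCENT_THRESHOLD,
    inclusive: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a full foci TSV (pdx, sample, arm, cell_id, marker_positive, foci_count).

    Returns (per-sample scores, per-PDX HR status calls).
    """
    sample_rows = []
    per_pdx: dict[str, list[SampleFociScore]] = {}
    for (pdx, sample, arm), grp in foci.groupby(["pdx", "sample", "arm"], sort=False):
        score = score_sample(
            grp, sample_id=str(sample), arm=str(arm), foci_threshold=foci_threshold,
            inclusive=inclusive,
        )
        sample_rows.append((pdx, sample, arm, score.n_cells, score.percent_positive))
        if str(arm) == "treated":
            per_pdx.setdefault(str(pdx), []).append(score)
    status_rows = [
        (pdx, call.mean_treated_percent, call.status)
        for pdx, scores in per_pdx.items()
        for call in [classify_hr(pdx, scores, percent_threshold=percent_threshold)]
    ]
    samples = pd.DataFrame(
        sample_rows, columns=["pdx", "sample", "arm", "n_cells", "percent_positive"]
    )
    status = pd.DataFrame(status_rows, columns=["pdx", "mean_treated_percent", "status"])
    return samples, status
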