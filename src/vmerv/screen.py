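"""The interindividual methylation-variation screen.

The screen statistic for one LTR end is the difference between the
second-highest and second-lowest per-replicate mean methylation, in
percentage points — a robust spread measure that tolerates one outlying
replicate at each extreme.  Ends scoring at or above the threshold
(default 25 percentage points) are candidates unless the element is a
cell-type or sex DMR: a DMR is an element whose k highest and/or k
lowest replicate means all come from one group (default k = 8 of 16).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylation import LtrMethylationSummary, ReplicateMeta

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_PP = 25.0
DEFAULT_DMR_K = 8
MIN_SCORE_VALUES = 4

CLASSIFICATIONS = ("candidate", "non_variable", "excluded_dmr", "insufficient_data")


class InsufficientDataError(ValueError):
    """Raised when too few replicate means are available to score."""


def variation_score(means) -> float:
    """Variation score: 100 x (second-highest - second-lowest replicate mean).

    Requires at least four non-missing means.  The score is invariant
    under permutation and under replacing the single maximum by any
    value at least as large as the second maximum (and symmetrically
    for the minimum).
    """
    arr = np.asarray([m for m in np.ravel(np.asarray(means, dtype=float)) if np.isfinite(m)])
    if arr.size < MIN_SCORE_VALUES:
        raise InsufficientDataError(
            f"variation score needs >= {MIN_SCORE_VALUES} replicate means, got {arr.size}"
        )
    s = np.sort(arr)
    return float(100.0 * (s[-2] - s[1]))


def is_group_dmr(means, labels, k: int = DEFAULT_DMR_K) -> bool:
    """True if the k highest and/or k lowest means come from one group only.

    Labels must be two-level.  Strict separation is required: a tie in
    value spanning the k-th boundary disqualifies that side (so a flat
    profile is never a DMR).
    """
    arr = np.asarray(means, dtype=float)
    lab = np.asarray(labels)
    if arr.shape != lab.shape:
        raise ValueError("means and labels must align")
    keep = np.isfinite(arr)
    arr, lab = arr[keep], lab[keep]
    levels = np.unique(lab)
    if levels.size > 2:
        raise ValueError(f"labels must have at most two levels, got {levels.tolist()}")
    if levels.size < 2 or arr.size < k + 1 or k < 1:
        return False
    order = np.argsort(arr, kind="mergesort")
    low, high = order[:k], order[-k:]
    low_pure = (
        np.unique(lab[low]).size == 1 and arr[order[k - 1]] < arr[order[k]]
    )
    high_pure = (
        np.unique(lab[high]).size == 1 and arr[order[-k]] > arr[order[-k - 1]]
    )
    return bool(low_pure or high_pure)


@dataclass
class VariationResult:
    """Screen outcome for one element end."""

    element_id: str
    end: str
    score: float  # percentage points; nan when insufficient data
    n_replicates: int
    dmr_celltype: bool
    dmr_sex: bool
    classification: str
    means: dict[str, float]


def screen(
    summaries: list[LtrMethylationSummary],
    replicates: list[ReplicateMeta],
    threshold: float = DEFAULT_THRESHOLD_PP,
    dmr_k: int = DEFAULT_DMR_K,
    require_all_replicates: bool = True,
) -> list[VariationResult]:
    """Score and classify every summarised LTR end.

    An end is a candidate iff its score is at or above ``threshold``
    percentage points and the element is neither a cell-type nor a sex
    DMR.  Ends missing a replicate mean are excluded as
    insufficient_data (override with ``require_all_replicates=False``
    to score whatever is available, minimum four values).
    """
    rep_ids = [r.id for r in replicates]
    cell_labels = np.asarray([r.cell_type for r in replicates])
    sex_labels = np.asarray([r.sex for r in replicates])
    results = []
    for s in summaries:
        means = np.asarray([s.means[rid] for rid in rep_ids], dtype=float)
        available = np.isfinite(means) & ~np.asarray([s.missing[rid] for rid in rep_ids])
        usable = means.copy()
        usable[~available] = np.nan
        n_ok = int(available.sum())
        incomplete = n_ok < len(rep_ids)
        if (require_all_replicates and incomplete) or n_ok < MIN_SCORE_VALUES:
            if incomplete:
                logger.info(
                    "excluding %s %s: %d/%d replicate means available",
                    s.element_id, s.end, n_ok, len(rep_ids),
                )
            results.append(
                VariationResult(
                    element_id=s.element_id, end=s.end, score=float("nan"),
                    n_replicates=n_ok, dmr_celltype=False, dmr_sex=False,
                    classification="insufficient_data",
                    means=dict(zip(rep_ids, means)),
                )
            )
            continue
        score = variation_score(usable[available])
        dmr_ct = is_group_dmr(usable, cell_labels, k=dmr_k)
        dmr_sx = is_group_dmr(usable, sex_labels, k=dmr_k)
        if score >= threshold:
            classification = "excluded_dmr" if (dmr_ct or dmr_sx) else "candidate"
        else:
            classification = "non_variable"
        results.append(
            VariationResult(
                element_id=s.element_id, end=s.end, score=score, n_replicates=n_ok,
                dmr_celltype=dmr_ct, dmr_sex=dmr_sx, classification=classification,
                means=dict(zip(rep_ids, means)),
            )
        )
    return results


def results_to_table(results: list[VariationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element_id": r.element_id,
                "end": r.end,
                "score_pp": r.score,
                "n_replicates": r.n_replicates,
                "dmr_celltype": r.dmr_celltype,
                "dmr_sex": r.dmr_sex,
                "classification": r.classification,
            }
            for r in results
        ]
    )


def candidate_elements(results: list[VariationResult]) -> set[str]:
    """Element-level candidacy: the union over ends (an element is a
    candidate if either LTR end qualifies); per-end results are retained
    in the per-end table."""
    return {r.element_id for r in results if r.classification == "candidate"}


class CalibrationError(ValueError):
    """No threshold achieves the requested validation precision."""

    def __init__(self, best_threshold: float, best_precision: float):
        self.best_threshold = best_threshold
        self.best_precision = best_precision
        super().__init__(
            f"no threshold reaches the target precision; best is "
            f"{best_precision:.3f} at {best_threshold:g} pp"
        )


def calibrate_threshold(
    scores,
    experimental_ranges,
    validation_cutoff: float = 10.0,
    target_precision: float = 0.75,
) -> tuple[float, float]:
    """Smallest score threshold whose validation precision meets the target.

    Given paired (computational score, experimentally measured
    interindividual range) observations, scan the observed scores
    ascending and return the first threshold t such that among pairs
    scoring >= t, the fraction whose experimental range exceeds
    ``validation_cutoff`` percentage points is at least
    ``target_precision``.  Returns (threshold, achieved precision).
    """
    sc = np.asarray(scores, dtype=float)
    er = np.asarray(experimental_ranges, dtype=float)
    if sc.shape != er.shape:
        raise ValueError("scores and experimental ranges must align")
    if sc.size < 10:
        raise ValueError("calibration needs at least 10 validated pairs")
    best_t, best_p = float("nan"), -1.0
    for t in np.unique(sc):
        sel = sc >= t
        precision = float((er[sel] > validation_cutoff).mean())
        if precision > best_p:
            best_t, best_p = float(t), precision
        if precision >= target_precision:
            return float(t), precision
    raise CalibrationError(best_t, best_p)
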