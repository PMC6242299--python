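"""Genomic context of candidate elements.

Nearest-gene assignment, the biased differential-expression overlap
screen, scaled meta-element enrichment profiles (element bodies rescaled
to a fixed number of bins, fixed-width flanks, strand-aware), distances
to the nearest ChIP peak, and the transcript-overlap consistency rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import ErvElement

logger = logging.getLogger(__name__)

DEFAULT_GENE_WINDOW = 10_000
DEFAULT_FLANK = 5_000
DEFAULT_BODY_BINS = 20
DEFAULT_FLANK_BINS = 50
MIN_TRANSCRIPT_REPLICATES = 3


def read_bed(path: str | Path, names=("chrom", "start", "end", "name", "score", "strand")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    df = read_bed(path, names=("chrom", "start", "end", "gene_id", "score", "strand"))
    if "gene_id" not in df.columns:
        raise ValueError(f"gene BED {path} needs at least 4 columns")
    return df[[c for c in ("chrom", "start", "end", "gene_id", "strand") if c in df.columns]]


def read_signal_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def nearest_gene(element: ErvElement, genes: pd.DataFrame) -> tuple[str | None, int | None]:
    """Nearest gene and signed edge distance in bp.

    Distance is 0 for overlap, otherwise the minimal edge-to-edge gap;
    the sign is negative when the gene lies upstream (left) of the
    element in reference orientation.  Equidistant ties go to the gene
    with the lower start coordinate (logged).
    """
    sub = genes[genes["chrom"] == element.chrom]
    if len(sub) == 0:
        return None, None
    starts = sub["start"].to_numpy(dtype=np.int64)
    ends = sub["end"].to_numpy(dtype=np.int64)
    overlap = (starts < element.end) & (ends > element.start)
    signed = np.where(
        ends <= element.start,
        -(element.start - ends),  # upstream gap, negative
        starts - element.end,  # downstream gap, positive
    )
    signed = np.where(overlap, 0, signed)
    dist = np.abs(signed)
    best = dist.min()
    cand = np.flatnonzero(dist == best)
    if cand.size > 1:
        cand = cand[np.argsort(starts[cand], kind="mergesort")]
        logger.info(
            "nearest-gene tie for %s at %d bp; choosing lowest-coordinate gene %s",
            element.id, best, sub.iloc[cand[0]]["gene_id"],
        )
    pick = cand[0]
    return str(sub.iloc[pick]["gene_id"]), int(signed[pick])


def biased_screen(
    elements: list[ErvElement],
    de_genes: set[str] | list[str],
    genes: pd.DataFrame,
    window: int = DEFAULT_GENE_WINDOW,
) -> list[ErvElement]:
    """Elements lying within or near (<= window bp) a differentially expressed gene."""
    de = set(de_genes)
    if not de:
        logger.warning("empty DE gene list; biased screen returns no candidates")
        return []
    kept = []
    for el in elements:
        gene_id, dist = nearest_gene(el, genes)
        if gene_id is not None and gene_id in de and abs(dist) <= window:
            kept.append(el)
    return kept


class StepSignal:
    """Piecewise-constant signal from a bedGraph (per-chromosome interval arrays)."""

    def __init__(self, signal: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in signal.groupby("chrom", sort=False):
            sub = sub.sort_values("start", kind="mergesort")
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(dtype=float),
                sub["end"].to_numpy(dtype=float),
                sub["value"].to_numpy(dtype=float),
            )

    def mean(self, chrom: str, a: float, b: float) -> tuple[float, float]:
        """Base-weighted mean of the signal over [a, b); returns (mean, covered bases).

        Bases not covered by any interval do not enter the mean; a fully
        uncovered window returns (0.0, 0.0).
        """
        if b <= a or chrom not in self._by_chrom:
            return 0.0, 0.0
        starts, ends, values = self._by_chrom[chrom]
        i = np.searchsorted(ends, a, side="right")
        j = np.searchsorted(starts, b, side="left")
        if i >= j:
            return 0.0, 0.0
        s = np.maximum(starts[i:j], a)
        e = np.minimum(ends[i:j], b)
        w = np.maximum(e - s, 0.0)
        total = w.sum()
        if total <= 0:
            return 0.0, 0.0
        return float((values[i:j] * w).sum() / total), float(total)


@dataclass
class EnrichmentProfile:
    """Across-element mean signal over scaled bodies plus fixed flanks.

    ``values`` has 2*flank_bins + body_bins entries ordered 5' flank,
    body, 3' flank (profiles are strand-flipped so the left side is
    always the 5' flank).  ``coverage`` is the fraction of elements with
    signal coverage per bin.
    """

    values: np.ndarray
    coverage: np.ndarray
    flank: int
    body_bins: int
    flank_bins: int
    n_elements: int
    label: str = ""

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins


def _element_bin_edges(el: ErvElement, flank: float, body_bins: int, flank_bins: int) -> np.ndarray:
    left = el.start - flank + (flank / flank_bins) * np.arange(flank_bins + 1)
    body = el.start + (el.end - el.start) / body_bins * np.arange(body_bins + 1)
    right = el.end + (flank / flank_bins) * np.arange(flank_bins + 1)
    return np.concatenate([left, body[1:], right[1:]])


def scaled_profile(
    signal: pd.DataFrame,
    elements: list[ErvElement],
    flank: int = DEFAULT_FLANK,
    body_bins: int = DEFAULT_BODY_BINS,
    flank_bins: int = DEFAULT_FLANK_BINS,
    chrom_lengths: dict[str, int] | None = None,
    label: str = "",
) -> EnrichmentProfile:
    """Meta-element enrichment profile: bodies rescaled to ``body_bins``
    bins, flanks binned at fixed width, bin values are base-weighted
    signal means, orientation respected (minus-strand profiles are
    flipped so the left side is the 5' flank), and the profile is the
    across-element mean per bin."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if not elements:
        raise ValueError("scaled_profile needs at least one element")
    step = StepSignal(signal)
    nbins = 2 * flank_bins + body_bins
    acc = np.zeros(nbins)
    cov = np.zeros(nbins)
    used = 0
    for el in elements:
        if chrom_lengths is not None:
            limit = chrom_lengths.get(el.chrom)
            if limit is not None and (el.start - flank < 0 or el.end + flank > limit):
                logger.warning("skipping %s: flank extends beyond chromosome bounds", el.id)
                continue
        edges = _element_bin_edges(el, float(flank), body_bins, flank_bins)
        vals = np.empty(nbins)
        covered = np.empty(nbins, dtype=bool)
        for k in range(nbins):
            m, w = step.mean(el.chrom, edges[k], edges[k + 1])
            vals[k] = m
            covered[k] = w > 0
        if el.strand == "-":
            vals = vals[::-1]
            covered = covered[::-1]
        acc += vals
        cov += covered
        used += 1
    if used == 0:
        raise ValueError("no usable elements for profile")
    return EnrichmentProfile(
        values=acc / used,
        coverage=cov / used,
        flank=flank,
        body_bins=body_bins,
        flank_bins=flank_bins,
        n_elements=used,
        label=label,
    )


def profile_to_table(profile: EnrichmentProfile) -> pd.DataFrame:
    """Tidy table of a profile (bin index, region, mean signal, coverage)."""
    region = (
        ["flank5"] * profile.flank_bins
        + ["body"] * profile.body_bins
        + ["flank3"] * profile.flank_bins
    )
    return pd.DataFrame(
        {
            "bin": np.arange(profile.n_bins),
            "region": region,
            "mean_signal": profile.values,
            "coverage": profile.coverage,
        }
    )


def distance_to_nearest_peak(element: ErvElement, peaks: pd.DataFrame) -> int | None:
    """Minimal edge distance from the element borders to any peak on the
    same chromosome (0 when overlapping, None when the chromosome has no
    peak)."""
    sub = peaks[peaks["chrom"] == element.chrom]
    if len(sub) == 0:
        return None
    starts = sub["start"].to_numpy(dtype=np.int64)
    ends = sub["end"].to_numpy(dtype=np.int64)
    left_gap = element.start - ends  # peak entirely left
    right_gap = starts - element.end  # peak entirely right
    dist = np.maximum(np.maximum(left_gap, right_gap), 0)
    return int(dist.min())


@dataclass
class TranscriptHit:
    """An assembled transcript overlapping an element in one replicate."""

    element_id: str
    replicate_id: str
    cell_type: str
    sex: str
    t_start: int
    t_end: int
    t_strand: str
    relation: str  # initiating / terminating / overlapping


def compute_transcript_hits(
    elements: list[ErvElement],
    transcripts: dict[str, pd.DataFrame],
    replicate_meta: dict[str, tuple[str, str]],
) -> list[TranscriptHit]:
    """Overlap per-replicate transcript intervals with elements.

    A hit is initiating when the transcript's 5' end (strand-aware)
    lies within the element, terminating when its 3' end does, else
    overlapping.
    """
    hits = []
    for rid, df in transcripts.items():
        cell, sex = replicate_meta[rid]
        for el in elements:
            sub = df[(df["chrom"] == el.chrom) & (df["start"] < el.end) & (df["end"] > el.start)]
            for t in sub.itertuples(index=False):
                five = t.start if t.strand == "+" else t.end - 1
                three = t.end - 1 if t.strand == "+" else t.start
                if el.start <= five < el.end:
                    relation = "initiating"
                elif el.start <= three < el.end:
                    relation = "terminating"
                else:
                    relation = "overlapping"
                hits.append(
                    TranscriptHit(
                        element_id=el.id, replicate_id=rid, cell_type=cell, sex=sex,
                        t_start=int(t.start), t_end=int(t.end), t_strand=str(t.strand),
                        relation=relation,
                    )
                )
    return hits


def consistent_transcript_overlap(
    hits: list[TranscriptHit], min_reps: int = MIN_TRANSCRIPT_REPLICATES
) -> pd.DataFrame:
    """Elements with transcript hits in >= min_reps distinct replicates of
    one (cell type, sex) group; the reported relation is initiating if
    any qualifying group's hits initiate, else terminating if any
    terminate, else overlapping."""
    rows = []
    by_el: dict[str, dict[tuple[str, str], list[TranscriptHit]]] = {}
    for h in hits:
        by_el.setdefault(h.element_id, {}).setdefault((h.cell_type, h.sex), []).append(h)
    for eid, groups in by_el.items():
        qualifying = {
            grp: hs for grp, hs in groups.items()
            if len({h.replicate_id for h in hs}) >= min_reps
        }
        if not qualifying:
            continue
        relations = {h.relation for hs in qualifying.values() for h in hs}
        if "initiating" in relations:
            relation = "initiating"
        elif "terminating" in relations:
            relation = "terminating"
        else:
            relation = "overlapping"
        for (cell, sex), hs in qualifying.items():
            rows.append(
                {
                    "element_id": eid,
                    "cell_type": cell,
                    "sex": sex,
                    "n_replicates": len({h.replicate_id for h in hs}),
                    "relation": relation,
                }
            )
    return pd.DataFrame(rows, columns=["element_id", "cell_type", "sex", "n_replicates", "relation"])
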