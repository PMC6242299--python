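"""Assembly of endogenous retrovirus (ERV) elements from RepeatMasker fragments.

RepeatMasker annotates proviruses as separate fragments: long terminal
repeats (LTRs, e.g. ``IAPLTR1_Mm``) and internal retroviral sequence
(``*-int`` entries, e.g. ``IAPEz-int``).  An intact provirus is an
LTR–internal–LTR sandwich; recombination and truncation over evolutionary
time leave solo LTRs, elements missing one LTR, and bare internal
sequence.  This module stitches fragments back into elements, classifies
each element's structure, and computes the CpG density of LTR sequences.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

FAMILIES = ("IAP", "ERV1", "ERVK", "ERVL")
STRUCTURES = ("full_length", "solo_LTR", "trunc_5p", "trunc_3p", "internal_only")

RMSK_COLUMNS = ["chrom", "start", "end", "strand", "repName", "repClass", "repFamily"]

#: default maximum gap (bp) between consecutive fragments merged into one element
DEFAULT_MAX_GAP = 250


@dataclass
class RepeatFragment:
    """One RepeatMasker fragment (UCSC rmsk minimal column set)."""

    chrom: str
    start: int
    end: int
    strand: str
    repName: str
    repClass: str
    repFamily: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment start must be < end: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class ErvElement:
    """An assembled ERV element with per-end LTR sub-intervals.

    ``ltr5``/``ltr3`` are (start, end) genomic sub-intervals of the 5'
    and 3' LTR.  On the minus strand the 5' LTR is the genomically
    rightmost one.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    structure: str = ""
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None
    ltr5_subtype: str | None = None
    ltr3_subtype: str | None = None
    has_internal: bool = False
    n_fragments: int = 1
    extra: dict = field(default_factory=dict)

    def ltr(self, end: str) -> tuple[int, int] | None:
        if end == "5p":
            return self.ltr5
        if end == "3p":
            return self.ltr3
        raise ValueError(f"end must be '5p' or '3p', got {end!r}")

    @property
    def subtype(self) -> str | None:
        """Element-level LTR subtype: the 5' subtype when present, else 3'."""
        return self.ltr5_subtype if self.ltr5_subtype is not None else self.ltr3_subtype

    def ends(self) -> list[str]:
        """LTR ends present on this element, in ('5p', '3p') order."""
        out = []
        if self.ltr5 is not None:
            out.append("5p")
        if self.ltr3 is not None:
            out.append("3p")
        return out


def fragment_family(rep_name: str, rep_family: str) -> str:
    """ERV grouping of a fragment.

    Any fragment whose repName mentions IAP is grouped as IAP (IAPs are
    annotated under repFamily ERVK by RepeatMasker but are screened as
    their own group); all other fragments keep their repFamily.
    """
    if "IAP" in rep_name.upper():
        return "IAP"
    return rep_family


def is_internal_fragment(rep_name: str) -> bool:
    """True for internal retroviral sequence fragments (rmsk ``*-int``/``*-I``)."""
    return rep_name.endswith(("-int", "_int", "-I", "_I"))


def read_rmsk(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated rmsk-style fragment table.

    Accepts files with or without a header line.  Malformed rows are
    skipped with a logged per-row report.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = first.strip().startswith("#") or first.split("\t")[0] in ("chrom", "genoName")
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=None if has_header else RMSK_COLUMNS,
        dtype=str,
        comment=None,
    )
    if has_header:
        df.columns = [c.lstrip("#") for c in df.columns]
        df = df.rename(columns={"genoName": "chrom", "genoStart": "start", "genoEnd": "end"})
    missing = [c for c in RMSK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rmsk table {path} lacks columns: {missing}")
    rows, bad = [], 0
    for i, row in enumerate(df.itertuples(index=False), start=2 if has_header else 1):
        try:
            rec = {
                "chrom": str(row.chrom),
                "start": int(row.start),
                "end": int(row.end),
                "strand": str(row.strand),
                "repName": str(row.repName),
                "repClass": str(row.repClass),
                "repFamily": str(row.repFamily),
            }
            if rec["start"] >= rec["end"] or rec["strand"] not in ("+", "-"):
                raise ValueError("bad coordinates or strand")
        except (TypeError, ValueError) as exc:
            bad += 1
            logger.warning("skipping malformed rmsk row %d of %s: %s", i, path, exc)
            continue
        rows.append(rec)
    if bad:
        logger.warning("%d malformed rows skipped in %s", bad, path)
    return pd.DataFrame(rows, columns=RMSK_COLUMNS)


def _build_element(members: pd.DataFrame, idx: int) -> ErvElement:
    """Construct one element from a block of merged fragment rows."""
    members = members.sort_values("start")
    chrom = members.iloc[0]["chrom"]
    strand = members.iloc[0]["strand"]
    family = fragment_family(members.iloc[0]["repName"], members.iloc[0]["repFamily"])
    start = int(members["start"].min())
    end = int(members["end"].max())
    internal_mask = members["repName"].map(is_internal_fragment).to_numpy()
    has_internal = bool(internal_mask.any())

    left_ltr = right_ltr = None
    left_name = right_name = None
    if not has_internal:
        # a run of pure-LTR fragments is one (possibly fragmented) LTR
        left_ltr = (start, end)
        left_name = members.iloc[0]["repName"]
    else:
        # leading LTR run -> genomically left LTR; trailing run -> right LTR
        n = len(members)
        i = 0
        while i < n and not internal_mask[i]:
            i += 1
        if i > 0:
            left_ltr = (int(members.iloc[0]["start"]), int(members.iloc[i - 1]["end"]))
            left_name = members.iloc[0]["repName"]
        j = n
        while j > i and not internal_mask[j - 1]:
            j -= 1
        if j < n:
            right_ltr = (int(members.iloc[j]["start"]), int(members.iloc[n - 1]["end"]))
            right_name = members.iloc[j]["repName"]

    if strand == "+":
        ltr5, ltr3, s5, s3 = left_ltr, right_ltr, left_name, right_name
    else:
        ltr5, ltr3, s5, s3 = right_ltr, left_ltr, right_name, left_name
    # an isolated LTR has no orientation anchor; report it as the 5' slot
    if not has_internal and ltr5 is None and ltr3 is not None:
        ltr5, ltr3, s5, s3 = ltr3, None, s3, None

    el = ErvElement(
        id=f"{family}_{idx:05d}",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        family=family,
        ltr5=ltr5,
        ltr3=ltr3,
        ltr5_subtype=s5,
        ltr3_subtype=s3,
        has_internal=has_internal,
        n_fragments=len(members),
    )
    el.structure = classify_structure(el)
    return el


def assemble_elements(fragments: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP) -> list[ErvElement]:
    """Merge consecutive same-chromosome/strand/family fragments into elements.

    Fragments whose inter-fragment gap is at most ``max_gap`` bp merge;
    the element span runs from the minimum start to the maximum end.
    Assembly is idempotent and conserves fragments (element count plus
    merge count equals fragment count).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if len(fragments) == 0:
        return []
    df = fragments.copy()
    df["family"] = [fragment_family(n, f) for n, f in zip(df["repName"], df["repFamily"])]
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    elements: list[ErvElement] = []
    block_start = 0
    prev = df.iloc[0]
    prev_end = prev["end"]
    for i in range(1, len(df)):
        row = df.iloc[i]
        same = (
            row["chrom"] == prev["chrom"]
            and row["strand"] == prev["strand"]
            and row["family"] == prev["family"]
            and row["start"] - prev_end <= max_gap
        )
        if not same:
            elements.append(_build_element(df.iloc[block_start:i], len(elements)))
            block_start = i
        prev = row
        prev_end = max(prev_end, row["end"]) if same else row["end"]
    elements.append(_build_element(df.iloc[block_start:], len(elements)))
    return elements


def classify_structure(element: ErvElement) -> str:
    """Structural class of an assembled element.

    full_length: both LTRs plus internal sequence; solo_LTR: LTR
    sequence only; trunc_5p / trunc_3p: internal sequence missing the 5'
    or 3' LTR; internal_only: no LTR at all.
    """
    has5 = element.ltr5 is not None
    has3 = element.ltr3 is not None
    if element.has_internal:
        if has5 and has3:
            return "full_length"
        if has5:
            return "trunc_3p"
        if has3:
            return "trunc_5p"
        return "internal_only"
    return "solo_LTR"


def ltr_cpg_density(sequence: str) -> float:
    """CpG density of an LTR sequence: percent of CpG dinucleotides per bp."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"invalid bases in sequence: {sorted(invalid)}")
    return 100.0 * seq.count("CG") / len(seq)


def elements_to_table(elements: list[ErvElement]) -> pd.DataFrame:
    """Flatten assembled elements to a writable table (TSV-friendly)."""
    rows = []
    for el in elements:
        rows.append(
            {
                "id": el.id,
                "chrom": el.chrom,
                "start": el.start,
                "end": el.end,
                "strand": el.strand,
                "family": el.family,
                "structure": el.structure,
                "ltr5_start": el.ltr5[0] if el.ltr5 else -1,
                "ltr5_end": el.ltr5[1] if el.ltr5 else -1,
                "ltr3_start": el.ltr3[0] if el.ltr3 else -1,
                "ltr3_end": el.ltr3[1] if el.ltr3 else -1,
                "ltr5_subtype": el.ltr5_subtype or "",
                "ltr3_subtype": el.ltr3_subtype or "",
                "n_fragments": el.n_fragments,
            }
        )
    return pd.DataFrame(rows)


def elements_from_table(df: pd.DataFrame) -> list[ErvElement]:
    """Inverse of :func:`elements_to_table`."""
    out = []
    for row in df.itertuples(index=False):
        ltr5 = (int(row.ltr5_start), int(row.ltr5_end)) if int(row.ltr5_start) >= 0 else None
        ltr3 = (int(row.ltr3_start), int(row.ltr3_end)) if int(row.ltr3_start) >= 0 else None
        el = ErvElement(
            id=str(row.id),
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            family=str(row.family),
            structure=str(row.structure),
            ltr5=ltr5,
            ltr3=ltr3,
            ltr5_subtype=str(row.ltr5_subtype) or None,
            ltr3_subtype=str(row.ltr3_subtype) or None,
            has_internal=str(row.structure) in ("full_length", "trunc_5p", "trunc_3p", "internal_only"),
            n_fragments=int(getattr(row, "n_fragments", 1)),
        )
        out.append(el)
    return out
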