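"""Reading per-replicate CpG methylation tracks and summarising distal-LTR methylation.

Whole-genome bisulfite callers report one methylation fraction per CpG
strand position in bedGraph form, so each CpG contributes two records
(the C of the sense strand and the C of the antisense strand at the
next base).  The screen summarises each LTR end of an element by the
mean of the strand values at its most distal CpGs (by default 8 CpGs,
i.e. 16 values) per biological replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assembly import ErvElement

logger = logging.getLogger(__name__)

CELL_TYPES = ("B", "T")
SEXES = ("F", "M")
ASSAYS = ("WGBS", "oxBS")

#: default number of distal CpGs per LTR end
N_DISTAL_CPGS = 8
#: default minimum strand values required for a valid replicate mean
MIN_VALUES = 8


@dataclass(frozen=True)
class ReplicateMeta:
    """Metadata of one pooled biological replicate track."""

    id: str
    cell_type: str
    sex: str
    assay: str
    pool_size: int | None = None

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}")
        if self.pool_size is not None and self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


def read_methylation(
    path: str | Path, replicate: ReplicateMeta | None = None, dialect: str = "fraction"
) -> pd.DataFrame:
    """Read a bedGraph methylation track into (chrom, pos, fraction) records.

    ``dialect`` declares the value scale explicitly: ``"fraction"`` for
    [0, 1] values, ``"percent"`` for [0, 100]; it is never guessed.
    Values outside the declared range raise with the offending line
    number.  Unsorted input is sorted internally with a warning.
    """
    if dialect not in ("fraction", "percent"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    chroms: list[str] = []
    positions: list[int] = []
    values: list[float] = []
    hi = 1.0 if dialect == "fraction" else 100.0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, value = int(parts[1]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if not 0.0 <= value <= hi:
                raise ValueError(
                    f"{path}:{lineno}: value {value} outside [0, {hi:g}] for {dialect} dialect"
                )
            chroms.append(parts[0])
            positions.append(start)
            values.append(value)
    if not chroms:
        logger.warning("empty methylation track: %s", path)
        return pd.DataFrame(columns=["chrom", "pos", "fraction"])
    df = pd.DataFrame({"chrom": chroms, "pos": positions, "fraction": values})
    if dialect == "percent":
        df["fraction"] = df["fraction"] / 100.0
    if not df[["chrom", "pos"]].equals(df[["chrom", "pos"]].sort_values(["chrom", "pos"]).reset_index(drop=True)):
        logger.warning("unsorted methylation track %s; sorting internally", path)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


@dataclass
class MethylationTrackSet:
    """Per-replicate methylation tracks held in memory.

    ``tracks`` maps replicate id to a DataFrame with columns
    (chrom, pos, fraction), one row per CpG strand position.
    """

    replicates: list[ReplicateMeta]
    tracks: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.replicates]
        if len(set(ids)) != len(ids):
            raise ValueError("replicate ids must be unique")

    @property
    def replicate_ids(self) -> list[str]:
        return [r.id for r in self.replicates]

    def meta(self, rep_id: str) -> ReplicateMeta:
        for r in self.replicates:
            if r.id == rep_id:
                return r
        raise KeyError(rep_id)

    def write(self, outdir: str | Path, dialect: str = "fraction") -> Path:
        """Write one bedGraph per replicate plus a YAML manifest; returns manifest path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        entries = []
        scale = 1.0 if dialect == "fraction" else 100.0
        for rep in self.replicates:
            fname = f"{rep.id}.bedGraph"
            df = self.tracks[rep.id]
            with open(outdir / fname, "w") as fh:
                for chrom, pos, frac in zip(df["chrom"], df["pos"], df["fraction"]):
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{frac * scale:.6g}\n")
            entries.append(
                {
                    "id": rep.id,
                    "cell_type": rep.cell_type,
                    "sex": rep.sex,
                    "assay": rep.assay,
                    "pool_size": rep.pool_size,
                    "path": fname,
                    "dialect": dialect,
                }
            )
        manifest = outdir / "manifest.yaml"
        with open(manifest, "w") as fh:
            yaml.safe_dump({"replicates": entries}, fh, sort_keys=False)
        return manifest

    @classmethod
    def read(cls, manifest_path: str | Path) -> "MethylationTrackSet":
        manifest_path = Path(manifest_path)
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh)
        reps, tracks = [], {}
        for entry in manifest["replicates"]:
            meta = ReplicateMeta(
                id=entry["id"],
                cell_type=entry["cell_type"],
                sex=entry["sex"],
                assay=entry["assay"],
                pool_size=entry.get("pool_size"),
            )
            reps.append(meta)
            tracks[meta.id] = read_methylation(
                manifest_path.parent / entry["path"], meta, dialect=entry.get("dialect", "fraction")
            )
        return cls(replicates=reps, tracks=tracks)


def collapse_strand_positions(positions: np.ndarray) -> np.ndarray:
    """Collapse strand-level record positions to C-strand CpG coordinates.

    A record at position p belongs to the CpG whose C is at p (sense
    strand) or at p-1 (antisense strand); consecutive position pairs
    (p, p+1) are therefore collapsed to p.
    """
    pos = np.unique(np.asarray(positions, dtype=np.int64))
    if pos.size == 0:
        return pos
    prev_present = np.isin(pos - 1, pos)
    return pos[~prev_present]


def infer_cpg_positions(trackset: MethylationTrackSet) -> dict[str, np.ndarray]:
    """Per-chromosome CpG C positions from the union of all replicate tracks."""
    by_chrom: dict[str, list[np.ndarray]] = {}
    for df in trackset.tracks.values():
        for chrom, sub in df.groupby("chrom", sort=False):
            by_chrom.setdefault(chrom, []).append(sub["pos"].to_numpy())
    return {
        chrom: collapse_strand_positions(np.concatenate(arrs)) for chrom, arrs in by_chrom.items()
    }


@dataclass
class DistalCpGs:
    """The distal CpGs of one LTR end, ordered outer -> inner."""

    element_id: str
    end: str
    positions: np.ndarray
    insufficient: bool


def extract_distal_cpgs(
    element: ErvElement,
    end: str,
    cpg_positions: dict[str, np.ndarray] | np.ndarray,
    n: int = N_DISTAL_CPGS,
) -> DistalCpGs:
    """The ``n`` CpGs of an LTR closest to its element-external boundary.

    For the 5' LTR the outer boundary is the element's left edge on the
    plus strand and the right edge on the minus strand (and conversely
    for the 3' LTR).  Returned positions are ordered outer to inner;
    an LTR with fewer than ``n`` CpGs is flagged ``insufficient``.
    """
    ltr = element.ltr(end)
    if ltr is None:
        raise ValueError(f"element {element.id} has no {end} LTR")
    pos = cpg_positions[element.chrom] if isinstance(cpg_positions, dict) else np.asarray(cpg_positions)
    lo, hi = ltr
    inside = pos[(pos >= lo) & (pos < hi)]
    outer_is_left = (element.strand == "+") == (end == "5p")
    ordered = np.sort(inside) if outer_is_left else np.sort(inside)[::-1]
    chosen = ordered[:n]
    return DistalCpGs(
        element_id=element.id, end=end, positions=chosen, insufficient=chosen.size < n
    )


@dataclass
class LtrMean:
    """Mean of the available strand values for one replicate at one LTR end."""

    mean: float
    n_values: int
    missing: bool


def replicate_ltr_mean(values, min_values: int = MIN_VALUES) -> LtrMean:
    """Arithmetic mean of strand-level methylation values for one replicate.

    The result is flagged missing when fewer than ``min_values`` values
    are available (e.g. CpGs without coverage in that replicate).
    """
    arr = np.asarray([v for v in np.ravel(values) if np.isfinite(v)], dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("methylation values must lie in [0, 1]")
    mean = float(arr.mean()) if arr.size else float("nan")
    return LtrMean(mean=mean, n_values=int(arr.size), missing=arr.size < min_values)


@dataclass
class LtrMethylationSummary:
    """Per-replicate distal-LTR means for one element end."""

    element_id: str
    end: str
    positions: np.ndarray
    means: dict[str, float]
    n_values: dict[str, int]
    missing: dict[str, bool]
    insufficient_cpgs: bool = False


def _track_index(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    idx = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
        idx[chrom] = (sub["pos"].to_numpy()[order], sub["fraction"].to_numpy()[order])
    return idx


def _lookup(idx, chrom: str, wanted: np.ndarray) -> np.ndarray:
    if chrom not in idx:
        return np.full(wanted.size, np.nan)
    pos, val = idx[chrom]
    j = np.searchsorted(pos, wanted)
    out = np.full(wanted.size, np.nan)
    ok = (j < pos.size) & (pos[np.minimum(j, pos.size - 1)] == wanted)
    out[ok] = val[j[ok]]
    return out


def summarize_ltr_methylation(
    elements: list[ErvElement],
    trackset: MethylationTrackSet,
    n_distal: int = N_DISTAL_CPGS,
    min_values: int = MIN_VALUES,
    cpg_positions: dict[str, np.ndarray] | None = None,
) -> list[LtrMethylationSummary]:
    """Per-replicate distal-LTR mean methylation for every LTR end.

    CpG positions default to those inferred from the union of the
    tracks themselves.  For each chosen CpG the values of both strand
    records (C position and the following base) enter the mean.
    """
    if cpg_positions is None:
        cpg_positions = infer_cpg_positions(trackset)
    indexes = {rid: _track_index(df) for rid, df in trackset.tracks.items()}
    summaries = []
    for el in elements:
        for end in el.ends():
            distal = extract_distal_cpgs(el, end, cpg_positions, n=n_distal)
            strand_pos = np.concatenate([distal.positions, distal.positions + 1])
            means, nvals, missing = {}, {}, {}
            for rid in trackset.replicate_ids:
                vals = _lookup(indexes[rid], el.chrom, strand_pos)
                lm = replicate_ltr_mean(vals[np.isfinite(vals)], min_values=min_values)
                means[rid] = lm.mean
                nvals[rid] = lm.n_values
                missing[rid] = lm.missing
            summaries.append(
                LtrMethylationSummary(
                    element_id=el.id,
                    end=end,
                    positions=distal.positions,
                    means=means,
                    n_values=nvals,
                    missing=missing,
                    insufficient_cpgs=distal.insufficient,
                )
            )
    return summaries


def summaries_to_table(summaries: list[LtrMethylationSummary], replicate_ids: list[str]) -> pd.DataFrame:
    """Long-format table of per-replicate LTR means (one row per element end x replicate)."""
    rows = []
    for s in summaries:
        for rid in replicate_ids:
            rows.append(
                {
                    "element_id": s.element_id,
                    "end": s.end,
                    "replicate_id": rid,
                    "mean": s.means[rid],
                    "n_values": s.n_values[rid],
                    "missing": s.missing[rid],
                    "insufficient_cpgs": s.insufficient_cpgs,
                }
            )
    return pd.DataFrame(rows)
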