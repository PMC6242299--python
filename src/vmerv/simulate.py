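"""Synthetic pooled-replicate bisulfite screen data.

Generates every input the screening pipeline consumes — RepeatMasker-style
fragment tables, per-replicate bedGraph methylation tracks, gene
annotation, ChIP signal/peaks, per-replicate transcript intervals, DE
gene lists, and breeding pedigrees — with the statistical structure the
analysis assumes:

* Each biological replicate is a pool of 4-5 individuals; the observed
  methylation fraction at a CpG strand is Binomial(depth, p_pool)/depth
  with Poisson read depth, where p_pool is the mean latent level of the
  pooled individuals.
* Elements carry a latent methylation class: hypermethylated (the
  genomic default for these repeats), variably methylated (the screen's
  quarry: per-individual levels drawn from a wide uniform range,
  independently per LTR end, constant across an individual's cell
  types), cell-type or sex DMRs (group-specific means, confounders the
  screen must exclude), and hypomethylated.
* Oxidative bisulfite (oxBS) replicates read 5mC only, so their
  modified signal is reduced by the hydroxymethylation fraction.

All randomness flows from a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .assembly import FAMILIES, STRUCTURES, RMSK_COLUMNS, ErvElement
from .methylation import ReplicateMeta, MethylationTrackSet

METH_CLASSES = ("hypermethylated", "variable", "celltype_DMR", "sex_DMR", "hypomethylated")

_LTR_SUBTYPES = {
    "IAP": {"full": "IAPLTR1_Mm", "solo": "IAPLTR2_Mm"},
    "ERV1": {"full": "RLTR4_Mm", "solo": "RLTR4_Mm"},
    "ERVK": {"full": "RLTR10C", "solo": "RLTR10C"},
    "ERVL": {"full": "MT2_Mm", "solo": "MT2_Mm"},
}
_INTERNAL_NAMES = {
    "IAP": "IAPEz-int",
    "ERV1": "MuRRS-int",
    "ERVK": "MMERVK10C-int",
    "ERVL": "MERVL-int",
}
_REP_FAMILY = {"IAP": "ERVK", "ERV1": "ERV1", "ERVK": "ERVK", "ERVL": "ERVL"}


def default_element_counts() -> dict[tuple[str, str, str], int]:
    """Default study composition: a genome dominated by stably hypermethylated
    IAPs, a planted minority of variably methylated elements, and cell-type
    DMRs that the screen must exclude."""
    return {
        ("IAP", "full_length", "variable"): 30,
        ("IAP", "solo_LTR", "variable"): 20,
        ("IAP", "full_length", "hypermethylated"): 300,
        ("IAP", "solo_LTR", "hypermethylated"): 120,
        ("IAP", "trunc_5p", "hypermethylated"): 40,
        ("IAP", "trunc_3p", "hypermethylated"): 40,
        ("IAP", "full_length", "celltype_DMR"): 20,
    }


def default_replicates() -> list[ReplicateMeta]:
    """16 pooled replicates: B/T cell type x F/M sex x WGBS/oxBS assay x 2 pools... one
    pool per (cell type, sex, assay) pair duplicated across two pool indexes, pools of
    4 and 5 individuals."""
    reps = []
    for cell in ("B", "T"):
        for sex in ("F", "M"):
            for assay in ("WGBS", "oxBS"):
                for k, pool_size in enumerate((4, 5), start=1):
                    reps.append(
                        ReplicateMeta(
                            id=f"{cell}_{sex}_{assay}_{k}",
                            cell_type=cell,
                            sex=sex,
                            assay=assay,
                            pool_size=pool_size,
                        )
                    )
    return reps[:16]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate the pooled design
    (16 replicates of 4-5 pooled individuals, WGBS and oxBS treated as
    biological replicates, mean strand depth 30)."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 20_000_000
    element_counts: dict[tuple[str, str, str], int] = field(default_factory=default_element_counts)
    ltr_length_bp: dict[str, int] = field(
        default_factory=lambda: {"IAP": 350, "ERV1": 400, "ERVK": 450, "ERVL": 500}
    )
    internal_length_bp: dict[str, int] = field(
        default_factory=lambda: {"IAP": 5000, "ERV1": 4000, "ERVK": 4500, "ERVL": 4000}
    )
    cpg_density_pct: dict[str, float] = field(
        default_factory=lambda: {"IAP": 4.0, "ERV1": 2.0, "ERVK": 2.5, "ERVL": 1.6}
    )
    replicates: list[ReplicateMeta] = field(default_factory=default_replicates)
    coverage: float = 30.0
    variable_range: tuple[float, float] = (0.05, 0.95)
    variable_distribution: str = "uniform"  # or "beta"
    variable_beta_ab: tuple[float, float] = (0.8, 0.8)
    hyper_mean: float = 0.90
    hyper_sd: float = 0.03
    hypo_mean: float = 0.05
    hypo_sd: float = 0.02
    dmr_celltype_means: dict[str, float] = field(default_factory=lambda: {"B": 0.9, "T": 0.1})
    dmr_sex_means: dict[str, float] = field(default_factory=lambda: {"F": 0.85, "M": 0.15})
    hmc_fraction: float = 0.015
    share_individuals_between_cell_types: bool = False
    n_genes: int = 200
    gene_length_bp: tuple[int, int] = (5_000, 40_000)
    fragment_gap_bp: tuple[int, int] = (5, 60)
    element_spacing_bp: tuple[int, int] = (12_000, 30_000)
    peak_distance_bp: tuple[int, int] = (0, 1_500)
    peak_width_bp: int = 200
    n_background_peaks_per_chrom: int = 40
    n_transcript_elements: int = 8
    transcript_replicates: int = 3
    n_de_elements: int = 10
    de_gene_window_bp: int = 10_000

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length_bp <= 0:
            raise ValueError("chromosome count and length must be positive")
        for key, n in self.element_counts.items():
            fam, struct, mclass = key
            if fam not in FAMILIES or struct not in STRUCTURES or mclass not in METH_CLASSES:
                raise ValueError(f"unknown element count key {key}")
            if n < 0:
                raise ValueError("element counts must be >= 0")
        lo, hi = self.variable_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("variable_range must satisfy 0 <= lo < hi <= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        for rep in self.replicates:
            if rep.pool_size is None or rep.pool_size < 1:
                raise ValueError(f"replicate {rep.id} needs pool_size >= 1")
        if not 0 <= self.hmc_fraction < 1:
            raise ValueError("hmc_fraction must lie in [0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["element_counts"] = [
            {"family": k[0], "structure": k[1], "meth_class": k[2], "count": v}
            for k, v in self.element_counts.items()
        ]
        data["replicates"] = [dataclasses.asdict(r) for r in self.replicates]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "element_counts" in data:
            data["element_counts"] = {
                (e["family"], e["structure"], e["meth_class"]): e["count"]
                for e in data["element_counts"]
            }
        if "replicates" in data:
            data["replicates"] = [ReplicateMeta(**r) for r in data["replicates"]]
        for key in ("variable_range", "variable_beta_ab", "gene_length_bp", "fragment_gap_bp",
                    "element_spacing_bp", "peak_distance_bp"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class TruthTable:
    """Planted ground truth for every generated element.

    ``elements`` has one row per element (id, coordinates, family,
    structure, methylation class, LTR sub-intervals/subtypes, planted
    context flags).  ``latents`` maps (element_id, end) to the
    per-individual latent methylation levels of individual-level
    classes; DMR classes are driven by group means in the config.
    ``pools`` maps replicate id to the indices of its pooled
    individuals.
    """

    elements: pd.DataFrame
    latents: dict[tuple[str, str], np.ndarray]
    pools: dict[str, np.ndarray]
    n_individuals: int
    ltr_sequences: dict[tuple[str, str], str]
    genes: pd.DataFrame

    def ends_of(self, element_id: str) -> list[str]:
        row = self.elements.set_index("id").loc[element_id]
        out = []
        if row["ltr5_start"] >= 0:
            out.append("5p")
        if row["ltr3_start"] >= 0:
            out.append("3p")
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = {
            "elements": self.elements.to_dict(orient="records"),
            "latents": {f"{eid}|{end}": arr.tolist() for (eid, end), arr in self.latents.items()},
            "pools": {rid: arr.tolist() for rid, arr in self.pools.items()},
            "n_individuals": self.n_individuals,
            "ltr_sequences": {f"{eid}|{end}": seq for (eid, end), seq in self.ltr_sequences.items()},
            "genes": self.genes.to_dict(orient="records"),
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def read(cls, outdir: str | Path) -> "TruthTable":
        with open(Path(outdir) / "truth.json") as fh:
            payload = json.load(fh)

        def split(k):
            eid, end = k.rsplit("|", 1)
            return eid, end

        return cls(
            elements=pd.DataFrame(payload["elements"]),
            latents={split(k): np.asarray(v) for k, v in payload["latents"].items()},
            pools={k: np.asarray(v, dtype=int) for k, v in payload["pools"].items()},
            n_individuals=payload["n_individuals"],
            ltr_sequences={split(k): v for k, v in payload["ltr_sequences"].items()},
            genes=pd.DataFrame(payload["genes"]),
        )


def truth_to_elements(truth: TruthTable) -> list[ErvElement]:
    """ErvElement views of the truth table (for driving downstream stages directly)."""
    out = []
    for row in truth.elements.itertuples(index=False):
        ltr5 = (int(row.ltr5_start), int(row.ltr5_end)) if row.ltr5_start >= 0 else None
        ltr3 = (int(row.ltr3_start), int(row.ltr3_end)) if row.ltr3_start >= 0 else None
        out.append(
            ErvElement(
                id=row.id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                family=row.family,
                structure=row.structure,
                ltr5=ltr5,
                ltr3=ltr3,
                ltr5_subtype=row.ltr5_subtype or None,
                ltr3_subtype=row.ltr3_subtype or None,
                has_internal=row.structure in ("full_length", "trunc_5p", "trunc_3p", "internal_only"),
            )
        )
    return out


def _ltr_sequence(length: int, density_pct: float, rng: np.random.Generator) -> str:
    """Random LTR sequence with an exact planted CpG count.

    CpGs are planted at even offsets (spacing >= 2) and all accidental
    CG dinucleotides in the background are broken, so the realised CpG
    density equals the target to rounding.
    """
    n_cpg = max(1, round(density_pct / 100.0 * length))
    slots = np.arange(0, length - 2, 2)
    planted = set(rng.choice(slots, size=min(n_cpg, slots.size), replace=False).tolist())
    seq = rng.choice(list("ACGT"), size=length).tolist()
    for i in sorted(planted):
        seq[i], seq[i + 1] = "C", "G"
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in planted:
            seq[i + 1] = "A"
    return "".join(seq)


def _element_layout(structure: str, strand: str, ltr_len: int, int_len: int):
    """Genomic part order (kind, length) for a structure; kinds are
    'ltr_left', 'ltr_right', 'int'.  Strand decides which genomic side a
    surviving LTR occupies for truncated structures (the 5' LTR is the
    genomically rightmost one on the minus strand)."""
    if structure == "full_length":
        return [("ltr_left", ltr_len), ("int", int_len), ("ltr_right", ltr_len)]
    if structure == "solo_LTR":
        return [("ltr_left", ltr_len)]
    if structure == "internal_only":
        return [("int", int_len // 2), ("int", int_len - int_len // 2)]
    if structure == "trunc_5p":  # 3' LTR survives
        if strand == "+":
            return [("int", int_len), ("ltr_right", ltr_len)]
        return [("ltr_left", ltr_len), ("int", int_len)]
    if structure == "trunc_3p":  # 5' LTR survives
        if strand == "+":
            return [("ltr_left", ltr_len), ("int", int_len)]
        return [("int", int_len), ("ltr_right", ltr_len)]
    raise ValueError(f"unknown structure {structure!r}")


def _side_to_end(side: str, strand: str, structure: str = "") -> str:
    if structure == "solo_LTR":
        # an isolated LTR has no internal anchor to orient it; report in the 5' slot
        return "5p"
    left_is_5p = strand == "+"
    if side == "ltr_left":
        return "5p" if left_is_5p else "3p"
    return "3p" if left_is_5p else "5p"


def _assign_pools(config: SimulationConfig) -> tuple[dict[str, np.ndarray], int]:
    """Assign pooled individuals to replicates.

    By default every replicate pools its own individuals; in shared
    mode the B and T replicates with matching (sex, assay, pool index)
    pool the same individuals, exposing the intraindividual-consistency
    structure across cell types.
    """
    pools: dict[str, np.ndarray] = {}
    registry: dict[tuple, np.ndarray] = {}
    occurrence: dict[tuple, int] = {}
    next_individual = 0
    for rep in config.replicates:
        occ_key = (rep.cell_type, rep.sex, rep.assay)
        k = occurrence.get(occ_key, 0)
        occurrence[occ_key] = k + 1
        pool_key = (
            (rep.sex, rep.assay, k)
            if config.share_individuals_between_cell_types
            else (rep.cell_type, rep.sex, rep.assay, k)
        )
        if pool_key not in registry:
            registry[pool_key] = np.arange(next_individual, next_individual + rep.pool_size)
            next_individual += rep.pool_size
        pools[rep.id] = registry[pool_key]
    return pools, next_individual


def _draw_latents(meth_class: str, n: int, config: SimulationConfig, rng: np.random.Generator):
    lo, hi = config.variable_range
    if meth_class == "variable":
        if config.variable_distribution == "beta":
            a, b = config.variable_beta_ab
            return lo + (hi - lo) * rng.beta(a, b, size=n)
        return rng.uniform(lo, hi, size=n)
    if meth_class == "hypermethylated":
        return np.clip(rng.normal(config.hyper_mean, config.hyper_sd, size=n), 0.0, 1.0)
    if meth_class == "hypomethylated":
        return np.clip(rng.normal(config.hypo_mean, config.hypo_sd, size=n), 0.0, 1.0)
    return None  # DMR classes are driven by group means


def generate_annotation(config: SimulationConfig):
    """Generate the repeat fragment table, gene annotation and truth table.

    Full-length elements emit LTR-internal-LTR fragment triplets with
    gaps below the assembler's default merge gap.  Returns
    ``(fragments, genes, truth)`` where fragments/genes are DataFrames
    (rmsk-style and BED-style columns respectively).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    pools, n_individuals = _assign_pools(config)

    specs: list[tuple[str, str, str]] = []
    for (fam, struct, mclass), count in sorted(config.element_counts.items()):
        specs.extend([(fam, struct, mclass)] * count)
    rng.shuffle(specs)

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    margin = 60_000  # keep elements clear of chromosome ends (flanks, planted peaks)
    cursors = {c: margin for c in chrom_names}
    chrom_idx = 0

    frag_rows, el_rows = [], []
    latents: dict[tuple[str, str], np.ndarray] = {}
    ltr_sequences: dict[tuple[str, str], str] = {}

    for idx, (fam, struct, mclass) in enumerate(specs):
        strand = str(rng.choice(["+", "-"]))
        ltr_len = config.ltr_length_bp[fam]
        int_len = config.internal_length_bp[fam]
        layout = _element_layout(struct, strand, ltr_len, int_len)
        gaps = [int(rng.integers(*config.fragment_gap_bp)) for _ in range(max(0, len(layout) - 1))]
        span = sum(length for _, length in layout) + sum(gaps)
        spacing = int(rng.integers(*config.element_spacing_bp))

        while chrom_idx < len(chrom_names) and (
            cursors[chrom_names[chrom_idx]] + spacing + span > config.chrom_length_bp - margin
        ):
            chrom_idx += 1
        if chrom_idx >= len(chrom_names):
            raise ValueError(
                "synthetic genome too small for the requested element counts; "
                "increase chrom_length_bp or n_chromosomes"
            )
        chrom = chrom_names[chrom_idx]
        start = cursors[chrom] + spacing
        cursors[chrom] = start + span

        eid = f"{fam}_{idx:05d}"
        subtype = _LTR_SUBTYPES[fam]["solo" if struct == "solo_LTR" else "full"]
        pos = start
        ltr_intervals: dict[str, tuple[int, int]] = {}
        for part_i, (kind, length) in enumerate(layout):
            if part_i > 0:
                pos += gaps[part_i - 1]
            interval = (pos, pos + length)
            if kind == "int":
                rep_name = _INTERNAL_NAMES[fam]
            else:
                rep_name = subtype
                ltr_intervals[_side_to_end(kind, strand, struct)] = interval
            frag_rows.append(
                {
                    "chrom": chrom,
                    "start": interval[0],
                    "end": interval[1],
                    "strand": strand,
                    "repName": rep_name,
                    "repClass": "LTR",
                    "repFamily": _REP_FAMILY[fam],
                }
            )
            pos += length
        end = pos

        for ltr_end in sorted(ltr_intervals):
            ltr_sequences[(eid, ltr_end)] = _ltr_sequence(
                ltr_intervals[ltr_end][1] - ltr_intervals[ltr_end][0],
                config.cpg_density_pct[fam],
                rng,
            )
            lat = _draw_latents(mclass, n_individuals, config, rng)
            if lat is not None:
                latents[(eid, ltr_end)] = lat

        el_rows.append(
            {
                "id": eid,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "family": fam,
                "structure": struct,
                "meth_class": mclass,
                "ltr5_start": ltr_intervals.get("5p", (-1, -1))[0],
                "ltr5_end": ltr_intervals.get("5p", (-1, -1))[1],
                "ltr3_start": ltr_intervals.get("3p", (-1, -1))[0],
                "ltr3_end": ltr_intervals.get("3p", (-1, -1))[1],
                "ltr5_subtype": subtype if "5p" in ltr_intervals else "",
                "ltr3_subtype": subtype if "3p" in ltr_intervals else "",
                "peak_distance": -1,
                "transcript_cell": "",
                "transcript_sex": "",
                "transcript_nreps": 0,
                "de_overlap": False,
            }
        )

    elements = pd.DataFrame(
        el_rows,
        columns=[
            "id", "chrom", "start", "end", "strand", "family", "structure", "meth_class",
            "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end", "ltr5_subtype", "ltr3_subtype",
            "peak_distance", "transcript_cell", "transcript_sex", "transcript_nreps", "de_overlap",
        ],
    )
    fragments = pd.DataFrame(frag_rows, columns=RMSK_COLUMNS)

    # genes: non-overlapping intervals laid out independently of elements
    gene_rows = []
    per_chrom = -(-config.n_genes // config.n_chromosomes) if config.n_genes else 0
    gid = 0
    for chrom in chrom_names:
        cursor = int(rng.integers(1_000, 50_000))
        for _ in range(per_chrom):
            if gid >= config.n_genes:
                break
            length = int(rng.integers(*config.gene_length_bp))
            gap = int(rng.integers(1_000, max(2_000, config.chrom_length_bp // (2 * per_chrom))))
            start = cursor + gap
            if start + length > config.chrom_length_bp:
                break
            gene_rows.append(
                {"chrom": chrom, "start": start, "end": start + length,
                 "gene_id": f"gene{gid:04d}", "strand": str(rng.choice(["+", "-"]))}
            )
            cursor = start + length
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id", "strand"])

    truth = TruthTable(
        elements=elements,
        latents=latents,
        pools=pools,
        n_individuals=n_individuals,
        ltr_sequences=ltr_sequences,
        genes=genes,
    )
    _plant_context_flags(truth, config, rng)
    return fragments, genes, truth


def _plant_context_flags(truth: TruthTable, config: SimulationConfig, rng: np.random.Generator):
    el = truth.elements
    # CTCF-like peaks are planted near variable elements; everything else is background
    variable_idx = el.index[el["meth_class"] == "variable"]
    el.loc[variable_idx, "peak_distance"] = rng.integers(
        config.peak_distance_bp[0], config.peak_distance_bp[1] + 1, size=variable_idx.size
    )
    # transcript-overlap groups
    with_ltr = el.index[(el["ltr5_start"] >= 0) | (el["ltr3_start"] >= 0)]
    n_tx = min(config.n_transcript_elements, with_ltr.size)
    tx_idx = with_ltr[:n_tx]
    combos = [(c, s) for c in ("B", "T") for s in ("F", "M")]
    for j, i in enumerate(tx_idx):
        cell, sex = combos[j % len(combos)]
        el.loc[i, ["transcript_cell", "transcript_sex"]] = (cell, sex)
        el.loc[i, "transcript_nreps"] = config.transcript_replicates
    # biased-screen planting: DE status will be given to the nearest genes of these elements
    n_de = min(config.n_de_elements, el.shape[0])
    de_idx = el.index[el["meth_class"] == "variable"][:n_de]
    if de_idx.size < n_de:
        extra = el.index.difference(de_idx)[: n_de - de_idx.size]
        de_idx = de_idx.union(extra)
    el.loc[de_idx, "de_overlap"] = True


def generate_methylation_tracks(truth: TruthTable, config: SimulationConfig) -> MethylationTrackSet:
    """Per-replicate bedGraph-style methylation tracks over all LTR CpGs.

    Each CpG yields two strand records per replicate; the observed
    fraction is Binomial(depth, p_pool)/depth with depth ~
    Poisson(coverage) per strand, where p_pool is the mean latent level
    of the replicate's pooled individuals (or the group mean for DMR
    classes).  oxBS replicates see the modified signal reduced by the
    hydroxymethylation fraction.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    el = truth.elements
    chrom_chunks: dict[str, list] = {rep.id: [] for rep in config.replicates}
    pos_chunks: dict[str, list] = {rep.id: [] for rep in config.replicates}
    frac_chunks: dict[str, list] = {rep.id: [] for rep in config.replicates}

    for row in el.itertuples(index=False):
        ends = []
        if row.ltr5_start >= 0:
            ends.append(("5p", int(row.ltr5_start)))
        if row.ltr3_start >= 0:
            ends.append(("3p", int(row.ltr3_start)))
        for end_name, ltr_start in ends:
            seq = truth.ltr_sequences[(row.id, end_name)]
            c_offsets = np.array([i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"])
            if c_offsets.size == 0:
                continue
            c_pos = ltr_start + c_offsets
            strand_pos = np.concatenate([c_pos, c_pos + 1])
            strand_pos.sort()
            m = strand_pos.size
            for rep in config.replicates:
                if row.meth_class == "celltype_DMR":
                    p_pool = config.dmr_celltype_means[rep.cell_type]
                elif row.meth_class == "sex_DMR":
                    p_pool = config.dmr_sex_means[rep.sex]
                else:
                    lat = truth.latents[(row.id, end_name)]
                    p_pool = float(lat[truth.pools[rep.id]].mean())
                if rep.assay == "oxBS":
                    p_pool = p_pool * (1.0 - config.hmc_fraction)
                depth = rng.poisson(config.coverage, size=m)
                hits = rng.binomial(np.maximum(depth, 1), p_pool)
                keep = depth > 0
                frac = hits[keep] / depth[keep]
                chrom_chunks[rep.id].append((row.chrom, int(keep.sum())))
                pos_chunks[rep.id].append(strand_pos[keep])
                frac_chunks[rep.id].append(frac)

    out = {}
    for rep in config.replicates:
        if pos_chunks[rep.id]:
            chroms = np.repeat(
                [c for c, _n in chrom_chunks[rep.id]],
                [n for _c, n in chrom_chunks[rep.id]],
            )
            df = pd.DataFrame(
                {
                    "chrom": chroms,
                    "pos": np.concatenate(pos_chunks[rep.id]),
                    "fraction": np.concatenate(frac_chunks[rep.id]),
                }
            )
            df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        else:
            df = pd.DataFrame(columns=["chrom", "pos", "fraction"])
        out[rep.id] = df
    return MethylationTrackSet(replicates=list(config.replicates), tracks=out)


@dataclass
class ContextData:
    """Planted genomic context: ChIP-like signal, peak calls, per-replicate
    transcript intervals, and a DE gene list."""

    signal: pd.DataFrame  # chrom, start, end, value
    peaks: pd.DataFrame  # BED6
    transcripts: dict[str, pd.DataFrame]  # rna replicate id -> BED6
    transcript_meta: dict[str, tuple[str, str]]  # rna replicate id -> (cell_type, sex)
    de_genes: list[str]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.signal.to_csv(outdir / "signal.bedGraph", sep="\t", header=False, index=False)
        self.peaks.to_csv(outdir / "peaks.bed", sep="\t", header=False, index=False)
        tx_dir = outdir / "transcripts"
        tx_dir.mkdir(exist_ok=True)
        for rid, df in self.transcripts.items():
            df.to_csv(tx_dir / f"{rid}.bed", sep="\t", header=False, index=False)
        with open(outdir / "de_genes.txt", "w") as fh:
            fh.write("\n".join(self.de_genes) + ("\n" if self.de_genes else ""))


def generate_context(truth: TruthTable, config: SimulationConfig) -> ContextData:
    """Signal/peak/transcript/DE-list inputs consistent with the planted truth.

    Peaks are placed at each flagged element's planted distance from a
    border (plus uniform background peaks); flank signal is enriched
    around peak-flagged elements; transcripts are emitted for the
    planted (cell type, sex) replicate groups; the DE list contains the
    nearest genes of the de-flagged elements.
    """
    from .context import nearest_gene  # local import to avoid a module cycle

    rng = np.random.default_rng([config.seed, 2])
    el = truth.elements
    chrom_names = sorted(el["chrom"].unique().tolist()) or [
        f"chr{i + 1}" for i in range(config.n_chromosomes)
    ]

    signal_rows, peak_rows = [], []
    for row in el.itertuples(index=False):
        if row.peak_distance < 0:
            continue
        d = int(row.peak_distance)
        side = rng.choice(["left", "right"])
        if side == "left":
            p_end = int(row.start) - d
            p_start = p_end - config.peak_width_bp
        else:
            p_start = int(row.end) + d
            p_end = p_start + config.peak_width_bp
        if p_start < 0 or p_end > config.chrom_length_bp:
            raise ValueError(
                f"planted peak distance {d} puts peak outside chromosome bounds for {row.id}"
            )
        peak_rows.append({"chrom": row.chrom, "start": p_start, "end": p_end,
                          "name": f"peak_{row.id}", "score": 1000, "strand": "."})
        height = float(rng.uniform(1.5, 2.5))
        signal_rows.append({"chrom": row.chrom, "start": int(row.start) - 1_000,
                            "end": int(row.start), "value": height})
        signal_rows.append({"chrom": row.chrom, "start": int(row.end),
                            "end": int(row.end) + 1_000, "value": height})
    for chrom in chrom_names:
        starts = rng.integers(0, config.chrom_length_bp - config.peak_width_bp,
                              size=config.n_background_peaks_per_chrom)
        for j, s in enumerate(sorted(starts.tolist())):
            peak_rows.append({"chrom": chrom, "start": s, "end": s + config.peak_width_bp,
                              "name": f"bg_{chrom}_{j}", "score": 200, "strand": "."})

    signal = pd.DataFrame(signal_rows, columns=["chrom", "start", "end", "value"])
    if len(signal):
        signal = signal.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    if len(peaks):
        peaks = peaks.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    # 12 RNA replicates: 3 per (cell type, sex)
    tx_meta = {}
    transcripts: dict[str, list] = {}
    for cell in ("B", "T"):
        for sex in ("F", "M"):
            for k in range(1, 4):
                rid = f"RNA_{cell}_{sex}_{k}"
                tx_meta[rid] = (cell, sex)
                transcripts[rid] = []
    for row in el.itertuples(index=False):
        if not row.transcript_cell:
            continue
        group = [r for r, (c, s) in tx_meta.items()
                 if c == row.transcript_cell and s == row.transcript_sex]
        for rid in group[: int(row.transcript_nreps)]:
            # transcript initiates inside the element and runs outward (strand-aware)
            jitter = int(rng.integers(10, max(11, (int(row.end) - int(row.start)) // 4)))
            length = int(rng.integers(2_000, 8_000))
            if row.strand == "+":
                t_start = int(row.start) + jitter
                t_end = int(row.end) + length
                t_strand = "+"
            else:
                t_end = int(row.end) - jitter
                t_start = max(0, int(row.start) - length)
                t_strand = "-"
            transcripts[rid].append({"chrom": row.chrom, "start": t_start, "end": t_end,
                                     "name": f"tx_{row.id}", "score": 0, "strand": t_strand})
    # background transcripts over genes, present in all replicates
    genes = truth.genes
    if len(genes):
        bg = genes.iloc[:: max(1, len(genes) // 20)]
        for rid in transcripts:
            for g in bg.itertuples(index=False):
                transcripts[rid].append({"chrom": g.chrom, "start": int(g.start),
                                         "end": int(g.end), "name": f"tx_{g.gene_id}",
                                         "score": 0, "strand": g.strand})
    tx_frames = {
        rid: pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
        for rid, rows in transcripts.items()
    }

    de_genes: list[str] = []
    if len(genes):
        for e in truth_to_elements(truth):
            flag = el.loc[el["id"] == e.id, "de_overlap"]
            if len(flag) and bool(flag.iloc[0]):
                gene_id, _dist = nearest_gene(e, genes)
                if gene_id is not None:
                    de_genes.append(gene_id)
        de_genes = sorted(set(de_genes))

    return ContextData(signal=signal, peaks=peaks, transcripts=tx_frames,
                       transcript_meta=tx_meta, de_genes=de_genes)


def generate_pedigree(
    seed: int = 0,
    n_pairs: int = 30,
    litters_per_pair: int = 2,
    pups_per_litter: int = 6,
    beta_maternal: float = 0.5,
    beta_paternal: float = 0.0,
    beta_sex: float = 0.0,
    intercept: float = 0.0,
    sd_pair: float = 0.3,
    sd_litter: float = 0.2,
    sd_residual: float = 0.5,
    parental_range: tuple[float, float] = (0.05, 0.95),
) -> pd.DataFrame:
    """Simulated breeding data with planted parental/sex effects.

    Offspring logit-methylation = intercept + beta_maternal*logit(m_dam)
    + beta_paternal*logit(m_sire) + beta_sex*I(male) + pair intercept +
    litter intercept + residual, mapped back through the inverse logit.
    Parental levels are drawn from the variably-methylated range and
    sexes are assigned ~1:1.
    """
    if min(n_pairs, litters_per_pair, pups_per_litter) <= 0:
        raise ValueError("pedigree counts must be positive")
    if min(sd_pair, sd_litter, sd_residual) < 0:
        raise ValueError("standard deviations must be >= 0")
    lo, hi = parental_range
    if not 0 < lo < hi < 1:
        raise ValueError("parental_range must lie strictly inside (0, 1)")
    rng = np.random.default_rng([seed, 3])
    rows = []
    for p in range(1, n_pairs + 1):
        m_dam = float(rng.uniform(lo, hi))
        m_sire = float(rng.uniform(lo, hi))
        u_pair = float(rng.normal(0.0, sd_pair))
        for l in range(1, litters_per_pair + 1):
            u_litter = float(rng.normal(0.0, sd_litter))
            for a in range(1, pups_per_litter + 1):
                sex = str(rng.choice(["F", "M"]))
                eta = (
                    intercept
                    + beta_maternal * np.log(m_dam / (1 - m_dam))
                    + beta_paternal * np.log(m_sire / (1 - m_sire))
                    + beta_sex * (sex == "M")
                    + u_pair
                    + u_litter
                    + float(rng.normal(0.0, sd_residual))
                )
                rows.append(
                    {
                        "animal_id": f"P{p:03d}_L{l}_A{a}",
                        "sex": sex,
                        "methylation": float(expit(eta)),
                        "dam_id": f"D{p:03d}",
                        "sire_id": f"S{p:03d}",
                        "pair_id": f"P{p:03d}",
                        "litter_id": f"P{p:03d}_L{l}",
                        "maternal_methylation": m_dam,
                        "paternal_methylation": m_sire,
                    }
                )
    return pd.DataFrame(rows)


def write_annotation(fragments: pd.DataFrame, genes: pd.DataFrame, outdir: str | Path) -> None:
    """Write the rmsk-style fragment table and gene BED to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fragments.to_csv(outdir / "rmsk.tsv", sep="\t", index=False)
    genes.to_csv(outdir / "genes.bed", sep="\t", header=False, index=False)
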