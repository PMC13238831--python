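"""Readers and writers for the package's file formats.

Formats are deliberately plain text: FASTA allele libraries with
``Sasa-<LOCUS>*dd:dd``-style headers, Phred+33 FASTQ read pairs, long-format
genotype CSV (one row per individual x locus), primer CSV, TSV summaries and
JSON fit/config outputs. Every writer stamps a provenance header
(``# salmhc ... config_hash=... seed=...``) which readers skip.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotyping import PrimerPool, ReadPair
from .nomenclature import AlleleRecord, parse_allele_name
from .simulate import GENOTYPE_COLUMNS

LOCI = ("UBA", "DAA", "DAB")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Thresholds and options shared by the CLI subcommands."""

    reads_dir: str | None = None
    library: str | None = None
    primers: str | None = None
    genotype_table: str | None = None
    top_n: int = 5
    min_frac: float = 0.01
    trim_max: int = 2
    homozygote_depth_floor: int = 50
    min_mean_quality: float = 20.0
    rarefaction_individuals: int = 17
    fst_estimator: str = "nei1987"
    hwe_permutations: int = 10_000
    bootstrap_iters: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.top_n <= 100:
            raise ValueError("top_n outside [1, 100]")
        if not 0.0 <= self.min_frac <= 0.5:
            raise ValueError("min_frac outside [0, 0.5]")
        if self.trim_max != 2:
            raise ValueError("frame trimming is defined for 0-2 nt from each end")
        if self.hwe_permutations < 100 or self.bootstrap_iters < 1:
            raise ValueError("resampling iteration counts too small")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    @property
    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(config: RunConfig | None = None, seed: int | None = None) -> str:
    cfg = config.hash if config else "default"
    sd = seed if seed is not None else (config.seed if config else 0)
    return f"# salmhc config_hash={cfg} seed={sd}\n"


# ---------------------------------------------------------------------------
# allele libraries (FASTA)
# ---------------------------------------------------------------------------


def read_library(path: str | Path) -> list[AlleleRecord]:
    """Read a reference allele library from FASTA.

    Headers must parse as ``Sasa-<LOCUS>*dd:dd[:dd][_suffix]``; an optional
    ``lineage=<roman>`` tag in the description carries the alpha-1 lineage.
    Malformed headers raise a parse error naming the record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            name = parse_allele_name(rec.id)
        except ValueError as e:
            raise ValueError(f"malformed FASTA header {rec.id!r}: {e}") from e
        lineage = None
        for tok in rec.description.split():
            if tok.startswith("lineage="):
                lineage = tok.split("=", 1)[1]
        records.append(AlleleRecord(name, str(rec.seq).upper(), lineage=lineage))
    return records


def write_library(records: list[AlleleRecord], path: str | Path) -> None:
    out = []
    for r in records:
        desc = f"lineage={r.lineage}" if r.lineage else ""
        out.append(SeqRecord(Seq(r.sequence), id=str(r.name), description=desc))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------


def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format genotype CSV.

    Columns: individual, population, group, sex, locus, allele1, allele2.
    Duplicate (individual, locus) rows and unknown loci are rejected with
    the offending row numbers.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table missing columns: {missing}")
    bad = df[~df["locus"].isin(LOCI)]
    if not bad.empty:
        raise ValueError(f"unknown locus in rows {list(bad.index + 2)}")
    dup = df.duplicated(subset=["individual", "locus"], keep=False)
    if dup.any():
        raise ValueError(
            f"duplicate individual x locus rows: {list(df.index[dup] + 2)}"
        )
    return df


def write_genotype_table(
    df: pd.DataFrame, path: str | Path, config: RunConfig | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config))
        df.to_csv(fh, index=False)


def read_wide_genotype_table(path: str | Path) -> pd.DataFrame:
    """Import a wide per-individual table (one row per individual with
    UBA_1..DAB_2 columns, the supplementary-table layout) into the
    long format used by all statistics. A row carrying a third allele
    column for a locus is rejected with its row number.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    for locus in LOCI:
        extra = [c for c in df.columns if c.startswith(f"{locus}_") and
                 c not in (f"{locus}_1", f"{locus}_2")]
        if extra:
            raise ValueError(
                f"{locus}: more than two allele columns ({extra}); "
                "a diploid carries at most two alleles per locus"
            )
    rows = []
    for i, row in df.iterrows():
        for locus in LOCI:
            c1, c2 = f"{locus}_1", f"{locus}_2"
            if c1 not in df.columns:
                continue
            a1, a2 = row.get(c1), row.get(c2)
            if pd.isna(a1) != pd.isna(a2):
                raise ValueError(f"row {i + 2}: half-missing {locus} genotype")
            rows.append([
                row["individual"], row["population"], row.get("group", ""),
                row.get("sex", ""), locus, a1, a2,
            ])
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


# ---------------------------------------------------------------------------
# primers and reads
# ---------------------------------------------------------------------------


def read_primers(path: str | Path) -> list[PrimerPool]:
    """Primer CSV: pool,locus,forward,reverse,lineages (lineages '|'-separated,
    empty for class II)."""
    df = pd.read_csv(path, comment="#", dtype=str).fillna("")
    pools = []
    for _, row in df.iterrows():
        lineages = tuple(x for x in row.get("lineages", "").split("|") if x)
        pools.append(
            PrimerPool(row["pool"], row["locus"], row["forward"].upper(),
                       row["reverse"].upper(), lineages)
        )
    return pools


def write_primers(pools: list[PrimerPool], path: str | Path) -> None:
    rows = [
        {"pool": p.name, "locus": p.locus, "forward": p.forward,
         "reverse": p.reverse, "lineages": "|".join(p.lineages)}
        for p in pools
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fastq_pairs(
    pairs: list[ReadPair], prefix: str | Path, name: str
) -> tuple[Path, Path]:
    """Write read pairs as <prefix>_R1.fastq / <prefix>_R2.fastq."""
    p1 = Path(f"{prefix}_R1.fastq")
    p2 = Path(f"{prefix}_R2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for i, rp in enumerate(pairs):
            f1.write(f"@{name}:{i + 1}/1\n{rp.seq1}\n+\n{rp.qual1}\n")
            f2.write(f"@{name}:{i + 1}/2\n{rp.seq2}\n+\n{rp.qual2}\n")
    return p1, p2


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    r1 = list(SeqIO.parse(str(path1), "fastq"))
    r2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("read 1 / read 2 files differ in record count")
    pairs = []
    for a, b in zip(r1, r2):
        q1 = "".join(chr(q + 33) for q in a.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in b.letter_annotations["phred_quality"])
        pairs.append(ReadPair(str(a.seq).upper(), q1, str(b.seq).upper(), q2))
    return pairs


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def write_table(
    df: pd.DataFrame, path: str | Path, config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(
    obj: dict, path: str | Path, config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    payload = {"_provenance": provenance_header(config, seed).strip("# \n"), **obj}
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
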