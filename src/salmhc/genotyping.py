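"""Amplicon genotyping: paired reads -> at most two called alleles per locus.

The pipeline mirrors a standard MHC amplicon workflow on quality-filtered
reads: primer demultiplexing with zero mismatches, FLASH-style overlap
merging, exact collapsing of merged reads ranked by abundance, selection of
the top candidates above a fractional-abundance floor, and a 0-2 nt trim at
each end to restore the reading frame before translation. Since UBA, DAA and
DAB are each single-copy classical loci, an individual carries at most two
alleles per locus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .nomenclature import translate

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TOP_N = 5
MIN_FRAC = 0.01
MIN_OVERLAP = 10
MAX_MISMATCH_DENSITY = 0.25
MIN_MEAN_QUALITY = 20.0
HOMOZYGOTE_DEPTH_FLOOR = 50


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPool:
    """One first-PCR primer pair. For UBA, each forward primer amplifies a
    fixed subset of alpha-1 lineages; class II loci use a single pool."""

    name: str
    locus: str
    forward: str
    reverse: str
    lineages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError(f"pool {self.name}: primers must be non-empty")


@dataclass
class ReadPair:
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class CandidateSet:
    """Ranked unique merged reads for one individual x primer pool."""

    individual: str
    pool: str
    ranked: list[tuple[str, int]]
    total_merged: int


@dataclass
class GenotypeCall:
    individual: str
    locus: str
    allele1: str | None
    allele2: str | None
    support1: int = 0
    support2: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def missing(self) -> bool:
        return self.allele1 is None


def mean_quality(qual: str) -> float:
    if not qual:
        return 0.0
    return float(np.mean(np.frombuffer(qual.encode(), np.uint8))) - 33.0


def quality_filter(
    pairs: list[ReadPair],
    min_mean_q: float = MIN_MEAN_QUALITY,
    min_length: int = 0,
) -> list[ReadPair]:
    """Drop read pairs whose either mate has mean Phred quality below
    *min_mean_q* or length below *min_length*."""
    return [
        p
        for p in pairs
        if len(p.seq1) >= min_length
        and len(p.seq2) >= min_length
        and mean_quality(p.qual1) >= min_mean_q
        and mean_quality(p.qual2) >= min_mean_q
    ]


def demultiplex_by_primer(
    pairs: list[ReadPair], pools: list[PrimerPool]
) -> tuple[dict[str, list[ReadPair]], int]:
    """Assign read pairs to primer pools with zero mismatches.

    A pair belongs to a pool iff read 1 begins exactly with the pool's
    forward primer and read 2 with its reverse; primers are stripped from
    the assigned reads. Returns (pool name -> stripped pairs, n unassigned).
    A pair matching two pools signals a malformed pool configuration (e.g.
    one forward primer a prefix of another) and raises.
    """
    forwards = [p.forward for p in pools]
    if len(set(forwards)) != len(forwards):
        raise ValueError("primer pools must have distinct forward primers")
    out: dict[str, list[ReadPair]] = {p.name: [] for p in pools}
    unassigned = 0
    for rp in pairs:
        hits = [
            p
            for p in pools
            if rp.seq1.startswith(p.forward) and rp.seq2.startswith(p.reverse)
        ]
        if len(hits) > 1:
            raise ValueError(
                f"read pair matches pools {[p.name for p in hits]}; "
                "malformed pool configuration"
            )
        if not hits:
            unassigned += 1
            continue
        p = hits[0]
        nf, nr = len(p.forward), len(p.reverse)
        out[p.name].append(
            ReadPair(rp.seq1[nf:], rp.qual1[nf:], rp.seq2[nr:], rp.qual2[nr:])
        )
    return out, unassigned


def merge_pairs(
    pair: ReadPair,
    min_overlap: int = MIN_OVERLAP,
    max_mismatch_density: float = MAX_MISMATCH_DENSITY,
) -> str | None:
    """FLASH-style merge of a primer-stripped read pair.

    Read 2 is reverse-complemented and slid against read 1; among overlap
    lengths >= *min_overlap* whose mismatch density is <= the cap, the one
    with the most matching bases wins. Disagreeing overlap bases take the
    higher-quality call (read 1 wins ties). Returns ``None`` when no
    admissible overlap exists.
    """
    s1 = np.frombuffer(pair.seq1.encode(), np.uint8)
    s2 = np.frombuffer(revcomp(pair.seq2).encode(), np.uint8)
    q1 = np.frombuffer(pair.qual1.encode(), np.uint8)
    q2 = np.frombuffer(pair.qual2.encode(), np.uint8)[::-1].copy()
    n1, n2 = len(s1), len(s2)
    best_ov, best_matches = 0, -1
    for ov in range(min_overlap, min(n1, n2) + 1):
        matches = int(np.count_nonzero(s1[n1 - ov:] == s2[:ov]))
        if (ov - matches) / ov > max_mismatch_density:
            continue
        if matches > best_matches:
            best_matches, best_ov = matches, ov
    if best_ov == 0:
        return None
    ov = best_ov
    a, b = s1[n1 - ov:], s2[:ov]
    qa, qb = q1[n1 - ov:], q2[:ov]
    cons = np.where((a == b) | (qa >= qb), a, b)
    return (
        pair.seq1[: n1 - ov]
        + cons.tobytes().decode()
        + revcomp(pair.seq2)[ov:]
    )


def collapse_and_rank(
    merged: list[str], individual: str = "", pool: str = ""
) -> CandidateSet:
    """Collapse exact duplicate merged reads and rank by count.

    Count ties break lexicographically on the sequence so output order is
    deterministic and independent of input read order.
    """
    counts = Counter(merged)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return CandidateSet(individual, pool, ranked, total_merged=len(merged))


def select_candidates(
    candidates: CandidateSet, top_n: int = TOP_N, min_frac: float = MIN_FRAC
) -> list[tuple[str, int]]:
    """Keep the *top_n* most abundant merged sequences whose count is at
    least *min_frac* of all merged reads in the pool."""
    if candidates.total_merged == 0:
        return []
    floor = min_frac * candidates.total_merged
    return [(s, c) for s, c in candidates.ranked[:top_n] if c >= floor]


@dataclass
class FrameAdjustment:
    trimmed: str
    offset5: int
    offset3: int
    peptide: str


def frame_adjust(sequence: str) -> FrameAdjustment | None:
    """Trim 0-2 nt from each end to restore reading frame 0.

    Among the 9 trim combinations, pick the one whose frame-0 translation
    has no internal stop codon and the longest peptide; ties prefer the
    smallest (offset5, offset3). Returns ``None`` when every combination
    yields an internal stop (non-coding artefact).
    """
    if len(sequence) < 30:
        raise ValueError("sequence too short for frame adjustment")
    best: tuple | None = None
    for o5 in range(3):
        for o3 in range(3):
            trimmed = sequence[o5 : len(sequence) - o3 if o3 else len(sequence)]
            pep = translate(trimmed)
            core = pep[:-1] if pep.endswith("*") else pep
            if "*" in core:
                continue
            key = (-len(core), o5, o3)
            if best is None or key < best[0]:
                best = (key, FrameAdjustment(trimmed, o5, o3, core))
    return None if best is None else best[1]


def call_genotype(
    per_pool: dict[str, list[tuple[str, int]]],
    locus: str,
    individual: str = "",
    total_depth: int | None = None,
    homozygote_depth_floor: int = HOMOZYGOTE_DEPTH_FLOOR,
) -> GenotypeCall:
    """Unify named candidate alleles across primer pools into <= 2 calls.

    *per_pool* maps pool name -> [(allele name, read support)]. Support for
    the same allele seen in several pools is summed. More than two distinct
    alleles keeps the two best-supported and flags ``excess_alleles``; a
    single allele is a homozygote, flagged ``low_support`` when the merged
    read depth (*total_depth*, falling back to the candidate support) is
    below the depth floor; none is a missing genotype.
    """
    support: Counter[str] = Counter()
    for calls in per_pool.values():
        for name, cnt in calls:
            support[name] += cnt
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    flags: list[str] = []
    if not ranked:
        return GenotypeCall(individual, locus, None, None, flags=["missing_genotype"])
    if len(ranked) > 2:
        flags.append("excess_alleles")
        ranked = ranked[:2]
    if len(ranked) == 1:
        (a, c) = ranked[0]
        depth = total_depth if total_depth is not None else c
        if depth < homozygote_depth_floor:
            flags.append("low_support")
        return GenotypeCall(individual, locus, a, a, c, c, flags)
    (a1, c1), (a2, c2) = ranked
    return GenotypeCall(individual, locus, a1, a2, c1, c2, flags)


def genotype_individual(
    individual: str,
    pairs: list[ReadPair],
    pools: list[PrimerPool],
    classify,
    locus: str,
    top_n: int = TOP_N,
    min_frac: float = MIN_FRAC,
    min_mean_q: float = MIN_MEAN_QUALITY,
) -> GenotypeCall:
    """Run the full per-individual pipeline for one locus.

    *classify* maps a frame-adjusted nucleotide sequence to an allele name
    (typically a closure over ``nomenclature.assign_name``); returning
    ``None`` rejects the candidate.
    """
    locus_pools = [p for p in pools if p.locus == locus]
    kept = quality_filter(pairs, min_mean_q=min_mean_q)
    by_pool, _ = demultiplex_by_primer(kept, locus_pools)
    per_pool: dict[str, list[tuple[str, int]]] = {}
    total_depth = 0
    for pool_name, stripped in by_pool.items():
        merged = [m for p in stripped if (m := merge_pairs(p)) is not None]
        total_depth += len(merged)
        cset = collapse_and_rank(merged, individual, pool_name)
        selected = select_candidates(cset, top_n=top_n, min_frac=min_frac)
        calls: list[tuple[str, int]] = []
        for seq, cnt in selected:
            adj = frame_adjust(seq)
            if adj is None:
                continue
            name = classify(adj.trimmed)
            if name is not None:
                calls.append((name, cnt))
        per_pool[pool_name] = calls
    return call_genotype(per_pool, locus, individual, total_depth=total_depth)
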