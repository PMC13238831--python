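"""Synthetic allele libraries, populations, genotypes and amplicon reads.

Everything downstream of wet-lab sequencing is testable against a known
truth: this module generates (1) reference libraries with the class I
hallmark of ancient alpha-1 domain lineages shuffled onto divergent alpha-2
backgrounds, (2) skewed allele-frequency spectra with many rare alleles,
(3) diploid genotypes under Hardy-Weinberg equilibrium with an optional
homozygote excess F, and (4) paired amplicon reads with independent
substitution errors plus a truth manifest.

Sequences are built codon-safely so every allele translates without stop
codons in frame 0, and the alpha-1/alpha-2 junction is constrained so that
any alpha-1 can be recombined onto any alpha-2 without creating a stop —
the same property that intron-mediated domain shuffling exploits in vivo.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyping import PrimerPool, ReadPair, revcomp
from .nomenclature import AlleleName, AlleleRecord

# Sequence geometry: alpha-1 is modelled as 236 nt (the alignment frame
# commonly used for salmonid class I alpha-1 phylogenies) plus a short
# 16 nt alpha-2/downstream tail, keeping the class I insert (252 nt) well
# inside one 300 nt read so merged full-length amplicons retain an
# error-free modal sequence at realistic per-base error rates. Class II
# amplicons are a single 261 nt domain.
ALPHA1_LEN = 236
ALPHA2_LEN = 16
CLASSII_LEN = 261

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]

#: which alpha-1 lineages each UBA forward primer amplifies
UBA_POOL_LINEAGES = {
    "UBA.F1": ("I", "II", "V", "VI"),
    "UBA.F2": ("III", "VII"),
    "UBA.F3": ("IV",),
}

_LINEAGE_ORDER = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


def default_primer_pools() -> list[PrimerPool]:
    """Primer pools used throughout the synthetic pipeline: three UBA
    forward primers partitioning the alpha-1 lineages, one pool each for
    DAA and DAB. Sequences are fixed arbitrary 20-mers."""
    return [
        PrimerPool("UBA.F1", "UBA", "ACGTGTCTGACTCAGGTCAA", "TGCACCATGGACTTCAGACA",
                   UBA_POOL_LINEAGES["UBA.F1"]),
        PrimerPool("UBA.F2", "UBA", "GATTACCAGTCGCTGAACCT", "TGCACCATGGACTTCAGACA",
                   UBA_POOL_LINEAGES["UBA.F2"]),
        PrimerPool("UBA.F3", "UBA", "CCTGAGTTCGAATCCGGTAT", "TGCACCATGGACTTCAGACA",
                   UBA_POOL_LINEAGES["UBA.F3"]),
        PrimerPool("DAA.F", "DAA", "GGTCACTTGCTCCAGTAGAC", "CAGTGAACCTGGTTCGACTT"),
        PrimerPool("DAB.F", "DAB", "TTCGAGACCGTTAGCTGGAA", "GACCTTAGCAACGGTTCACA"),
    ]


@dataclass
class DivergenceParams:
    """Per-site substitution rates used when deriving sequences.

    ``between_lineage`` separates alpha-1 lineage founders from a common
    root; ``within`` separates alpha-2 backgrounds (class I) or alleles
    (class II) from their root.
    """

    within: float = 0.08
    between_lineage: float = 0.30


@dataclass
class SyntheticPopulationSpec:
    """Conditions for one simulated population at one locus."""

    locus: str = "UBA"
    K_true: int = 25
    freq_model: str = "geometric"  # or "dirichlet"
    r: float = 0.8
    alpha: float = 1.0
    n_individuals: int = 40
    F: float = 0.0
    seed: int = 0
    population: str = "sim"
    group: str = "wild"

    def __post_init__(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must lie in [0, 1]")


# ---------------------------------------------------------------------------
# codon-safe sequence construction
# ---------------------------------------------------------------------------


def _random_codon_seq(n_codons: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_CODONS, size=n_codons))


def _mutate_stop_free(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    frame_offset: int = 0,
    protect_tail: int = 0,
) -> str:
    """Substitute bases i.i.d. at *rate*, rejecting any substitution that
    creates a stop codon in the frame starting at *frame_offset*. The last
    *protect_tail* bases are never touched."""
    s = list(seq)
    n = len(s) - protect_tail
    hit = np.flatnonzero(rng.random(n) < rate)
    for i in hit:
        alts = [b for b in _BASES if b != s[i]]
        rng.shuffle(alts)
        for b in alts:
            old = s[i]
            s[i] = b
            if i >= frame_offset:
                c0 = frame_offset + 3 * ((i - frame_offset) // 3)
                if c0 + 3 <= len(s) and "".join(s[c0 : c0 + 3]) in _STOPS:
                    s[i] = old
                    continue
            break
    return "".join(s)


def _alpha1_founder(rng: np.random.Generator) -> str:
    # 234 nt of stop-free codons plus a 2 nt tail that cannot start a stop
    # codon ("CC"), so any alpha-2 first base completes a safe junction.
    return _random_codon_seq(ALPHA1_LEN // 3, rng)[: ALPHA1_LEN - 2] + "CC"


def alpha1_of(sequence: str) -> str:
    """The alpha-1 region of a class I amplicon sequence."""
    return sequence[:ALPHA1_LEN]


def gen_allele_library(
    locus: str,
    K_true: int,
    lineage_count: int = 4,
    divergence: DivergenceParams | None = None,
    seed: int = 0,
) -> list[AlleleRecord]:
    """Generate *K_true* distinct named alleles for one locus.

    UBA alleles are concatenations alpha1(lineage) + alpha2(background):
    lineages are assigned round-robin, every allele carries the exact
    alpha-1 founder of its lineage, and alpha-2 backgrounds are mutually
    distinct mutants of a shared root — so whenever two alleles share a
    lineage they exhibit the domain-shuffling signature (identical alpha-1,
    divergent alpha-2). Class II alleles are single-domain sequences
    differing pairwise by at least one nucleotide.

    Raises ``ValueError`` when the divergence constraints cannot produce
    *K_true* distinct sequences (e.g. ``within`` rate 0 with K_true > 1).
    """
    div = divergence or DivergenceParams()
    if K_true < 1:
        raise ValueError("K_true must be >= 1")
    if K_true > 1 and div.within <= 0:
        raise ValueError("impossible divergence constraints: within rate 0 "
                         "cannot yield distinct alleles")
    rng = np.random.default_rng(seed)
    records: list[AlleleRecord] = []

    if locus == "UBA":
        if lineage_count > 8:
            raise ValueError("UBA has at most 8 alpha-1 lineages")
        lineages = _LINEAGE_ORDER[:lineage_count]
        root1 = _alpha1_founder(rng)
        founders = {
            lin: _mutate_stop_free(root1, div.between_lineage, rng, protect_tail=2)
            for lin in lineages
        }
        # alpha-2: first base free (junction), then 87 codons at offset 1
        alpha2_root = rng.choice(list(_BASES)) + _random_codon_seq(
            (ALPHA2_LEN - 1) // 3, rng
        )
        seen: set[str] = set()
        for i in range(K_true):
            lin = lineages[i % lineage_count]
            for _ in range(200):
                a2 = _mutate_stop_free(alpha2_root, div.within, rng, frame_offset=1)
                seq = founders[lin] + a2
                if seq not in seen:
                    break
            else:
                raise ValueError("impossible divergence constraints: could not "
                                 f"generate {K_true} distinct UBA alleles")
            seen.add(seq)
            records.append(
                AlleleRecord(AlleleName("UBA", i + 1, 1), seq, lineage=lin)
            )
    elif locus in ("DAA", "DAB"):
        root = _random_codon_seq(CLASSII_LEN // 3, rng)
        seen = set()
        for i in range(K_true):
            if i == 0:
                seq = root
            else:
                for _ in range(200):
                    seq = _mutate_stop_free(root, div.within, rng)
                    if seq not in seen:
                        break
                else:
                    raise ValueError(
                        "impossible divergence constraints: could not generate "
                        f"{K_true} distinct {locus} alleles"
                    )
            seen.add(seq)
            records.append(AlleleRecord(AlleleName(locus, i + 1, 1), seq))
    else:
        raise ValueError(f"unknown locus {locus!r}")
    return records


def lineage_exemplars(library: list[AlleleRecord]) -> dict[str, str]:
    """One exemplar alpha-1 sequence per lineage present in a UBA library."""
    out: dict[str, str] = {}
    for rec in library:
        if rec.lineage and rec.lineage not in out:
            out[rec.lineage] = alpha1_of(rec.sequence)
    return out


# ---------------------------------------------------------------------------
# frequencies and genotypes
# ---------------------------------------------------------------------------


def geometric_frequencies(K: int, r: float) -> np.ndarray:
    """Frequencies p_i proportional to r**i (i = 0..K-1); r in (0, 1]."""
    if not 0.0 < r <= 1.0:
        raise ValueError("geometric ratio r must lie in (0, 1]")
    p = r ** np.arange(K, dtype=float)
    return p / p.sum()


def dirichlet_frequencies(
    K: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    if alpha <= 0:
        raise ValueError("dirichlet concentration must be positive")
    return rng.dirichlet(np.full(K, alpha))


def gen_frequencies(spec: SyntheticPopulationSpec) -> np.ndarray:
    """Allele frequency vector for *spec* (sums to 1 within 1e-12)."""
    if spec.freq_model == "geometric":
        return geometric_frequencies(spec.K_true, spec.r)
    if spec.freq_model == "dirichlet":
        rng = np.random.default_rng(spec.seed)
        return dirichlet_frequencies(spec.K_true, spec.alpha, rng)
    raise ValueError(f"unknown freq_model {spec.freq_model!r}")


def default_allele_labels(locus: str, K: int) -> list[str]:
    return [str(AlleleName(locus, i + 1, 1)) for i in range(K)]


GENOTYPE_COLUMNS = [
    "individual", "population", "group", "sex", "locus", "allele1", "allele2",
]


def gen_genotypes(
    freqs: np.ndarray,
    n_individuals: int,
    F: float = 0.0,
    seed: int = 0,
    labels: list[str] | None = None,
    locus: str = "UBA",
    population: str = "sim",
    group: str = "wild",
) -> pd.DataFrame:
    """Draw unordered diploid genotypes from allele frequencies.

    With inbreeding-style parameter F, an individual is autozygous (one
    allele drawn and duplicated) with probability F, else its two alleles
    are drawn independently: P(hom i) = p_i^2 + F p_i (1-p_i) and
    P(het i,j) = 2 p_i p_j (1-F). Marginal allele frequencies are unbiased
    for p. Returns a long-format genotype table (one row per individual).
    """
    freqs = np.asarray(freqs, dtype=float)
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if abs(freqs.sum() - 1.0) > 1e-9 or (freqs <= 0).any():
        raise ValueError("freqs must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    K = len(freqs)
    labels = labels or default_allele_labels(locus, K)
    a = rng.choice(K, size=n_individuals, p=freqs)
    b = rng.choice(K, size=n_individuals, p=freqs)
    auto = rng.random(n_individuals) < F
    b = np.where(auto, a, b)
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    sex = rng.choice(["M", "F"], size=n_individuals)
    return pd.DataFrame(
        {
            "individual": [f"{population}_{i + 1:04d}" for i in range(n_individuals)],
            "population": population,
            "group": group,
            "sex": sex,
            "locus": locus,
            "allele1": [labels[i] for i in lo],
            "allele2": [labels[i] for i in hi],
        }
    )


def gen_haplotype_genotypes(
    haplotypes: list[tuple[str, str]],
    hap_freqs: np.ndarray,
    n_individuals: int,
    seed: int = 0,
    population: str = "sim",
    group: str = "wild",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw DAA-DAB genotypes from two-locus haplotype frequencies.

    Each individual receives two haplotypes (DAA allele, DAB allele) drawn
    independently; returns the long-format genotype table (two rows per
    individual: one DAA, one DAB) and the truth phasing table.
    """
    hap_freqs = np.asarray(hap_freqs, float)
    if len(haplotypes) != len(hap_freqs):
        raise ValueError("haplotypes and hap_freqs length mismatch")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(haplotypes), size=(n_individuals, 2), p=hap_freqs / hap_freqs.sum())
    sex = rng.choice(["M", "F"], size=n_individuals)
    rows, truth = [], []
    for i in range(n_individuals):
        ind = f"{population}_{i + 1:04d}"
        h1, h2 = haplotypes[idx[i, 0]], haplotypes[idx[i, 1]]
        for locus, pair in (("DAA", (h1[0], h2[0])), ("DAB", (h1[1], h2[1]))):
            a1, a2 = sorted(pair)
            rows.append([ind, population, group, sex[i], locus, a1, a2])
        truth.append([ind, h1[0], h1[1], h2[0], h2[1]])
    gt = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
    ph = pd.DataFrame(
        truth, columns=["individual", "hap1_daa", "hap1_dab", "hap2_daa", "hap2_dab"]
    )
    return gt, ph


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSimSpec:
    """Read-simulation conditions. Depth is per individual per locus; the
    paper-style run uses 300 nt paired reads; the substitution error rate
    is i.i.d. per base with a matching constant Phred quality."""

    depth_per_individual: int = 500
    read_length: int = 300
    error_rate: float = 0.005
    pools: list[PrimerPool] = field(default_factory=default_primer_pools)

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        longest = max(len(p.forward) for p in self.pools)
        if self.read_length < longest + 20:
            raise ValueError("read_length must be >= primer length + 20")

    @property
    def quality_char(self) -> str:
        q = 40 if self.error_rate == 0 else min(40, round(-10 * math.log10(self.error_rate)))
        return chr(33 + q)


@dataclass
class ReadSet:
    """Simulated reads plus ground truth for one genotype table."""

    pairs: dict[tuple[str, str], list[ReadPair]]  # (individual, locus) -> reads
    manifest: pd.DataFrame  # individual, locus, allele1, allele2, reads1, reads2
    warnings: list[str] = field(default_factory=list)


def _individual_rng(seed: int, individual: str) -> np.random.Generator:
    # per-individual substream keyed by a stable hash of the ID, so any
    # subset of individuals reproduces identically under one global seed
    return np.random.default_rng([seed, zlib.crc32(individual.encode())])


def _pool_for(rec: AlleleRecord, pools: list[PrimerPool]) -> PrimerPool:
    if rec.locus == "UBA":
        hits = [p for p in pools if p.locus == "UBA" and rec.lineage in p.lineages]
    else:
        hits = [p for p in pools if p.locus == rec.locus]
    if len(hits) != 1:
        raise ValueError(
            f"allele {rec.name} amplifiable by {len(hits)} pools; expected exactly 1"
        )
    return hits[0]


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    if hit.size:
        bases = np.frombuffer(b"ACGT", np.uint8)
        for i in hit:
            arr[i] = rng.choice(bases[bases != arr[i]])
    return arr.tobytes().decode()


def gen_reads(
    genotypes: pd.DataFrame,
    library: list[AlleleRecord],
    spec: ReadSimSpec | None = None,
    seed: int = 0,
) -> ReadSet:
    """Simulate paired amplicon reads for every row of a genotype table.

    Each amplicon is forward primer + allele sequence + reverse-complemented
    reverse primer; read 1 is its first ``read_length`` bases and read 2 the
    first ``read_length`` bases of its reverse complement, so mates overlap
    whenever 2*read_length exceeds the amplicon length. Reads are emitted
    already 3'-trimmed at the opposite primer boundary (the upstream
    cleaning step this pipeline assumes removes primer/adapter
    read-through), so a read never extends past its template. A
    heterozygote's depth is split binomially between its two alleles.
    Amplicons too long to merge (> 2*read_length - 10) are flagged in
    ``warnings``.
    """
    spec = spec or ReadSimSpec()
    by_name = {str(rec.name): rec for rec in library}
    by_name.update({rec.name.short: rec for rec in library})
    pairs: dict[tuple[str, str], list[ReadPair]] = {}
    manifest_rows = []
    warnings: list[str] = []
    L = spec.read_length
    for row in genotypes.itertuples(index=False):
        rng = _individual_rng(seed, f"{row.individual}/{row.locus}")
        recs = [by_name[row.allele1], by_name[row.allele2]]
        if row.allele1 == row.allele2:
            counts = [spec.depth_per_individual, 0]
            recs = [recs[0]]
            counts = counts[:1]
        else:
            n1 = int(rng.binomial(spec.depth_per_individual, 0.5))
            counts = [n1, spec.depth_per_individual - n1]
        out: list[ReadPair] = []
        for rec, cnt in zip(recs, counts):
            pool = _pool_for(rec, spec.pools)
            amplicon = pool.forward + rec.sequence + revcomp(pool.reverse)
            if len(amplicon) > 2 * L - 10:
                warnings.append(
                    f"{row.individual}/{row.locus}/{rec.name}: amplicon "
                    f"{len(amplicon)} nt unmergeable at read length {L}"
                )
            # 3'-trim at the opposite primer: mate 1 stops at the template
            # end, mate 2 at the template start
            t1 = amplicon[: min(L, len(pool.forward) + len(rec.sequence))]
            t2 = revcomp(amplicon)[: min(L, len(pool.reverse) + len(rec.sequence))]
            for _ in range(cnt):
                s1 = _with_errors(t1, spec.error_rate, rng)
                s2 = _with_errors(t2, spec.error_rate, rng)
                q = spec.quality_char
                out.append(ReadPair(s1, q * len(s1), s2, q * len(s2)))
        order = rng.permutation(len(out))
        pairs[(row.individual, row.locus)] = [out[i] for i in order]
        c1 = counts[0]
        c2 = counts[1] if len(counts) > 1 else counts[0]
        manifest_rows.append(
            [row.individual, row.locus, row.allele1, row.allele2, c1, c2]
        )
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["individual", "locus", "allele1", "allele2", "reads1", "reads2"],
    )
    return ReadSet(pairs=pairs, manifest=manifest, warnings=warnings)
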