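"""Allele classification and IPD-MHC-style nomenclature.

Candidate amplicon sequences are compared against a reference library of
named alleles by Smith-Waterman local alignment (EMBOSS ``water`` default
scoring). Names follow the salmonid MHC convention ``Sasa-<LOCUS>*dd:dd[:dd]``:
the two-digit field groups alleles into families separated by more than T
amino acids (T = 4 for class I *UBA*, 3 for class II *DAA*/*DAB*), the
four-digit field distinguishes non-synonymous variants within a family, and
a six-digit extension marks synonymous (nucleotide-only) variants. A ``_L``
suffix marks a longer sequence identical to a named allele over the shared
span.

MHC class I alpha-1 domains fall into ancient cross-species lineages
(labelled I..VIII); lineage assignment here is by Jukes-Cantor distance to
per-lineage exemplar alpha-1 sequences.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

LOCI = ("UBA", "DAA", "DAB")
LINEAGES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

#: maximum amino-acid difference that keeps a new allele inside the matched
#: two-digit family ("more than T amino acids" opens a new family)
FAMILY_AA_THRESHOLD = {"UBA": 4, "DAA": 3, "DAB": 3}

_NAME_RE = re.compile(
    r"^(?:Sasa-)?(?P<locus>UBA|DAA|DAB)\*"
    r"(?P<two>\d{2,}):(?P<four>\d{2,})(?::(?P<six>\d{2,}))?"
    r"(?P<suffix>_[A-Za-z]+)?$"
)


@dataclass(frozen=True)
class AlleleName:
    """Structured ``Sasa-UBA*13:01``-style allele name."""

    locus: str
    two_digit: int
    four_digit: int
    six_digit: int | None = None
    suffix: str | None = None

    def __str__(self) -> str:
        s = f"Sasa-{self.locus}*{self.two_digit:02d}:{self.four_digit:02d}"
        if self.six_digit is not None:
            s += f":{self.six_digit:02d}"
        if self.suffix:
            s += self.suffix
        return s

    @property
    def short(self) -> str:
        """Name without the species prefix, e.g. ``UBA*13:01``."""
        return str(self).removeprefix("Sasa-")

    def base(self) -> "AlleleName":
        """Name with six-digit extension and suffix stripped (the allele
        identity used by all statistics: ``_L`` variants and synonymous
        siblings count as one allele)."""
        return AlleleName(self.locus, self.two_digit, self.four_digit)


def parse_allele_name(text: str) -> AlleleName:
    m = _NAME_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed allele name: {text!r}")
    return AlleleName(
        locus=m["locus"],
        two_digit=int(m["two"]),
        four_digit=int(m["four"]),
        six_digit=int(m["six"]) if m["six"] else None,
        suffix=m["suffix"],
    )


def translate(nt: str) -> str:
    """Frame-0 translation, truncated to whole codons."""
    n = len(nt) - len(nt) % 3
    return str(Seq(nt[:n]).translate())


@dataclass
class AlleleRecord:
    """A named reference or novel allele sequence."""

    name: AlleleName
    sequence: str
    peptide: str = ""
    lineage: str | None = None  # alpha-1 domain lineage, UBA only
    novel: bool = False

    def __post_init__(self) -> None:
        if not self.peptide:
            self.peptide = translate(self.sequence)

    @property
    def locus(self) -> str:
        return self.name.locus


# ---------------------------------------------------------------------------
# Local alignment (EMBOSS water defaults)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=2)
def _aligner(alphabet: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    if alphabet == "nt":
        al.match_score = 5.0
        al.mismatch_score = -4.0
    elif alphabet == "aa":
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    return al


@dataclass
class AlignmentResult:
    score: float
    length: int  # alignment columns, gaps included
    identities: int
    mismatches: int
    gap_columns: int
    identity: float  # percent over alignment columns
    similarity: float  # percent positive-scoring pairs over columns

    @property
    def aa_diff(self) -> int:
        """Substitutions plus gap columns over the aligned span."""
        return self.mismatches + self.gap_columns


def local_align(a: str, b: str, alphabet: str = "nt") -> AlignmentResult:
    """Smith-Waterman local alignment of two sequences.

    Scoring follows the ``water`` tool's defaults: nucleotide match +5 /
    mismatch -4, protein BLOSUM62; gap open 10, extend 0.5. Identity and
    similarity are percentages over alignment columns (gaps included).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = _aligner(alphabet).align(a, b)[0]
    c = aln.counts()
    length = aln.length
    ident = c.identities
    mism = c.mismatches
    gaps = length - ident - mism
    if alphabet == "aa":
        mat = _aligner("aa").substitution_matrix
        pos = 0
        for x, y in zip(aln[0], aln[1]):
            if x != "-" and y != "-" and mat[x, y] > 0:
                pos += 1
    else:
        pos = ident
    return AlignmentResult(
        score=aln.score,
        length=length,
        identities=ident,
        mismatches=mism,
        gap_columns=gaps,
        identity=100.0 * ident / length,
        similarity=100.0 * pos / length,
    )


@dataclass
class MatchReport:
    """Closest-reference comparison for one candidate sequence."""

    query: str
    reference: AlleleRecord
    nt_identity: float
    aa_identity: float
    aa_diff_count: int
    decision: str | None = None


def closest_reference(query: str, library: list[AlleleRecord]) -> MatchReport:
    """Find the library allele with highest nucleotide identity to *query*.

    Ties in percent identity are broken by higher alignment score (a longer
    perfect alignment outranks a clipped one), then higher amino-acid
    identity, then lexicographic name, so the result is deterministic.
    ``aa_diff_count`` is substitutions plus gap columns over the locally
    aligned peptide region.
    """
    if not library:
        raise ValueError("reference library is empty")
    qpep = translate(query)
    best: tuple | None = None
    for rec in library:
        nt = local_align(query, rec.sequence, "nt")
        aa = local_align(qpep, rec.peptide, "aa")
        key = (-nt.identity, -nt.score, -aa.identity, str(rec.name))
        if best is None or key < best[0]:
            best = (key, rec, nt, aa)
    _, rec, nt, aa = best
    return MatchReport(
        query=query,
        reference=rec,
        nt_identity=nt.identity,
        aa_identity=aa.identity,
        aa_diff_count=aa.aa_diff,
    )


def closest_match_classifier(library: list[AlleleRecord], locus: str):
    """Classifier mapping a candidate sequence to the name of its closest
    library allele (memoized). This is the genotyping-time classification:
    sequencing-error variants of a known allele collapse onto it, so read
    support aggregates per allele. Naming genuinely novel alleles is the
    separate, curated ``assign_name`` step.
    """
    refs = [r for r in library if r.locus == locus]
    cache: dict[str, str] = {}

    def classify(seq: str) -> str:
        if seq not in cache:
            cache[seq] = str(closest_reference(seq, refs).reference.name)
        return cache[seq]

    return classify


# ---------------------------------------------------------------------------
# Name registry and assignment
# ---------------------------------------------------------------------------


class NameRegistry:
    """Tracks allocated allele names per locus.

    Numbers are allocated first-come; callers wanting reproducible reruns
    should present candidates in a stable order (by descending read support,
    then name).
    """

    def __init__(self, library: list[AlleleRecord] | None = None):
        self._names: dict[str, set[tuple]] = {loc: set() for loc in LOCI}
        self._seq_of: dict[str, str] = {}
        for rec in library or []:
            self.register(rec.name, rec.sequence)

    def _key(self, name: AlleleName) -> tuple:
        return (name.two_digit, name.four_digit, name.six_digit, name.suffix)

    def register(self, name: AlleleName, sequence: str) -> None:
        key = self._key(name)
        if key in self._names[name.locus]:
            if self._seq_of.get((name.locus, key)) != sequence:
                raise ValueError(f"registry collision for {name}")
            return
        self._names[name.locus].add(key)
        self._seq_of[(name.locus, key)] = sequence

    def next_two_digit(self, locus: str) -> int:
        taken = self._names[locus]
        return max((k[0] for k in taken), default=0) + 1

    def next_four_digit(self, locus: str, two: int) -> int:
        taken = [k[1] for k in self._names[locus] if k[0] == two]
        return max(taken, default=0) + 1

    def next_six_digit(self, locus: str, two: int, four: int) -> int:
        taken = [
            k[2] or 1
            for k in self._names[locus]
            if k[0] == two and k[1] == four
        ]
        # an allele with no six-digit field implicitly occupies :01
        return max(taken, default=1) + 1


def assign_name(
    query: str,
    locus: str,
    library: list[AlleleRecord],
    registry: NameRegistry,
    lineage: str | None = None,
) -> tuple[AlleleRecord, MatchReport]:
    """Classify *query* against *library* and assign a name.

    Decision table (T = 4 aa for UBA, 3 for DAA/DAB):

    * identical nucleotide sequence -> existing name (not novel);
    * longer sequence containing a reference exactly -> same name + ``_L``;
    * synonymous (0 aa diff, nucleotides differ) -> new six-digit sibling;
    * 0 < aa diff <= T -> new four-digit number in the matched family;
    * aa diff > T -> new two-digit family.

    The new record is registered so naming is idempotent: re-classifying a
    just-registered allele returns the same name with ``novel=False``.
    """
    if locus not in LOCI:
        raise ValueError(f"unknown locus {locus!r}")
    report = closest_reference(query, [r for r in library if r.locus == locus])
    ref = report.reference
    T = FAMILY_AA_THRESHOLD[locus]

    if query == ref.sequence:
        report.decision = "existing"
        rec = replace(ref, novel=False)
        return rec, report

    if len(query) > len(ref.sequence) and ref.sequence in query:
        report.decision = "long_variant"
        name = AlleleName(
            locus, ref.name.two_digit, ref.name.four_digit,
            ref.name.six_digit, suffix="_L",
        )
    elif report.aa_diff_count == 0:
        report.decision = "new_six_digit"
        six = registry.next_six_digit(locus, ref.name.two_digit, ref.name.four_digit)
        name = AlleleName(locus, ref.name.two_digit, ref.name.four_digit, six)
    elif report.aa_diff_count <= T:
        report.decision = "new_four_digit"
        four = registry.next_four_digit(locus, ref.name.two_digit)
        name = AlleleName(locus, ref.name.two_digit, four)
    else:
        report.decision = "new_two_digit"
        name = AlleleName(locus, registry.next_two_digit(locus), 1)

    rec = AlleleRecord(name=name, sequence=query, lineage=lineage, novel=True)
    registry.register(name, query)
    library.append(rec)
    return rec, report


# ---------------------------------------------------------------------------
# Jukes-Cantor distance and alpha-1 lineage assignment
# ---------------------------------------------------------------------------

JC_SATURATED = math.inf
MIN_UNGAPPED_COLUMNS = 50


def jc_distance(a: str, b: str, min_columns: int = MIN_UNGAPPED_COLUMNS) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) between two aligned
    sequences of equal length; gap columns are skipped.

    Returns ``math.inf`` when the proportion of differing sites p >= 0.75
    (saturation).
    """
    if len(a) != len(b):
        raise ValueError("jc_distance requires pre-aligned, equal-length sequences")
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if len(pairs) < min_columns:
        raise ValueError(
            f"need >= {min_columns} ungapped columns, got {len(pairs)}"
        )
    p = sum(x != y for x, y in pairs) / len(pairs)
    if p >= 0.75:
        return JC_SATURATED
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class LineageCall:
    lineage: str | None
    distance: float
    margin: float
    ambiguous: bool
    distances: dict[str, float] = field(default_factory=dict)


AMBIGUITY_MARGIN = 0.01


def assign_lineage(
    alpha1: str, exemplars: dict[str, str], margin_threshold: float = AMBIGUITY_MARGIN
) -> LineageCall:
    """Assign the alpha-1 lineage of the Jukes-Cantor-nearest exemplar.

    The alpha-1 region of *alpha1* is located by local alignment against
    each exemplar; the JC distance is computed over the aligned, ungapped
    columns. A best-vs-second-best margin below *margin_threshold* flags
    the call as ambiguous; saturation against every exemplar leaves the
    sequence unassigned.
    """
    if not exemplars:
        raise ValueError("no lineage exemplars supplied")
    dists: dict[str, float] = {}
    for lin, ex in exemplars.items():
        aln = local_align(alpha1, ex, "nt")
        cols = aln.identities + aln.mismatches
        if cols < MIN_UNGAPPED_COLUMNS:
            dists[lin] = JC_SATURATED
            continue
        p = aln.mismatches / cols
        dists[lin] = (
            JC_SATURATED if p >= 0.75 else -0.75 * math.log1p(-4.0 * p / 3.0)
        )
    ranked = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
    best_lin, best_d = ranked[0]
    if math.isinf(best_d):
        return LineageCall(None, best_d, 0.0, False, dists)
    second = ranked[1][1] if len(ranked) > 1 else math.inf
    margin = second - best_d
    return LineageCall(best_lin, best_d, margin, margin < margin_threshold, dists)
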