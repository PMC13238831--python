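"""Allele naming, alignment and lineage assignment.

The Smith-Waterman path is cross-checked against an independent Gotoh
dynamic-programming oracle implemented here with the same scoring.
"""

import math
import random

import numpy as np
import pytest

from salmhc import simulate
from salmhc.nomenclature import (
    AlleleName,
    AlleleRecord,
    NameRegistry,
    assign_lineage,
    assign_name,
    closest_reference,
    jc_distance,
    local_align,
    parse_allele_name,
    translate,
)


class TestNames:
    @pytest.mark.parametrize(
        "text,expect",
        [
            ("Sasa-UBA*13:01", ("UBA", 13, 1, None, None)),
            ("DAA*03:03:02", ("DAA", 3, 3, 2, None)),
            ("Sasa-DAB*09:01_L", ("DAB", 9, 1, None, "_L")),
        ],
    )
    def test_parse(self, text, expect):
        n = parse_allele_name(text)
        assert (n.locus, n.two_digit, n.four_digit, n.six_digit, n.suffix) == expect

    def test_roundtrip(self):
        assert str(parse_allele_name("Sasa-UBA*13:01")) == "Sasa-UBA*13:01"

    @pytest.mark.parametrize("bad", ["UBX*01:01", "UBA13:01", "UBA*1", ""])
    def test_malformed_raises(self, bad):
        with pytest.raises(ValueError):
            parse_allele_name(bad)

    def test_base_strips_extensions(self):
        n = parse_allele_name("DAB*09:01:02_L")
        assert str(n.base()) == "Sasa-DAB*09:01"


def _gotoh_local(a, b, match=5.0, mismatch=-4.0, gap_open=10.0, gap_ext=0.5):
    """Independent affine-gap local alignment score (Gotoh)."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]))
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_ext)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_ext)
            best = max(best, M[i, j])
    return best


class TestLocalAlign:
    def test_identical_sequences(self, rng):
        s = "".join(rng.choice(list("ACGT"), 100))
        res = local_align(s, s)
        assert res.identity == 100.0 and res.length == 100

    def test_internal_mismatch_identity(self):
        # an internal substitution stays inside the local alignment
        res = local_align("ACGTA", "ACATA")
        assert res.identity == 80.0 and res.length == 5

    def test_terminal_mismatch_is_clipped(self):
        # Smith-Waterman clips a disagreeing tail: alignment ends at the
        # last matching column, so identity is computed over ACG only
        res = local_align("ACGT", "ACGA")
        assert res.identity == 100.0 and res.length == 3

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_score_matches_gotoh_oracle(self):
        rnd = random.Random(3)
        for _ in range(15):
            a = "".join(rnd.choice("ACGT") for _ in range(60))
            b = "".join(rnd.choice("ACGT") for _ in range(60))
            assert local_align(a, b).score == pytest.approx(_gotoh_local(a, b))

    def test_protein_similarity_counts_positive_pairs(self):
        # I/L score positively in BLOSUM62 without being identical
        res = local_align("MKILVW", "MKLLVW", alphabet="aa")
        assert res.similarity > res.identity


@pytest.fixture()
def daa_library():
    lib = simulate.gen_allele_library("DAA", 4, seed=5)
    # rename to a stable nomenclature scenario: families 01, 02, 03
    lib[0].name = AlleleName("DAA", 1, 1)
    lib[1].name = AlleleName("DAA", 2, 1)
    lib[2].name = AlleleName("DAA", 3, 3, 1)  # has a six-digit: DAA*03:03:01
    lib[3].name = AlleleName("DAA", 4, 1)
    return lib


def _mutate_nonsyn(seq, n_codons, rot=0):
    """Replace the first n_codons spaced codons with codons of different
    amino acids; *rot* rotates the replacement codon set so repeated calls
    yield distinct variants at the same positions."""
    from Bio.Seq import Seq

    choices = ("GCT", "TGG", "CAT", "AAA", "GAA", "TTT")
    choices = choices[rot % len(choices):] + choices[: rot % len(choices)]
    s = list(seq)
    for k in range(n_codons):
        pos = 3 * (4 * k + 2)
        old = "".join(s[pos:pos + 3])
        for cand in choices:
            if cand != old and Seq(cand).translate() != Seq(old).translate():
                s[pos:pos + 3] = cand
                break
    return "".join(s)


def _mutate_syn(seq):
    """One synonymous change (wobble position of a 4-fold codon)."""
    from Bio.Seq import Seq

    s = list(seq)
    for pos in range(0, len(s) - 2, 3):
        codon = "".join(s[pos:pos + 3])
        for b in "ACGT":
            alt = codon[:2] + b
            if alt != codon and Seq(alt).translate() == Seq(codon).translate():
                s[pos:pos + 3] = alt
                return "".join(s)
    raise AssertionError("no synonymous site found")


class TestClosestReference:
    def test_exact_hit(self, daa_library):
        rep = closest_reference(daa_library[1].sequence, daa_library)
        assert rep.reference is daa_library[1]
        assert rep.nt_identity == 100.0 and rep.aa_identity == 100.0

    def test_synonymous_query_keeps_aa_identity(self, daa_library):
        q = _mutate_syn(daa_library[0].sequence)
        rep = closest_reference(q, daa_library)
        assert rep.reference.name.two_digit == 1
        assert rep.nt_identity < 100.0 and rep.aa_diff_count == 0

    def test_identity_spans_divergent_libraries(self):
        # libraries spanning high divergence still resolve a closest match
        lib = simulate.gen_allele_library(
            "UBA", 6, lineage_count=6,
            divergence=simulate.DivergenceParams(within=0.08, between_lineage=0.5),
            seed=8,
        )
        q = _mutate_nonsyn(lib[0].sequence, 1)
        rep = closest_reference(q, lib)
        assert rep.reference is lib[0]


class TestAssignName:
    def test_existing_sequence_returns_same_name(self, daa_library):
        reg = NameRegistry(daa_library)
        rec, rep = assign_name(daa_library[0].sequence, "DAA", daa_library, reg)
        assert str(rec.name) == "Sasa-DAA*01:01" and not rec.novel
        assert rep.decision == "existing"

    def test_small_aa_difference_gets_four_digit(self, daa_library):
        reg = NameRegistry(daa_library)
        q = _mutate_nonsyn(daa_library[0].sequence, 2)
        rec, rep = assign_name(q, "DAA", daa_library, reg)
        assert rep.aa_diff_count == 2 and rep.decision == "new_four_digit"
        assert rec.name.two_digit == 1 and rec.name.four_digit == 2

    def test_synonymous_gets_six_digit_sibling(self, daa_library):
        reg = NameRegistry(daa_library)
        q = _mutate_syn(daa_library[2].sequence)
        rec, rep = assign_name(q, "DAA", daa_library, reg)
        assert str(rec.name) == "Sasa-DAA*03:03:02"
        assert rep.decision == "new_six_digit"

    def test_uba_boundary_four_aa_stays_in_family(self, uba_library):
        lib = list(uba_library)
        reg = NameRegistry(lib)
        q = _mutate_nonsyn(lib[0].sequence, 4)
        rec, rep = assign_name(q, "UBA", lib, reg)
        assert rep.aa_diff_count == 4
        assert rec.name.two_digit == lib[0].name.two_digit  # "more than 4" rule

    def test_daa_four_aa_opens_new_family(self, daa_library):
        reg = NameRegistry(daa_library)
        q = _mutate_nonsyn(daa_library[0].sequence, 4)
        rec, rep = assign_name(q, "DAA", daa_library, reg)
        assert rep.aa_diff_count == 4 and rep.decision == "new_two_digit"
        assert rec.name.two_digit == 5 and rec.name.four_digit == 1

    def test_long_variant_suffix(self, daa_library):
        reg = NameRegistry(daa_library)
        q = daa_library[0].sequence + "GGTTCA"
        rec, rep = assign_name(q, "DAA", daa_library, reg)
        assert rec.name.suffix == "_L" and rep.decision == "long_variant"
        assert rec.name.base() == daa_library[0].name.base()

    def test_naming_is_idempotent(self, daa_library):
        lib = list(daa_library)
        reg = NameRegistry(lib)
        q = _mutate_nonsyn(lib[0].sequence, 2)
        rec1, _ = assign_name(q, "DAA", lib, reg)
        rec2, rep2 = assign_name(q, "DAA", lib, reg)
        assert str(rec2.name) == str(rec1.name) and not rec2.novel
        assert rep2.decision == "existing"

    def test_registry_collision_raises(self):
        reg = NameRegistry()
        reg.register(AlleleName("DAA", 1, 1), "AAA")
        with pytest.raises(ValueError, match="collision"):
            reg.register(AlleleName("DAA", 1, 1), "CCC")

    def test_family_count_matches_single_linkage_oracle(self):
        # families created by sequential naming == single-linkage clusters
        # at threshold aa_diff > T, for well-separated synthetic libraries
        rnd = random.Random(17)
        roots = simulate.gen_allele_library(
            "DAB", 3, seed=21,
            divergence=simulate.DivergenceParams(within=0.4),
        )
        seqs = []
        for root in roots:
            seqs.append(root.sequence)
            for k in range(rnd.randint(1, 3)):
                # same mutated positions, rotated substitutions: variants of
                # one family stay pairwise within the 3-aa threshold
                seqs.append(_mutate_nonsyn(root.sequence, rnd.randint(1, 3),
                                           rot=k + 1))
        rnd.shuffle(seqs)
        lib = [AlleleRecord(AlleleName("DAB", 1, 1), seqs[0])]
        reg = NameRegistry(lib)
        for s in seqs[1:]:
            assign_name(s, "DAB", lib, reg)
        families = {r.name.two_digit for r in lib}
        # oracle: single-linkage over pairwise aa differences, threshold 3
        n = len(seqs)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        # oracle distance: Hamming over the (equal-length, positionally
        # comparable) peptides — independent of the alignment machinery
        peps = [translate(s) for s in seqs]
        for i in range(n):
            for j in range(i + 1, n):
                d = sum(x != y for x, y in zip(peps[i], peps[j]))
                if d <= 3:
                    parent[find(i)] = find(j)
        clusters = {find(i) for i in range(n)}
        assert len(families) == len(clusters)


class TestJukesCantor:
    def test_identical_is_zero(self):
        assert jc_distance("ACGT" * 20, "ACGT" * 20) == 0.0

    def test_closed_form_value(self):
        p = 0.0951625820
        n = 10_000
        k = round(p * n)
        a = "A" * n
        b = "C" * k + "A" * (n - k)
        expect = -0.75 * math.log(1 - 4 * (k / n) / 3)
        assert jc_distance(a, b) == pytest.approx(expect)
        assert expect == pytest.approx(0.1015, abs=5e-4)

    def test_monotone_in_p(self):
        n = 300
        ds = []
        for k in range(0, 200, 20):
            ds.append(jc_distance("A" * n, "C" * k + "A" * (n - k)))
        assert ds == sorted(ds)

    def test_saturation(self):
        assert math.isinf(jc_distance("A" * 100, "C" * 80 + "A" * 20))

    def test_short_alignment_raises(self):
        with pytest.raises(ValueError):
            jc_distance("ACGT", "ACGT")


class TestLineages:
    def test_exemplar_maps_to_itself(self, uba_library):
        ex = simulate.lineage_exemplars(uba_library)
        for lin, seq in ex.items():
            call = assign_lineage(seq, ex)
            assert call.lineage == lin and call.margin > 0

    def test_shuffled_allele_keeps_alpha1_lineage(self, uba_library):
        ex = simulate.lineage_exemplars(uba_library)
        a1 = ex["III"]
        foreign_tail = uba_library[0].sequence[simulate.ALPHA1_LEN:]
        call = assign_lineage(a1 + foreign_tail, ex)
        assert call.lineage == "III"

    def test_primer_pools_partition_lineages(self, uba_library, primer_pools):
        served = {}
        for p in primer_pools:
            for lin in p.lineages:
                assert lin not in served, "lineage served by two pools"
                served[lin] = p.name
        for rec in uba_library:
            assert rec.lineage in served
        assert served["III"] == "UBA.F2" and served["IV"] == "UBA.F3"

    def test_saturated_query_unassigned(self, uba_library):
        ex = simulate.lineage_exemplars(uba_library)
        # a homopolymer cannot produce >= 50 aligned columns against any
        # exemplar, so every distance saturates and no lineage is assigned
        call = assign_lineage("A" * 250, ex)
        assert call.lineage is None
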