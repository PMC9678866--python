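"""Unit and property tests for the primer exclusion cascade."""

import itertools
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arbamp import primer_filters as pf
from arbamp.errors import (
    CatalogParseError,
    ConfigurationError,
    InvalidParameterError,
    InvalidSequenceError,
)
from arbamp.genome_profile import GradeProfile

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept deliberately naive)


def oracle_ssr(seq, max_mono_run=5, thresholds={2: 3, 3: 3, 4: 2}, extra=()):
    for base in "ACGT":
        if base * (max_mono_run + 1) in seq:
            return False
    for unit_len, reps in thresholds.items():
        for i in range(len(seq)):
            unit = seq[i : i + unit_len]
            if len(unit) == unit_len and unit * reps in seq:
                return False
    comp = str.maketrans("ACGT", "TGCA")
    for motif in extra:
        if motif in seq or motif.translate(comp)[::-1] in seq:
            return False
    return True


def oracle_motif(seq, consensuses, both_strands=True):
    iupac = {
        "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
        "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
        "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    comp = str.maketrans("ACGT", "TGCA")
    subjects = [seq] + ([seq.translate(comp)[::-1]] if both_strands else [])
    for cons in consensuses:
        if len(cons) > len(seq):
            continue
        for subject in subjects:
            for i in range(len(subject) - len(cons) + 1):
                if all(b in iupac[c] for b, c in zip(subject[i:], cons)):
                    return False
    return True


def oracle_selfcomp(target, w=3):
    comp = str.maketrans("ACGT", "TGCA")
    rc = lambda s: s.translate(comp)[::-1]
    if len(target) >= 2 and rc(target[-2:]) == target[-2:]:
        return False
    for i in range(len(target) - w + 1):
        probe = rc(target[i : i + w])
        for j in range(len(target) - w + 1):
            if target[j : j + w] == probe and (j + w <= i or j >= i + w):
                return False
    return True


# ---------------------------------------------------------------------------
# enumerate_kmers


class TestEnumerate:
    def test_k1_is_alphabet(self):
        cat = pf.enumerate_kmers(1)
        assert cat.sequences == ("A", "C", "G", "T")

    def test_k3_lexicographic(self):
        cat = pf.enumerate_kmers(3)
        assert len(cat) == 64
        assert cat.sequences[0] == "AAA"
        assert cat.sequences[-1] == "TTT"
        assert list(cat.sequences) == sorted(cat.sequences)

    @pytest.mark.parametrize("k", [1, 2, 5, 8])
    def test_counts_are_4_to_k(self, k):
        assert len(pf.enumerate_kmers(k)) == 4 ** k

    @pytest.mark.parametrize("k", [0, -1, 17, "3"])
    def test_k_out_of_range(self, k):
        with pytest.raises(InvalidParameterError):
            pf.enumerate_kmers(k)


# ---------------------------------------------------------------------------
# ssr_filter


class TestSsrFilter:
    def test_dinucleotide_ssr_fails(self):
        v = pf.ssr_filter("ACACACACAC")
        assert not v.passed
        assert "unit=AC" in v.evidence and "repeats=5" in v.evidence

    def test_run_of_five_passes(self):
        assert pf.ssr_filter("TTTTTGTAAA").passed

    def test_run_of_six_fails(self):
        v = pf.ssr_filter("TTTTTTGTAA")
        assert not v.passed
        assert "Tx6" in v.evidence

    def test_tri_and_tetra_units(self):
        assert not pf.ssr_filter("CAGCAGCAGA").passed  # tri x3
        assert not pf.ssr_filter("ACGTACGTAA").passed  # tetra x2
        assert pf.ssr_filter("ACGTAACGTA").passed  # interrupted

    def test_extra_motifs_both_strands(self):
        policy = pf.SsrPolicy(extra_motifs=("GACA",))
        assert not pf.ssr_filter("TTGACATT", policy).passed
        assert not pf.ssr_filter("TTTGTCTT", policy).passed  # revcomp GACA=TGTC
        assert pf.ssr_filter("TTGGCATT", policy).passed

    def test_non_acgt_rejected(self):
        with pytest.raises(InvalidSequenceError):
            pf.ssr_filter("ACGTN")

    def test_bad_policy(self):
        with pytest.raises(InvalidParameterError):
            pf.SsrPolicy(max_mono_run=0)
        with pytest.raises(InvalidParameterError):
            pf.SsrPolicy(min_repeats_by_unit={2: 1})

    @given(dna)
    @settings(max_examples=300, deadline=None)
    def test_matches_oracle(self, seq):
        assert pf.ssr_filter(seq).passed == oracle_ssr(seq)

    @given(dna)
    @settings(max_examples=100, deadline=None)
    def test_idempotent(self, seq):
        assert pf.ssr_filter(seq) == pf.ssr_filter(seq)


# ---------------------------------------------------------------------------
# motif_filter


TBP = pf.MotifCatalog(motifs=(pf.MotifEntry("TBP-like", "TATAA"),))


class TestMotifFilter:
    def test_exact_substring_fails(self):
        v = pf.motif_filter("GGTATAAGGG", TBP)
        assert not v.passed
        assert "TBP-like" in v.evidence and "at 2" in v.evidence

    def test_no_match_passes(self):
        assert pf.motif_filter("GGGGGGGGGG", TBP).passed

    def test_reverse_strand_fails(self):
        v = pf.motif_filter("GGTTATAGGG", TBP)
        assert not v.passed
        assert "strand=-" in v.evidence

    def test_forward_only_when_single_strand(self):
        cat = pf.MotifCatalog(
            motifs=(pf.MotifEntry("TBP-like", "TATAA"),), scan_both_strands=False
        )
        assert pf.motif_filter("GGTTATAGGG", cat).passed

    def test_longer_motifs_skipped(self):
        cat = pf.MotifCatalog(motifs=(pf.MotifEntry("long", "A" * 20),))
        assert pf.motif_filter("AAAA", cat).passed

    def test_iupac_degeneracy(self):
        cat = pf.MotifCatalog(motifs=(pf.MotifEntry("deg", "TRTAW"),))
        assert not pf.motif_filter("GGTATAAGGG", cat).passed

    def test_empty_catalog_passes_everything(self):
        assert pf.motif_filter("ACGTACGT", pf.MotifCatalog()).passed

    def test_malformed_iupac_raises(self):
        with pytest.raises(CatalogParseError):
            pf.MotifEntry("bad", "TAXAA")

    @given(dna, st.lists(st.text("ACGTRYN", min_size=2, max_size=4), max_size=3))
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle(self, seq, consensuses):
        entries = tuple(
            pf.MotifEntry(f"m{i}", c) for i, c in enumerate(consensuses)
        )
        cat = pf.MotifCatalog(motifs=entries)
        assert pf.motif_filter(seq, cat).passed == oracle_motif(seq, consensuses)


class TestJasparParsing:
    JASPAR = """\
>MA0001.1 TEST1
A  [ 10  0  0 10 ]
C  [  0 10  0  0 ]
G  [  0  0 10  0 ]
T  [  0  0  0  0 ]
>MA0002.1 TEST2
A 5 5
C 5 0
G 0 5
T 0 0
"""

    def test_parses_consensus(self):
        cat = pf.MotifCatalog.from_jaspar(self.JASPAR)
        assert [m.motif_id for m in cat.motifs] == ["MA0001.1", "MA0002.1"]
        assert cat.motifs[0].consensus == "ACGA"
        assert cat.motifs[1].consensus == "MR"  # A/C then A/G

    def test_consensus_lines(self):
        cat = pf.MotifCatalog.from_consensus_lines("TATAA\nid7\tCCGG\n")
        assert cat.motifs[0].consensus == "TATAA"
        assert cat.motifs[1].motif_id == "id7"

    def test_ragged_pfm_raises(self):
        bad = ">M1 x\nA 1 2\nC 1\nG 1 2\nT 1 2\n"
        with pytest.raises(CatalogParseError):
            pf.MotifCatalog.from_jaspar(bad)


# ---------------------------------------------------------------------------
# grades and concordance


class TestGrades:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, "LOW"), (99, "LOW"), (100, "MID"), (1000, "MID"), (1001, "HIGH")],
    )
    def test_default_boundaries(self, count, expected):
        assert pf.grade_of(count) == expected

    def test_negative_count(self):
        with pytest.raises(InvalidParameterError):
            pf.grade_of(-1)

    def test_invalid_boundaries(self):
        with pytest.raises(InvalidParameterError):
            pf.GradeBoundaries(low_upper=1000, high_lower=100)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_partition(self, count):
        # every count maps to exactly one grade
        assert pf.grade_of(count) in ("LOW", "MID", "HIGH")


class TestConcordance:
    def test_14_of_17_keeps(self):
        grades = ["MID"] * 14 + ["LOW", "HIGH", "LOW"]
        res = pf.concordance_filter(grades)
        assert res.keep and res.modal_grade == "MID" and res.modal_count == 14

    def test_13_of_17_drops(self):
        grades = ["MID"] * 13 + ["LOW"] * 2 + ["HIGH"] * 2
        assert not pf.concordance_filter(grades).keep

    def test_unanimous_small_cohort(self):
        assert pf.concordance_filter(["LOW"] * 5).keep  # 5 > 4.0

    def test_single_species_trivially_keeps(self):
        assert pf.concordance_filter(["HIGH"]).keep  # 1 > 0.8

    def test_empty_list_raises(self):
        with pytest.raises(InvalidParameterError):
            pf.concordance_filter([])

    def test_tie_does_not_affect_verdict(self):
        res = pf.concordance_filter(["LOW"] * 2 + ["MID"] * 2)
        assert not res.keep
        assert res.modal_count == 2


# ---------------------------------------------------------------------------
# self-complementarity


class TestSelfComplementarity:
    def test_palindrome_fails(self):
        v = pf.self_complementarity_filter("GAATTC")
        assert not v.passed

    def test_all_a_with_empty_adapters_passes(self):
        policy = pf.SelfCompPolicy(adapter_forward="", adapter_reverse="")
        assert pf.self_complementarity_filter("AAAAAAA", policy).passed

    def test_3prime_cg_fails(self):
        v = pf.self_complementarity_filter("AAAGACG")
        assert not v.passed
        assert "3'-terminal" in v.evidence

    @pytest.mark.parametrize("target", ["GTCGCCC", "TTTGATC", "TTTATGT", "TTTTTGT"])
    def test_published_targets_pass(self, target):
        assert pf.self_complementarity_filter(target).passed

    def test_pairwise_scope_sees_adapters(self):
        # AGA's revcomp TCT occurs in both adapters
        policy = pf.SelfCompPolicy(scope="pairwise_cocktail")
        v = pf.self_complementarity_filter("AGAGGGG", policy)
        assert not v.passed and "adapter" in v.evidence

    def test_pairwise_scope_sees_other_targets(self):
        policy = pf.SelfCompPolicy(
            adapter_forward="", adapter_reverse="", scope="pairwise_cocktail"
        )
        # GGG pairs with CCC in the context target
        v = pf.self_complementarity_filter(
            "AGGGA", policy, cocktail_context=["TCCCT"]
        )
        assert not v.passed

    def test_invalid_scope(self):
        with pytest.raises(InvalidParameterError):
            pf.SelfCompPolicy(scope="bogus")

    @given(st.text("ACGT", min_size=3, max_size=10))
    @settings(max_examples=300, deadline=None)
    def test_self_only_matches_oracle(self, target):
        got = pf.self_complementarity_filter(target).passed
        assert got == oracle_selfcomp(target)


# ---------------------------------------------------------------------------
# derive_short_primers


class TestDeriveShortPrimers:
    def test_prefix(self):
        cat = pf.KmerCatalog(k=10, sequences=("GTCGCCCAAA",))
        assert pf.derive_short_primers(cat, 7).sequences == ("GTCGCCC",)

    def test_dedup(self):
        cat = pf.KmerCatalog(k=10, sequences=("AAAAAAAAAA", "AAAAAAATTT"))
        out = pf.derive_short_primers(cat, 7)
        assert out.sequences == ("AAAAAAA",)

    def test_prefix_surjection_on_full_catalog(self):
        out = pf.derive_short_primers(pf.enumerate_kmers(8), 4)
        assert len(out) == 4 ** 4
        assert set(out.sequences) == set(pf.enumerate_kmers(4).sequences)

    def test_m_ge_k_raises(self):
        cat = pf.enumerate_kmers(3)
        with pytest.raises(InvalidParameterError):
            pf.derive_short_primers(cat, 3)

    @given(st.integers(min_value=2, max_value=5), st.integers(min_value=1, max_value=4))
    @settings(max_examples=20, deadline=None)
    def test_every_output_is_a_prefix(self, k, m):
        if m >= k:
            return
        cat = pf.enumerate_kmers(k)
        out = pf.derive_short_primers(cat, m)
        originals = set(cat.sequences)
        for short in out:
            assert any(s.startswith(short) for s in originals)


# ---------------------------------------------------------------------------
# the pipeline


def naive_pipeline_survivors(k, ssr_policy=None, motif_catalog=None):
    """Brute-force reimplementation: intersect per-filter pass sets."""
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    out = []
    for kmer in kmers:
        ok = oracle_ssr(kmer) if ssr_policy is None else pf.ssr_filter(kmer, ssr_policy).passed
        if motif_catalog is not None:
            ok = ok and oracle_motif(kmer, [m.consensus for m in motif_catalog.motifs])
        ok = ok and oracle_selfcomp(kmer)
        if ok:
            out.append(kmer)
    return out


class TestPipeline:
    def test_toy_run_equals_bruteforce(self):
        config = pf.DesignConfig(k=4, short_k=None)
        result = pf.run_design_pipeline(config)
        assert list(result.survivors) == naive_pipeline_survivors(4)

    def test_with_motifs_equals_bruteforce(self):
        cat = pf.MotifCatalog(motifs=(pf.MotifEntry("m", "TATA"),))
        config = pf.DesignConfig(k=4, short_k=None, motif_catalog=cat)
        result = pf.run_design_pipeline(config)
        assert list(result.survivors) == naive_pipeline_survivors(4, motif_catalog=cat)

    def test_single_profile_concordance_keeps_all(self):
        profile = GradeProfile(species_id="sp1", k=3, grades={})
        config = pf.DesignConfig(k=3, short_k=None, grade_profiles=(profile,))
        result = pf.run_design_pipeline(config)
        assert all(c.verdicts["concordance"].passed for c in result.candidates)

    def test_profile_k_mismatch_raises(self):
        profile = GradeProfile(species_id="sp1", k=5, grades={})
        with pytest.raises(ConfigurationError):
            pf.run_design_pipeline(
                pf.DesignConfig(k=4, grade_profiles=(profile,), short_k=None)
            )

    def test_order_invariance_of_per_sequence_filters(self):
        kmers = pf.enumerate_kmers(4)
        filters = [
            lambda s: pf.ssr_filter(s).passed,
            lambda s: pf.motif_filter(s, TBP).passed,
            lambda s: pf.self_complementarity_filter(s).passed,
        ]
        reference = None
        for order in itertools.permutations(range(3)):
            surv = [s for s in kmers if all(filters[i](s) for i in order)]
            if reference is None:
                reference = surv
            assert surv == reference

    def test_filter_idempotence(self):
        survivors = pf.run_design_pipeline(pf.DesignConfig(k=3, short_k=None)).survivors
        twice = [s for s in survivors if pf.ssr_filter(s).passed
                 and pf.self_complementarity_filter(s).passed]
        assert list(survivors) == twice

    def test_short_primer_derivation_in_pipeline(self):
        result = pf.run_design_pipeline(pf.DesignConfig(k=4, short_k=2))
        assert result.short_primers is not None
        assert result.short_primers.k == 2
        prefixes = {s[:2] for s in result.survivors}
        assert set(result.short_primers.sequences) == prefixes

    def test_candidates_tsv(self, tmp_path):
        result = pf.run_design_pipeline(pf.DesignConfig(k=3, short_k=None))
        out = tmp_path / "cand.tsv"
        pf.write_candidates_tsv(result.candidates, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("target\tssr")
        assert len(lines) == 1 + 64
        surviving_rows = [l for l in lines[1:] if l.endswith("\ttrue")]
        assert len(surviving_rows) == len(result.survivors)
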