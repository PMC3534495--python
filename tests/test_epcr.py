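"""Electronic PCR: approximate primer matching, amplicon prediction,
specificity screening and the primersearch-report parser."""

import io

import pytest

from conftest import random_dna
from pcrmarkers.enzymes import revcomp
from pcrmarkers.epcr import (
    EpcrConfig,
    epcr,
    map_primer,
    match_primer,
    parse_amplimer_report,
    specificity_table,
)


def brute_match(primer, seq, max_mm, anchor):
    """Position-by-position oracle for ungapped matching (both strands)."""
    out = []
    for strand in "+-":
        probe = primer if strand == "+" else revcomp(primer)
        m = len(probe)
        anchor_idx = set(range(m - anchor, m)) if strand == "+" else set(range(anchor))
        for s in range(len(seq) - m + 1):
            mism = [i for i in range(m) if probe[i] != seq[s + i] or "N" in (probe[i], seq[s + i])]
            if len(mism) <= max_mm and not (set(mism) & anchor_idx):
                out.append((s + 1, strand, len(mism)))
    return sorted(out)


class TestMatchPrimer:
    def test_exact_planted_substring(self, rng):
        seq = random_dna(rng, 100)
        primer = seq[10:30]
        hits = [h for h in match_primer(primer, seq) if h.strand == "+"]
        assert any(h.start == 11 and h.mismatches == 0 for h in hits)

    def test_one_internal_mismatch_budget(self, rng):
        seq = random_dna(rng, 80)
        primer = list(seq[20:40])
        primer[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[primer[5]]
        primer = "".join(primer)
        assert match_primer(primer, seq, max_mismatch=0) == [] or all(
            h.start != 21 for h in match_primer(primer, seq, max_mismatch=0)
        )
        hits = match_primer(primer, seq, max_mismatch=1)
        assert any(h.start == 21 and h.mismatches == 1 for h in hits)

    def test_three_prime_mismatch_kills_the_match(self, rng):
        seq = random_dna(rng, 80)
        primer = list(seq[20:40])
        primer[-1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[primer[-1]]
        primer = "".join(primer)
        hits = match_primer(primer, seq, max_mismatch=2, three_prime_exact=3)
        assert all(h.start != 21 or h.strand == "-" for h in hits)

    def test_reverse_strand_match(self, rng):
        seq = random_dna(rng, 100)
        primer = revcomp(seq[40:60])
        hits = [h for h in match_primer(primer, seq) if h.strand == "-"]
        assert any(h.start == 41 and h.mismatches == 0 for h in hits)

    def test_agrees_with_exhaustive_oracle(self, rng):
        """500 random primer/sequence cases against a brute-force comparator."""
        for _ in range(500):
            seq = random_dna(rng, 60)
            plen = int(rng.integers(12, 20))
            start = int(rng.integers(0, 60 - plen))
            primer = list(seq[start: start + plen])
            if rng.random() < 0.5:  # mutate up to 2 bases
                for _k in range(int(rng.integers(1, 3))):
                    i = int(rng.integers(0, plen))
                    primer[i] = "ACGT"[int(rng.integers(0, 4))]
            primer = "".join(primer)
            mm = int(rng.integers(0, 3))
            got = sorted((h.start, h.strand, h.mismatches)
                         for h in match_primer(primer, seq, mm, 3))
            assert got == brute_match(primer, seq, mm, 3)

    def test_primer_shorter_than_anchor_rejected(self):
        with pytest.raises(ValueError):
            match_primer("AC", "ACGTACGT", three_prime_exact=3)


class TestEpcr:
    def make_template(self, rng, n=60):
        seq = random_dna(rng, n)
        return seq, seq[:20], revcomp(seq[40:60])

    def test_excised_pair_recovered_once_with_exact_length(self, rng):
        seq, left, right = self.make_template(rng)
        hits, counts = epcr([("p1", left, right)], {"c1": seq})
        assert counts == {"p1": 1}
        (h,) = hits
        assert (h.forward_start, h.product_length) == (1, 60)

    def test_duplicated_template_flagged_non_specific(self, rng):
        seq, left, right = self.make_template(rng)
        ref = {"c1": seq + random_dna(rng, 30) + seq}
        hits, counts = epcr([("p1", left, right)], ref)
        assert counts["p1"] > 1
        assert specificity_table(hits, counts).flag.tolist() == ["non_specific"]

    def test_shuffled_primer_no_hits(self, rng):
        seq, left, right = self.make_template(rng)
        shuffled = "".join(sorted(right))
        hits, counts = epcr([("p1", left, shuffled)], {"c1": seq})
        if shuffled != right:
            assert counts["p1"] == 0
            assert specificity_table(hits, counts).flag.tolist() == ["no_product"]

    def test_product_length_cap(self, rng):
        seq = random_dna(rng, 300)
        left, right = seq[:20], revcomp(seq[280:300])
        _, counts = epcr([("p1", left, right)], {"c1": seq}, EpcrConfig(max_product=100))
        assert counts["p1"] == 0

    def test_flipped_orientation_found(self, rng):
        seq, left, right = self.make_template(rng)
        hits, counts = epcr([("p1", right, left)], {"c1": seq})
        assert counts["p1"] == 1 and hits[0].orientation == "reverse"

    def test_strand_symmetry_on_revcomp_reference(self, rng):
        """Same hits with mirrored coordinates on the reverse-complemented reference."""
        for _ in range(300):
            n = int(rng.integers(70, 120))
            seq = random_dna(rng, n)
            a = int(rng.integers(0, n - 60))
            left = seq[a: a + 18]
            right = revcomp(seq[a + 42: a + 60])
            fwd_hits, fc = epcr([("p", left, right)], {"c": seq})
            rev_hits, rc = epcr([("p", left, right)], {"c": revcomp(seq)})
            assert fc == rc
            fwd = sorted((h.forward_start, h.product_length) for h in fwd_hits)
            mirrored = sorted(
                (n - (h.forward_start + h.product_length - 1) + 1, h.product_length)
                for h in rev_hits
            )
            assert fwd == mirrored


class TestMapPrimer:
    def test_exact_and_gapped_placements(self, rng):
        seq = random_dna(rng, 120)
        primer = seq[30:52]
        (hit,) = [h for h in map_primer(primer, seq) if h.edits == 0]
        assert hit.start == 31 and hit.strand == "+"
        gapped = primer[:10] + primer[11:]  # one deletion in the primer
        hits = map_primer(gapped, seq, max_edits=2)
        assert any(h.start == 31 and h.deletions == 1 for h in hits)

    def test_edit_budget_enforced(self, rng):
        seq = random_dna(rng, 100)
        primer = "ACGTACGTACGTACGTACGT"
        for h in map_primer(primer, seq, max_edits=2):
            assert h.edits <= 2


AMPLIMER_REPORT = """\
Primer name pair_v0001

Amplimer 1
\tSequence: contig0001

\tCCTTGAAGGTAACGTTAAGG hits forward strand at 12 with 0 mismatches
\tGGAATTGGCCAATTGGAATT hits reverse strand at [33] with 1 mismatches
\tAmplimer length: 104 bp

Primer name pair_v0002

Amplimer 1
\tSequence: contig0002

\tAATTCCGGAATTCCGGAATT hits forward strand at 40 with 0 mismatches
\tTTAACCGGTTAACCGGTTAA hits reverse strand at [7] with 0 mismatches
\tAmplimer length: 88 bp
"""


class TestAmplimerReportParser:
    def test_two_blocks_in_order(self):
        hits = parse_amplimer_report(io.StringIO(AMPLIMER_REPORT))
        assert [h.pair_id for h in hits] == ["pair_v0001", "pair_v0002"]
        assert hits[0].seqid == "contig0001"
        assert hits[0].forward_start == 12
        assert hits[0].reverse_start == 33
        assert hits[0].product_length == 104
        assert (hits[0].forward_mismatches, hits[0].reverse_mismatches) == (0, 1)
        assert hits[1].product_length == 88

    def test_empty_report(self):
        assert parse_amplimer_report(io.StringIO("")) == []

    def test_malformed_block_raises_with_index(self):
        broken = "Primer name p\nAmplimer 1\n\tSequence: c1\n"
        with pytest.raises(ValueError, match="block 1"):
            parse_amplimer_report(io.StringIO(broken))
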