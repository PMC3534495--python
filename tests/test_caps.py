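"""CAPS detection against brute-force digestion, plus HRM class filtering."""

import itertools

import pytest

from conftest import random_dna
from pcrmarkers.caps import (
    apply_variant,
    candidates_to_table,
    detect_caps,
    filter_hrm_targets,
    scan_variants,
    snp_class,
    table_to_candidates,
)
from pcrmarkers.enzymes import revcomp
from pcrmarkers.simulate import brute_caps_truth, make_junction_indel, make_pure_shift_indel
from pcrmarkers.variants import VariantFeature


def snv(seqid, pos, ref, alt, vid="v"):
    return VariantFeature(seqid, "t", "SNV", pos, pos, ref, alt, vid)


class TestApplyVariant:
    def test_snv_substitution(self):
        v = snv("c", 5, "C", "T")
        assert apply_variant("GGGTCGAGGG", v, 1) == "GGGTTGAGGG"

    def test_insertion_goes_three_prime_of_anchor(self):
        v = VariantFeature("c", "t", "insertion", 4, 4, "-", "G", "i")
        assert apply_variant("GGTCAGG", v, 1) == "GGTCGAGG"

    def test_deletion_removes_span(self):
        v = VariantFeature("c", "t", "deletion", 5, 5, "G", "-", "d")
        assert apply_variant("GGTCGAGG", v, 1) == "GGTCAGG"

    def test_window_offset_shifts_local_position(self):
        v = snv("c", 105, "C", "T")
        assert apply_variant("GGGTCGAGGG", v, 101) == "GGGTTGAGGG"

    def test_variant_outside_window_rejected(self):
        with pytest.raises(ValueError):
            apply_variant("ACGT", snv("c", 99, "A", "G"), 1)


class TestDetectCaps:
    def test_snv_destroys_taqi_site(self, panel):
        cands = detect_caps("GGGTCGAGGG", snv("c", 5, "C", "T"), panel, flank=5)
        assert [(c.enzyme, c.status) for c in cands] == [("TaqI", "lost")]
        assert cands[0].ref_sites == (4,) and cands[0].alt_sites == ()

    def test_snv_creates_taqi_site(self, panel):
        cands = detect_caps("GGGTTGAGGG", snv("c", 5, "T", "C"), panel, flank=5)
        assert [(c.enzyme, c.status) for c in cands] == [("TaqI", "gained")]

    def test_snv_touching_no_site_yields_nothing(self, panel):
        assert detect_caps("GGGTTGAGGG", snv("c", 1, "G", "A"), panel, flank=5) == []

    def test_n_allele_skipped(self, panel):
        assert detect_caps("GGGTCGAGGG", snv("c", 5, "C", "N"), panel, flank=5) == []

    def test_flank_too_small_rejected(self, panel):
        with pytest.raises(ValueError, match="flank"):
            detect_caps("GGGTCGAGGG", snv("c", 5, "C", "T"), panel, flank=2)

    def test_confounded_flag_from_other_variants(self, panel):
        contig = "GGG" + "A" * 40 + "TCGA" + "A" * 40 + "GGG"
        target = snv("c", 45, "C", "T", "t")  # inside the TaqI site
        near = snv("c", 60, "A", "G", "nb")
        far = snv("c", 5000, "A", "G", "far")
        (cand,) = detect_caps(contig, target, panel, flank=50, other_variants=[target, near])
        assert cand.confounded
        (cand,) = detect_caps(contig, target, panel, flank=50, other_variants=[far])
        assert not cand.confounded

    def test_oracle_equivalence_on_random_windows(self, panel, rng):
        """Detection agrees with independent brute-force digest on 300 cases."""
        for _ in range(300):
            window = random_dna(rng, 200)
            pos = int(rng.integers(60, 140))
            ref = window[pos - 1]
            alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            v = snv("w", pos, ref, alt)
            got = sorted((c.enzyme, c.status) for c in detect_caps(window, v, panel, flank=50))
            assert got == sorted(brute_caps_truth(window, v, panel, flank=50))

    def test_soundness_a_site_overlaps_the_edit(self, panel, rng):
        """Every candidate has a site overlapping the edited base in one allele."""
        n_checked = 0
        for _ in range(300):
            window = random_dna(rng, 120)
            pos = int(rng.integers(30, 90))
            ref = window[pos - 1]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            v = snv("w", pos, ref, alt)
            for c in detect_caps(window, v, panel, flank=50):
                n_checked += 1
                local = pos - c.window_start + 1
                m = len(panel[c.enzyme].site)
                overlap = lambda sites: any(p <= local <= p + m - 1 for p in sites)
                assert overlap(c.ref_sites) or overlap(c.alt_sites)
        assert n_checked > 10

    def test_strand_invariance(self, panel, rng):
        """Mirrored variant on the revcomp contig gives the same candidates."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(200):
            contig = random_dna(rng, 150)
            pos = int(rng.integers(40, 110))
            ref = contig[pos - 1]
            alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            fwd = detect_caps(contig, snv("c", pos, ref, alt), panel, flank=50)
            mirrored = snv("c", len(contig) - pos + 1, comp[ref], comp[alt])
            rev = detect_caps(revcomp(contig), mirrored, panel, flank=50)
            assert sorted((c.enzyme, c.status) for c in fwd) == sorted(
                (c.enzyme, c.status) for c in rev
            )


class TestIndelSafety:
    def test_pure_shift_indels_yield_no_candidate(self, panel, rng):
        for _ in range(30):
            contig, v = make_pure_shift_indel(rng, panel)
            assert detect_caps(contig, v, panel, flank=50) == []

    def test_junction_deletion_gains_exactly_the_constructed_enzyme(self, panel, rng):
        for _ in range(30):
            contig, v, enzyme = make_junction_indel(rng, panel)
            cands = detect_caps(contig, v, panel, flank=50)
            assert [(c.enzyme, c.status) for c in cands] == [(enzyme, "gained")]


class TestScanVariants:
    def test_fixture_truth_reproduced_with_tallies(self, fixture_small, panel):
        scan = scan_variants(
            fixture_small.contigs,
            sorted(fixture_small.variants, key=lambda v: (v.seqid, v.start)),
            panel,
        )
        got = {}
        for c in scan:
            got.setdefault(c.variant_id, []).append(f"{c.enzyme}:{c.status}")
        truth = fixture_small.truth
        for row in truth.itertuples(index=False):
            expected = sorted(row.expected.split(";")) if row.expected else []
            assert sorted(got.get(row.id, [])) == expected, row.id
        n_expected = sum(len(e.split(";")) for e in truth.expected if e)
        assert scan.stats["candidates"] == n_expected
        assert sum(scan.stats["per_enzyme"].values()) == n_expected

    def test_generator_input_equals_list_input(self, fixture_small, panel):
        vs = sorted(fixture_small.variants, key=lambda v: (v.seqid, v.start))
        a = [c.variant_id for c in scan_variants(fixture_small.contigs, vs, panel)]
        b = [c.variant_id for c in scan_variants(fixture_small.contigs, iter(vs), panel)]
        assert a == b

    def test_empty_stream(self, fixture_small, panel):
        scan = scan_variants(fixture_small.contigs, iter(()), panel)
        assert list(scan) == [] and scan.stats["variants_seen"] == 0

    def test_noncontiguous_seqid_instructs_to_sort(self, fixture_small, panel):
        c1, c2 = list(fixture_small.contigs)

        def mk(cname, pos, vid):
            ref = fixture_small.contigs[cname][pos - 1]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            return snv(cname, pos, ref, alt, vid)

        vs = [mk(c1, 100, "a"), mk(c2, 100, "b"), mk(c1, 200, "c")]
        with pytest.raises(ValueError, match="sort"):
            list(scan_variants(fixture_small.contigs, vs, panel))

    def test_missing_contig_named_in_error(self, panel):
        with pytest.raises(KeyError, match="nope"):
            list(scan_variants({"c": "ACGT" * 50}, [snv("nope", 60, "A", "G")], panel))


class TestSnpClass:
    @pytest.mark.parametrize("pair, cls", [
        (("C", "T"), "I"), (("T", "C"), "I"), (("G", "A"), "I"), (("A", "G"), "I"),
        (("C", "A"), "II"), (("A", "C"), "II"), (("G", "T"), "II"), (("T", "G"), "II"),
        (("C", "G"), "III"), (("G", "C"), "III"),
        (("A", "T"), "IV"), (("T", "A"), "IV"),
    ])
    def test_all_twelve_ordered_pairs(self, pair, cls):
        assert snp_class(*pair) == cls

    def test_strand_symmetry(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for a, b in itertools.permutations("ACGT", 2):
            assert snp_class(a, b) == snp_class(comp[a], comp[b])

    def test_indel_alleles_rejected(self):
        with pytest.raises(ValueError):
            snp_class("-", "G")
        with pytest.raises(ValueError):
            snp_class("A", "N")


class TestHrmFilter:
    def test_retains_only_class_i_and_ii(self):
        vs = [snv("c", 10 * i, a, b, f"v{i}") for i, (a, b) in
              enumerate([("A", "G"), ("A", "T"), ("C", "G"), ("C", "A")], start=1)]
        res = filter_hrm_targets(vs)
        kept = [(v.ref_allele, v.alt_allele) for v in res]
        assert kept == [("A", "G"), ("C", "A")]
        assert res.dropped_class == 2 and res.dropped_indel == 0

    def test_indels_dropped_and_counted(self):
        vs = [VariantFeature("c", "t", "insertion", 5, 5, "-", "G", "i1"),
              VariantFeature("c", "t", "deletion", 9, 9, "G", "-", "d1")]
        res = filter_hrm_targets(vs)
        assert list(res) == [] and res.dropped_indel == 2

    def test_empty_input(self):
        assert list(filter_hrm_targets([])) == []


class TestCandidateTable:
    def test_round_trip_and_ordering(self, fixture_small, panel):
        cands = list(scan_variants(
            fixture_small.contigs,
            sorted(fixture_small.variants, key=lambda v: (v.seqid, v.start)),
            panel,
        ))
        df = candidates_to_table(cands)
        keys = list(zip(df.seqid, df.start, df.enzyme))
        assert keys == sorted(keys)
        back = table_to_candidates(df)
        orig = {(c.variant_id, c.enzyme): c for c in cands}
        assert len(back) == len(cands)
        for c in back:
            o = orig[(c.variant_id, c.enzyme)]
            assert (c.status, c.ref_sites, c.alt_sites, c.confounded, c.window_start) == (
                o.status, o.ref_sites, o.alt_sites, o.confounded, o.window_start
            )
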