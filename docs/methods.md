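# Methods

## Variant model and coordinate conventions

Variants are site-level records (no genotype/phase semantics): SNVs,
insertions and deletions on named reference sequences, in GFF3/GVF
convention — 1-based inclusive coordinates, alleles carried as
`Reference_seq`/`Variant_seq` attributes. VCF indels arrive with a
shared leading anchor base; on import the anchor is trimmed, deletions
are placed at the deleted bases and insertions become zero-length
features (`start == end`) anchored on the base 5′ of the insertion
point. This makes allele application unambiguous: the alternate window
is always obtained by substituting, removing or inserting exactly the
allele bases.

Galaxy/BED-like intervals are 0-based half-open. Zero-length insertions
map to `start == end` intervals (the format has no insertion encoding);
the mapping is the identity under round-trip in both directions,
including the zero-length case.

VCF parsing is deliberately a small streaming line parser: the records
consumed are plain 8-column site lines, parsers must accept unbuffered
text streams and yield lazily, and the anchor-trim conversion is itself
part of what the package implements. Structural problems (bad column
count, non-integer positions) fail with the line number; allele symbols
outside {A,C,G,T,N} are skipped and counted, because real variant files
routinely contain ambiguity codes and symbolic alleles. The gsMapper
dialect parser reads rows beginning `>` with the first five fields
(accession, start, end, reference bases, variant bases; `-` marking the
empty side of an indel) and tolerates version-dependent trailing
depth/frequency columns, since that schema varies between gsMapper
releases.

## Restriction-site scanning

An enzyme is a named IUPAC-degenerate recognition pattern (minimum
length 3) with an optional cut offset. Scanning matches the pattern's
IUPAC expansion on the top strand and the expansion of its reverse
complement for the bottom strand; for palindromic patterns the two
coincide and a locus is reported once. All overlapping matches are
reported — digestion occurs at every site. An `N` in the *sequence*
matches no pattern symbol (including pattern `N`): treating ambiguous
reference bases as non-cuttable avoids manufacturing spurious
gained/lost calls from low-quality sequence. Cut offsets are carried
but unused by detection, which needs site presence only.

The default panel (TaqI `TCGA`, AluI `AGCT`, RsaI `GTAC`, DpnII `GATC`,
HinfI `GANTC`, HaeIII `GGCC`) covers frequent 4-5 bp cutters that
perform well directly in PCR buffer; recognition sequences live in a
bundled TSV (`data/default_enzymes.tsv`), not in code, so user panels
are the same format.

## CAPS candidate criterion

For each variant a window of `flank` bases either side (default 50) is
extracted and the alternate allele applied. For every panel enzyme the
number of recognition sites in the two windows is compared; a candidate
is any enzyme with a count difference — `gained` when the alternate
allele has more sites, `lost` when fewer.

Counts, not positions, are compared. For SNVs the two criteria
coincide, but a length-changing indel translates every downstream site
by its length difference: a positional comparison would flag every such
variant, while the count criterion correctly ignores pure shifts and
still catches sites created or destroyed at an indel junction. The
50 bp default flank exceeds the longest bundled site minus one by a wide
margin and covers junction effects of multi-base indels.

Design choices for the awkward cases:

* **Nearby variants** are never applied to the alternate window (phase
  between site-level calls is unknown); instead any other variant
  overlapping the window sets a `confounded` flag, so downstream
  filtering can discard or deprioritise those candidates.
* **Windows clipped at contig ends** are processed and flagged rather
  than skipped — transcriptome contigs are short, and skipping would
  silently drop real targets.
* **Variants with `N` in an allele** are skipped and counted; under the
  conservative-N rule they could only produce artifactual losses.

Streaming: the scanner accepts any iterator of variants grouped by
contig, holds only one contig's group in memory (the group is needed
for confounding flags), and yields candidates lazily with summary
counters (variants seen, skipped, per-enzyme tallies) available after
exhaustion. Non-contiguous contig groups raise an error instructing the
caller to sort.

## HRM melting classes

SNV classes follow the standard melt-genotyping classification of the
unordered allele pair: C/T and G/A (transitions) are class I, C/A and
G/T class II, C/G class III, A/T class IV. Classes I and II give the
largest homoduplex melting-temperature differences and are the only
ones retained by the HRM target filter; the classification is
strand-symmetric by construction.

## Primer design

Templates are reference windows centred on the target (max product size
plus one max primer length each side, clipped at contig ends) in which
every non-target variant position is replaced by `N` — a deletion masks
its whole span, an insertion masks the anchor base and the base 3′ of
it (the junction). Masking is belt-and-braces: primers containing `N`
are rejected *and* footprints are checked against the masked-position
set after design. A neighbour overlapping the target is an error — the
target is ambiguous and should be resolved upstream.

The design engine enumerates every candidate primer footprint
(length 18-27 nt, default optimum 20) whose 3′ end lies strictly before
the target (left) or whose footprint starts strictly after it (right),
rejects candidates with `N`, GC outside 20-80 % or nearest-neighbour
melting temperature (SantaLucia parameters via Biopython) outside
55-65 °C, and pairs them under the marker-type product-size range —
CAPS 90-120 bp, indel and HRM 60-100 bp, all overridable. The CAPS
range is smaller than classical CAPS amplicons by design: small
products keep digests resolvable on high-percentage agarose and PCR
robust on fragmented template. Pairs are scored
`|Tm_L − 60| + |Tm_R − 60| + 0.5(|len_L − 20| + |len_R − 20|) + |Tm_L − Tm_R|`
(rounded to 4 decimals so ranking and the reported penalty cannot
disagree), sorted by penalty with ties broken by leftmost left primer
then leftmost right primer, and the top `max_pairs` (default 5)
returned. Exhaustive enumeration on these ~170-230 bp windows is
a few thousand candidates per template, so no heuristic pruning is
needed, and identical inputs always give identical output.

Failure is a value, not an exception: a window that cannot hold the
minimum product (or leaves less than a minimum-length primer of flank)
returns an empty result with reason `"flanks too short"`; a feasible
window where no candidate passes the filters returns
`"no acceptable pair"`. Every returned pair is revalidated against the
pair invariants (product arithmetic, target strictly inside, masked
positions avoided) as a defensive boundary, and violations dropped.

Coordinates: window-local position `x` lifts to the contig as
`window_offset + x − 1`; the right primer's recorded start is its 5′
base, i.e. the rightmost base of the product, so
`product_size = right_start − left_start + 1`.

## Electronic PCR and primer mapping

Single-primer matching is ungapped: all placements of the primer (and
of its reverse complement, for the bottom strand) with at most
`max_mismatch` mismatches and zero mismatches in the 3′-terminal
`three_prime_exact` bases (default 3) — polymerase extension is most
sensitive to 3′ mismatches, so specificity is anchored there. `N` on
either side counts as a mismatch. Amplicons are all convergent
forward/reverse match combinations with product length between the
longer primer and `max_product` (default 2000 bp); both pair
orientations are tried. Defaults are deliberately strict
(`max_mismatch=0`) because the primary use is a redundancy/specificity
screen: a pair is `specific` at exactly one product, `no_product` at
zero, `non_specific` above one.

Gapped matching (edit distance ≤ 2 by default, via edlib infix
alignment, with a per-location realignment for the mismatch/indel
breakdown) is confined to the primer-*mapping* path: useful for locating
primer sets on a new assembly, wrong for amplicon prediction, since PCR
priming tolerates mismatches but not indels at practical stringency.

A parser for the EMBOSS primersearch "Amplimer" report dialect feeds
externally computed e-PCR results into the same hit model; it carries
the positions exactly as the report states them (the reverse position
is the report's 3′-offset convention).

## Synthetic fixtures

The generator emulates variant calls against transcriptome-like contigs:
uniform-composition contigs (default 5 × 3000 bp), a configurable number
of variants (default 100) of which a fraction (default 0.4) is
engineered to gain or lose one panel enzyme's site — a concrete site
instance is embedded and one constraining base edited in the reference
(site present, `lost`) or in the alternate direction (one-off site
completed, `gained`). The rest are neutral SNVs and 1-3 bp indels
(default 15 % indels among neutrals) accepted only if no panel enzyme's
count changes. Placement keeps ≥ 120 bp between primary variants and
≥ 90 bp from contig ends so detection windows do not interact; an
optional `neighbour_fraction` plants additional neutral SNVs 15-45 bp
from chosen targets to exercise confounding flags and masking. Separate
constructors build pure-shift indels (two embedded sites, an indel
between them) and junction deletions (a site's two halves separated by
a spacer whose deletion fuses them).

Every planted variant's expected outcome is verified at generation time
by the module's own brute-force digest — window-by-window IUPAC set
expansion on both strands, sharing no code with the production scanner —
and recorded in the truth table together with the HRM class and
neighbour links; placements whose brute-force outcome disagrees with the
construction are retried within a bounded budget. All randomness flows
through one `numpy` generator seeded from the single `seed` argument;
outputs are byte-identical per seed.

What passing against these fixtures shows — and does not: the
combinatorics of detection, masking, design and recovery are correct on
clean single-allele calls; nothing is claimed about caller error,
clustered or phased variation, repetitive references or heterozygous
material.

## Workflow, determinism and problem sizes

The workflow runs convert → detect → filter-by-marker-type → design →
e-PCR, writing one flat TSV/GFF3 artifact per stage with a provenance
header (inputs, seed, parameters — no timestamps, so identical configs
give byte-identical tables) and a run log with reconciling per-stage
counts. Input paths are validated before anything is written; the first
failing stage aborts with its name. The validation suite and the
acceptance script size their simulations at 1000 oracle windows, 200
constructed indel cases, 500 strand-symmetry cases per route, ~100
design targets and a 30-variant end-to-end fixture — large enough that
every code path is exercised many times while a full run completes in
well under a minute.

## Known limitations

* No dCAPS design: variants that condition no site are reported as
  non-candidates, not rescued by mismatch-primer engineering.
* Fragment-length/gel-separability scoring is not performed (cut
  offsets are stored for future use).
* The thermodynamic model is primer-level Tm only — no hairpin, dimer
  or ΔG-based off-target scoring.
* Enzyme practicalities (methylation sensitivity, star activity,
  isoschizomers, buffer compatibility) are out of scope; the panel is
  the user's statement of what works in their hands.
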