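# pcrmarkers

Bulk PCR-marker design from NGS variant calls.

Breeding and mapping projects that genotype on agarose gels or simple
melt-curve instruments need cheap, robust single-locus assays — not
array- or sequencing-based genotyping. Given a reference (for example a
transcriptome assembly) and variant calls against it, `pcrmarkers`
finds the variants that can be scored as:

* **CAPS** (cleaved amplified polymorphic sequence) markers — SNPs or
  indels that create or destroy a restriction-enzyme recognition site, so
  the two alleles of a small PCR product differ in digestibility;
* **indel** markers — scored directly as a product-length difference;
* **HRM** (high-resolution melting) markers — small amplicons whose melt
  curve distinguishes the SNP alleles; only class I (C/T, G/A) and
  class II (C/A, G/T) SNPs give reliable melt shifts, so class III (C/G)
  and IV (A/T) targets are filtered out.

The pipeline is: convert variant calls (VCF, or Roche gsMapper
`454HCDiffs.txt`/`454AllDiffs.txt` tables) into GFF3/GVF variant
features → scan each variant against a restriction-enzyme panel for
allele-specific digestion (recognition sites are IUPAC-degenerate
patterns matched on both strands; a candidate is any enzyme whose site
*count* differs between the two alleles of a ±50 bp window) → design
flanking primer pairs on templates in which every non-target variant
position is masked with `N`, under marker-type-specific amplicon-size
ranges (90–120 bp for CAPS, 60–100 bp for indel/HRM) → validate the
pairs by electronic PCR against the full reference, flagging pairs that
amplify at zero or more than one locus.

The default enzyme panel is six enzymes that digest reliably in PCR
buffer: TaqI, AluI, RsaI, DpnII, HinfI, HaeIII. User panels are a TSV of
(name, IUPAC site, cut offset).

## Worked example

No external data is needed: the package ships a seeded generator that
produces reference contigs with planted variants and a ground-truth
table.

```sh
pcr-markers simulate --seed 42 --n-variants 20 --outdir demo/fx
pcr-markers run --reference demo/fx/reference.fa \
                --variants demo/fx/variants.vcf \
                --outdir demo/out
```

which reports (stage log in `demo/out/run.log`):

```
pcrmarkers run: seed=42 marker_type=CAPS
convert: read 20 variant features
detect: 20 variants in, 9 candidates out (per-enzyme {'DpnII': 3, 'HinfI': 3, 'RsaI': 1, 'AluI': 1, 'HaeIII': 1})
filter: 8 design targets (CAPS)
design: 8/8 targets got primer pairs (40 pairs)
epcr: 40 pairs tested, 40 specific
```

Reading the log: of 20 simulated variants, 8 condition a restriction
polymorphism for a panel enzyme (9 candidate rows — one variant is
cut differently by two enzymes) (`candidates.tsv` lists each with the
enzyme, whether the alternate allele *gained* or *lost* the site, and a
`confounded` flag when another variant falls in the detection window).
All 8 got primer pairs with 90–120 bp products (`primers.tsv`: sequences,
melting temperatures, penalty, contig coordinates), and all 40 returned
pairs amplify exactly one locus in the reference (`epcr.tsv`), so every
designed assay is usable as-is.

Individual stages are also exposed (`vcf2gff`, `gsmapper2gff`,
`find-caps`, `design-primers`, `epcr`, `map-primers`, `filter`) and all
read/write stdin/stdout so they compose in shell pipelines, e.g.

```sh
pcr-markers vcf2gff calls.vcf | pcr-markers find-caps \
    --reference contigs.fa --variants /dev/stdin -o candidates.tsv
pcr-markers filter candidates.tsv --where enzyme=TaqI --where confounded=false
```

The same functionality is available as a library (`import pcrmarkers`);
see `docs/methods.md` for the model and parameter details.

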