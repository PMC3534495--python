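"""CAPS polymorphism detection: which enzymes cut the two alleles differently.

For each variant a window of ``flank`` bases either side is extracted, the
alternate allele is applied, and every panel enzyme's recognition-site
count is compared between the two windows.  A count difference means the
variant conditions a restriction polymorphism (a CAPS candidate): the
alternate allele has *gained* or *lost* a site relative to the reference.

Counts, not site positions, are compared: a length-changing indel that
merely translates downstream sites leaves every count unchanged and is
correctly not a candidate, while any site actually created or destroyed
(including at an indel junction) changes a count.

Also provides the HRM melting-class filter: small-amplicon melt genotyping
works best for class I (C/T, G/A) and class II (C/A, G/T) SNPs, whose
homoduplex melting-temperature shifts are largest; class III (C/G) and
class IV (A/T) targets are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .enzymes import EnzymePanel, find_sites
from .variants import VariantFeature

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 50


@dataclass(frozen=True)
class CapsCandidate:
    """A (variant, enzyme) pair whose digestion differs between alleles."""

    variant: VariantFeature
    enzyme: str
    status: str  # gained | lost (alternate allele relative to reference)
    ref_sites: tuple[int, ...]  # window-local 1-based site positions, ref allele
    alt_sites: tuple[int, ...]  # window-local positions in the alternate window
    confounded: bool = False  # another variant lies inside the window
    window_start: int = 1  # genomic position of window base 1
    clipped: bool = False  # window truncated at a contig end

    def __post_init__(self) -> None:
        if self.status not in ("gained", "lost"):
            raise ValueError(f"bad status {self.status!r}")
        nref, nalt = len(self.ref_sites), len(self.alt_sites)
        if nref == nalt:
            raise ValueError("candidate requires a site-count difference")
        expect = "gained" if nalt > nref else "lost"
        if self.status != expect:
            raise ValueError(f"status {self.status} inconsistent with counts {nref}->{nalt}")

    @property
    def variant_id(self) -> str:
        return self.variant.id


def apply_variant(window: str, variant: VariantFeature, window_offset: int) -> str:
    """Return the window with the variant's alternate allele applied.

    ``window_offset`` is the 1-based genomic position of ``window[0]``.
    Insertions add bases immediately 3' of the anchor base ``start``.
    """
    local = variant.start - window_offset  # 0-based index of the anchor base
    if local < 0 or variant.end - window_offset >= len(window):
        raise ValueError(f"variant {variant.id} lies outside the window")
    if variant.vtype == "SNV":
        return window[:local] + variant.alt_allele + window[local + 1:]
    if variant.vtype == "insertion":
        return window[: local + 1] + variant.alt_allele + window[local + 1:]
    # deletion
    return window[:local] + window[local + len(variant.ref_allele):]


def detect_caps(
    ref_seq: str,
    variant: VariantFeature,
    panel: EnzymePanel,
    flank: int = DEFAULT_FLANK,
    other_variants: Iterable[VariantFeature] = (),
) -> list[CapsCandidate]:
    """CAPS candidates for one variant against a panel.

    Extracts ``[start - flank, end + flank]`` clipped to the contig,
    applies the alternate allele, and emits one candidate per enzyme whose
    site count differs between the two windows.  Other supplied variants
    are never applied; if one overlaps the window the candidate is flagged
    ``confounded`` (phase with the target is unknown).
    """
    if flank < panel.max_site_length - 1:
        raise ValueError(f"flank {flank} < max site length - 1 ({panel.max_site_length - 1})")
    if "N" in variant.ref_allele or "N" in variant.alt_allele:
        return []
    length = len(ref_seq)
    ws = max(1, variant.start - flank)
    we = min(length, variant.end + flank)
    clipped = ws > variant.start - flank or we < variant.end + flank
    window = ref_seq[ws - 1: we].upper()
    alt_window = apply_variant(window, variant, ws)
    confounded = any(
        v.id != variant.id and v.seqid == variant.seqid and v.start <= we and v.end >= ws
        for v in other_variants
    )
    out: list[CapsCandidate] = []
    for enz in panel:
        ref_hits = tuple(p for p, _ in find_sites(window, enz))
        alt_hits = tuple(p for p, _ in find_sites(alt_window, enz))
        if len(ref_hits) == len(alt_hits):
            continue
        status = "gained" if len(alt_hits) > len(ref_hits) else "lost"
        out.append(
            CapsCandidate(variant, enz.name, status, ref_hits, alt_hits, confounded, ws, clipped)
        )
    return out


class ScanResult:
    """Lazy iterator over CAPS candidates with post-hoc summary counters."""

    def __init__(self, gen: Iterator[CapsCandidate]):
        self._gen = gen
        self.stats: dict = {
            "variants_seen": 0,
            "variants_skipped_n_allele": 0,
            "candidates": 0,
            "per_enzyme": {},
        }

    def __iter__(self) -> Iterator[CapsCandidate]:
        return self._gen

    def __next__(self) -> CapsCandidate:
        return next(self._gen)


def _get_contig(ref, seqid: str) -> str:
    try:
        seq = ref[seqid]
    except KeyError:
        raise KeyError(f"reference sequence {seqid!r} not found in the supplied FASTA") from None
    return str(seq)


def scan_variants(
    ref: Mapping[str, str] | str | Path,
    variants: Iterable[VariantFeature],
    panel: EnzymePanel,
    flank: int = DEFAULT_FLANK,
) -> ScanResult:
    """Stream CAPS candidates over many variants, grouped by contig.

    ``ref`` may be a FASTA path (indexed with pyfaidx) or any mapping of
    seqid to sequence.  Input must arrive grouped by seqid (sorted files
    satisfy this); a seqid that reappears after another contig raises an
    error instructing the caller to sort, because confounding flags are
    computed per contiguous contig group.  Candidates are yielded lazily
    in input order; only one contig's variants are held in memory.
    """
    if isinstance(ref, (str, Path)):
        import pyfaidx

        ref = pyfaidx.Fasta(str(ref))

    def gen(result: ScanResult) -> Iterator[CapsCandidate]:
        import itertools

        seen: set[str] = set()
        for seqid, group in itertools.groupby(variants, key=lambda v: v.seqid):
            if seqid in seen:
                raise ValueError(
                    f"variants for {seqid!r} are not contiguous: sort input by seqid, start"
                )
            seen.add(seqid)
            contig = _get_contig(ref, seqid)
            batch = list(group)
            for v in batch:
                result.stats["variants_seen"] += 1
                if "N" in v.ref_allele or "N" in v.alt_allele:
                    result.stats["variants_skipped_n_allele"] += 1
                    continue
                for cand in detect_caps(contig, v, panel, flank, other_variants=batch):
                    result.stats["candidates"] += 1
                    tally = result.stats["per_enzyme"]
                    tally[cand.enzyme] = tally.get(cand.enzyme, 0) + 1
                    yield cand

    result = ScanResult(iter(()))
    result._gen = gen(result)
    return result


# ---------------------------------------------------------------------------
# HRM melting classes

_SNP_CLASS = {
    frozenset("CT"): "I",
    frozenset("GA"): "I",
    frozenset("CA"): "II",
    frozenset("GT"): "II",
    frozenset("CG"): "III",
    frozenset("AT"): "IV",
}


def snp_class(ref_allele: str, alt_allele: str) -> str:
    """HRM melting class (I-IV) of a SNV from its unordered allele pair."""
    pair = frozenset((ref_allele.upper(), alt_allele.upper()))
    try:
        return _SNP_CLASS[pair]
    except KeyError:
        raise ValueError(
            f"SNP class undefined for alleles {ref_allele!r}/{alt_allele!r}: "
            "need two distinct bases from A,C,G,T"
        ) from None


class FilterResult:
    """Lazy HRM-target filter with drop counters."""

    def __init__(self, variants: Iterable[VariantFeature]):
        self.dropped_indel = 0
        self.dropped_class = 0
        self.passed = 0
        self._variants = variants

    def __iter__(self) -> Iterator[VariantFeature]:
        for v in self._variants:
            if v.vtype != "SNV":
                self.dropped_indel += 1
                continue
            if snp_class(v.ref_allele, v.alt_allele) in ("I", "II"):
                self.passed += 1
                yield v
            else:
                self.dropped_class += 1


def filter_hrm_targets(variants: Iterable[VariantFeature]) -> FilterResult:
    """Keep only class I/II SNVs (good HRM targets); drop indels and III/IV."""
    return FilterResult(variants)


# ---------------------------------------------------------------------------
# Tabular output

TABLE_COLUMNS = [
    "seqid",
    "start",
    "end",
    "variant_id",
    "vtype",
    "ref_allele",
    "alt_allele",
    "enzyme",
    "status",
    "n_ref_sites",
    "n_alt_sites",
    "ref_sites",
    "alt_sites",
    "confounded",
    "window_start",
    "clipped",
]


def candidates_to_table(candidates: Iterable[CapsCandidate]) -> pd.DataFrame:
    """One row per candidate, sorted stably by (seqid, start, enzyme).

    Site-position lists are comma-joined so the table round-trips through
    line-oriented tools and :func:`table_to_candidates`.
    """
    rows = []
    for c in candidates:
        v = c.variant
        rows.append(
            {
                "seqid": v.seqid,
                "start": v.start,
                "end": v.end,
                "variant_id": v.id,
                "vtype": v.vtype,
                "ref_allele": v.ref_allele,
                "alt_allele": v.alt_allele,
                "enzyme": c.enzyme,
                "status": c.status,
                "n_ref_sites": len(c.ref_sites),
                "n_alt_sites": len(c.alt_sites),
                "ref_sites": ",".join(map(str, c.ref_sites)),
                "alt_sites": ",".join(map(str, c.alt_sites)),
                "confounded": c.confounded,
                "window_start": c.window_start,
                "clipped": c.clipped,
            }
        )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return df.sort_values(["seqid", "start", "enzyme"], kind="mergesort").reset_index(drop=True)


def table_to_candidates(df: pd.DataFrame, source: str = "caps_table") -> list[CapsCandidate]:
    """Rebuild candidates from :func:`candidates_to_table` output."""

    def split_pos(s) -> tuple[int, ...]:
        if isinstance(s, float) or not s:
            return ()
        return tuple(int(x) for x in str(s).split(","))

    out = []
    for row in df.itertuples(index=False):
        v = VariantFeature(
            row.seqid, source, row.vtype, int(row.start), int(row.end),
            row.ref_allele, row.alt_allele, row.variant_id,
        )
        out.append(
            CapsCandidate(
                v, row.enzyme, row.status, split_pos(row.ref_sites), split_pos(row.alt_sites),
                bool(row.confounded), int(row.window_start), bool(row.clipped),
            )
        )
    return out
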