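"""Variant-masked flanking-primer design for CAPS/indel/HRM assays.

A design template is a reference window centred on the target variant in
which every *non-target* variant position is replaced by ``N`` (masking),
so primers can never anneal over a polymorphic base and assays amplify
uniformly across genotypes.  The design engine enumerates all candidate
left/right primers that avoid masked positions, pass length, GC and
melting-temperature filters (nearest-neighbour Tm), and pair them under
the marker-type-specific amplicon-size constraint:

* CAPS markers: 90-120 bp products (small products keep restriction
  fragments resolvable on agarose and PCR robust on fragmented template);
* indel and HRM markers: 60-100 bp (melt-curve discrimination is best for
  very small amplicons).

Pairs are ranked by a primer3-style penalty (deviation from optimal Tm and
length, plus the Tm difference between mates), ties broken by leftmost
left-primer start for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqUtils import MeltingTemp

from .enzymes import revcomp
from .variants import VariantFeature

logger = logging.getLogger(__name__)


@dataclass
class DesignConfig:
    """Tunable primer-design constraints; defaults follow common practice."""

    product_size_range: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"CAPS": (90, 120), "indel": (60, 100), "HRM": (60, 100)}
    )
    primer_len_range: tuple[int, int] = (18, 27)
    primer_len_opt: int = 20
    tm_range: tuple[float, float] = (55.0, 65.0)
    tm_opt: float = 60.0
    gc_range: tuple[float, float] = (20.0, 80.0)
    max_pairs: int = 5
    mask_char: str = "N"

    def __post_init__(self) -> None:
        for k, (lo, hi) in self.product_size_range.items():
            if lo > hi:
                raise ValueError(f"empty product-size range for {k}")
        if self.primer_len_range[0] > self.primer_len_range[1]:
            raise ValueError("empty primer length range")


@dataclass(frozen=True)
class DesignTemplate:
    """A masked design window around one target variant."""

    seqid: str
    sequence: str  # window with non-target variants masked
    window_offset: int  # 1-based genomic position of sequence[0]
    target_span: tuple[int, int]  # window-local 1-based inclusive
    masked_positions: frozenset[int]  # window-local 1-based
    marker_type: str  # CAPS | indel | HRM
    target_id: str = ""
    enzyme: str = ""  # for CAPS markers, joined from detection

    def __post_init__(self) -> None:
        lo, hi = self.target_span
        if any(lo <= p <= hi for p in self.masked_positions):
            raise ValueError(f"{self.target_id}: target span intersects a masked position")


@dataclass(frozen=True)
class PrimerPair:
    """A left/right primer pair on a design template.

    ``left_start`` is the window-local 1-based position of the left
    primer's 5' base; ``right_start`` the position of the right primer's
    5' base, which is the rightmost (genomically 3'-most) base of the
    product, so ``product_size == right_start - left_start + 1``.
    """

    pair_id: str
    left_seq: str  # 5'->3' on the top strand
    right_seq: str  # 5'->3' on the reverse strand
    left_start: int
    right_start: int
    product_size: int
    left_tm: float
    right_tm: float
    penalty: float
    marker_type: str

    def __post_init__(self) -> None:
        if self.product_size != self.right_start - self.left_start + 1:
            raise ValueError(f"{self.pair_id}: product size inconsistent with coordinates")


@dataclass
class DesignResult:
    """Primer pairs for one template, or a machine-readable failure reason."""

    pairs: list[PrimerPair]
    failure: str | None = None

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _variant_mask_span(v: VariantFeature) -> tuple[int, int]:
    # insertions mask the anchor base and the base 3' of it (the junction)
    if v.vtype == "insertion":
        return v.start, v.start + 1
    return v.start, v.end


def build_template(
    ref_seq: str,
    target: VariantFeature,
    neighbours: Iterable[VariantFeature],
    config: DesignConfig,
    marker_type: str = "CAPS",
    enzyme: str = "",
) -> DesignTemplate:
    """Extract and mask a design window around ``target``.

    The window spans max product size plus one max primer length each
    side, clipped at contig ends.  Neighbour variant positions become the
    mask character; target bases stay untouched.  A neighbour overlapping
    the target is an error (ambiguous target).
    """
    if marker_type not in config.product_size_range:
        raise ValueError(f"unknown marker type {marker_type!r}")
    half = config.product_size_range[marker_type][1] // 2 + config.primer_len_range[1]
    ws = max(1, target.start - half)
    we = min(len(ref_seq), target.end + half)
    window = list(ref_seq[ws - 1: we].upper())
    if target.vtype == "insertion":
        t_lo, t_hi = target.start, min(target.start + 1, we)
    else:
        t_lo, t_hi = target.start, target.end
    masked: set[int] = set()
    for nb in neighbours:
        if nb.id == target.id or nb.seqid != target.seqid:
            continue
        lo, hi = _variant_mask_span(nb)
        if lo <= t_hi and hi >= t_lo:
            raise ValueError(f"neighbour {nb.id} overlaps target {target.id}: ambiguous target")
        for pos in range(max(lo, ws), min(hi, we) + 1):
            local = pos - ws + 1
            masked.add(local)
            window[local - 1] = config.mask_char
    return DesignTemplate(
        seqid=target.seqid,
        sequence="".join(window),
        window_offset=ws,
        target_span=(t_lo - ws + 1, t_hi - ws + 1),
        masked_positions=frozenset(masked),
        marker_type=marker_type,
        target_id=target.id,
        enzyme=enzyme,
    )


def _gc_fraction(seq: str) -> float:
    return 100.0 * sum(seq.count(b) for b in "GCgc") / len(seq)


def _candidate_primers(
    window: str, lo_end: int, hi_end: int, config: DesignConfig, reverse: bool
) -> list[tuple[float, int, int, str, float]]:
    """Single-primer candidates as (penalty, start, end, seq5'3', tm).

    ``start``/``end`` are window-local 1-based top-strand coordinates of
    the annealing footprint; candidates whose footprint falls outside
    [lo_end, hi_end] or touches an N are rejected.
    """
    out = []
    lmin, lmax = config.primer_len_range
    for end in range(lo_end, hi_end + 1):
        for length in range(lmin, lmax + 1):
            if reverse:
                s, e = end, end + length - 1
            else:
                s, e = end - length + 1, end
            if s < 1 or e > len(window):
                continue
            if not reverse and e > hi_end:
                continue
            if reverse and e > hi_end:
                continue
            footprint = window[s - 1: e]
            if "N" in footprint:
                continue
            seq = revcomp(footprint) if reverse else footprint
            gc = _gc_fraction(seq)
            if not (config.gc_range[0] <= gc <= config.gc_range[1]):
                continue
            tm = MeltingTemp.Tm_NN(seq)
            if not (config.tm_range[0] <= tm <= config.tm_range[1]):
                continue
            pen = abs(tm - config.tm_opt) + 0.5 * abs(length - config.primer_len_opt)
            out.append((pen, s, e, seq, tm))
    return out


def design_primers(template: DesignTemplate, config: DesignConfig | None = None) -> DesignResult:
    """Design flanking primer pairs for a masked template.

    Left primers must end strictly before the target span, right primers
    start strictly after it; the product must contain the whole target and
    fall in the marker type's size range.  Returns at most
    ``config.max_pairs`` pairs sorted by ascending penalty (ties: leftmost
    left primer, then leftmost right primer).  Every returned pair is
    revalidated against the pair invariants; an infeasible template gives
    an empty result with a failure reason.
    """
    config = config or DesignConfig()
    window = template.sequence
    t_lo, t_hi = template.target_span
    pmin, pmax = config.product_size_range[template.marker_type]
    lmin = config.primer_len_range[0]
    # arithmetic feasibility: shortest possible product containing the target
    left_room = t_lo - 1
    right_room = len(window) - t_hi
    if left_room < lmin or right_room < lmin or len(window) < pmin:
        return DesignResult([], "flanks too short")
    lefts = _candidate_primers(window, lo_end=lmin, hi_end=t_lo - 1, config=config, reverse=False)
    rights = _candidate_primers(
        window, lo_end=t_hi + 1, hi_end=len(window), config=config, reverse=True
    )
    if not lefts or not rights:
        return DesignResult([], "no acceptable pair")
    scored: list[tuple[float, int, int, PrimerPair]] = []
    for lpen, ls, le, lseq, ltm in lefts:
        for rpen, rs, re_, rseq, rtm in rights:
            size = re_ - ls + 1
            if not (pmin <= size <= pmax):
                continue
            # rounded so that ranking and the reported value can't disagree
            pen = round(lpen + rpen + abs(ltm - rtm), 4)
            scored.append(
                (
                    pen,
                    ls,
                    re_,
                    PrimerPair(
                        pair_id=f"{template.target_id}_p",
                        left_seq=lseq,
                        right_seq=rseq,
                        left_start=ls,
                        right_start=re_,
                        product_size=size,
                        left_tm=round(ltm, 2),
                        right_tm=round(rtm, 2),
                        penalty=pen,
                        marker_type=template.marker_type,
                    ),
                )
            )
    if not scored:
        return DesignResult([], "no acceptable pair")
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    pairs = []
    for rank, (_, _, _, p) in enumerate(scored[: config.max_pairs], start=1):
        p = PrimerPair(**{**p.__dict__, "pair_id": f"{template.target_id}_p{rank}"})
        if not _pair_valid(p, template):
            logger.warning("dropping invalid engine pair %s", p.pair_id)
            continue
        pairs.append(p)
    return DesignResult(pairs, None if pairs else "no acceptable pair")


def _pair_valid(p: PrimerPair, template: DesignTemplate) -> bool:
    """Defensive revalidation of the pair invariants against the template."""
    t_lo, t_hi = template.target_span
    left_span = range(p.left_start, p.left_start + len(p.left_seq))
    right_span = range(p.right_start - len(p.right_seq) + 1, p.right_start + 1)
    if p.product_size != p.right_start - p.left_start + 1:
        return False
    if not (left_span.stop <= t_lo and right_span.start > t_hi):
        return False  # target must sit strictly between the primers
    if any(pos in template.masked_positions for pos in left_span):
        return False
    if any(pos in template.masked_positions for pos in right_span):
        return False
    return True


PRIMER_TABLE_COLUMNS = [
    "target_id",
    "pair_id",
    "marker_type",
    "enzyme",
    "seqid",
    "left_seq",
    "right_seq",
    "product_size",
    "left_tm",
    "right_tm",
    "penalty",
    "left_start_genomic",
    "right_start_genomic",
]


def primer_table(
    results: Iterable[tuple[DesignTemplate, DesignResult]]
) -> pd.DataFrame:
    """Tabulate designed pairs with coordinates lifted to the contig.

    Genomic position of a window-local coordinate ``x`` is
    ``window_offset + x - 1`` (both 1-based).
    """
    rows = []
    for template, result in results:
        for p in result:
            rows.append(
                {
                    "target_id": template.target_id,
                    "pair_id": p.pair_id,
                    "marker_type": p.marker_type,
                    "enzyme": template.enzyme,
                    "seqid": template.seqid,
                    "left_seq": p.left_seq,
                    "right_seq": p.right_seq,
                    "product_size": p.product_size,
                    "left_tm": p.left_tm,
                    "right_tm": p.right_tm,
                    "penalty": p.penalty,
                    "left_start_genomic": template.window_offset + p.left_start - 1,
                    "right_start_genomic": template.window_offset + p.right_start - 1,
                }
            )
    return pd.DataFrame(rows, columns=PRIMER_TABLE_COLUMNS)
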