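"""Electronic PCR: validate primer pairs against reference sequences.

Three routes are provided:

* :func:`match_primer` — ungapped approximate matching of a single primer
  on both strands, with a mismatch budget and a mandatory exact-match
  3'-terminal anchor (polymerase extension is most sensitive to 3'
  mismatches, so priming specificity is modelled there).
* :func:`epcr` — combine convergent forward/reverse matches of a pair
  into predicted amplicons within a product-size limit, and flag pairs
  hitting zero or more than one locus (the redundancy/specificity screen).
* :func:`parse_amplimer_report` — read the EMBOSS primersearch "Amplimer"
  report dialect, so externally computed e-PCR results drop into the same
  :class:`AmpliconHit` model.

Gapped (edit-distance) matching is deliberately confined to
:func:`map_primer` for mapping primers back onto sequence sets; PCR
priming tolerates mismatches but not indels at practical stringency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import pandas as pd

from .enzymes import revcomp
from .primers import PrimerPair


@dataclass(frozen=True)
class PrimerMatch:
    """One approximate placement of a primer on a reference sequence."""

    primer_id: str
    seqid: str
    start: int  # 1-based leftmost base of the match on the top strand
    strand: str  # + | -
    mismatches: int
    insertions: int = 0
    deletions: int = 0

    @property
    def edits(self) -> int:
        return self.mismatches + self.insertions + self.deletions


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product for one primer pair on one sequence."""

    pair_id: str
    seqid: str
    forward_start: int  # 1-based start of the forward-matching primer
    reverse_start: int  # 1-based leftmost base of the reverse-primer window
    product_length: int
    forward_mismatches: int
    reverse_mismatches: int
    orientation: str = "forward"  # which mate matched the top strand

    def __post_init__(self) -> None:
        if self.product_length < 1:
            raise ValueError("non-positive product length")


@dataclass
class EpcrConfig:
    max_mismatch: int = 0
    three_prime_exact: int = 3
    max_product: int = 2000


def _scan(primer: str, seq: str, max_mm: int, anchor: int, strand: str) -> list[tuple[int, int]]:
    """Ungapped matches of a (possibly revcomped) probe; (start0, mismatches).

    ``primer`` is given 5'->3'; on the minus strand the probe compared to
    the top strand is its reverse complement, whose *leftmost* bases
    correspond to the primer's 3' end — the anchor moves accordingly.
    """
    probe = primer if strand == "+" else revcomp(primer)
    n, m = len(seq), len(probe)
    anchor_idx = range(m - anchor, m) if strand == "+" else range(0, anchor)
    anchor_set = set(anchor_idx)
    out = []
    for s in range(0, n - m + 1):
        mm = 0
        ok = True
        for i in range(m):
            a, b = probe[i], seq[s + i]
            if a != b or a == "N" or b == "N":
                if i in anchor_set:
                    ok = False
                    break
                mm += 1
                if mm > max_mm:
                    ok = False
                    break
        if ok:
            out.append((s, mm))
    return out


def match_primer(
    primer: str,
    seq: str,
    max_mismatch: int = 0,
    three_prime_exact: int = 3,
    seqid: str = "",
    primer_id: str = "",
) -> list[PrimerMatch]:
    """All ungapped placements of a primer on both strands of ``seq``.

    A placement needs at most ``max_mismatch`` mismatches overall and
    zero mismatches in the primer's 3'-terminal ``three_prime_exact``
    bases.  ``N`` on either side counts as a mismatch.
    """
    if len(primer) < three_prime_exact:
        raise ValueError("primer shorter than the 3' exact-anchor length")
    primer, seq = primer.upper(), seq.upper()
    out = [
        PrimerMatch(primer_id, seqid, s + 1, "+", mm)
        for s, mm in _scan(primer, seq, max_mismatch, three_prime_exact, "+")
    ] + [
        PrimerMatch(primer_id, seqid, s + 1, "-", mm)
        for s, mm in _scan(primer, seq, max_mismatch, three_prime_exact, "-")
    ]
    out.sort(key=lambda h: (h.start, h.strand))
    return out


def map_primer(
    primer: str,
    seq: str,
    max_edits: int = 2,
    seqid: str = "",
    primer_id: str = "",
) -> list[PrimerMatch]:
    """Gapped (edit-distance) placements of a primer, both strands.

    Uses infix alignment with at most ``max_edits`` total edits
    (mismatches + insertions + deletions); intended for mapping primer
    sets back onto assemblies, not for amplicon prediction.
    """
    import edlib

    primer, seq = primer.upper(), seq.upper()
    out = []
    for strand, probe in (("+", primer), ("-", revcomp(primer))):
        res = edlib.align(probe, seq, mode="HW", task="locations", k=max_edits)
        if res["editDistance"] < 0:
            continue
        seen = set()
        for start0, end0 in res["locations"]:
            if start0 is None or (start0, end0) in seen:
                continue
            seen.add((start0, end0))
            # per-location edit breakdown from a global realignment
            local = edlib.align(probe, seq[start0: end0 + 1], mode="NW", task="path")
            ins = dels = mms = 0
            for count, op in re.findall(r"(\d+)([=XID])", local["cigar"] or ""):
                if op == "X":
                    mms += int(count)
                elif op == "I":  # base in probe absent from the reference
                    ins += int(count)
                elif op == "D":  # reference base absent from the probe
                    dels += int(count)
            if mms + ins + dels > max_edits:
                continue
            out.append(PrimerMatch(primer_id, seqid, start0 + 1, strand, mms, ins, dels))
    out.sort(key=lambda h: (h.start, h.strand))
    return out


def _pair_hits(
    pair_id: str,
    fwd_primer: str,
    rev_primer: str,
    seqid: str,
    seq: str,
    cfg: EpcrConfig,
    orientation: str,
) -> list[AmpliconHit]:
    fwd = _scan(fwd_primer.upper(), seq, cfg.max_mismatch, cfg.three_prime_exact, "+")
    rev = _scan(rev_primer.upper(), seq, cfg.max_mismatch, cfg.three_prime_exact, "-")
    lf, lr = len(fwd_primer), len(rev_primer)
    hits = []
    for fs, fmm in fwd:
        for rs, rmm in rev:
            length = (rs + lr) - fs  # rightmost base of reverse window - fwd start + 1
            if length < max(lf, lr) or length > cfg.max_product or rs < fs:
                continue
            hits.append(
                AmpliconHit(pair_id, seqid, fs + 1, rs + 1, length, fmm, rmm, orientation)
            )
    return hits


def epcr(
    pairs: Iterable[PrimerPair] | Iterable[tuple[str, str, str]],
    ref: Mapping[str, str],
    config: EpcrConfig | None = None,
) -> tuple[list[AmpliconHit], dict[str, int]]:
    """Predict amplicons for each pair on each reference sequence.

    ``pairs`` may be :class:`~pcrmarkers.primers.PrimerPair` objects or
    ``(pair_id, left_seq, right_seq)`` tuples; ``ref`` maps seqid to
    sequence.  Both pair orientations are tried (left priming the top
    strand with right on the bottom, and vice versa).  Returns the hits
    plus a per-pair hit count; pairs with 0 hits (no product) or >1 hit
    (non-specific) fail the specificity screen.
    """
    config = config or EpcrConfig()
    hits: list[AmpliconHit] = []
    counts: dict[str, int] = {}
    for pair in pairs:
        if isinstance(pair, PrimerPair):
            pid, left, right = pair.pair_id, pair.left_seq, pair.right_seq
        else:
            pid, left, right = pair
        counts.setdefault(pid, 0)
        for seqid, seq in ref.items():
            seq = str(seq).upper()
            found = _pair_hits(pid, left, right, seqid, seq, config, "forward")
            if left.upper() != right.upper():
                found += _pair_hits(pid, right, left, seqid, seq, config, "reverse")
            counts[pid] += len(found)
            hits.extend(found)
    return hits, counts


def specificity_table(hits: list[AmpliconHit], counts: dict[str, int]) -> pd.DataFrame:
    """Per-pair summary: hit count and a specific/no-product/non-specific flag."""
    rows = []
    for pid, n in counts.items():
        flag = "specific" if n == 1 else ("no_product" if n == 0 else "non_specific")
        rows.append({"pair_id": pid, "n_hits": n, "flag": flag})
    return pd.DataFrame(rows, columns=["pair_id", "n_hits", "flag"])


def hits_table(hits: Iterable[AmpliconHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair_id": h.pair_id,
                "seqid": h.seqid,
                "forward_start": h.forward_start,
                "reverse_start": h.reverse_start,
                "product_length": h.product_length,
                "forward_mismatches": h.forward_mismatches,
                "reverse_mismatches": h.reverse_mismatches,
                "orientation": h.orientation,
            }
            for h in hits
        ],
        columns=[
            "pair_id",
            "seqid",
            "forward_start",
            "reverse_start",
            "product_length",
            "forward_mismatches",
            "reverse_mismatches",
            "orientation",
        ],
    )


# ---------------------------------------------------------------------------
# EMBOSS primersearch "Amplimer" report dialect

_RE_PRIMER_NAME = re.compile(r"^Primer name\s+(\S.*)$")
_RE_AMPLIMER = re.compile(r"^Amplimer\s+(\d+)")
_RE_SEQUENCE = re.compile(r"^\s*Sequence:\s*(\S+)")
_RE_FWD = re.compile(r"hits forward strand at (\d+) with (\d+) mismatches")
_RE_REV = re.compile(r"hits reverse strand at \[(\d+)\] with (\d+) mismatches")
_RE_LENGTH = re.compile(r"^\s*Amplimer length:\s*(\d+)\s*bp")


def parse_amplimer_report(stream: IO[str]) -> list[AmpliconHit]:
    """Parse primersearch-format amplimer blocks into :class:`AmpliconHit`.

    Each block reports the forward hit position, the reverse hit position
    counted from the sequence 3' end (bracketed), the per-primer mismatch
    counts and the amplimer length.  The reverse-window start on the top
    strand is recoverable only when the sequence length is known, so it is
    reported here as ``forward_start + product_length - 1`` minus the
    reverse offset convention is *not* applied; the positions carried are
    the ones the report states.
    """
    hits = []
    pair_id = ""
    block: dict = {}
    n_blocks = 0

    def flush() -> None:
        if not block:
            return
        missing = {"fwd", "rev", "length"} - set(block)
        if missing:
            raise ValueError(f"malformed amplimer block {n_blocks}: missing {sorted(missing)}")
        hits.append(
            AmpliconHit(
                pair_id=block.get("pair", pair_id),
                seqid=block.get("seqid", ""),
                forward_start=block["fwd"][0],
                reverse_start=block["rev"][0],
                product_length=block["length"],
                forward_mismatches=block["fwd"][1],
                reverse_mismatches=block["rev"][1],
            )
        )

    for line in stream:
        if m := _RE_PRIMER_NAME.match(line):
            pair_id = m.group(1).strip()
            continue
        if _RE_AMPLIMER.match(line):
            flush()
            n_blocks += 1
            block = {"pair": pair_id}
            continue
        if m := _RE_SEQUENCE.match(line):
            block["seqid"] = m.group(1)
        elif m := _RE_FWD.search(line):
            block["fwd"] = (int(m.group(1)), int(m.group(2)))
        elif m := _RE_REV.search(line):
            block["rev"] = (int(m.group(1)), int(m.group(2)))
        elif m := _RE_LENGTH.match(line):
            block["length"] = int(m.group(1))
    flush()
    return hits
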