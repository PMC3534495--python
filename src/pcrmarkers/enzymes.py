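"""Restriction enzymes with IUPAC-degenerate recognition sites.

An enzyme is a named recognition pattern over the IUPAC nucleotide
alphabet, with an optional cut offset.  :func:`find_sites` scans a
sequence for matches on both strands; pattern codes match their IUPAC
expansion while an ``N`` in the *sequence* matches nothing, so ambiguous
reference bases never produce a site call.

The default panel bundles six enzymes that cut reliably in PCR buffer
(TaqI, AluI, RsaI, DpnII, HinfI, HaeIII); users can supply their own
panel as a TSV of (name, site, cut offset).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterator

IUPAC_EXPAND = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_revcomp(pattern: str) -> str:
    """Reverse complement of an IUPAC-degenerate pattern."""
    up = pattern.upper()
    bad = set(up) - set(IUPAC_EXPAND)
    if bad:
        raise ValueError(f"invalid IUPAC symbol(s) {sorted(bad)} in {pattern!r}")
    return up.translate(_IUPAC_COMPLEMENT)[::-1]


def _pattern_regex(pattern: str) -> re.Pattern[str]:
    # sequence N must not match: character classes list concrete bases only
    return re.compile("(?=(" + "".join(f"[{IUPAC_EXPAND[c]}]" for c in pattern) + "))")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Named IUPAC recognition pattern; palindromy is derived, never stored."""

    name: str
    site: str
    cut_offset: int | None = None

    def __post_init__(self) -> None:
        up = self.site.upper()
        object.__setattr__(self, "site", up)
        if len(up) < 3:
            raise ValueError(f"{self.name}: recognition site shorter than 3 bases")
        bad = set(up) - set(IUPAC_EXPAND)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC character(s) {sorted(bad)}")

    @property
    def palindromic(self) -> bool:
        return self.site == iupac_revcomp(self.site)


class EnzymePanel:
    """Ordered set of restriction enzymes, unique by name."""

    def __init__(self, enzymes: Iterator[RestrictionEnzyme] | list[RestrictionEnzyme]):
        self._enzymes: dict[str, RestrictionEnzyme] = {}
        for e in enzymes:
            if e.name in self._enzymes:
                raise ValueError(f"duplicate enzyme name {e.name!r}")
            self._enzymes[e.name] = e

    def __iter__(self) -> Iterator[RestrictionEnzyme]:
        return iter(self._enzymes.values())

    def __len__(self) -> int:
        return len(self._enzymes)

    def __contains__(self, name: str) -> bool:
        return name in self._enzymes

    def __getitem__(self, name: str) -> RestrictionEnzyme:
        return self._enzymes[name]

    @property
    def names(self) -> list[str]:
        return list(self._enzymes)

    @property
    def max_site_length(self) -> int:
        return max(len(e.site) for e in self)


def _parse_panel_rows(lines: Iterator[str]) -> Iterator[RestrictionEnzyme]:
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        name, site = fields[0], fields[1]
        cut = int(fields[2]) if len(fields) > 2 and fields[2] not in (".", "") else None
        yield RestrictionEnzyme(name, site, cut)


def load_panel(config: str | Path | IO[str] | None = None) -> EnzymePanel:
    """Load an enzyme panel from a TSV (name, site, cut offset).

    With no config, returns the bundled default six-enzyme panel
    (TaqI, AluI, RsaI, DpnII, HinfI, HaeIII).
    """
    if config is None:
        text = (resources.files("pcrmarkers.data") / "default_enzymes.tsv").read_text()
        return EnzymePanel(_parse_panel_rows(iter(text.splitlines())))
    if hasattr(config, "read"):
        return EnzymePanel(_parse_panel_rows(iter(config)))
    with open(config) as fh:
        return EnzymePanel(_parse_panel_rows(fh))


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[tuple[int, str]]:
    """All recognition-site matches in ``seq`` on both strands.

    Returns ``(position, strand)`` tuples sorted by position, where
    position is the 1-based start of the matched window on the top strand.
    For palindromic enzymes the coincident +/- hits at one locus collapse
    to a single ``(pos, '+')``.  Overlapping matches are all reported.
    """
    seq = seq.upper()
    hits = [(m.start() + 1, "+") for m in _pattern_regex(enzyme.site).finditer(seq)]
    if not enzyme.palindromic:
        rc = iupac_revcomp(enzyme.site)
        hits += [(m.start() + 1, "-") for m in _pattern_regex(rc).finditer(seq)]
        hits.sort()
    return hits


def count_sites(seq: str, enzyme: RestrictionEnzyme) -> int:
    """Number of recognition sites in ``seq`` (both strands, collapsed)."""
    return len(find_sites(seq, enzyme))


DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a plain {A,C,G,T,N} sequence."""
    return seq.upper().translate(DNA_COMPLEMENT)[::-1]
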