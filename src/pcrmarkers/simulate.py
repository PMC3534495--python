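"""Seeded synthetic fixtures: reference contigs with planted variants and truth.

The generator emulates the kind of data the toolkit is built for —
transcriptome-scale reference contigs (uniform base composition) with
SNVs and small indels called against them.  A configurable fraction of
variants is *constructed* to create or destroy a recognition site of a
panel enzyme (by embedding a site instance and editing one base of it);
the remainder are placed so that no panel enzyme's site count changes.

Every planted variant's expected detection outcome is verified at
generation time by this module's own brute-force digest (an independent
window-by-window IUPAC expansion scan, deliberately sharing no code with
:mod:`pcrmarkers.enzymes`), so the truth table can serve as an oracle for
the detection pipeline.  The same seed always yields byte-identical FASTA
and VCF output.

What this does not emulate: real base-composition bias, sequencing error,
read-depth-dependent call quality, clustered variation or heterozygous
genotype calls — fixtures validate the combinatorics and bookkeeping of
marker design, not caller behaviour on real reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .caps import snp_class
from .enzymes import EnzymePanel, load_panel
from .variants import VariantFeature

BASES = "ACGT"

# independent IUPAC machinery for the generation-time oracle
_EXPAND = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}


def _rc_pattern(site: str) -> str:
    return "".join(_COMP[c] for c in reversed(site))


def _window_matches(seq: str, site: str, at: int) -> bool:
    for j, code in enumerate(site):
        if seq[at + j] not in _EXPAND[code]:
            return False
    return True


def brute_site_count(seq: str, site: str) -> int:
    """Both-strand site count by exhaustive window scan (oracle path)."""
    seq = seq.upper()
    m = len(site)
    rc = _rc_pattern(site)
    n = 0
    for i in range(len(seq) - m + 1):
        if _window_matches(seq, site, i):
            n += 1
        elif site != rc and _window_matches(seq, rc, i):
            n += 1
    return n


def brute_apply(seq: str, v: VariantFeature, offset: int = 1) -> str:
    """Apply an alternate allele (oracle path, independent of caps module)."""
    i = v.start - offset
    if v.vtype == "SNV":
        return seq[:i] + v.alt_allele + seq[i + 1:]
    if v.vtype == "insertion":
        return seq[: i + 1] + v.alt_allele + seq[i + 1:]
    return seq[:i] + seq[i + len(v.ref_allele):]


def brute_caps_truth(
    contig: str, v: VariantFeature, panel: EnzymePanel, flank: int = 50
) -> list[tuple[str, str]]:
    """Expected (enzyme, status) list for one variant, by brute-force digest."""
    ws = max(1, v.start - flank)
    we = min(len(contig), v.end + flank)
    ref_win = contig[ws - 1: we]
    alt_win = brute_apply(ref_win, v, ws)
    out = []
    for e in panel:
        nref = brute_site_count(ref_win, e.site)
        nalt = brute_site_count(alt_win, e.site)
        if nalt > nref:
            out.append((e.name, "gained"))
        elif nalt < nref:
            out.append((e.name, "lost"))
    return out


@dataclass
class Fixture:
    """Generated contigs, variant records and the generation-time truth table."""

    contigs: dict[str, str]
    variants: list[VariantFeature]
    truth: pd.DataFrame
    seed: int
    panel: EnzymePanel = field(repr=False, default=None)

    def fasta_text(self) -> str:
        chunks = []
        for name, seq in self.contigs.items():
            chunks.append(f">{name}\n")
            for i in range(0, len(seq), 60):
                chunks.append(seq[i: i + 60] + "\n")
        return "".join(chunks)

    def vcf_text(self) -> str:
        lines = [
            "##fileformat=VCFv4.2",
            f"##source=pcrmarkers-simulate seed={self.seed}",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        for v in sorted(self.variants, key=lambda v: (v.seqid, v.start, v.id)):
            contig = self.contigs[v.seqid]
            if v.vtype == "SNV":
                pos, ref, alt = v.start, v.ref_allele, v.alt_allele
            elif v.vtype == "insertion":
                anchor = contig[v.start - 1]
                pos, ref, alt = v.start, anchor, anchor + v.alt_allele
            else:  # deletion: anchor on the base 5' of the deleted run
                anchor = contig[v.start - 2]
                pos, ref, alt = v.start - 1, anchor + v.ref_allele, anchor
            lines.append(f"{v.seqid}\t{pos}\t{v.id}\t{ref}\t{alt}\t.\tPASS\t.")
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "reference.fa",
            "vcf": outdir / "variants.vcf",
            "truth": outdir / "truth.tsv",
        }
        paths["fasta"].write_text(self.fasta_text())
        paths["vcf"].write_text(self.vcf_text())
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _instantiate(rng: np.random.Generator, site: str) -> str:
    return "".join(sorted(_EXPAND[c])[rng.integers(0, len(_EXPAND[c]))] for c in site)


class PlacementError(RuntimeError):
    """Raised when a variant cannot be planted within the retry budget."""


def generate_fixture(
    seed: int,
    n_contigs: int = 5,
    contig_length: int = 3000,
    n_variants: int = 100,
    planted_caps_fraction: float = 0.4,
    indel_fraction: float = 0.15,
    neighbour_fraction: float = 0.0,
    flank: int = 50,
    panel: EnzymePanel | None = None,
    max_retries: int = 200,
) -> Fixture:
    """Build a seeded fixture with ground-truth CAPS outcomes.

    ``planted_caps_fraction`` of the ``n_variants`` primary variants are
    SNVs engineered to gain or lose one panel enzyme's site; the rest are
    neutral SNVs/indels (``indel_fraction`` of the neutral ones are 1-3 bp
    indels) verified to change no site count.  ``neighbour_fraction`` of
    primary variants additionally get a neutral SNV planted 15-45 bp away
    (for exercising confounding flags and primer masking); neighbours are
    extra records on top of ``n_variants``.
    """
    if not 0 <= planted_caps_fraction <= 1:
        raise ValueError("planted_caps_fraction must be in [0, 1]")
    panel = panel or load_panel()
    rng = np.random.default_rng(seed)
    contigs = {f"contig{i + 1:04d}": list(_random_seq(rng, contig_length)) for i in range(n_contigs)}
    names = list(contigs)
    margin = flank + 40
    min_sep = 2 * flank + 20
    occupied: dict[str, list[int]] = {n: [] for n in names}

    n_caps = round(n_variants * planted_caps_fraction)
    variants: list[VariantFeature] = []
    rows: list[dict] = []

    def pick_position(seqid: str) -> int | None:
        for _ in range(max_retries):
            p = int(rng.integers(margin, contig_length - margin))
            if all(abs(p - q) >= min_sep for q in occupied[seqid]):
                return p
        return None

    def plant(i: int, make_caps: bool) -> None:
        vid = f"v{i + 1:04d}"
        for _ in range(max_retries):
            seqid = names[int(rng.integers(0, n_contigs))]
            p = pick_position(seqid)
            if p is None:
                continue
            contig = contigs[seqid]
            if make_caps:
                enz = list(panel)[int(rng.integers(0, len(panel)))]
                inst = _instantiate(rng, enz.site)
                # only positions that constrain the base can break the site
                breakable = [j for j, c in enumerate(enz.site) if len(_EXPAND[c]) < 4]
                off = breakable[int(rng.integers(0, len(breakable)))]
                allowed = _EXPAND[enz.site[off]]
                breakers = [b for b in BASES if b not in allowed]
                broken = breakers[int(rng.integers(0, len(breakers)))]
                lose = bool(rng.integers(0, 2))
                if lose:  # reference carries the intact site; alt destroys it
                    ref_base, alt_base = inst[off], broken
                    planted = inst
                else:  # reference carries a one-off site; alt completes it
                    ref_base, alt_base = broken, inst[off]
                    planted = inst[:off] + broken + inst[off + 1:]
                saved = contig[p - 1: p - 1 + len(planted)]
                contig[p - 1: p - 1 + len(planted)] = list(planted)
                v = VariantFeature(seqid, "simulate", "SNV", p + off, p + off, ref_base, alt_base, vid)
                truth = brute_caps_truth("".join(contig), v, panel, flank)
                want = (enz.name, "lost" if lose else "gained")
                if want in truth:
                    _record(v, truth)
                    return
                contig[p - 1: p - 1 + len(planted)] = saved  # undo and retry
            else:
                v = _neutral_variant(rng, seqid, "".join(contig), p, vid, indel_fraction)
                if v is not None and not brute_caps_truth("".join(contig), v, panel, flank):
                    _record(v, [])
                    return
        raise PlacementError(f"could not plant variant {vid} within {max_retries} retries")

    def _record(v: VariantFeature, truth: list[tuple[str, str]]) -> None:
        occupied[v.seqid].append(v.start)
        variants.append(v)
        rows.append(
            {
                "id": v.id,
                "seqid": v.seqid,
                "vtype": v.vtype,
                "start": v.start,
                "end": v.end,
                "ref_allele": v.ref_allele,
                "alt_allele": v.alt_allele,
                "expected": ";".join(f"{e}:{s}" for e, s in truth),
                "hrm_class": snp_class(v.ref_allele, v.alt_allele) if v.vtype == "SNV" else "",
                "neighbours": "",
            }
        )

    for i in range(n_variants):
        plant(i, make_caps=i < n_caps)

    # optional close neighbours (neutral SNVs 15-45 bp from their target)
    n_neigh = round(n_variants * neighbour_fraction)
    target_idx = rng.choice(n_variants, size=n_neigh, replace=False) if n_neigh else []
    for k, ti in enumerate(sorted(int(t) for t in np.atleast_1d(target_idx))):
        tv = variants[ti]
        nid = f"n{k + 1:04d}"
        for _ in range(max_retries):
            delta = int(rng.integers(15, 46)) * (1 if rng.integers(0, 2) else -1)
            p = tv.start + delta
            if not (margin <= p <= contig_length - margin) or abs(delta) < 10:
                continue
            if any(v.seqid == tv.seqid and v.start == p for v in variants):
                continue
            nv = _neutral_variant(rng, tv.seqid, "".join(contigs[tv.seqid]), p, nid, 0.0)
            if nv is not None and not brute_caps_truth("".join(contigs[tv.seqid]), nv, panel, flank):
                variants.append(nv)
                rows.append(
                    {
                        "id": nid, "seqid": nv.seqid, "vtype": "SNV", "start": nv.start,
                        "end": nv.end, "ref_allele": nv.ref_allele, "alt_allele": nv.alt_allele,
                        "expected": "", "hrm_class": snp_class(nv.ref_allele, nv.alt_allele),
                        "neighbours": tv.id,
                    }
                )
                rows[ti]["neighbours"] = nid
                break
        else:
            raise PlacementError(f"could not plant neighbour for {tv.id}")

    truth_df = pd.DataFrame(rows)
    return Fixture({n: "".join(s) for n, s in contigs.items()}, variants, truth_df, seed, panel)


def _neutral_variant(
    rng: np.random.Generator, seqid: str, contig: str, p: int, vid: str, indel_fraction: float
) -> VariantFeature | None:
    """One candidate neutral variant at position p (caller verifies neutrality)."""
    r = rng.random()
    if r < indel_fraction / 2:  # insertion of 1-3 bases
        ins = _random_seq(rng, int(rng.integers(1, 4)))
        return VariantFeature(seqid, "simulate", "insertion", p, p, "-", ins, vid)
    if r < indel_fraction:  # deletion of 1-3 bases
        k = int(rng.integers(1, 4))
        return VariantFeature(seqid, "simulate", "deletion", p, p + k - 1, contig[p - 1: p + k - 1], "-", vid)
    ref = contig[p - 1]
    alts = [b for b in BASES if b != ref]
    alt = alts[int(rng.integers(0, 3))]
    return VariantFeature(seqid, "simulate", "SNV", p, p, ref, alt, vid)


# ---------------------------------------------------------------------------
# constructed indel cases (shift-safety and junction-site checks)


def make_pure_shift_indel(
    rng: np.random.Generator, panel: EnzymePanel | None = None, flank: int = 50
) -> tuple[str, VariantFeature]:
    """A contig + indel where sites only translate: no count changes.

    The indel sits between two embedded enzyme sites; its alternate allele
    shifts the downstream site without creating or destroying any site
    (verified by brute-force digest, retried until clean).
    """
    panel = panel or load_panel()
    length = 2 * flank + 61
    pos = flank + 20
    for _ in range(500):
        contig = _random_seq(rng, length)
        enz = list(panel)[int(rng.integers(0, len(panel)))]
        inst = _instantiate(rng, enz.site)
        # one site upstream, one downstream of the future indel
        contig = contig[:10] + inst + contig[10 + len(inst):]
        down = pos + 15
        contig = contig[:down] + inst + contig[down + len(inst):]
        v = _neutral_variant(rng, "shift", contig, pos, "shift_case", 1.0)
        if v is None or v.vtype == "SNV":
            continue
        if not brute_caps_truth(contig, v, panel, flank):
            return contig, v
    raise PlacementError("no clean pure-shift case found")


def make_junction_indel(
    rng: np.random.Generator, panel: EnzymePanel | None = None, flank: int = 50
) -> tuple[str, VariantFeature, str]:
    """A contig + deletion that fuses its flanks into a new enzyme site.

    The reference carries the two halves of a site instance separated by a
    spacer; deleting the spacer creates the site (status 'gained' for the
    returned enzyme).  Verified by brute digest, retried until exactly the
    constructed enzyme changes.
    """
    panel = panel or load_panel()
    length = 2 * flank + 60
    for _ in range(500):
        enz = list(panel)[int(rng.integers(0, len(panel)))]
        inst = _instantiate(rng, enz.site)
        half = len(inst) // 2
        spacer = _random_seq(rng, int(rng.integers(2, 5)))
        pos = flank + 10
        contig = _random_seq(rng, length)
        piece = inst[:half] + spacer + inst[half:]
        contig = contig[: pos - half] + piece + contig[pos - half + len(piece):]
        v = VariantFeature("junction", "simulate", "deletion", pos + 1, pos + len(spacer),
                           spacer, "-", "junction_case")
        truth = brute_caps_truth(contig, v, panel, flank)
        if truth == [(enz.name, "gained")]:
            return contig, v, enz.name
    raise PlacementError("no clean junction case found")
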