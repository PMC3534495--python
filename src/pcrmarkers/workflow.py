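"""End-to-end marker-design workflows and tabular filtering.

Two documented entry points share all downstream stages: variant calls
arrive either as VCF (short-read pipelines) or as gsMapper
454HCDiffs/454AllDiffs tables, are converted to GFF3/GVF, screened for
CAPS candidates, filtered by marker type, run through masked primer
design, and validated by electronic PCR against the reference.  Every
artifact is a flat GFF3/TSV file with a provenance header so downstream
filtering works with ordinary line-oriented tools.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import variants as vio
from .caps import candidates_to_table, filter_hrm_targets, scan_variants
from .enzymes import load_panel
from .epcr import EpcrConfig, epcr, hits_table, specificity_table
from .primers import DesignConfig, build_template, design_primers, primer_table

logger = logging.getLogger(__name__)


class WorkflowError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    reference: str | Path
    variants: str | Path
    outdir: str | Path
    variant_format: str = "vcf"  # vcf | gsmapper | gff3
    panel: str | Path | None = None
    flank: int = 50
    marker_type: str = "CAPS"
    design: DesignConfig = field(default_factory=DesignConfig)
    epcr: EpcrConfig = field(default_factory=EpcrConfig)
    seed: int = 42
    log_level: str = "INFO"
    exclude_confounded: bool = False


def _provenance(config: RunConfig, stage: str, **extra) -> str:
    lines = [
        "# pcrmarkers workflow artifact",
        f"# stage={stage}",
        f"# reference={config.reference}",
        f"# variants={config.variants} format={config.variant_format}",
        f"# flank={config.flank} marker_type={config.marker_type} seed={config.seed}",
    ]
    for k, v in extra.items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def _write_table(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a workflow TSV artifact, skipping provenance comment lines."""
    return pd.read_csv(path, sep="\t", comment="#")


def filter_table(df: pd.DataFrame, spec: dict) -> pd.DataFrame:
    """Row-wise filter on named columns, preserving order.

    Predicate values: a scalar (equality), a 2-tuple (inclusive numeric
    range) or a callable.  Unknown columns raise an error listing the
    valid ones.
    """
    out = df
    for col, pred in spec.items():
        if col not in df.columns:
            raise KeyError(f"unknown column {col!r}; valid columns: {list(df.columns)}")
        if callable(pred):
            out = out[out[col].map(pred)]
        elif isinstance(pred, tuple) and len(pred) == 2:
            out = out[(out[col] >= pred[0]) & (out[col] <= pred[1])]
        else:
            out = out[out[col] == pred]
    return out


def _load_reference(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_caps_workflow(config: RunConfig) -> dict[str, Path]:
    """Convert -> detect -> filter -> design -> e-PCR, writing all artifacts.

    Returns paths of the five artifacts (GFF3 variants, candidate table,
    primer table, e-PCR report, run log).  The first failing stage aborts
    the run with its name; input paths are checked up front so a bad
    config writes nothing.
    """
    logging.basicConfig(level=config.log_level)
    for p in (config.reference, config.variants):
        if not Path(p).exists():
            raise WorkflowError("setup", f"input path does not exist: {p}")
    if config.panel is not None and not Path(config.panel).exists():
        raise WorkflowError("setup", f"panel path does not exist: {config.panel}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": outdir / "variants.gff3",
        "candidates": outdir / "candidates.tsv",
        "primers": outdir / "primers.tsv",
        "epcr": outdir / "epcr.tsv",
        "log": outdir / "run.log",
    }
    log_lines: list[str] = [f"pcrmarkers run: seed={config.seed} marker_type={config.marker_type}"]

    # stage 1: convert
    try:
        with open(config.variants) as fh:
            if config.variant_format == "vcf":
                feats = list(vio.parse_vcf(fh))
            elif config.variant_format == "gsmapper":
                feats = list(vio.parse_gsmapper_diffs(fh))
            elif config.variant_format == "gff3":
                feats = list(vio.parse_gff3(fh))
            else:
                raise ValueError(f"unknown variant format {config.variant_format!r}")
        buf = io.StringIO()
        buf.write(_provenance(config, "convert"))
        n = vio.write_gff3(feats, buf)
        paths["gff3"].write_text(buf.getvalue())
        log_lines.append(f"convert: read {n} variant features")
    except Exception as exc:
        raise WorkflowError("convert", str(exc)) from exc

    # stage 2: detect
    try:
        panel = load_panel(config.panel)
        reference = _load_reference(config.reference)
        scan = scan_variants(reference, feats, panel, config.flank)
        candidates = list(scan)
        cand_df = candidates_to_table(candidates)
        _write_table(cand_df, paths["candidates"], _provenance(config, "detect", **{
            "panel": ",".join(panel.names)}))
        log_lines.append(
            f"detect: {scan.stats['variants_seen']} variants in, "
            f"{scan.stats['candidates']} candidates out "
            f"(per-enzyme {scan.stats['per_enzyme']})"
        )
    except Exception as exc:
        raise WorkflowError("detect", str(exc)) from exc

    # stage 3: filter targets by marker type
    try:
        by_id = {f.id: f for f in feats}
        if config.marker_type == "CAPS":
            work = cand_df
            if config.exclude_confounded:
                work = filter_table(work, {"confounded": False})
            targets: list[tuple] = []
            for vid, grp in work.groupby("variant_id", sort=False):
                targets.append((by_id[vid], ",".join(sorted(set(grp["enzyme"])))))
        elif config.marker_type == "HRM":
            hrm = filter_hrm_targets(feats)
            targets = [(v, "") for v in hrm]
            log_lines.append(
                f"filter: dropped {hrm.dropped_indel} indels, {hrm.dropped_class} class III/IV"
            )
        elif config.marker_type == "indel":
            targets = [(v, "") for v in feats if v.vtype in ("insertion", "deletion")]
        else:
            raise ValueError(f"unknown marker type {config.marker_type!r}")
        log_lines.append(f"filter: {len(targets)} design targets ({config.marker_type})")
    except WorkflowError:
        raise
    except Exception as exc:
        raise WorkflowError("filter", str(exc)) from exc

    # stage 4: design
    try:
        results = []
        n_ok = 0
        for target, enzyme in targets:
            contig = reference.get(target.seqid)
            if contig is None:
                raise KeyError(f"reference sequence {target.seqid!r} missing")
            template = build_template(
                contig, target, feats, config.design, config.marker_type, enzyme
            )
            res = design_primers(template, config.design)
            if res.pairs:
                n_ok += 1
            else:
                logger.info("no primers for %s: %s", target.id, res.failure)
            results.append((template, res))
        prim_df = primer_table(results)
        _write_table(prim_df, paths["primers"], _provenance(config, "design"))
        log_lines.append(f"design: {n_ok}/{len(targets)} targets got primer pairs "
                         f"({len(prim_df)} pairs)")
    except Exception as exc:
        raise WorkflowError("design", str(exc)) from exc

    # stage 5: electronic PCR validation
    try:
        pairs = [
            (row.pair_id, row.left_seq, row.right_seq)
            for row in prim_df.itertuples(index=False)
        ]
        hits, counts = epcr(pairs, reference, config.epcr)
        report = hits_table(hits).merge(specificity_table(hits, counts), on="pair_id", how="right")
        _write_table(report, paths["epcr"], _provenance(config, "epcr", **{
            "max_mismatch": config.epcr.max_mismatch,
            "three_prime_exact": config.epcr.three_prime_exact,
            "max_product": config.epcr.max_product}))
        n_spec = sum(1 for n in counts.values() if n == 1)
        log_lines.append(f"epcr: {len(pairs)} pairs tested, {n_spec} specific")
    except Exception as exc:
        raise WorkflowError("epcr", str(exc)) from exc

    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths
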