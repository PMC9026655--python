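"""One-shot pipeline: read, harmonize, filter, compare, summarize, annotate.

Every stage writes its outputs under the run's output directory and the run
manifest records the configuration hash, the seed and per-stage record
counts, so identical inputs and configuration reproduce byte-identical
tables and an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import svconcord
from svconcord import annotation as ann
from svconcord import concordance as conc
from svconcord import harmonize as hz
from svconcord import io as fio
from svconcord import stats as st

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds (defaults are the analysis's)."""

    ont_diff: str = ""
    bionano_vcf: str = ""
    outdir: str = "svconcord_out"
    gff: str | None = None
    fasta: str | None = None
    exclusions_bed: str | None = None
    min_size: int = 1000              # strict size filter, bp
    bionano_min_quality: int = 10     # 0-20 score floor for INS/DEL
    tra_cutoff: float = 0.1           # translocation confidence cutoff
    inv_cutoff: float = 0.01          # inversion confidence cutoff
    bin_width: int = 100_000          # genome-bin width, bp
    motif: str = "CTTAAG"             # DLE-1 recognition site
    large_event_cutoff: int = 50_000  # size test re-run excluding >= this
    resolve_embedded_bionano: bool = True
    resolve_embedded_ont: bool = False
    quality_key: str = "QUAL_SCORE"
    confidence_key: str = "CONFIDENCE"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        # analysis identity: where outputs land is not part of it
        params = {k: v for k, v in asdict(self).items() if k != "outdir"}
        canon = yaml.safe_dump(params, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _report_frame(report: hz.FilterReport) -> pd.DataFrame:
    rows = []
    for item, reason in report.removed:
        if isinstance(item, hz.SvCall):
            rows.append(
                {
                    "record": item.call_id, "chrom": item.chrom,
                    "start": item.ref_start, "end": item.ref_end,
                    "sv_type": item.sv_type, "size": item.size,
                    "reason": reason,
                }
            )
        else:  # DiffRecord
            rows.append(
                {
                    "record": f"{item.feature_type}", "chrom": item.ref_seq,
                    "start": item.ref_start, "end": item.ref_end,
                    "sv_type": item.feature_type, "size": item.ref_gap_len,
                    "reason": reason,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["record", "chrom", "start", "end", "sv_type", "size", "reason"],
    )


def _chrom_lengths(
    config: RunConfig, calls: list[hz.SvCall]
) -> dict[str, int]:
    if config.fasta:
        return {c: len(s) for c, s in fio.read_fasta(config.fasta).items()}
    lengths: dict[str, int] = {}
    for call in calls:
        lengths[call.chrom] = max(lengths.get(call.chrom, 0), call.ext_end)
    # round up to whole bins so every call fits
    return {
        c: ((l // config.bin_width) + 1) * config.bin_width
        for c, l in lengths.items()
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def _stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rethrown with stage name
            raise PipelineError(name, exc) from exc

    # --- read + harmonize -------------------------------------------------
    diff_records = _stage("read_ont", fio.read_show_diff, config.ont_diff)
    counts["ont_raw_records"] = len(diff_records)
    bn_records = _stage(
        "read_bionano", fio.read_bionano_vcf, config.bionano_vcf,
        quality_key=config.quality_key, confidence_key=config.confidence_key,
    )
    counts["bionano_raw_records"] = len(bn_records)

    ont_harm = _stage("harmonize_ont", hz.harmonize_ont, diff_records)
    counts["ont_harmonized"] = len(ont_harm.retained)
    counts["ont_assembly_discordance"] = len(ont_harm.removed)
    bn_calls = _stage("harmonize_bionano", hz.harmonize_bionano, bn_records)
    counts["bionano_harmonized"] = len(bn_calls)

    # --- filter -----------------------------------------------------------
    ont_calls = ont_harm.retained
    removals = [ont_harm]
    if config.resolve_embedded_ont:
        rep = _stage("resolve_embedded_ont", hz.resolve_embedded, ont_calls)
        ont_calls = rep.retained
        removals.append(rep)
    exclusions = (
        fio.read_bed_intervals(config.exclusions_bed)
        if config.exclusions_bed
        else ()
    )
    ont_filter = _stage(
        "filter_ont", hz.filter_ont, ont_calls,
        min_size=config.min_size, exclusions=exclusions,
    )
    removals.append(ont_filter)
    ont_final = ont_filter.retained
    counts["ont_filtered"] = len(ont_final)

    bn_removals = []
    if config.resolve_embedded_bionano:
        rep = _stage("resolve_embedded_bionano", hz.resolve_embedded, bn_calls)
        bn_calls = rep.retained
        bn_removals.append(rep)
    bn_filter = _stage(
        "filter_bionano", hz.filter_bionano, bn_calls,
        min_size=config.min_size, min_quality=config.bionano_min_quality,
        tra_cutoff=config.tra_cutoff, inv_cutoff=config.inv_cutoff,
    )
    bn_removals.append(bn_filter)
    bn_final = bn_filter.retained
    counts["bionano_filtered"] = len(bn_final)

    hz.calls_to_frame(ont_final).to_csv(
        outdir / "ont_filtered.tsv", sep="\t", index=False
    )
    hz.calls_to_frame(bn_final).to_csv(
        outdir / "bionano_filtered.tsv", sep="\t", index=False
    )
    pd.concat([_report_frame(r) for r in removals], ignore_index=True).to_csv(
        outdir / "ont_removed.tsv", sep="\t", index=False
    )
    pd.concat([_report_frame(r) for r in bn_removals], ignore_index=True).to_csv(
        outdir / "bionano_removed.tsv", sep="\t", index=False
    )

    # --- compare ----------------------------------------------------------
    groups = _stage("compare", conc.classify, ont_final, bn_final)
    counts["locations"] = len(groups)
    venn = conc.venn_counts(groups)
    counts["common_locations"] = venn["common_locations"]
    conc.groups_to_table(groups).to_csv(
        outdir / "groups.tsv", sep="\t", index=False
    )
    with open(outdir / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=2, sort_keys=True)

    # --- summarize --------------------------------------------------------
    st.summarize_by_type(ont_final).to_csv(outdir / "ont_by_type.tsv", sep="\t")
    st.summarize_by_type(bn_final).to_csv(
        outdir / "bionano_by_type.tsv", sep="\t"
    )
    st.summarize_by_class(groups).to_csv(outdir / "by_class.tsv", sep="\t")
    size_tests = {}
    if ont_final and bn_final:
        for label, cutoff in (
            ("all", None), ("lt_large", config.large_event_cutoff),
        ):
            try:
                res = st.compare_size_distributions(
                    [c.size for c in ont_final],
                    [c.size for c in bn_final],
                    large_event_cutoff=cutoff,
                )
                size_tests[label] = asdict(res)
            except ValueError as exc:
                size_tests[label] = {"error": str(exc)}
    with open(outdir / "size_tests.json", "w") as fh:
        json.dump(size_tests, fh, indent=2, sort_keys=True)

    chrom_lengths = _chrom_lengths(config, ont_final + bn_final)
    if chrom_lengths:
        _stage(
            "bin_tracks", st.bin_occurrences, ont_final, chrom_lengths,
            config.bin_width,
        ).to_bedgraph(outdir / "ont_occurrences.bedgraph")
        st.bin_occurrences(
            bn_final, chrom_lengths, config.bin_width
        ).to_bedgraph(outdir / "bionano_occurrences.bedgraph")
    if config.fasta:
        _, density = _stage(
            "label_density", st.insilico_label_density, config.fasta,
            config.motif, config.bin_width,
        )
        density.to_bedgraph(outdir / "label_density.bedgraph")

    # --- annotate ---------------------------------------------------------
    if config.gff:
        features = _stage("read_gff", fio.read_gff3_features, config.gff)
        flags = _stage("annotate", ann.classify_annotation, ont_final, features)
        class_by_call = {
            c.call_id: g.svid_code for g in groups for c in g.ont_members
        }
        table = ann.crosstab(flags, class_by_call)
        table.to_csv(outdir / "annotation_crosstab.tsv", sep="\t")
        ann.export_gene_lists(flags, class_by_call, outdir / "gene_lists")
        counts["ont_te_overlap"] = int(flags["overlaps_te"].sum())
        counts["ont_gene_overlap"] = int(flags["overlaps_gene"].sum())

    manifest = {
        "package_version": svconcord.__version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
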