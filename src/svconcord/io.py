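"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Internal coordinates are 1-based inclusive throughout (the native convention
of MUMmer ``show-diff``, GFF3 and VCF).  The only 0-based half-open format is
BED, converted at the boundary by :func:`write_bed` / :func:`read_bed`.

All readers accept plain or gzip-compressed input (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator

import pysam
from gffutils.iterators import DataIterator

if TYPE_CHECKING:  # pragma: no cover
    from svconcord.harmonize import SvCall

logger = logging.getLogger(__name__)

#: The six record types emitted by MUMmer's show-diff utility.
DIFF_TYPES = frozenset({"GAP", "DUP", "BRK", "JMP", "INV", "SEQ"})

#: Bionano SV-VCF type vocabulary (lower-cased SVTYPE values).
BIONANO_TYPES = frozenset(
    {"insertion", "deletion", "inversion", "translocation", "duplication"}
)


class ParseError(ValueError):
    """A malformed record in an input file; the message names the location."""


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# MUMmer show-diff
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffRecord:
    """One parsed show-diff line.

    ``GAP`` records describe a gap between two consistently ordered
    alignments and carry both a reference-side and a query-side gap length
    plus their difference.  ``BRK``/``JMP``/``SEQ`` mark alignment
    discontinuities (treated downstream as assembly discordance), ``INV`` an
    inverted alignment segment and ``DUP`` a duplicated query segment; these
    carry a single length column.  Coordinates are 1-based inclusive on the
    reference.
    """

    ref_seq: str
    feature_type: str
    ref_start: int
    ref_end: int
    ref_gap_len: int
    query_gap_len: int | None = None
    gap_diff: int | None = None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.feature_type not in DIFF_TYPES:
            raise ValueError(f"unknown show-diff feature type {self.feature_type!r}")
        if self.feature_type == "GAP" and self.query_gap_len is None:
            raise ValueError("GAP records carry both gap lengths")


_HEADER_PREFIXES = ("#", "/", "NUCMER", "PROMER", "[")


def _is_diff_header(fields: list[str], raw: str) -> bool:
    if not fields:
        return True
    if raw.lstrip().startswith(_HEADER_PREFIXES):
        return True
    # column-title row ("[SEQ] [TYPE] ...") or the file-path line
    if len(fields) >= 2 and fields[1].startswith("["):
        return True
    return len(fields) == 2 and not fields[1].lstrip("-").isdigit()


def read_show_diff(path: str | Path) -> list[DiffRecord]:
    """Parse a MUMmer ``show-diff`` DIFF file into :class:`DiffRecord` rows.

    Header lines (file paths, ``NUCMER``, bracketed column titles, blanks)
    are tolerated anywhere.  Data lines must carry the column layout of
    their feature type: GAP rows have reference gap, query gap and gap
    difference; the five other types a single length, with any trailing
    columns (e.g. SEQ neighbour sequence names) kept verbatim.

    Raises
    ------
    ParseError
        On an unknown feature type or a wrong column count, naming the
        offending line number.
    """
    records: list[DiffRecord] = []
    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            fields = raw.split()
            if _is_diff_header(fields, raw):
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}:{line_no}: unparseable line {raw!r}")
            ftype = fields[1]
            if ftype not in DIFF_TYPES:
                raise ParseError(
                    f"{path}:{line_no}: unknown feature type {ftype!r}"
                )
            try:
                if ftype == "GAP":
                    if len(fields) != 7:
                        raise ParseError(
                            f"{path}:{line_no}: GAP record needs 7 columns, "
                            f"got {len(fields)}"
                        )
                    records.append(
                        DiffRecord(
                            ref_seq=fields[0],
                            feature_type=ftype,
                            ref_start=int(fields[2]),
                            ref_end=int(fields[3]),
                            ref_gap_len=int(fields[4]),
                            query_gap_len=int(fields[5]),
                            gap_diff=int(fields[6]),
                        )
                    )
                else:
                    if len(fields) < 5:
                        raise ParseError(
                            f"{path}:{line_no}: {ftype} record needs at least "
                            f"5 columns, got {len(fields)}"
                        )
                    records.append(
                        DiffRecord(
                            ref_seq=fields[0],
                            feature_type=ftype,
                            ref_start=int(fields[2]),
                            ref_end=int(fields[3]),
                            ref_gap_len=int(fields[4]),
                            extra=tuple(fields[5:]),
                        )
                    )
            except ValueError as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(f"{path}:{line_no}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Bionano SV-VCF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BionanoVariant:
    """One Bionano Solve SV-VCF record.

    ``cipos``/``ciend`` are the signed breakpoint-uncertainty offsets around
    POS and END ((0, 0) when the record carries none).  ``quality`` is the
    manufacturer's 0--20 insertion/deletion quality score (``None`` when the
    record reports no score) and ``confidence`` the breakpoint-confidence
    value attached to inversion and translocation calls.
    """

    chrom: str
    pos: int
    end: int
    sv_type: str
    size: int
    cipos: tuple[int, int] = (0, 0)
    ciend: tuple[int, int] = (0, 0)
    quality: int | None = None
    confidence: float | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.sv_type not in BIONANO_TYPES:
            raise ValueError(f"unknown Bionano SV type {self.sv_type!r}")
        if not (self.cipos[0] <= 0 <= self.cipos[1]):
            raise ValueError(f"CIPOS {self.cipos} must bracket zero")
        if not (self.ciend[0] <= 0 <= self.ciend[1]):
            raise ValueError(f"CIEND {self.ciend} must bracket zero")


def read_bionano_vcf(
    path: str | Path,
    quality_key: str = "QUAL_SCORE",
    confidence_key: str = "CONFIDENCE",
    size_key: str = "SVSIZE",
) -> list[BionanoVariant]:
    """Parse a Bionano Solve "Convert SMAP to VCF" output file.

    The Bionano VCF dialect varies between Solve versions, so the fields
    carrying the insertion/deletion quality score and the breakpoint
    confidence are configurable: ``quality_key`` names an INFO key tried
    first, with the VCF QUAL column as fallback; ``confidence_key`` names
    the INFO key holding the inversion/translocation confidence.  The
    reported SV size is taken from ``size_key`` when present, then
    ``|SVLEN|``, then the POS..END span (note that when SVLEN is present
    htslib re-derives the record end from it, per VCF 4.4).  Absent
    CIPOS/CIEND are stored as ``(0, 0)``; an absent score as ``None``.

    Raises
    ------
    ParseError
        When a record lacks SVTYPE, carries an unknown SVTYPE, or is a
        deletion whose END precedes POS.
    """
    variants: list[BionanoVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            if "SVTYPE" not in info:
                raise ParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} has no SVTYPE"
                )
            sv_type = str(info["SVTYPE"]).lower()
            if sv_type not in BIONANO_TYPES:
                raise ParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} has unknown "
                    f"SVTYPE {sv_type!r}"
                )
            pos, end = rec.pos, rec.stop
            if sv_type == "deletion" and end < pos:
                raise ParseError(
                    f"{path}: deletion {rec.chrom}:{pos} has END {end} < POS"
                )
            cipos = tuple(int(x) for x in info.get("CIPOS", (0, 0)))
            ciend = tuple(int(x) for x in info.get("CIEND", (0, 0)))
            svlen = info.get(size_key, info.get("SVLEN"))
            if svlen is not None:
                if isinstance(svlen, tuple):
                    svlen = svlen[0]
                size = abs(int(svlen))
            else:
                size = end - pos + 1
            quality: int | None = None
            if quality_key in info:
                quality = int(info[quality_key])
            elif rec.qual is not None:
                quality = int(round(rec.qual))
            confidence = info.get(confidence_key)
            if confidence is not None:
                confidence = float(confidence)
            variants.append(
                BionanoVariant(
                    chrom=rec.chrom,
                    pos=pos,
                    end=end,
                    sv_type=sv_type,
                    size=size,
                    cipos=cipos,  # type: ignore[arg-type]
                    ciend=ciend,  # type: ignore[arg-type]
                    quality=quality,
                    confidence=confidence,
                    record_id=rec.id or "",
                )
            )
    return variants


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

#: Default GFF3 column-3 type -> category mapping (Araport11-style names).
DEFAULT_GENE_TYPES = frozenset({"gene"})
DEFAULT_TE_TYPES = frozenset(
    {"transposable_element", "transposable_element_gene", "transposon_fragment"}
)


@dataclass(frozen=True)
class AnnotationFeature:
    """A gene or transposable-element feature, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    category: str  # GENE or TE
    feature_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.feature_id}: start > end")


def read_gff3_features(
    path: str | Path,
    gene_types: frozenset[str] | set[str] = DEFAULT_GENE_TYPES,
    te_types: frozenset[str] | set[str] = DEFAULT_TE_TYPES,
) -> list[AnnotationFeature]:
    """Extract gene and TE features from a GFF3 file.

    Only features whose column-3 type is in ``gene_types`` (mapped to
    category GENE) or ``te_types`` (mapped to TE) are returned; everything
    else is dropped.  Malformed coordinate fields are warned about and
    skipped, never fatal.
    """
    overlap = set(gene_types) & set(te_types)
    if overlap:
        raise ValueError(f"types mapped to both GENE and TE: {sorted(overlap)}")
    features: list[AnnotationFeature] = []
    for feat in DataIterator(str(path)):
        if feat.featuretype in gene_types:
            category = "GENE"
        elif feat.featuretype in te_types:
            category = "TE"
        else:
            continue
        try:
            start, end = int(feat.start), int(feat.end)
        except (TypeError, ValueError):
            logger.warning(
                "skipping %s feature with bad coordinates: %s", category, feat
            )
            continue
        fid = (feat.attributes.get("ID") or feat.attributes.get("Name") or [""])[0]
        if not fid:
            fid = f"{feat.seqid}:{start}-{end}"
        features.append(
            AnnotationFeature(
                chrom=feat.seqid, start=start, end=end,
                category=category, feature_id=fid,
            )
        )
    return features


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(calls: "list[SvCall]", path: str | Path) -> None:
    """Write calls as BED6 (0-based half-open).

    The name column encodes ``call_id|source|sv_type|size`` so that
    :func:`read_bed` can reconstruct the call; the score column carries the
    quality score (``.`` when absent).
    """
    with open(path, "w") as fh:
        for call in calls:
            if call.ref_end < call.ref_start:
                raise ValueError(
                    f"{call.call_id}: end {call.ref_end} < start {call.ref_start}"
                )
            name = f"{call.call_id}|{call.source}|{call.sv_type}|{call.size}"
            score = "." if call.quality is None else str(call.quality)
            fh.write(
                f"{call.chrom}\t{call.ref_start - 1}\t{call.ref_end}"
                f"\t{name}\t{score}\t.\n"
            )


def read_bed(path: str | Path) -> "list[SvCall]":
    """Read calls written by :func:`write_bed` back to 1-based inclusive."""
    from svconcord.harmonize import SvCall

    calls: list[SvCall] = []
    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            fields = raw.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{line_no}: expected BED6 with name column")
            chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
            parts = fields[3].split("|")
            if len(parts) != 4:
                raise ParseError(
                    f"{path}:{line_no}: name column not call_id|source|type|size"
                )
            call_id, source, sv_type, size = parts
            quality = None
            if len(fields) > 4 and fields[4].strip() not in (".", ""):
                quality = int(fields[4])
            calls.append(
                SvCall(
                    call_id=call_id, source=source, chrom=chrom,
                    ref_start=start0 + 1, ref_end=end,
                    ext_start=start0 + 1, ext_end=end,
                    sv_type=sv_type, size=int(size), quality=quality,
                )
            )
    return calls


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a plain BED file (e.g. an exclusion list) to 1-based inclusive
    ``(chrom, start, end)`` tuples."""
    intervals: list[tuple[str, int, int]] = []
    with _open_text(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            fields = raw.split()
            intervals.append((fields[0], int(fields[1]) + 1, int(fields[2])))
    return intervals


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into an ordered name -> sequence map."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
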