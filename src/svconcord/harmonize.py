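"""Harmonization of raw callsets into unified SV calls, and filtering.

Both technologies are reduced to one :class:`SvCall` representation.  For
the assembly-based (ONT) side, show-diff GAP records become insertions or
deletions by comparing the query-side and reference-side gap lengths, while
SEQ/BRK/JMP records are discarded as assembly discordance.  For the
optical-map (Bionano) side, the breakpoint-uncertainty intervals CIPOS/CIEND
are folded into a "most extended" interval so that label fuzz does not break
downstream overlap detection.

Every filtering operation returns a :class:`FilterReport` that conserves
records: each input ends up either retained or removed with exactly one
primary reason code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from svconcord.io import BionanoVariant, DiffRecord

logger = logging.getLogger(__name__)

ONT = "ONT"
BIONANO = "BIONANO"

#: Unified SV type vocabulary.
SV_TYPES = ("INS", "DEL", "INV", "TRA", "DUP")

#: Bionano VCF SVTYPE -> unified type.
_BIONANO_TYPE_MAP = {
    "insertion": "INS",
    "deletion": "DEL",
    "inversion": "INV",
    "translocation": "TRA",
    "duplication": "DUP",
}

# Removal reason codes.
ASSEMBLY_DISCORDANCE = "ASSEMBLY_DISCORDANCE"
SIZE_LE_MIN = "SIZE_LE_MIN"
LOW_QUALITY = "LOW_QUALITY"
LOW_CONFIDENCE = "LOW_CONFIDENCE"
NO_CONFIDENCE = "NO_CONFIDENCE"
EMBEDDED = "EMBEDDED"
EXCLUDED_REGION = "EXCLUDED_REGION"


@dataclass(frozen=True)
class SvCall:
    """A unified, technology-tagged structural-variant call.

    ``ref_start``/``ref_end`` is the reference footprint (1-based
    inclusive); ``ext_start``/``ext_end`` the extended interval including
    breakpoint uncertainty (equal to the reference interval for assembly
    calls).  ``size`` is the SV length in bp: query-based for
    assembly-derived insertions, reference-based otherwise.
    """

    call_id: str
    source: str
    chrom: str
    ref_start: int
    ref_end: int
    ext_start: int
    ext_end: int
    sv_type: str
    size: int
    quality: int | None = None
    confidence: float | None = None
    provenance: object | None = None

    def __post_init__(self) -> None:
        if self.source not in (ONT, BIONANO):
            raise ValueError(f"unknown source {self.source!r}")
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if not (self.ext_start <= self.ref_start and self.ref_end <= self.ext_end):
            raise ValueError(
                f"{self.call_id}: extended interval must contain the "
                f"reference interval"
            )
        if self.size < 1:
            raise ValueError(f"{self.call_id}: size must be >= 1")
        if self.source == ONT and self.sv_type == "TRA":
            raise ValueError("assembly-based calls cannot be translocations")

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start + 1

    @property
    def ext_len(self) -> int:
        return self.ext_end - self.ext_start + 1


@dataclass
class FilterReport:
    """Retained calls plus removed records, each with one primary reason."""

    retained: list[SvCall] = field(default_factory=list)
    removed: list[tuple[object, str]] = field(default_factory=list)

    @property
    def input_count(self) -> int:
        return len(self.retained) + len(self.removed)

    def removal_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in self.removed:
            counts[reason] = counts.get(reason, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# ONT (assembly) side
# ---------------------------------------------------------------------------

def harmonize_ont(records: Sequence[DiffRecord]) -> FilterReport:
    """Convert show-diff records to unified calls.

    SEQ, BRK and JMP records mark reference-sequence junctions, breaks and
    jumps between alignments; they concentrate in centromeric/telomeric and
    rDNA-cluster regions and are removed as ``ASSEMBLY_DISCORDANCE``.  INV
    and DUP become calls sized by their reference span.  A GAP becomes an
    insertion when its query-side gap exceeds its reference-side gap
    (size = query gap) and a deletion otherwise (size = reference gap; a
    tie counts as deletion).  A GAP with both gap lengths <= 0 is a
    degenerate alignment artifact, removed as ``ASSEMBLY_DISCORDANCE``.
    """
    report = FilterReport()
    for idx, rec in enumerate(records):
        call_id = f"ONT_{idx + 1:05d}"
        lo, hi = sorted((rec.ref_start, rec.ref_end))
        if rec.feature_type in ("SEQ", "BRK", "JMP"):
            report.removed.append((rec, ASSEMBLY_DISCORDANCE))
            continue
        if rec.feature_type in ("INV", "DUP"):
            size = hi - lo + 1
            report.retained.append(
                SvCall(
                    call_id=call_id, source=ONT, chrom=rec.ref_seq,
                    ref_start=lo, ref_end=hi, ext_start=lo, ext_end=hi,
                    sv_type=rec.feature_type, size=size, provenance=rec,
                )
            )
            continue
        # GAP
        ref_gap = rec.ref_gap_len
        query_gap = rec.query_gap_len if rec.query_gap_len is not None else 0
        if ref_gap <= 0 and query_gap <= 0:
            report.removed.append((rec, ASSEMBLY_DISCORDANCE))
            continue
        if query_gap > ref_gap:
            sv_type, size = "INS", query_gap
        else:
            sv_type, size = "DEL", ref_gap
            if query_gap == ref_gap:
                logger.debug("GAP tie at %s:%d treated as DEL", rec.ref_seq, lo)
        report.retained.append(
            SvCall(
                call_id=call_id, source=ONT, chrom=rec.ref_seq,
                ref_start=lo, ref_end=hi, ext_start=lo, ext_end=hi,
                sv_type=sv_type, size=size, provenance=rec,
            )
        )
    return report


def _overlaps_any(
    call: SvCall, exclusions: Sequence[tuple[str, int, int]]
) -> bool:
    for chrom, start, end in exclusions:
        if call.chrom == chrom and call.ref_start <= end and start <= call.ref_end:
            return True
    return False


def filter_ont(
    calls: Sequence[SvCall],
    min_size: int = 1000,
    exclusions: Sequence[tuple[str, int, int]] = (),
) -> FilterReport:
    """Apply the assembly-side size filter (strictly ``size > min_size``)
    and an optional exclusion list of known artifact regions.

    The size filter compensates for long-read sequencing error (false small
    indels) and matches the detection floor of the optical-map technology.
    Exclusion intervals are 1-based inclusive ``(chrom, start, end)``.
    """
    if min_size < 0:
        raise ValueError("min_size must be non-negative")
    report = FilterReport()
    for call in calls:
        if call.size <= min_size:
            report.removed.append((call, SIZE_LE_MIN))
        elif _overlaps_any(call, exclusions):
            report.removed.append((call, EXCLUDED_REGION))
        else:
            report.retained.append(call)
    return report


# ---------------------------------------------------------------------------
# Bionano (optical map) side
# ---------------------------------------------------------------------------

def harmonize_bionano(records: Sequence[BionanoVariant]) -> list[SvCall]:
    """Convert SV-VCF records to unified calls with extended intervals.

    The extended interval folds the breakpoint uncertainty in:
    ``ext_start = pos + cipos_low`` and ``ext_end = end + ciend_high``.
    An extended start below 1 is clipped to 1 with a warning.
    """
    calls: list[SvCall] = []
    for idx, rec in enumerate(records):
        ext_start = rec.pos + rec.cipos[0]
        ext_end = rec.end + rec.ciend[1]
        if ext_start < 1:
            logger.warning(
                "clipping extended start %d to 1 for %s:%d",
                ext_start, rec.chrom, rec.pos,
            )
            ext_start = 1
        calls.append(
            SvCall(
                call_id=rec.record_id or f"BN_{idx + 1:05d}",
                source=BIONANO, chrom=rec.chrom,
                ref_start=rec.pos, ref_end=max(rec.end, rec.pos),
                ext_start=ext_start, ext_end=max(ext_end, rec.end, rec.pos),
                sv_type=_BIONANO_TYPE_MAP[rec.sv_type],
                size=rec.size, quality=rec.quality,
                confidence=rec.confidence, provenance=rec,
            )
        )
    return calls


def filter_bionano(
    calls: Sequence[SvCall],
    min_size: int = 1000,
    min_quality: int = 10,
    tra_cutoff: float = 0.1,
    inv_cutoff: float = 0.01,
) -> FilterReport:
    """Apply the optical-map quality filters.

    Insertions, deletions and duplications are kept when strictly larger
    than ``min_size`` and not scored below ``min_quality`` (an absent score
    does not remove an INS/DEL — only sub-threshold scores do).
    Translocations and inversions are instead gated on their breakpoint
    confidence, at the manufacturer-recommended cutoffs of 0.1 and 0.01
    respectively; an inversion (or translocation) with no confidence value
    is removed as ``NO_CONFIDENCE``.
    """
    if min_size < 0:
        raise ValueError("min_size must be non-negative")
    report = FilterReport()
    for call in calls:
        if call.sv_type in ("INS", "DEL", "DUP"):
            if call.size <= min_size:
                report.removed.append((call, SIZE_LE_MIN))
            elif call.quality is not None and call.quality < min_quality:
                report.removed.append((call, LOW_QUALITY))
            else:
                report.retained.append(call)
        elif call.sv_type == "TRA":
            if call.confidence is None:
                report.removed.append((call, NO_CONFIDENCE))
            elif call.confidence < tra_cutoff:
                report.removed.append((call, LOW_CONFIDENCE))
            else:
                report.retained.append(call)
        else:  # INV
            if call.confidence is None:
                report.removed.append((call, NO_CONFIDENCE))
            elif call.confidence < inv_cutoff:
                report.removed.append((call, LOW_CONFIDENCE))
            else:
                report.retained.append(call)
    return report


# ---------------------------------------------------------------------------
# Call-table serialization (TSV interchange between pipeline stages)
# ---------------------------------------------------------------------------

def calls_to_frame(calls: Iterable[SvCall]):
    """Calls as a DataFrame (one row per call, full field set)."""
    import pandas as pd

    columns = [
        "call_id", "source", "chrom", "ref_start", "ref_end",
        "ext_start", "ext_end", "sv_type", "size", "quality", "confidence",
    ]
    return pd.DataFrame(
        [{col: getattr(c, col) for col in columns} for c in calls],
        columns=columns,
    )


def frame_to_calls(frame) -> list[SvCall]:
    """Inverse of :func:`calls_to_frame` (NaN quality/confidence -> absent)."""
    import pandas as pd

    calls = []
    for row in frame.itertuples(index=False):
        calls.append(
            SvCall(
                call_id=str(row.call_id), source=str(row.source),
                chrom=str(row.chrom),
                ref_start=int(row.ref_start), ref_end=int(row.ref_end),
                ext_start=int(row.ext_start), ext_end=int(row.ext_end),
                sv_type=str(row.sv_type), size=int(row.size),
                quality=None if pd.isna(row.quality) else int(row.quality),
                confidence=(
                    None if pd.isna(row.confidence) else float(row.confidence)
                ),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Embedded-call resolution
# ---------------------------------------------------------------------------

def resolve_embedded(calls: Sequence[SvCall]) -> FilterReport:
    """Remove calls whose reference interval lies inside another call's.

    When the caller reports one SV embedded in a second one, only the
    largest is kept.  Containment is applied transitively (of a nested
    chain only the outermost survives); two calls with identical intervals
    keep the one first in ``call_id`` order.  Intended for one technology's
    calls at a time.
    """
    order = sorted(
        range(len(calls)),
        key=lambda i: (
            calls[i].chrom,
            calls[i].ref_start,
            -calls[i].ref_end,
            calls[i].call_id,
        ),
    )
    report = FilterReport()
    max_end: int = 0
    cur_chrom: str | None = None
    contained: set[int] = set()
    for i in order:
        call = calls[i]
        if call.chrom != cur_chrom:
            cur_chrom, max_end = call.chrom, 0
        # sort guarantees an earlier call on this chrom has start <= ours;
        # containment then reduces to its end covering ours
        if call.ref_end <= max_end:
            contained.add(i)
        max_end = max(max_end, call.ref_end)
    for i, call in enumerate(calls):
        if i in contained:
            report.removed.append((call, EMBEDDED))
        else:
            report.retained.append(call)
    return report
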