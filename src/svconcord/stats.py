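"""Summary tables, size-distribution tests and genome-bin tracks.

Table conventions follow the comparison-report layout: counts with percents
to one decimal, cumulated sizes in Mb to one decimal, median and average
sizes in bp (median of an even-sized sample is the midpoint of the central
pair; averages are rounded to the nearest integer).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from svconcord.concordance import LocationGroup
from svconcord.harmonize import SvCall

_TYPE_ORDER = ("INS", "DEL", "INV", "TRA", "DUP")


def _size_stats(sizes: Sequence[int]) -> dict[str, float]:
    if len(sizes) == 0:
        return {
            "count": 0, "cumulated_mb": 0.0,
            "min_bp": np.nan, "max_bp": np.nan,
            "median_bp": np.nan, "average_bp": np.nan,
        }
    arr = np.asarray(sizes, dtype=float)
    return {
        "count": int(arr.size),
        "cumulated_mb": round(float(arr.sum()) / 1e6, 1),
        "min_bp": float(arr.min()),
        "max_bp": float(arr.max()),
        "median_bp": float(np.median(arr)),
        "average_bp": float(np.round(arr.mean())),
    }


def summarize_by_type(calls: Sequence[SvCall]) -> pd.DataFrame:
    """Per-SV-type summary (count, percent, cumulated/median/average size)
    with a TOTAL row, for one technology's filtered calls."""
    total = len(calls)
    rows = {}
    present = [t for t in _TYPE_ORDER if any(c.sv_type == t for c in calls)]
    for sv_type in present + ["TOTAL"]:
        sizes = [
            c.size for c in calls if sv_type == "TOTAL" or c.sv_type == sv_type
        ]
        st = _size_stats(sizes)
        st["percent"] = round(100.0 * st["count"] / total, 1) if total else np.nan
        rows[sv_type] = st
    df = pd.DataFrame.from_dict(rows, orient="index")
    if not rows:
        df = pd.DataFrame(
            {"count": [0]}, index=["TOTAL"]
        ).reindex(
            columns=["count", "percent", "cumulated_mb", "min_bp", "max_bp",
                     "median_bp", "average_bp"]
        )
    return df[
        ["count", "percent", "cumulated_mb", "min_bp", "max_bp",
         "median_bp", "average_bp"]
    ]


def summarize_by_class(
    groups: Sequence[LocationGroup],
    n_ont_total: int | None = None,
    n_bionano_total: int | None = None,
) -> pd.DataFrame:
    """Common/specific summary per technology, plus the MU detail rows.

    Rows: ONT_common, ONT_specific, BIONANO_common, BIONANO_specific and,
    for the many-to-one locations specifically, MU_ONT / MU_BIONANO.
    Percentages are of each technology's total filtered calls.
    """
    ont_common = [c for g in groups if g.is_common for c in g.ont_members]
    ont_spec = [c for g in groups if not g.is_common for c in g.ont_members]
    bn_common = [c for g in groups if g.is_common for c in g.bionano_members]
    bn_spec = [c for g in groups if not g.is_common for c in g.bionano_members]
    mu = [g for g in groups if g.svid_code == "MU"]
    mu_ont = [c for g in mu for c in g.ont_members]
    mu_bn = [c for g in mu for c in g.bionano_members]
    n_ont = n_ont_total if n_ont_total is not None else len(ont_common) + len(ont_spec)
    n_bn = (
        n_bionano_total if n_bionano_total is not None
        else len(bn_common) + len(bn_spec)
    )

    common_locs = sum(1 for g in groups if g.is_common)
    spec_ont_locs = sum(
        1 for g in groups if not g.is_common and g.ont_members
    )
    spec_bn_locs = sum(
        1 for g in groups if not g.is_common and g.bionano_members
    )
    spec = [
        ("ONT_common", ont_common, common_locs, n_ont),
        ("ONT_specific", ont_spec, spec_ont_locs, n_ont),
        ("BIONANO_common", bn_common, common_locs, n_bn),
        ("BIONANO_specific", bn_spec, spec_bn_locs, n_bn),
        ("MU_ONT", mu_ont, len(mu), n_ont),
        ("MU_BIONANO", mu_bn, len(mu), n_bn),
    ]
    rows = {}
    for name, calls, locs, denom in spec:
        st = _size_stats([c.size for c in calls])
        st["locations"] = locs
        st["percent"] = round(100.0 * st["count"] / denom, 1) if denom else np.nan
        rows[name] = st
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df[
        ["locations", "count", "percent", "min_bp", "max_bp",
         "cumulated_mb", "median_bp", "average_bp"]
    ]


# ---------------------------------------------------------------------------
# Size-distribution comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SizeTestResult:
    """One-sided Wilcoxon rank-sum outcome for ONT-vs-Bionano sizes."""

    statistic: float
    p_value: float
    median_ont: float
    median_bionano: float
    n_ont: int
    n_bionano: int
    method: str  # "exact" or "asymptotic"


def compare_size_distributions(
    ont_sizes: Sequence[int],
    bionano_sizes: Sequence[int],
    large_event_cutoff: int | None = None,
) -> SizeTestResult:
    """Test whether assembly-call sizes are stochastically smaller than
    optical-map call sizes (one-sided Wilcoxon rank-sum, alternative
    "less").

    With ``large_event_cutoff`` set, sizes >= the cutoff are excluded from
    both samples before testing, so the comparison can be run with and
    without the extreme events.  The exact null distribution is used for
    combined n <= 20 without ties; otherwise the normal approximation with
    continuity correction.
    """
    x = [s for s in ont_sizes if large_event_cutoff is None or s < large_event_cutoff]
    y = [
        s for s in bionano_sizes
        if large_event_cutoff is None or s < large_event_cutoff
    ]
    if not x or not y:
        raise ValueError("empty size sample (after large-event exclusion)")
    pooled = list(x) + list(y)
    no_ties = len(set(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="less", method=method)
    return SizeTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_ont=float(np.median(x)),
        median_bionano=float(np.median(y)),
        n_ont=len(x),
        n_bionano=len(y),
        method=method,
    )


# ---------------------------------------------------------------------------
# Genome-bin tracks
# ---------------------------------------------------------------------------

@dataclass
class BinTrack:
    """Fixed-width genome bins with one value per bin.

    Bin ``i`` of a chromosome nominally covers positions
    ``[i*bin_width, (i+1)*bin_width)`` (a 1-based position ``p`` falls in
    bin ``p // bin_width``).
    """

    bin_width: int
    values: dict[str, np.ndarray]

    def to_bedgraph(self, path: str | Path) -> None:
        """Write a ``chrom start end value`` (0-based half-open) track."""
        with open(path, "w") as fh:
            for chrom in self.values:
                vals = self.values[chrom]
                for i, v in enumerate(vals):
                    fh.write(
                        f"{chrom}\t{i * self.bin_width}"
                        f"\t{(i + 1) * self.bin_width}\t{v:g}\n"
                    )


def _n_bins(length: int, width: int) -> int:
    return length // width + 1


def bin_occurrences(
    calls: Sequence[SvCall],
    chrom_lengths: Mapping[str, int],
    bin_width: int = 100_000,
) -> BinTrack:
    """Count, per genome bin, how many calls' reference intervals touch it.

    A call spanning several bins increments each of them, so per-bin counts
    can sum to more than the number of calls.
    """
    values = {
        chrom: np.zeros(_n_bins(length, bin_width), dtype=float)
        for chrom, length in chrom_lengths.items()
    }
    for call in calls:
        if call.chrom not in values:
            raise ValueError(f"{call.call_id}: unknown chromosome {call.chrom}")
        if call.ref_end > chrom_lengths[call.chrom]:
            raise ValueError(
                f"{call.call_id}: end {call.ref_end} beyond chromosome length"
            )
        first = call.ref_start // bin_width
        last = call.ref_end // bin_width
        values[call.chrom][first : last + 1] += 1
    return BinTrack(bin_width=bin_width, values=values)


def insilico_label_density(
    fasta: str | Path | Mapping[str, str],
    motif: str = "CTTAAG",
    bin_width: int = 100_000,
) -> tuple[dict[str, np.ndarray], BinTrack]:
    """In-silico labelling: motif match positions and per-bin label density.

    Emulates direct-label enzyme (DLE-1, recognition site CTTAAG) labelling
    of a reference sequence.  Matches are found on the forward strand only
    (CTTAAG is its own reverse complement) with overlapping matches
    counted; positions are the 1-based starts of each match.  Degenerate
    IUPAC motif characters are rejected.
    """
    if not motif or any(ch not in "ACGT" for ch in motif.upper()):
        raise ValueError(f"motif {motif!r} must be non-degenerate A/C/G/T")
    if isinstance(fasta, (str, Path)):
        from svconcord.io import read_fasta

        sequences = read_fasta(fasta)
    else:
        sequences = dict(fasta)
    pattern = re.compile(f"(?={re.escape(motif.upper())})")
    labels: dict[str, np.ndarray] = {}
    density: dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        positions = np.array(
            [m.start() + 1 for m in pattern.finditer(seq.upper())], dtype=int
        )
        labels[chrom] = positions
        track = np.zeros(_n_bins(len(seq), bin_width), dtype=float)
        if positions.size:
            np.add.at(track, positions // bin_width, 1)
        density[chrom] = track
    return labels, BinTrack(bin_width=bin_width, values=density)
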