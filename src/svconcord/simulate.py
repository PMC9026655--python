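"""Synthetic paired-callset generator with planted ground truth.

One planted truth set of structural variants is emitted twice, through two
noise models that mimic how each technology actually reports SVs:

* the **assembly-like (ONT) emitter** writes MUMmer show-diff GAP/INV
  records, sees events down to tens of bp, under-reports sizes slightly
  (alignment trimming), and fragments large events into several adjacent
  sub-calls — the behaviour that produces many-to-one (MU) locations;
* the **optical-map-like (Bionano) emitter** writes a single coarse SV-VCF
  record per event, cannot see events below ~1 kb, pads its breakpoints
  with CIPOS/CIEND uncertainty, inflates reported sizes (label-interval
  coarsening), and misses events in simulated low-label-density
  (centromere-like) regions.  Translocations are reported only here.

Because every planted event is spaced further apart than any pad or
fragment can reach, the svID classification of the emitted callsets is
exactly predictable from the two emission plans
(:func:`expected_classification`), which is what end-to-end recovery tests
assert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

_DEFAULT_CHROMS = {f"chr{i}": 30_000_000 for i in range(1, 6)}

#: Truth-set type mix: balanced INS/DEL with rare INV and rarer TRA.
_DEFAULT_TYPE_WEIGHTS = {"INS": 0.49, "DEL": 0.49, "INV": 0.015, "TRA": 0.005}


@dataclass
class SimConfig:
    """Truth-set generation parameters.

    Sizes are drawn log-normally (median ``size_median`` bp, log-sd
    ``size_sigma``), reproducing the heavy right tail of real SV size
    spectra (medians of a few kb, maxima of hundreds of kb).  Inversions
    and translocations are drawn ``inv_tra_median_factor`` times larger,
    as balanced rearrangements are typically detected at much larger
    scales.  Planted events keep at least ``min_spacing`` bp between them
    so that emitted noisy calls can never bridge two events.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_CHROMS)
    )
    n_sv: int = 600
    type_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TYPE_WEIGHTS)
    )
    counts: dict[str, int] | None = None  # explicit per-type counts override
    size_median: float = 3500.0
    size_sigma: float = 1.2
    size_min: int = 50
    size_max: int = 400_000
    inv_tra_median_factor: float = 10.0
    min_spacing: int = 10_000
    ins_footprint_max: int = 20

    def type_counts(self) -> dict[str, int]:
        if self.counts is not None:
            return {t: int(n) for t, n in self.counts.items() if n}
        total_w = sum(self.type_weights.values())
        counts = {
            t: int(round(self.n_sv * w / total_w))
            for t, w in self.type_weights.items()
        }
        # keep the configured total after rounding
        drift = self.n_sv - sum(counts.values())
        if drift and counts:
            top = max(counts, key=lambda t: counts[t])
            counts[top] += drift
        return {t: n for t, n in counts.items() if n > 0}


@dataclass
class TruthSet:
    """Planted SVs (1-based inclusive reference intervals) plus provenance.

    ``svs`` columns: sv_id, chrom, start, end, type, size.  For insertions
    the interval is the small reference footprint the event leaves and
    ``size`` the inserted length; otherwise size equals the span.
    """

    chrom_lengths: dict[str, int]
    svs: pd.DataFrame
    seed: int
    config: SimConfig


def simulate_truth(config: SimConfig | None = None, seed: int = 0) -> TruthSet:
    """Plant a reproducible, non-overlapping truth set of SVs.

    Raises
    ------
    ValueError
        When the requested events cannot be packed into the genome at the
        configured spacing.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    if len(chroms) == 0 or (lengths <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    weights = lengths / lengths.sum()

    events: list[tuple[str, str, int]] = []  # (sv_id, type, size)
    counter = 0
    for sv_type, n in sorted(config.type_counts().items()):
        median = config.size_median * (
            config.inv_tra_median_factor if sv_type in ("INV", "TRA") else 1.0
        )
        for _ in range(n):
            counter += 1
            size = 0
            while not (config.size_min <= size <= config.size_max):
                size = int(round(rng.lognormal(math.log(median), config.size_sigma)))
            events.append((f"SV_{counter:05d}", sv_type, size))
    # place large events first: easier packing, same result distribution
    rng.shuffle(events)  # type: ignore[arg-type]

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for sv_id, sv_type, size in events:
        span = (
            int(rng.integers(1, config.ins_footprint_max + 1))
            if sv_type == "INS"
            else size
        )
        placed = False
        for _ in range(2000):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            chrom_len = config.chrom_lengths[chrom]
            if chrom_len - span - 2 < 1:
                continue
            start = int(rng.integers(1, chrom_len - span - 1))
            end = start + span - 1
            pad = config.min_spacing
            if all(
                end + pad < s or e + pad < start for s, e in occupied[chrom]
            ):
                occupied[chrom].append((start, end))
                rows.append(
                    {
                        "sv_id": sv_id, "chrom": chrom, "start": start,
                        "end": end, "type": sv_type, "size": size,
                    }
                )
                placed = True
                break
        if not placed:
            raise ValueError(
                "infeasible packing: cannot place all events at the "
                "configured spacing; reduce n_sv or sizes"
            )
    svs = pd.DataFrame(
        rows, columns=["sv_id", "chrom", "start", "end", "type", "size"]
    ).sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)
    return TruthSet(
        chrom_lengths=dict(config.chrom_lengths), svs=svs, seed=seed,
        config=config,
    )


# ---------------------------------------------------------------------------
# Assembly-like (show-diff) emission
# ---------------------------------------------------------------------------

def _fragment_bounds(
    start: int, end: int, k: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Split [start, end] into k adjacent sub-intervals (1 bp apart),
    each at least ~a quarter of an even share long."""
    span = end - start + 1
    base = span // k
    cuts = [start]
    for i in range(1, k):
        jitter = int(rng.integers(-base // 4, base // 4 + 1)) if base >= 8 else 0
        cuts.append(start + i * base + jitter)
    cuts.append(end + 1)
    return [(cuts[i], cuts[i + 1] - 2 if i < k - 1 else end) for i in range(k)]


def emit_ont_callset(
    truth: TruthSet,
    path: str | Path,
    frag_prob: float = 0.7,
    frag_min_span: int = 10_000,
    k_range: tuple[int, int] = (2, 4),
    fn_rate: float = 0.05,
    size_jitter: float = 0.12,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write an assembly-like show-diff file; return the emission plan.

    Deletions and inversions spanning at least ``frag_min_span`` fragment
    with probability ``frag_prob`` into ``k`` (uniform in ``k_range``)
    adjacent sub-records inside the parent interval.  Reported gap sizes
    shrink by up to ``size_jitter`` (multiplicative), never grow.
    Translocations are invisible to this emitter.  The plan has one row
    per planted SV: emitted flag, fragment count ``k`` and emitted type.
    """
    rng = np.random.default_rng(
        [truth.seed if seed is None else seed, 1]
    )
    lines: list[tuple[str, int, str]] = []
    plan_rows = []
    for row in truth.svs.itertuples(index=False):
        emitted, k, etype = True, 0, ""
        if row.type == "TRA" or rng.random() < fn_rate:
            emitted = False
        else:
            shrink = 1.0 - rng.uniform(0.0, size_jitter)
            span = row.end - row.start + 1
            if row.type == "INS":
                k, etype = 1, "INS"
                query_gap = max(span + 1, int(round(row.size * shrink)))
                line = (
                    f"{row.chrom}\tGAP\t{row.start}\t{row.end}\t{span}"
                    f"\t{query_gap}\t{span - query_gap}"
                )
                lines.append((row.chrom, row.start, line))
            else:  # DEL or INV
                fragment = (
                    span >= frag_min_span and rng.random() < frag_prob
                )
                k = int(rng.integers(k_range[0], k_range[1] + 1)) if fragment else 1
                etype = row.type
                if k == 1:
                    new_span = max(1, int(round(span * shrink)))
                    end = row.start + new_span - 1
                    if row.type == "DEL":
                        query_gap = int(rng.integers(0, min(50, new_span)))
                        lines.append(
                            (
                                row.chrom, row.start,
                                f"{row.chrom}\tGAP\t{row.start}\t{end}"
                                f"\t{new_span}\t{query_gap}"
                                f"\t{new_span - query_gap}",
                            )
                        )
                    else:
                        lines.append(
                            (
                                row.chrom, row.start,
                                f"{row.chrom}\tINV\t{row.start}\t{end}"
                                f"\t{new_span}",
                            )
                        )
                else:
                    for f_start, f_end in _fragment_bounds(
                        row.start, row.end, k, rng
                    ):
                        f_span = f_end - f_start + 1
                        if row.type == "DEL":
                            query_gap = int(rng.integers(0, min(50, f_span)))
                            lines.append(
                                (
                                    row.chrom, f_start,
                                    f"{row.chrom}\tGAP\t{f_start}\t{f_end}"
                                    f"\t{f_span}\t{query_gap}"
                                    f"\t{f_span - query_gap}",
                                )
                            )
                        else:
                            lines.append(
                                (
                                    row.chrom, f_start,
                                    f"{row.chrom}\tINV\t{f_start}\t{f_end}"
                                    f"\t{f_span}",
                                )
                            )
        plan_rows.append(
            {
                "sv_id": row.sv_id, "emitted": emitted, "k": k,
                "emitted_type": etype,
            }
        )
    lines.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        fh.write("reference.fasta\tassembly.fasta\nNUCMER\n\n")
        fh.write("[SEQ]\t[TYPE]\t[S1]\t[E1]\t[LEN 1]\t[LEN 2]\t[GAP DIFF]\n")
        for _, _, line in lines:
            fh.write(line + "\n")
    return pd.DataFrame(
        plan_rows, columns=["sv_id", "emitted", "k", "emitted_type"]
    )


# ---------------------------------------------------------------------------
# Optical-map-like (SV-VCF) emission
# ---------------------------------------------------------------------------

def _default_quality(rng: np.random.Generator, sv_type: str, size: int) -> int | None:
    # reported score tracks size, mirroring the manufacturer's 0-20 scale
    if rng.random() < 0.03:
        return None
    if size > 1000:
        return int(rng.integers(10, 21))
    return int(rng.integers(0, 10))


def _default_confidence(
    rng: np.random.Generator, sv_type: str, size: int
) -> float | None:
    if rng.random() < 0.05:
        return None
    return float(np.round(rng.uniform(0.05, 1.0), 3))


def _simulate_density(
    chrom_lengths: Mapping[str, int],
    rng: np.random.Generator,
    bin_width: int,
    mean_density: float = 18.5,
) -> dict[str, np.ndarray]:
    """Per-bin label-density track with a centromere-like central dip."""
    tracks = {}
    for chrom, length in chrom_lengths.items():
        n = length // bin_width + 1
        x = np.arange(n, dtype=float)
        dip = 1.0 - 0.85 * np.exp(-(((x - n / 2) / (0.08 * n)) ** 2))
        noise = rng.lognormal(0.0, 0.25, size=n)
        tracks[chrom] = mean_density * dip * noise
    return tracks


def emit_bionano_callset(
    truth: TruthSet,
    path: str | Path,
    min_size: int = 1000,
    pad_range: tuple[int, int] = (50, 500),
    miss_in_low_density: float = 0.8,
    base_fn_rate: float = 0.02,
    size_inflation: float = 0.4,
    type_confusion: float = 0.01,
    quality_model: Callable[..., int | None] | None = None,
    confidence_model: Callable[..., float | None] | None = None,
    low_density_threshold: float = 9.0,
    bin_width: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write an optical-map-like SV-VCF; return the emission plan.

    Events below ``min_size`` are never emitted (the technology's detection
    floor).  Each emitted event gets one coarse record with CIPOS/CIEND
    pads drawn from ``pad_range`` and a reported size inflated by up to
    ``size_inflation`` (label-interval coarsening).  Events whose midpoint
    falls in a simulated low-label-density bin are missed with probability
    ``miss_in_low_density`` (otherwise ``base_fn_rate``); insertions and
    deletions rarely swap reported type (``type_confusion``).  Quality and
    confidence values come from the pluggable models (defaults mirror the
    size-tracking 0-20 score and a mostly confident breakpoint p-value).
    """
    rng = np.random.default_rng([truth.seed if seed is None else seed, 2])
    quality_model = quality_model or _default_quality
    confidence_model = confidence_model or _default_confidence
    density = _simulate_density(truth.chrom_lengths, rng, bin_width)
    pad_lo, pad_hi = pad_range

    records: list[tuple[str, int, str]] = []
    plan_rows = []
    for row in truth.svs.itertuples(index=False):
        mid_bin = ((row.start + row.end) // 2) // bin_width
        low = bool(density[row.chrom][mid_bin] < low_density_threshold)
        miss_p = miss_in_low_density if low else base_fn_rate
        emitted = row.size >= min_size and rng.random() >= miss_p
        plan = {
            "sv_id": row.sv_id, "emitted": emitted, "low_density": low,
            "emitted_type": "", "cipos_low": 0, "cipos_high": 0,
            "ciend_low": 0, "ciend_high": 0, "quality": None,
            "confidence": None, "reported_size": 0,
        }
        if emitted:
            pads = [
                int(rng.integers(pad_lo, pad_hi + 1)) if pad_hi > 0 else 0
                for _ in range(4)
            ]
            etype = row.type
            if etype in ("INS", "DEL") and rng.random() < type_confusion:
                etype = "DEL" if etype == "INS" else "INS"
            reported = int(round(row.size * (1.0 + rng.uniform(0.0, size_inflation))))
            pos = row.start
            end = row.start + 1 if row.type == "INS" else row.end
            quality = confidence = None
            if etype in ("INS", "DEL", "DUP"):
                quality = quality_model(rng, etype, reported)
            else:
                confidence = confidence_model(rng, etype, reported)
            vcf_type = {
                "INS": "insertion", "DEL": "deletion", "INV": "inversion",
                "TRA": "translocation", "DUP": "duplication",
            }[etype]
            info = [
                f"SVTYPE={vcf_type}",
                f"END={end}",
                f"CIPOS=-{pads[0]},{pads[1]}",
                f"CIEND=-{pads[2]},{pads[3]}",
                f"SVSIZE={reported}",
            ]
            if quality is not None:
                info.append(f"QUAL_SCORE={quality}")
            if confidence is not None:
                info.append(f"CONFIDENCE={confidence}")
            records.append(
                (
                    row.chrom, pos,
                    f"{row.chrom}\t{pos}\tBN_{row.sv_id}\tN\t<{etype}>\t.\t"
                    f"PASS\t{';'.join(info)}",
                )
            )
            plan.update(
                {
                    "emitted_type": etype,
                    "cipos_low": -pads[0], "cipos_high": pads[1],
                    "ciend_low": -pads[2], "ciend_high": pads[3],
                    "quality": quality, "confidence": confidence,
                    "reported_size": reported,
                }
            )
        plan_rows.append(plan)
    records.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=svconcord-synthetic\n")
        for chrom, length in truth.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n'
            '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description='
            '"Confidence interval around POS">\n'
            '##INFO=<ID=CIEND,Number=2,Type=Integer,Description='
            '"Confidence interval around END">\n'
            '##INFO=<ID=SVSIZE,Number=1,Type=Integer,Description="Reported SV size">\n'
            '##INFO=<ID=QUAL_SCORE,Number=1,Type=Integer,Description='
            '"Insertion/deletion quality score (0-20)">\n'
            '##INFO=<ID=CONFIDENCE,Number=1,Type=Float,Description='
            '"Breakpoint confidence">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, _, line in records:
            fh.write(line + "\n")
    return pd.DataFrame(plan_rows)


# ---------------------------------------------------------------------------
# Expected classification
# ---------------------------------------------------------------------------

def expected_classification(
    truth: TruthSet, ont_plan: pd.DataFrame, bn_plan: pd.DataFrame
) -> pd.DataFrame:
    """Deterministic svID expectation per planted SV, from the two plans.

    UU when both technologies emitted a single call, MU when the assembly
    side fragmented (k >= 2) and the optical side emitted, UN / NU for
    single-technology emissions and NN when both missed.  Expected
    conformance compares the emitted (not planted) types; it is ``None``
    for single-technology locations.  Valid because planted events are
    spaced so emitted calls from different events can never overlap.
    """
    ont = ont_plan.set_index("sv_id")
    bn = bn_plan.set_index("sv_id")
    rows = []
    for row in truth.svs.itertuples(index=False):
        o_emitted = bool(ont.loc[row.sv_id, "emitted"])
        b_emitted = bool(bn.loc[row.sv_id, "emitted"])
        k = int(ont.loc[row.sv_id, "k"]) if o_emitted else 0
        first = "N" if not o_emitted else ("U" if k == 1 else "M")
        second = "U" if b_emitted else "N"
        code = first + second if (o_emitted or b_emitted) else "NN"
        conforming: bool | None = None
        if o_emitted and b_emitted:
            conforming = bool(
                ont.loc[row.sv_id, "emitted_type"]
                == bn.loc[row.sv_id, "emitted_type"]
            )
        rows.append(
            {
                "sv_id": row.sv_id, "expected_code": code,
                "expected_ont_members": k,
                "expected_bionano_members": int(b_emitted),
                "expected_conforming": conforming,
            }
        )
    return pd.DataFrame(rows)


def zero_noise() -> dict[str, dict]:
    """Emitter keyword arguments for the noise-free regime: every planted
    SV emitted once by each technology (translocations excepted on the
    assembly side), with exact sizes, no pads and deterministic scores."""
    return {
        "ont": {
            "frag_prob": 0.0, "fn_rate": 0.0, "size_jitter": 0.0,
        },
        "bionano": {
            "pad_range": (0, 0), "miss_in_low_density": 0.0,
            "base_fn_rate": 0.0, "size_inflation": 0.0,
            "type_confusion": 0.0,
            "quality_model": lambda rng, t, s: 20,
            "confidence_model": lambda rng, t, s: 0.99,
        },
    }
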