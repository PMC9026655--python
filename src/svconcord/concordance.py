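"""Cross-technology overlap grouping and svID classification.

Calls from the two technologies are compared on their absolute reference
positions: an assembly (ONT) call and an optical-map (Bionano) call are
linked when their intervals overlap by at least 1 bp — the ONT side by its
reference footprint, the Bionano side by its uncertainty-extended interval.
Connected components of the resulting bipartite graph are "locations", each
labelled with a two-letter svID code: first letter for ONT, second for
Bionano, with U (unique member), M (multiple members) or N (no member).
UU and MU (and the unobserved UM/MM) locations are *common*; UN and NU are
*specific* to one technology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
from intervaltree import IntervalTree

from svconcord.harmonize import BIONANO, ONT, SvCall

#: Overlap-fraction classes for one-to-one (UU) locations.
FULL, GT50, LE50, NA = "FULL", "GT50", "LE50", "NA"


@dataclass
class LocationGroup:
    """One overlap location: a connected component of the bipartite graph."""

    location_id: str
    svid_code: str
    ont_members: list[SvCall]
    bionano_members: list[SvCall]
    chrom: str
    span_start: int
    span_end: int
    conforming: bool | None  # None = not applicable (single-technology)
    overlap_class: str

    @property
    def is_common(self) -> bool:
        return "N" not in self.svid_code

    @property
    def member_count(self) -> int:
        return len(self.ont_members) + len(self.bionano_members)


def _code_letter(n: int) -> str:
    return "N" if n == 0 else ("U" if n == 1 else "M")


def _ont_interval(call: SvCall) -> tuple[int, int]:
    # assembly calls participate via their reference footprint (for an
    # insertion, the gap it leaves on the reference)
    return call.ref_start, call.ref_end


def _bionano_interval(call: SvCall) -> tuple[int, int]:
    return call.ext_start, call.ext_end


def build_overlap_graph(
    ont: Sequence[SvCall], bionano: Sequence[SvCall]
) -> list[tuple[str, str]]:
    """Edges ``(ont_call_id, bionano_call_id)`` for every pair of calls on
    the same chromosome whose intervals share at least 1 bp.

    Edge order is deterministic: sorted by (chrom, ONT start, ONT id,
    Bionano start, Bionano id).
    """
    trees: dict[str, IntervalTree] = {}
    by_id = {c.call_id: c for c in bionano}
    for call in bionano:
        lo, hi = _bionano_interval(call)
        trees.setdefault(call.chrom, IntervalTree()).addi(lo, hi + 1, call.call_id)
    edges: list[tuple[str, str]] = []
    for o in ont:
        tree = trees.get(o.chrom)
        if tree is None:
            continue
        lo, hi = _ont_interval(o)
        hits = [iv.data for iv in tree.overlap(lo, hi + 1)]
        hits.sort(key=lambda bid: (by_id[bid].ext_start, bid))
        edges.extend((o.call_id, bid) for bid in hits)
    ont_by_id = {c.call_id: c for c in ont}
    edges.sort(
        key=lambda e: (
            ont_by_id[e[0]].chrom,
            ont_by_id[e[0]].ref_start,
            e[0],
            by_id[e[1]].ext_start,
            e[1],
        )
    )
    return edges


def score_conformance(
    ont_members: Sequence[SvCall], bionano_members: Sequence[SvCall]
) -> bool | None:
    """Whether every call grouped at a location shares one SV type across
    technologies; ``None`` (not applicable) for single-technology groups."""
    if not ont_members or not bionano_members:
        return None
    types = {c.sv_type for c in ont_members} | {c.sv_type for c in bionano_members}
    return len(types) == 1


def score_overlap_fraction(
    ont_members: Sequence[SvCall], bionano_members: Sequence[SvCall]
) -> str:
    """Overlap class for a one-to-one (UU) location.

    The fraction is the intersection length over the *shorter* of the two
    intervals, so containment of a precise assembly call inside a coarse
    optical-map interval reads as 100%.  FULL means fraction == 1, GT50
    a fraction strictly between 0.5 and 1, LE50 at most 0.5; any non-UU
    multiplicity returns NA.
    """
    if len(ont_members) != 1 or len(bionano_members) != 1:
        return NA
    o_lo, o_hi = _ont_interval(ont_members[0])
    b_lo, b_hi = _bionano_interval(bionano_members[0])
    inter = min(o_hi, b_hi) - max(o_lo, b_lo) + 1
    if inter <= 0:
        return LE50
    shorter = min(o_hi - o_lo + 1, b_hi - b_lo + 1)
    if inter == shorter:
        return FULL
    return GT50 if 2 * inter > shorter else LE50


def assign_locations(
    edges: Sequence[tuple[str, str]],
    ont: Sequence[SvCall],
    bionano: Sequence[SvCall],
) -> list[LocationGroup]:
    """Group calls into locations and assign svID codes.

    Locations are the connected components of the bipartite overlap graph;
    calls with no cross-technology overlap form singleton UN (ONT-only) or
    NU (Bionano-only) locations.  Ordinals in location ids are assigned
    per code in genome order (chrom, span start).
    """
    graph: nx.Graph = nx.Graph()
    ont_by_id = {c.call_id: c for c in ont}
    bn_by_id = {c.call_id: c for c in bionano}
    for call_id in ont_by_id:
        graph.add_node(("O", call_id))
    for call_id in bn_by_id:
        graph.add_node(("B", call_id))
    for o_id, b_id in edges:
        if o_id not in ont_by_id or b_id not in bn_by_id:
            raise ValueError(f"edge ({o_id}, {b_id}) references an unknown call")
        graph.add_edge(("O", o_id), ("B", b_id))

    raw_groups = []
    for component in nx.connected_components(graph):
        o_members = sorted(
            (ont_by_id[cid] for side, cid in component if side == "O"),
            key=lambda c: (c.ref_start, c.call_id),
        )
        b_members = sorted(
            (bn_by_id[cid] for side, cid in component if side == "B"),
            key=lambda c: (c.ext_start, c.call_id),
        )
        code = _code_letter(len(o_members)) + _code_letter(len(b_members))
        intervals = [_ont_interval(c) for c in o_members] + [
            _bionano_interval(c) for c in b_members
        ]
        chrom = (o_members or b_members)[0].chrom
        span_start = min(lo for lo, _ in intervals)
        span_end = max(hi for _, hi in intervals)
        raw_groups.append((code, chrom, span_start, span_end, o_members, b_members))

    raw_groups.sort(key=lambda g: (g[1], g[2], g[3], g[0]))
    counters: dict[str, int] = {}
    groups: list[LocationGroup] = []
    for code, chrom, span_start, span_end, o_members, b_members in raw_groups:
        counters[code] = counters.get(code, 0) + 1
        groups.append(
            LocationGroup(
                location_id=f"{code}_{counters[code]:03d}",
                svid_code=code,
                ont_members=o_members,
                bionano_members=b_members,
                chrom=chrom,
                span_start=span_start,
                span_end=span_end,
                conforming=score_conformance(o_members, b_members),
                overlap_class=score_overlap_fraction(o_members, b_members),
            )
        )
    return groups


def classify(
    ont: Sequence[SvCall], bionano: Sequence[SvCall]
) -> list[LocationGroup]:
    """Full comparison: overlap graph plus location assignment."""
    return assign_locations(build_overlap_graph(ont, bionano), ont, bionano)


def venn_counts(groups: Sequence[LocationGroup]) -> dict[str, int]:
    """Common/specific location counts (the Venn-diagram contract)."""
    by_code: dict[str, int] = {}
    for group in groups:
        by_code[group.svid_code] = by_code.get(group.svid_code, 0) + 1
    return {
        "common_locations": sum(1 for g in groups if g.is_common),
        "ont_specific_locations": by_code.get("UN", 0) + by_code.get("MN", 0),
        "bionano_specific_locations": by_code.get("NU", 0) + by_code.get("NM", 0),
        "by_code": by_code,  # type: ignore[dict-item]
    }


def groups_to_table(groups: Sequence[LocationGroup]):
    """Location table as a DataFrame (one row per location)."""
    import pandas as pd

    rows = []
    for g in groups:
        rows.append(
            {
                "location_id": g.location_id,
                "svid_code": g.svid_code,
                "chrom": g.chrom,
                "span_start": g.span_start,
                "span_end": g.span_end,
                "ont_members": ",".join(c.call_id for c in g.ont_members),
                "bionano_members": ",".join(c.call_id for c in g.bionano_members),
                "ont_types": ",".join(c.sv_type for c in g.ont_members),
                "bionano_types": ",".join(c.sv_type for c in g.bionano_members),
                "ont_sizes": ",".join(str(c.size) for c in g.ont_members),
                "bionano_sizes": ",".join(str(c.size) for c in g.bionano_members),
                "conforming": "NA" if g.conforming is None else str(g.conforming),
                "overlap_class": g.overlap_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "location_id", "svid_code", "chrom", "span_start", "span_end",
            "ont_members", "bionano_members", "ont_types", "bionano_types",
            "ont_sizes", "bionano_sizes", "conforming", "overlap_class",
        ],
    )
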