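"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from svconcord.harmonize import BIONANO, ONT, SvCall

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_call(
    call_id: str,
    start: int,
    end: int,
    source: str = ONT,
    chrom: str = "chr1",
    sv_type: str = "DEL",
    size: int | None = None,
    ext: tuple[int, int] | None = None,
    quality: int | None = None,
    confidence: float | None = None,
) -> SvCall:
    ext_start, ext_end = ext if ext is not None else (start, end)
    return SvCall(
        call_id=call_id, source=source, chrom=chrom,
        ref_start=start, ref_end=end, ext_start=ext_start, ext_end=ext_end,
        sv_type=sv_type, size=size if size is not None else (end - start + 1),
        quality=quality, confidence=confidence,
    )


@pytest.fixture
def mk():
    return make_call


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_edges(
    ont: list[SvCall], bionano: list[SvCall]
) -> set[tuple[str, str]]:
    """O(n*m) pairwise >=1 bp overlap on ONT ref vs Bionano ext intervals."""
    edges = set()
    for o in ont:
        for b in bionano:
            if (
                o.chrom == b.chrom
                and o.ref_start <= b.ext_end
                and b.ext_start <= o.ref_end
            ):
                edges.add((o.call_id, b.call_id))
    return edges


def union_find_components(
    ont: list[SvCall], bionano: list[SvCall], edges: set[tuple[str, str]]
) -> set[frozenset[str]]:
    """Connected components via textbook union-find over node ids."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for call in list(ont) + list(bionano):
        parent[f"{call.source}:{call.call_id}"] = f"{call.source}:{call.call_id}"
    for o_id, b_id in edges:
        union(f"{ONT}:{o_id}", f"{BIONANO}:{b_id}")
    groups: dict[str, set[str]] = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    return {frozenset(g) for g in groups.values()}


def brute_force_embedded(calls: list[SvCall]) -> set[str]:
    """O(n^2) containment closure: ids removed as embedded."""
    order = {c.call_id: i for i, c in enumerate(calls)}
    removed = set()
    for a in calls:
        for b in calls:
            if a.call_id == b.call_id or a.chrom != b.chrom:
                continue
            contains = b.ref_start <= a.ref_start and a.ref_end <= b.ref_end
            if not contains:
                continue
            proper = (b.ref_start, b.ref_end) != (a.ref_start, a.ref_end)
            if proper:
                removed.add(a.call_id)
            else:
                # identical intervals: keep the call_id-first one
                first = min(a, b, key=lambda c: c.call_id)
                removed.add(a.call_id if a is not first else b.call_id)
    return removed


def exact_wilcoxon_less(x: list[float], y: list[float]) -> float:
    """One-sided (x stochastically smaller) rank-sum p-value by full
    enumeration of rank assignments; requires no ties."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires distinct values"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    nx = len(x)
    u_obs = sum(rank[v] for v in x) - nx * (nx + 1) / 2
    count = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), nx):
        u = sum(combo) - nx * (nx + 1) / 2
        if u <= u_obs:
            count += 1
    return count / comb(len(pooled), nx)


def random_callsets(
    rng: np.random.Generator,
    n_ont: int,
    n_bionano: int,
    genome: int = 10_000,
    max_len: int = 500,
    pad_max: int = 50,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
) -> tuple[list[SvCall], list[SvCall]]:
    """Random interval callsets for oracle-equivalence checks."""
    ont, bionano = [], []
    for i in range(n_ont):
        start = int(rng.integers(1, genome))
        end = start + int(rng.integers(0, max_len))
        ont.append(
            make_call(
                f"O{i:03d}", start, end, source=ONT,
                chrom=str(rng.choice(chroms)),
                sv_type=str(rng.choice(["INS", "DEL", "INV"])),
            )
        )
    for i in range(n_bionano):
        start = int(rng.integers(1, genome))
        end = start + int(rng.integers(0, max_len))
        pad_l = int(rng.integers(0, pad_max))
        pad_r = int(rng.integers(0, pad_max))
        bionano.append(
            make_call(
                f"B{i:03d}", start, end, source=BIONANO,
                chrom=str(rng.choice(chroms)),
                sv_type=str(rng.choice(["INS", "DEL", "INV", "TRA"])),
                ext=(max(1, start - pad_l), end + pad_r),
            )
        )
    return ont, bionano
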