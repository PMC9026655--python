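"""Cross-tabulation of SV calls against gene and TE annotation.

Each call is flagged for overlap (>= 1 bp on its reference footprint) with
transposable-element and gene features, then tabulated per svID class into
the four (TE-status x GENE-status) cells.  The two flags are independent: a
call over a TE nested in a gene counts in the TE&GENE cell.  Gene
identifiers hit by each class are exported for external GO-term enrichment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from svconcord.harmonize import SvCall
from svconcord.io import AnnotationFeature

CELL_COLUMNS = ("noTE_noGENE", "noTE_GENE", "TE_noGENE", "TE_GENE")


def classify_annotation(
    calls: Sequence[SvCall], features: Sequence[AnnotationFeature]
) -> pd.DataFrame:
    """Per-call annotation flags.

    Returns a DataFrame indexed by ``call_id`` with boolean ``overlaps_te``
    and ``overlaps_gene`` columns and a ``gene_ids`` column holding the
    sorted tuple of gene identifiers the call touches.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for feat in features:
        trees.setdefault((feat.chrom, feat.category), IntervalTree()).addi(
            feat.start, feat.end + 1, feat.feature_id
        )
    rows = []
    for call in calls:
        te_tree = trees.get((call.chrom, "TE"))
        gene_tree = trees.get((call.chrom, "GENE"))
        query = (call.ref_start, call.ref_end + 1)
        gene_hits = (
            sorted({iv.data for iv in gene_tree.overlap(*query)})
            if gene_tree is not None
            else []
        )
        rows.append(
            {
                "call_id": call.call_id,
                "overlaps_te": bool(te_tree is not None and te_tree.overlap(*query)),
                "overlaps_gene": bool(gene_hits),
                "gene_ids": tuple(gene_hits),
            }
        )
    return pd.DataFrame(
        rows, columns=["call_id", "overlaps_te", "overlaps_gene", "gene_ids"]
    ).set_index("call_id")


def crosstab(
    flags: pd.DataFrame, class_by_call: Mapping[str, str]
) -> pd.DataFrame:
    """Counts per (svID class) x (TE-status x GENE-status) cell.

    ``class_by_call`` maps every classified call id to its svID class
    (e.g. UU/MU/UN); a flagged call without a class is an error.  The
    result has one row per class plus a TOTAL row, the four cell columns
    plus a row TOTAL and its one-decimal percent of the grand total.
    """
    missing = [cid for cid in flags.index if cid not in class_by_call]
    if missing:
        raise ValueError(f"calls without an svID class: {missing[:5]}")
    classes = sorted({class_by_call[cid] for cid in flags.index})
    counts = pd.DataFrame(0, index=classes, columns=list(CELL_COLUMNS))
    for cid, row in flags.iterrows():
        cell = (
            ("TE_" if row["overlaps_te"] else "noTE_")
            + ("GENE" if row["overlaps_gene"] else "noGENE")
        )
        counts.loc[class_by_call[cid], cell] += 1
    counts.loc["TOTAL"] = counts.sum(axis=0)
    counts["TOTAL"] = counts.sum(axis=1)
    grand = counts.loc["TOTAL", "TOTAL"]
    counts["percent"] = (
        (100.0 * counts["TOTAL"] / grand).round(1) if grand else 0.0
    )
    return counts


def export_gene_lists(
    flags: pd.DataFrame,
    class_by_call: Mapping[str, str],
    outdir: str | Path,
) -> dict[str, list[str]]:
    """Write deduplicated, sorted gene-id lists per svID class plus a
    combined list (one id per line), for external enrichment tools.

    Returns the in-memory lists keyed by class name, with the combined
    list under ``"all"``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per_class: dict[str, set[str]] = {}
    for cid, row in flags.iterrows():
        cls = class_by_call[cid]
        per_class.setdefault(cls, set()).update(row["gene_ids"])
    result: dict[str, list[str]] = {}
    combined: set[str] = set()
    for cls in sorted(per_class):
        genes = sorted(per_class[cls])
        combined.update(genes)
        (outdir / f"genes_{cls}.txt").write_text(
            "".join(g + "\n" for g in genes)
        )
        result[cls] = genes
    all_genes = sorted(combined)
    (outdir / "genes_all.txt").write_text("".join(g + "\n" for g in all_genes))
    result["all"] = all_genes
    return result
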