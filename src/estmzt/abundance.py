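"""Copy-number filtering and library composition summaries.

Genes represented by few ESTs carry unreliable stage profiles (their EST
profile is not reflected by qPCR of the same genes), so a copy-number
threshold — 9 or more total sequences per gene by default — gates all
downstream analysis.  Composition summaries report the mitochondrial
contribution per stage, optional ribosomal fractions from a caller-supplied
annotation, and presence categories (maternal-only, gastrula-only,
all-stages).
"""

from __future__ import annotations

import pandas as pd

from estmzt.core import STAGES, StageCountMatrix, ValidationError, require

__all__ = [
    "filter_by_total",
    "mito_fraction",
    "presence_category",
    "top_n_table",
    "composition_summary",
]

DEFAULT_MIN_TOTAL = 9


def filter_by_total(
    matrix: StageCountMatrix, min_total: int = DEFAULT_MIN_TOTAL
) -> tuple[StageCountMatrix, pd.DataFrame]:
    """Retain genes with row sum >= ``min_total``; drop pseudogenes regardless.

    Returns the filtered matrix and a report listing removed genes with
    reasons (``pseudogene`` wins over ``below_threshold`` when both apply).
    """
    require(min_total >= 1, "min_total must be >= 1")
    totals = matrix.totals()
    removed: list[tuple[str, int, str]] = []
    keep: list[str] = []
    for gene in matrix.gene_ids:
        if bool(matrix.pseudogene[gene]):
            removed.append((gene, int(totals[gene]), "pseudogene"))
        elif totals[gene] < min_total:
            removed.append((gene, int(totals[gene]), "below_threshold"))
        else:
            keep.append(gene)
    filtered = StageCountMatrix(
        counts=matrix.counts.loc[keep].copy(),
        mito=matrix.mito.loc[keep].copy(),
        pseudogene=matrix.pseudogene.loc[keep].copy(),
    )
    report = pd.DataFrame(removed, columns=["gene_id", "total", "reason"])
    return filtered, report


def mito_fraction(matrix: StageCountMatrix, stage: str) -> float:
    """Fraction of a stage's ESTs that come from mitochondrial genes."""
    require(stage in STAGES, f"unknown stage {stage!r}")
    total = matrix.stage_total(stage)
    if total == 0:
        raise ValidationError(f"stage {stage} has zero total; fraction undefined")
    mito_total = int(matrix.counts.loc[matrix.mito, stage].sum())
    return mito_total / total


def presence_category(counts) -> str:
    """Categorize a gene's presence pattern across the four stages.

    ``maternal_only`` when absent from gastrula, ``zygotic_only`` when
    present in gastrula alone, ``all_stages`` when seen in every library,
    ``other`` otherwise.
    """
    o, c, b, g = (int(x) for x in counts)
    require(o >= 0 and c >= 0 and b >= 0 and g >= 0, "counts must be non-negative")
    if o == c == b == g == 0:
        raise ValidationError("all-zero count row has no presence category")
    if g == 0:
        return "maternal_only"
    if o == c == b == 0:
        return "zygotic_only"
    if o > 0 and c > 0 and b > 0 and g > 0:
        return "all_stages"
    return "other"


def top_n_table(matrix: StageCountMatrix, n: int) -> pd.DataFrame:
    """The n most abundant genes by total EST count, ties alphabetical."""
    require(n >= 1, "n must be >= 1")
    df = matrix.counts.copy()
    df.insert(0, "total", matrix.totals())
    df = df.sort_values(by=["total"], ascending=False, kind="mergesort")
    # stable sort on descending total preserves a prior alphabetical order
    df = df.loc[sorted(df.index)].sort_values(by=["total"], ascending=False, kind="mergesort")
    out = df.head(n).reset_index(names="gene_id")
    return out


def composition_summary(
    matrix: StageCountMatrix,
    annotation: pd.DataFrame | None = None,
) -> dict:
    """Per-stage totals, mitochondrial (and optional ribosomal) fractions,
    plus gene counts per presence category.

    ``annotation`` may supply columns ``gene_id`` and ``is_ribosomal``; when
    absent, ribosomal fractions are reported as None (not available), never
    as 0.
    """
    ribosomal: pd.Series | None = None
    if annotation is not None:
        require(
            {"gene_id", "is_ribosomal"} <= set(annotation.columns),
            "annotation table needs gene_id and is_ribosomal columns",
        )
        ribosomal = (
            annotation.set_index("gene_id")["is_ribosomal"]
            .reindex(matrix.counts.index, fill_value=False)
            .astype(bool)
        )
    per_stage = {}
    for stage in STAGES:
        total = matrix.stage_total(stage)
        entry: dict = {"total_transcripts": total}
        entry["mito_fraction"] = mito_fraction(matrix, stage) if total > 0 else None
        if ribosomal is not None and total > 0:
            entry["ribosomal_fraction"] = float(
                matrix.counts.loc[ribosomal, stage].sum() / total
            )
        else:
            entry["ribosomal_fraction"] = None
        per_stage[stage] = entry

    categories: dict[str, int] = {
        "maternal_only": 0,
        "zygotic_only": 0,
        "all_stages": 0,
        "other": 0,
    }
    for gene in matrix.gene_ids:
        row = matrix.counts.loc[gene].to_numpy()
        if row.sum() == 0:
            continue
        categories[presence_category(row)] += 1
    return {
        "per_stage": per_stage,
        "presence_categories": categories,
        "n_genes": len(matrix.gene_ids),
    }
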