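"""3'UTR length and isoform inference from poly-A-anchored ESTs.

The poly-A tail of a 3'-anchored EST marks the cleavage/polyadenylation
site; mapped through the EST's alignment this gives a transcript coordinate,
and the 3'UTR length is the distance from the end of the stop codon to that
site.  Distinct cleavage sites of one gene are clustered (single linkage,
default 10 nt tolerance) into 3'UTR isoforms.  Mitochondrial genes are
excluded: UTR length is predicted in nuclear sequences only.  Per-class
length summaries use one record per isoform, and between-class differences
are assessed with Kruskal-Wallis plus Dunn's post test after reporting
D'Agostino-Pearson normality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from estmzt.core import ValidationError, require
from estmzt.est import GeneAssignment, PolyATail
from estmzt import stats as _stats

__all__ = [
    "GeneModel",
    "CleavageSite",
    "Isoform",
    "UtrRecord",
    "infer_cleavage_site",
    "compute_utr_length",
    "cluster_isoforms",
    "build_utr_records",
    "utr_length_summary",
    "length_difference_test",
    "write_utr_bed",
    "write_utr_fasta",
]


@dataclass
class GeneModel:
    """Gene model in transcript orientation.

    ``cds_end`` is the 0-based coordinate of the base after the stop codon's
    last base; the 3'UTR starts there.
    """

    gene_id: str
    contig: str
    strand: str
    cds_end: int
    transcript_seq: str | None = None
    is_mito: bool = False
    contig_offset: int = 0  # transcript start on its contig (forward strand coords)

    def __post_init__(self) -> None:
        require(self.strand in "+-", f"gene {self.gene_id}: strand must be + or -")
        require(self.cds_end >= 0, f"gene {self.gene_id}: cds_end must be >= 0")


@dataclass
class CleavageSite:
    gene_id: str
    position: int  # transcript-orientation coordinate of the first poly-A base
    support: int = 1

    def __post_init__(self) -> None:
        require(self.support >= 1, "cleavage site support must be >= 1")


@dataclass
class Isoform:
    gene_id: str
    index: int
    position: int
    support: int


@dataclass
class UtrRecord:
    gene_id: str
    isoform_index: int
    length: int
    sequence: str = ""
    transcript_class: str = "unclassified"
    support: int = 1

    def __post_init__(self) -> None:
        require(self.length >= 0, "UTR length must be >= 0")
        if self.sequence:
            require(len(self.sequence) == self.length, "length must equal |sequence|")


def infer_cleavage_site(
    assignment: GeneAssignment,
    span_end: int,
    tail: PolyATail,
    model: GeneModel,
) -> tuple[CleavageSite | None, str | None]:
    """Map an EST's tail start through its alignment to a cleavage site.

    ``span_end`` is the transcript coordinate just past the EST body's last
    aligned base — the position where the poly-A tail begins.  Sites falling
    before the end of the stop codon are discarded (the read does not
    support a complete 3'UTR) with reason ``upstream_of_stop``.
    """
    require(assignment.gene_id == model.gene_id, "assignment/model gene mismatch")
    require(span_end >= 0, "span_end must be >= 0")
    if span_end < model.cds_end:
        return None, "upstream_of_stop"
    return CleavageSite(gene_id=model.gene_id, position=span_end), None


def compute_utr_length(model: GeneModel, site: CleavageSite) -> int:
    """3'UTR length in bp: cleavage position minus cds_end.

    Excludes both the stop codon and the poly-A tail; translation-invariant
    under a common shift of both coordinates.
    """
    require(site.gene_id == model.gene_id, "site/model gene mismatch")
    if site.position < model.cds_end:
        raise ValidationError(
            f"gene {model.gene_id}: site {site.position} upstream of cds_end {model.cds_end}"
        )
    return site.position - model.cds_end


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def cluster_isoforms(sites: Sequence[CleavageSite], tolerance: int = 10) -> list[Isoform]:
    """Single-linkage clustering of one gene's cleavage sites into isoforms.

    Sites whose positions differ by <= ``tolerance`` chain into one isoform;
    the isoform position is the support-weighted mean rounded half up, and
    its support is the sum of member supports.  Order-invariant and
    idempotent.
    """
    require(len(sites) >= 1, "cluster_isoforms needs at least one site")
    gene_ids = {s.gene_id for s in sites}
    require(len(gene_ids) == 1, f"sites from multiple genes: {sorted(gene_ids)}")
    require(tolerance >= 0, "tolerance must be >= 0")
    ordered = sorted(sites, key=lambda s: s.position)
    clusters: list[list[CleavageSite]] = [[ordered[0]]]
    for site in ordered[1:]:
        if site.position - clusters[-1][-1].position <= tolerance:
            clusters[-1].append(site)
        else:
            clusters.append([site])
    isoforms = []
    gene_id = ordered[0].gene_id
    for idx, members in enumerate(clusters):
        support = sum(s.support for s in members)
        mean_pos = sum(s.position * s.support for s in members) / support
        isoforms.append(
            Isoform(gene_id=gene_id, index=idx, position=_round_half_up(mean_pos), support=support)
        )
    return isoforms


def build_utr_records(
    isoforms_by_gene: dict[str, list[Isoform]],
    models: dict[str, GeneModel],
    classes: dict[str, str] | None = None,
    include_mito: bool = False,
) -> list[UtrRecord]:
    """Materialize UTR records (one per isoform) with sequence and class.

    Sequences come from the gene model's transcript sequence, not from
    error-bearing ESTs.  Mitochondrial genes are skipped unless
    ``include_mito``.
    """
    records: list[UtrRecord] = []
    for gene_id in sorted(isoforms_by_gene):
        model = models[gene_id]
        if model.is_mito and not include_mito:
            continue
        cls = (classes or {}).get(gene_id, "unclassified")
        for iso in isoforms_by_gene[gene_id]:
            length = iso.position - model.cds_end
            if length < 0:
                continue
            seq = ""
            if model.transcript_seq is not None:
                seq = model.transcript_seq[model.cds_end : iso.position]
            records.append(
                UtrRecord(
                    gene_id=gene_id,
                    isoform_index=iso.index,
                    length=length,
                    sequence=seq,
                    transcript_class=cls,
                    support=iso.support,
                )
            )
    return records


def utr_length_summary(records: Iterable[UtrRecord]) -> pd.DataFrame:
    """Per-class n, mean and SEM of 3'UTR isoform lengths.

    SEM uses the sample standard deviation (ddof=1); classes with a single
    record report SEM as NaN, and empty classes are absent from the table.
    """
    by_class: dict[str, list[int]] = {}
    for rec in records:
        by_class.setdefault(rec.transcript_class, []).append(rec.length)
    rows = []
    for cls in sorted(by_class):
        lengths = np.asarray(by_class[cls], dtype=float)
        n = lengths.size
        mean = float(lengths.mean())
        sem = float(lengths.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append({"class": cls, "n": n, "mean_length": mean, "sem": sem})
    return pd.DataFrame(rows, columns=["class", "n", "mean_length", "sem"])


def length_difference_test(
    groups: dict[str, Sequence[float]], alpha: float = 0.05
) -> dict:
    """Omnibus and pairwise tests for UTR-length differences between classes.

    Reports D'Agostino-Pearson normality per group, then Kruskal-Wallis;
    when the omnibus p <= alpha, Dunn's pairwise comparisons with a compact
    letter display (groups sharing no letter differ).
    """
    require(len(groups) >= 2, "need at least 2 groups")
    names = sorted(groups)
    data = [list(groups[name]) for name in names]
    for name, values in zip(names, data):
        require(len(values) >= 1, f"group {name!r} is empty")
    normality = {}
    for name, values in zip(names, data):
        try:
            normality[name] = _stats.dagostino_pearson(values)
        except ValidationError:
            normality[name] = _stats.TestResult(
                method="dagostino_pearson", statistic=None, p_value=None, note="zero variance"
            )
    omnibus = _stats.kruskal_wallis(data)
    result = {"groups": names, "normality": normality, "kruskal_wallis": omnibus, "dunn": None}
    if omnibus.p_value is not None and omnibus.p_value <= alpha:
        result["dunn"] = _stats.dunns_test(data, alpha=alpha)
    return result


def write_utr_bed(
    records: Iterable[UtrRecord], models: dict[str, GeneModel], path: str | Path
) -> None:
    """UTR intervals as BED (0-based half-open, transcript coordinates),
    name = gene|isoform, score = EST support."""
    with open(path, "w") as fh:
        for rec in records:
            model = models[rec.gene_id]
            start = model.cds_end
            end = model.cds_end + rec.length
            fh.write(
                f"{model.contig}\t{start}\t{end}\t{rec.gene_id}|{rec.isoform_index}"
                f"\t{rec.support}\t{model.strand}\n"
            )


def write_utr_fasta(records: Iterable[UtrRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if not rec.sequence:
                continue
            fh.write(f">{rec.gene_id}|{rec.isoform_index} class={rec.transcript_class}\n")
            fh.write(rec.sequence + "\n")
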