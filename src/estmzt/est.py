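"""3'-end EST processing: poly-A tails, orientation, gene assignment, counting.

Reads from a 3'-anchored cDNA library end in a poly-A tail (or begin with a
poly-T run when sequenced in the opposite orientation).  The tail anchors
the cleavage site; after trimming it, each EST is assigned to a gene by
identity-threshold rules over externally supplied alignments: above 85%
identity against a genome-mapped EST contig, or above 75% identity within a
gene or within 2000 bp downstream of one.  Assigned ESTs are tallied into a
genes x stages count matrix; everything else lands in a discard log with a
reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from estmzt.core import STAGES, StageCountMatrix, ValidationError, require

__all__ = [
    "EstRecord",
    "PolyATail",
    "AlignmentRecord",
    "GeneAssignment",
    "AssignmentThresholds",
    "detect_polya",
    "trim_polya",
    "assign_gene",
    "assign_all",
    "build_count_matrix",
    "NaiveAligner",
    "read_est_fasta",
    "read_alignment_tsv",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class EstRecord:
    id: str
    sequence: str
    stage: str

    def __post_init__(self) -> None:
        require(len(self.sequence) > 0, f"EST {self.id}: empty sequence")
        require(
            set(self.sequence) <= set("ACGTN"),
            f"EST {self.id}: sequence alphabet must be A/C/G/T/N",
        )
        require(self.stage in STAGES, f"EST {self.id}: unknown stage {self.stage!r}")


@dataclass
class PolyATail:
    start: int  # 0-based index into the oriented sequence
    length: int
    mismatches: int
    orientation_flipped: bool = False


@dataclass
class AlignmentRecord:
    est_id: str
    target_id: str
    target_kind: str  # gene | downstream | est_contig
    percent_identity: float  # fraction in [0, 1]
    downstream_distance: int = 0
    target_start: int = 0  # aligned span on the target, 0-based half-open
    target_end: int = 0
    gene_id: str | None = None  # gene the target resolves to (defaults to target_id)

    def __post_init__(self) -> None:
        require(0.0 <= self.percent_identity <= 1.0, "percent_identity must be in [0,1]")
        require(self.downstream_distance >= 0, "downstream_distance must be >= 0")
        if self.gene_id is None:
            self.gene_id = self.target_id

    @property
    def span_length(self) -> int:
        return self.target_end - self.target_start


@dataclass
class GeneAssignment:
    est_id: str
    gene_id: str
    rule: str  # contig_85 | gene_75 | downstream_75
    identity: float
    target_start: int = 0
    target_end: int = 0


@dataclass
class AssignmentThresholds:
    """Identity thresholds for EST-to-gene assignment.

    ``strict`` applies the thresholds as strict inequalities ("above 85%" /
    "above 75%"), the literal reading; set False for >=.
    """

    contig_min: float = 0.85
    gene_min: float = 0.75
    downstream_min: float = 0.75
    max_downstream: int = 2000
    strict: bool = True

    def _passes(self, value: float, threshold: float) -> bool:
        return value > threshold if self.strict else value >= threshold

    def qualifies(self, rec: AlignmentRecord) -> str | None:
        """Return the rule name the record qualifies under, or None."""
        if rec.target_kind == "est_contig" and self._passes(rec.percent_identity, self.contig_min):
            return "contig_85"
        if rec.target_kind == "gene" and self._passes(rec.percent_identity, self.gene_min):
            return "gene_75"
        if (
            rec.target_kind == "downstream"
            and self._passes(rec.percent_identity, self.downstream_min)
            and rec.downstream_distance <= self.max_downstream
        ):
            return "downstream_75"
        return None


def detect_polya(
    sequence: str, min_len: int = 8, max_mismatch: int = 1
) -> PolyATail | None:
    """Find a terminal poly-A tail, resolving orientation if needed.

    Scans backwards from the 3' terminus, extending the run while the number
    of non-A bases stays within ``max_mismatch``; non-A bases at the 5' edge
    of the run are then trimmed off.  A qualifying run must reach
    ``min_len``.  If the given orientation has no tail, the reverse
    complement is tried (a leading poly-T run becomes a trailing poly-A run)
    and ``orientation_flipped`` is set.  Returns None when neither
    orientation qualifies.
    """
    require(min_len >= 1, "min_len must be >= 1")
    require(max_mismatch >= 0, "max_mismatch must be >= 0")
    require(len(sequence) > 0, "sequence is empty")

    def scan(seq: str) -> PolyATail | None:
        n = len(seq)
        mismatches = 0
        i = n - 1
        while i >= 0:
            if seq[i] != "A":
                if mismatches + 1 > max_mismatch:
                    break
                mismatches += 1
            i -= 1
        start = i + 1
        # trim non-A bases at the 5' edge of the run
        while start < n and seq[start] != "A":
            mismatches -= 1
            start += 1
        length = n - start
        if length >= min_len:
            return PolyATail(start=start, length=length, mismatches=mismatches)
        return None

    tail = scan(sequence)
    if tail is not None:
        return tail
    flipped = scan(reverse_complement(sequence))
    if flipped is not None:
        flipped.orientation_flipped = True
        return flipped
    return None


def trim_polya(record: EstRecord, tail: PolyATail) -> tuple[str, PolyATail]:
    """Remove the detected tail, returning the oriented body sequence.

    With zero mismatches, body + "A" * tail.length reproduces the oriented
    sequence exactly.
    """
    oriented = (
        reverse_complement(record.sequence) if tail.orientation_flipped else record.sequence
    )
    if tail.start + tail.length != len(oriented):
        raise ValidationError(
            f"EST {record.id}: tail (start={tail.start}, length={tail.length}) "
            f"does not reach the 3' end of the oriented sequence (len={len(oriented)})"
        )
    trimmed = oriented[: tail.start]
    if not trimmed:
        warnings.warn(f"EST {record.id}: poly-A tail covers the entire sequence")
    return trimmed, tail


def assign_gene(
    alignments: Sequence[AlignmentRecord],
    thresholds: AssignmentThresholds | None = None,
) -> GeneAssignment | None:
    """Assign one EST to a gene from its candidate alignments.

    Keeps qualifying alignments only, then picks the highest identity,
    breaking ties by longer aligned span and then lexicographically smallest
    target id.  ESTs whose best candidates point at two different genes with
    identical identity and span are left unassigned (conservative discard).
    """
    thresholds = thresholds or AssignmentThresholds()
    if not alignments:
        return None
    est_ids = {a.est_id for a in alignments}
    require(len(est_ids) == 1, f"assign_gene: mixed est_ids {sorted(est_ids)}")

    qualified = [(a, thresholds.qualifies(a)) for a in alignments]
    qualified = [(a, rule) for a, rule in qualified if rule is not None]
    if not qualified:
        return None
    best_key = max((a.percent_identity, a.span_length) for a, _ in qualified)
    best = [
        (a, rule)
        for a, rule in qualified
        if (a.percent_identity, a.span_length) == best_key
    ]
    genes = {a.gene_id for a, _ in best}
    if len(genes) > 1:
        return None  # ambiguous between distinct genes
    a, rule = min(best, key=lambda pair: pair[0].target_id)
    return GeneAssignment(
        est_id=a.est_id,
        gene_id=a.gene_id,  # type: ignore[arg-type]
        rule=rule,
        identity=a.percent_identity,
        target_start=a.target_start,
        target_end=a.target_end,
    )


def assign_all(
    alignments_by_est: dict[str, list[AlignmentRecord]],
    est_ids: Iterable[str],
    thresholds: AssignmentThresholds | None = None,
) -> tuple[dict[str, GeneAssignment], pd.DataFrame]:
    """Assign every EST, returning assignments and a discard log with reasons."""
    thresholds = thresholds or AssignmentThresholds()
    assignments: dict[str, GeneAssignment] = {}
    discards: list[tuple[str, str]] = []
    for est_id in est_ids:
        hits = alignments_by_est.get(est_id, [])
        if not hits:
            discards.append((est_id, "no_hit"))
            continue
        assignment = assign_gene(hits, thresholds)
        if assignment is None:
            if any(thresholds.qualifies(a) for a in hits):
                discards.append((est_id, "ambiguous"))
            else:
                discards.append((est_id, "no_qualifying_hit"))
            continue
        assignments[est_id] = assignment
    discard_df = pd.DataFrame(discards, columns=["est_id", "reason"])
    return assignments, discard_df


def build_count_matrix(
    assignments: dict[str, GeneAssignment] | Iterable[GeneAssignment],
    records: Sequence[EstRecord],
    mito_flags: dict[str, bool] | None = None,
    pseudogene_flags: dict[str, bool] | None = None,
) -> tuple[StageCountMatrix, pd.DataFrame]:
    """Tally assigned ESTs into a genes x stages matrix.

    Returns the matrix plus a per-stage reconciliation table (assigned,
    discarded, total); assigned + discarded = input records per stage.
    """
    if isinstance(assignments, dict):
        assignment_list = list(assignments.values())
    else:
        assignment_list = list(assignments)
    by_id: dict[str, EstRecord] = {}
    for rec in records:
        if rec.id in by_id:
            raise ValidationError(f"duplicate est_id among records: {rec.id}")
        by_id[rec.id] = rec
    for a in assignment_list:
        require(a.est_id in by_id, f"assignment references unknown EST {a.est_id}")

    counts: dict[str, np.ndarray] = {}
    assigned_per_stage = {s: 0 for s in STAGES}
    for a in assignment_list:
        stage = by_id[a.est_id].stage
        row = counts.setdefault(a.gene_id, np.zeros(4, dtype=np.int64))
        row[STAGES.index(stage)] += 1
        assigned_per_stage[stage] += 1

    matrix = StageCountMatrix.from_records(
        {g: row.tolist() for g, row in sorted(counts.items())},
        mito=mito_flags,
        pseudogene=pseudogene_flags,
    ) if counts else StageCountMatrix(
        counts=pd.DataFrame(columns=list(STAGES), dtype=np.int64)
    )
    totals_per_stage = {s: 0 for s in STAGES}
    for rec in by_id.values():
        totals_per_stage[rec.stage] += 1
    recon = pd.DataFrame(
        {
            "stage": list(STAGES),
            "assigned": [assigned_per_stage[s] for s in STAGES],
            "discarded": [totals_per_stage[s] - assigned_per_stage[s] for s in STAGES],
            "total": [totals_per_stage[s] for s in STAGES],
        }
    )
    return matrix, recon


class NaiveAligner:
    """Exact-seed, ungapped aligner for the synthetic fixture only.

    Indexes target sequences by k-mer; queries are anchored by the first
    exact seed found walking in from the query's 3' end, then extended
    without gaps across the full overlap.  Sufficient for synthetic reads
    with substitution-only errors; real data should supply alignments from a
    dedicated aligner.
    """

    def __init__(self, targets: dict[str, str], k: int = 16, max_seed_tries: int = 12):
        self.k = k
        self.max_seed_tries = max_seed_tries
        self.targets = targets
        self._index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in targets.items():
            for i in range(0, len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((tid, i))

    def align(self, est_id: str, query: str) -> list[AlignmentRecord]:
        k = self.k
        if len(query) < k:
            return []
        hits: dict[tuple[str, int], tuple[int, int, int]] = {}
        tries = 0
        # seeds walking in from the 3' end, where the cleavage site anchors
        for qpos in range(len(query) - k, -1, -k):
            seed = query[qpos : qpos + k]
            candidates = self._index.get(seed)
            tries += 1
            if candidates:
                for tid, tpos in candidates:
                    diag = tpos - qpos
                    if (tid, diag) in hits:
                        continue
                    hits[(tid, diag)] = self._extend(query, tid, diag)
                break
            if tries >= self.max_seed_tries:
                break
        records = []
        for (tid, diag), (matches, t_start, t_end) in hits.items():
            span = t_end - t_start
            if span <= 0:
                continue
            records.append(
                AlignmentRecord(
                    est_id=est_id,
                    target_id=tid,
                    target_kind="gene",
                    percent_identity=matches / span,
                    target_start=t_start,
                    target_end=t_end,
                )
            )
        return records

    def _extend(self, query: str, tid: str, diag: int) -> tuple[int, int, int]:
        target = self.targets[tid]
        q_start = max(0, -diag)
        q_end = min(len(query), len(target) - diag)
        matches = 0
        for q in range(q_start, q_end):
            if query[q] == target[q + diag]:
                matches += 1
        return matches, q_start + diag, q_end + diag


def read_est_fasta(paths: dict[str, str | Path] | Sequence[str | Path]) -> list[EstRecord]:
    """Load ESTs from per-stage FASTA files.

    Accepts a mapping stage -> path, or a sequence of paths whose record ids
    encode the stage as ``<gene>|<stage>|<serial>``.
    """
    records: list[EstRecord] = []
    if isinstance(paths, dict):
        items = [(stage, Path(p)) for stage, p in paths.items()]
        for stage, path in items:
            for rec in SeqIO.parse(str(path), "fasta"):
                records.append(EstRecord(id=rec.id, sequence=str(rec.seq).upper(), stage=stage))
    else:
        for path in paths:
            for rec in SeqIO.parse(str(path), "fasta"):
                parts = rec.id.split("|")
                require(len(parts) >= 2, f"record id {rec.id} does not encode a stage")
                records.append(
                    EstRecord(id=rec.id, sequence=str(rec.seq).upper(), stage=parts[1])
                )
    return records


def read_alignment_tsv(path: str | Path) -> dict[str, list[AlignmentRecord]]:
    """Read alignments from TSV (est_id, target_id, target_kind,
    percent_identity, downstream_distance, target_start, target_end)."""
    df = pd.read_csv(path, sep="\t", dtype={"est_id": str, "target_id": str})
    out: dict[str, list[AlignmentRecord]] = {}
    for row in df.itertuples(index=False):
        rec = AlignmentRecord(
            est_id=row.est_id,
            target_id=row.target_id,
            target_kind=row.target_kind,
            percent_identity=float(row.percent_identity),
            downstream_distance=int(row.downstream_distance),
            target_start=int(row.target_start),
            target_end=int(row.target_end),
        )
        out.setdefault(rec.est_id, []).append(rec)
    return out


def write_alignment_tsv(
    alignments_by_est: dict[str, list[AlignmentRecord]], path: str | Path
) -> None:
    rows = []
    for est_id in sorted(alignments_by_est):
        for a in alignments_by_est[est_id]:
            rows.append(
                (
                    a.est_id,
                    a.target_id,
                    a.target_kind,
                    a.percent_identity,
                    a.downstream_distance,
                    a.target_start,
                    a.target_end,
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "est_id",
            "target_id",
            "target_kind",
            "percent_identity",
            "downstream_distance",
            "target_start",
            "target_end",
        ],
    ).to_csv(path, sep="\t", index=False)
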