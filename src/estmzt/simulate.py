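"""Ground-truth generator for staged 3'-end EST libraries.

Builds a toy genome of single-gene contigs, assigns each gene a transcript
class (degrading / stable / activating / unclassified), draws class-
consistent stage abundance profiles, plants 3'UTR isoforms with known
cleavage sites and polyadenylation hexamers, and synthesizes 3'-anchored
EST reads (CDS tail + 3'UTR + poly-A) with substitution errors.  Every
random quantity is recorded in a TruthTable so downstream inference can be
scored exactly.

Design guarantees that make truth recoverable at error_rate = 0:

* class-conditional stage profiles are rejection-sampled until they satisfy
  the strict classification rule for their class;
* the three bases immediately upstream of every cleavage site are forced
  non-A, so tail detection (max one mismatch) stops exactly at the site;
* catalogue hexamers are scrubbed from the background UTR sequence before
  motif insertion, so scanned presence equals inserted truth;
* distinct cleavage sites of one gene are at least 30 nt apart — above the
  default isoform-clustering tolerance — and each isoform owns an exclusive
  sequence region for its motif insertions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from estmzt.core import STAGES, ValidationError, require
from estmzt.est import EstRecord, reverse_complement
from estmzt.motifs import DEFAULT_CATALOGUE
from estmzt.utr import GeneModel

__all__ = [
    "SimConfig",
    "TruthTable",
    "SimulatedDataset",
    "generate_gene_models",
    "simulate_stage_profiles",
    "sample_counts",
    "synthesize_ests",
    "simulate_dataset",
    "synthesize_qpcr",
]

GENE_CLASSES = ("degrading", "stable", "activating", "unclassified")

_BASES = np.array(list("ACGT"))
_NON_A = np.array(list("CGT"))

#: Dirichlet concentration parameters per class; draws are rejected until
#: they satisfy the strict rule for the class (unclassified draws are flat).
_CLASS_DIRICHLET: dict[str, tuple[float, float, float, float]] = {
    "degrading": (5.0, 5.0, 2.5, 0.08),
    "activating": (0.08, 0.08, 2.5, 5.0),
    "stable": (12.0, 12.0, 12.0, 12.0),
    "unclassified": (1.0, 1.0, 1.0, 1.0),
}


def _default_utr_length_params() -> dict[str, tuple[float, float]]:
    # (median bp, log-space sigma); medians echo observed class means
    return {
        "degrading": (180.0, 0.45),
        "stable": (210.0, 0.45),
        "activating": (75.0, 0.45),
        "unclassified": (150.0, 0.50),
    }


def _default_isoform_prob() -> dict[str, float]:
    return {
        "degrading": 0.457,
        "stable": 0.346,
        "activating": 0.154,
        "unclassified": 0.25,
    }


def _default_motif_probs() -> dict[str, dict[str, float]]:
    canonical = {
        "degrading": 0.688,
        "stable": 0.829,
        "activating": 0.956,
        "unclassified": 0.80,
    }
    alternative = {
        "degrading": 0.06,
        "stable": 0.09,
        "activating": 0.025,
        "unclassified": 0.05,
    }
    probs: dict[str, dict[str, float]] = {}
    for cls in GENE_CLASSES:
        probs[cls] = {
            motif: canonical[cls] if motif == "AATAAA" else alternative[cls]
            for motif in DEFAULT_CATALOGUE
        }
    return probs


@dataclass
class SimConfig:
    """Generator parameters; defaults emulate the study's four-library design."""

    n_genes: int = 300
    n_mito_genes: int = 10
    class_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "degrading": 0.18,
            "stable": 0.14,
            "activating": 0.20,
            "unclassified": 0.48,
        }
    )
    library_sizes: tuple[int, int, int, int] = (1000, 1000, 1000, 1000)
    utr_length_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_utr_length_params
    )
    isoform_prob: dict[str, float] = field(default_factory=_default_isoform_prob)
    motif_probs: dict[str, dict[str, float]] = field(default_factory=_default_motif_probs)
    polya_len_params: tuple[int, int] = (15, 60)
    error_rate: float = 0.005
    tail_errors: bool = False
    seed: int = 0
    # sequence geometry
    cds_length: int = 150
    read_length: int = 400
    min_utr_len: int = 20
    min_site_gap: int = 30
    downstream_len: int = 100
    flank_len: int = 50
    # abundance model: per-gene weights ~ LogNormal(0, abundance_sigma);
    # EST libraries are heavily skewed (roughly half of all detected genes
    # are singletons), and mitochondrial genes are strongly over-represented
    mito_weight_multiplier: float = 25.0
    abundance_sigma: float = 2.0

    def __post_init__(self) -> None:
        require(self.n_genes >= 1, "SimConfig.n_genes must be >= 1")
        require(
            0 <= self.n_mito_genes <= self.n_genes,
            "SimConfig.n_mito_genes must be in [0, n_genes]",
        )
        require(
            set(self.class_mixture) == set(GENE_CLASSES),
            f"SimConfig.class_mixture must cover {GENE_CLASSES}",
        )
        require(
            abs(sum(self.class_mixture.values()) - 1.0) <= 1e-9,
            "SimConfig.class_mixture must sum to 1",
        )
        require(
            all(v >= 0 for v in self.class_mixture.values()),
            "SimConfig.class_mixture entries must be >= 0",
        )
        require(len(self.library_sizes) == 4, "SimConfig.library_sizes needs 4 entries")
        require(
            all(s >= 1 for s in self.library_sizes),
            "SimConfig.library_sizes must all be >= 1",
        )
        require(0.0 <= self.error_rate <= 0.1, "SimConfig.error_rate must be in [0, 0.1]")
        lo, hi = self.polya_len_params
        require(1 <= lo <= hi, "SimConfig.polya_len_params must satisfy 1 <= min <= max")
        for cls in GENE_CLASSES:
            require(cls in self.utr_length_params, f"SimConfig.utr_length_params missing {cls}")
            require(
                0.0 <= self.isoform_prob.get(cls, -1) <= 1.0,
                f"SimConfig.isoform_prob[{cls}] must be in [0, 1]",
            )
            for motif, p in self.motif_probs.get(cls, {}).items():
                require(0.0 <= p <= 1.0, f"SimConfig.motif_probs[{cls}][{motif}] must be in [0,1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthTable:
    """Per-gene and per-isoform ground truth.

    ``genes``: gene_id-indexed frame with transcript_class, is_mito, weight
    and (after profile simulation) p_oocyte..p_gastrula.
    ``isoforms``: one row per cleavage site: gene_id, isoform_index, site,
    utr_length, motifs (comma-joined hexamers actually inserted).
    ``counts``: genes x stages true sampled EST counts (after count sampling).
    """

    genes: pd.DataFrame
    isoforms: pd.DataFrame
    counts: pd.DataFrame | None = None

    def stage_proportions(self, gene_id: str) -> tuple[float, float, float, float]:
        row = self.genes.loc[gene_id]
        return tuple(float(row[f"p_{s}"]) for s in STAGES)  # type: ignore[return-value]

    def to_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genes.reset_index(names="gene_id").to_csv(
            out / "truth_genes.tsv", sep="\t", index=False
        )
        self.isoforms.to_csv(out / "truth_isoforms.tsv", sep="\t", index=False)
        if self.counts is not None:
            counts = self.counts.reset_index(names="gene_id")
            counts.to_csv(out / "truth_counts.tsv", sep="\t", index=False)


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: dict[str, str]
    models: dict[str, GeneModel]
    truth: TruthTable
    ests: list[EstRecord]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.truth.to_dir(out)
        with open(out / "genome.fasta", "w") as fh:
            for contig in sorted(self.genome):
                fh.write(f">{contig}\n{self.genome[contig]}\n")
        with open(out / "targets.fasta", "w") as fh:
            for gene_id in sorted(self.models):
                fh.write(f">{gene_id}\n{self.models[gene_id].transcript_seq}\n")
        write_gene_models_gff3(self.models, self.truth, out / "genes.gff3")
        models_df = pd.DataFrame(
            [
                (m.gene_id, m.contig, m.strand, m.cds_end, int(m.is_mito))
                for m in (self.models[g] for g in sorted(self.models))
            ],
            columns=["gene_id", "contig", "strand", "cds_end", "is_mito"],
        )
        models_df.to_csv(out / "models.tsv", sep="\t", index=False)
        for stage in STAGES:
            with open(out / f"ests_{stage}.fasta", "w") as fh:
                for rec in self.ests:
                    if rec.stage == stage:
                        fh.write(f">{rec.id}\n{rec.sequence}\n")


def _largest_remainder_allocation(n: int, mixture: dict[str, float]) -> list[str]:
    """Deterministic class counts matching the mixture as closely as possible."""
    raw = {cls: n * mixture[cls] for cls in GENE_CLASSES}
    alloc = {cls: int(math.floor(raw[cls])) for cls in GENE_CLASSES}
    remainder = n - sum(alloc.values())
    by_frac = sorted(GENE_CLASSES, key=lambda c: (raw[c] - alloc[c]), reverse=True)
    for cls in by_frac[:remainder]:
        alloc[cls] += 1
    labels: list[str] = []
    for cls in GENE_CLASSES:
        labels.extend([cls] * alloc[cls])
    return labels


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _scrub_motifs(seq: list[str], start: int, end: int,
                  protected: set[int], rng: np.random.Generator) -> None:
    """Remove accidental catalogue hexamers from seq[start:end] in place.

    Replacement bases are non-A and never touch protected positions; loops
    until clean (caps at 50 passes, which is never reached in practice).
    """
    text = "".join(seq)
    for _ in range(50):
        dirty = False
        for motif in DEFAULT_CATALOGUE:
            pos = text.find(motif, start)
            while pos != -1 and pos + 6 <= end:
                editable = [i for i in range(pos, pos + 6) if i not in protected]
                # pick an (index, base) whose edit leaves the focal window
                # matching no catalogue hexamer (a single fixed position can
                # cycle between catalogue variants, e.g. AATAxA)
                candidates = [
                    (i, b) for i in editable for b in "CGT" if b != seq[i]
                ]
                rng.shuffle(candidates)  # type: ignore[arg-type]
                for idx, base in candidates:
                    previous = seq[idx]
                    seq[idx] = base
                    window = "".join(seq[pos : pos + 6])
                    if window not in DEFAULT_CATALOGUE:
                        dirty = True
                        break
                    seq[idx] = previous
                pos = text.find(motif, pos + 1)
        if not dirty:
            return
        text = "".join(seq)


def generate_gene_models(
    config: SimConfig,
) -> tuple[dict[str, str], dict[str, GeneModel], TruthTable]:
    """Build the toy genome, per-gene models and the truth-table skeleton.

    Each gene sits on its own contig with flanking sequence, a CDS ending in
    a stop codon, one or more cleavage sites downstream of it, and extra
    downstream sequence.  Deterministic for a fixed config (seed included).
    """
    rng = config.rng(0)
    width = len(str(config.n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]

    labels = _largest_remainder_allocation(config.n_genes, config.class_mixture)
    rng.shuffle(labels)  # type: ignore[arg-type]
    mito_idx = set(rng.choice(config.n_genes, size=config.n_mito_genes, replace=False).tolist())
    # mitochondrial transcripts are maternally deposited: their stage
    # profiles are maternal-heavy (degrading or stable), which reproduces
    # the high mitochondrial share of maternal-stage libraries
    for i in mito_idx:
        labels[i] = "degrading" if rng.random() < 0.5 else "stable"

    weights = np.exp(rng.normal(0.0, config.abundance_sigma, size=config.n_genes))
    for i in range(config.n_genes):
        if i in mito_idx:
            weights[i] *= config.mito_weight_multiplier

    genome: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    gene_rows = []
    iso_rows = []
    for i, gene_id in enumerate(gene_ids):
        cls = labels[i]
        is_mito = i in mito_idx
        median, sigma = config.utr_length_params[cls]
        n_iso = 2 if rng.random() < config.isoform_prob[cls] else 1
        lengths = np.exp(rng.normal(math.log(median), sigma, size=n_iso))
        lengths = np.maximum(np.round(lengths).astype(int), config.min_utr_len)
        lengths = np.sort(lengths)
        for j in range(1, n_iso):
            lengths[j] = max(lengths[j], lengths[j - 1] + config.min_site_gap)

        cds_end = config.cds_length
        sites = [cds_end + int(length) for length in lengths]
        max_site = sites[-1]
        transcript = list(
            _random_seq(rng, cds_end - 3) + "TAA" + _random_seq(rng, max_site - cds_end)
        )
        # fixed non-A bases just upstream of every cleavage site keep the
        # poly-A tail from extending into the UTR during detection
        protected: set[int] = set()
        for site in sites:
            for pos in range(site - 3, site):
                transcript[pos] = _NON_A[int(rng.integers(3))]
                protected.add(pos)
        _scrub_motifs(transcript, cds_end, max_site, protected, rng)

        # Motif truth is per gene: all sampled hexamers are inserted inside
        # the proximal isoform's region so every isoform's UTR sequence
        # carries exactly the sampled motif set (a longer isoform's sequence
        # is a superset of the shorter one's, so per-isoform independent
        # insertion would inflate observed prevalence above the configured
        # probability).
        motif_probs = config.motif_probs[cls]
        occupied: list[tuple[int, int]] = [(p, p + 1) for p in protected]
        region_start, region_end = cds_end, sites[0] - 4
        inserted: list[str] = []
        for motif in DEFAULT_CATALOGUE:
            p = motif_probs.get(motif, 0.0)
            if rng.random() >= p:
                continue
            placed = False
            if motif == "AATAAA":
                # canonical signal sits a characteristic 18-30 nt upstream
                # of the (proximal) cleavage site when space allows
                preferred = sites[0] - int(rng.integers(18, 31)) - 6
                candidates: list[int | None] = [preferred] + [None] * 29
            else:
                candidates = [None] * 30
            for cand in candidates:
                if cand is None:
                    if region_end - 6 < region_start:
                        break
                    cand = int(rng.integers(region_start, region_end - 6 + 1))
                if cand < region_start or cand + 6 > region_end:
                    continue
                if any(cand < e and cand + 6 > s for s, e in occupied):
                    continue
                transcript[cand : cand + 6] = list(motif)
                occupied.append((cand, cand + 6))
                placed = True
                break
            if placed:
                inserted.append(motif)
        # insertion boundaries can create accidental catalogue hexamers;
        # scrub them while protecting the deliberately inserted motifs
        inserted_positions = {
            pos for s, e in occupied for pos in range(s, e)
        }
        _scrub_motifs(transcript, cds_end, max_site, protected | inserted_positions, rng)
        for j, site in enumerate(sites):
            iso_rows.append(
                {
                    "gene_id": gene_id,
                    "isoform_index": j,
                    "site": site,
                    "utr_length": site - cds_end,
                    "motifs": ",".join(inserted),
                }
            )

        transcript_seq = "".join(transcript) + _random_seq(rng, config.downstream_len)
        strand = "+" if rng.random() < 0.5 else "-"
        contig_id = f"contig_{gene_id}"
        oriented = transcript_seq if strand == "+" else reverse_complement(transcript_seq)
        contig_seq = (
            _random_seq(rng, config.flank_len) + oriented + _random_seq(rng, config.flank_len)
        )
        genome[contig_id] = contig_seq
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            contig=contig_id,
            strand=strand,
            cds_end=cds_end,
            transcript_seq=transcript_seq,
            is_mito=is_mito,
            contig_offset=config.flank_len,
        )
        gene_rows.append(
            {
                "gene_id": gene_id,
                "transcript_class": cls,
                "is_mito": is_mito,
                "weight": float(weights[i]),
                "n_isoforms": n_iso,
                "sites": ",".join(str(s) for s in sites),
                "motifs": ",".join(inserted),
            }
        )

    genes_df = pd.DataFrame(gene_rows).set_index("gene_id")
    iso_df = pd.DataFrame(iso_rows)
    return genome, models, TruthTable(genes=genes_df, isoforms=iso_df)


def _strict_rule_holds(p: np.ndarray, cls: str) -> bool:
    """True when the profile satisfies the strict rule for ``cls`` and for no
    other class, so the truth label is uniquely recoverable from the profile.

    Degrading and activating overlap on blastula-dominated profiles (both
    the >=95% maternal and >=95% blastula+gastrula criteria hold); such
    draws would classify as ambiguous, so they are rejected for labelled
    classes.  Stable is mutually exclusive with both by construction.
    """
    po, pc, pb, pg = p
    degrading = (po + pc + pb) >= 0.95 and pg <= 0.05
    activating = (pb + pg) >= 0.95
    if cls == "degrading":
        return degrading and not activating
    if cls == "activating":
        return activating and not degrading
    if cls == "stable":
        return bool(np.all(p >= 0.10) and np.all(p <= 0.40))
    return True


def simulate_stage_profiles(config: SimConfig, truth: TruthTable) -> TruthTable:
    """Draw class-consistent stage proportions for every gene.

    Rejection-samples from class-specific Dirichlet priors until the strict
    classification rule holds for the gene's class; after 1000 rejections
    the concentration parameters are scaled up (toward their mean) and
    sampling continues.  Unclassified genes draw from a flat Dirichlet.
    """
    rng = config.rng(1)
    props = np.zeros((len(truth.genes), 4))
    for row_idx, (gene_id, row) in enumerate(truth.genes.iterrows()):
        cls = row["transcript_class"]
        alpha = np.asarray(_CLASS_DIRICHLET[cls], dtype=float)
        tries = 0
        while True:
            p = rng.dirichlet(alpha)
            if _strict_rule_holds(p, cls):
                break
            tries += 1
            if tries % 1000 == 0:
                alpha = alpha * 1.5
        props[row_idx] = p
    genes = truth.genes.copy()
    for k, stage in enumerate(STAGES):
        genes[f"p_{stage}"] = props[:, k]
    return TruthTable(genes=genes, isoforms=truth.isoforms, counts=truth.counts)


def sample_counts(config: SimConfig, truth: TruthTable) -> TruthTable:
    """Multinomial per-stage EST counts: gene probability proportional to
    abundance weight times the gene's stage proportion."""
    rng = config.rng(2)
    genes = truth.genes
    require("p_oocyte" in genes.columns, "stage profiles must be simulated first")
    weights = genes["weight"].to_numpy()
    counts = np.zeros((len(genes), 4), dtype=np.int64)
    for k, stage in enumerate(STAGES):
        mass = weights * genes[f"p_{stage}"].to_numpy()
        if mass.sum() == 0:  # no gene expressed in this stage
            continue
        prob = mass / mass.sum()
        counts[:, k] = rng.multinomial(config.library_sizes[k], prob)
    counts_df = pd.DataFrame(counts, index=genes.index, columns=list(STAGES))
    return TruthTable(genes=genes, isoforms=truth.isoforms, counts=counts_df)


def synthesize_ests(
    config: SimConfig,
    models: dict[str, GeneModel],
    truth: TruthTable,
) -> list[EstRecord]:
    """Generate 3'-anchored EST reads for the sampled per-stage counts.

    Each read covers up to ``read_length`` nt of transcript upstream of a
    (uniformly chosen) cleavage site, gets substitution errors at
    ``error_rate`` in the body, and ends in an error-free poly-A tail of
    uniform length within ``polya_len_params`` (tail errors only when
    ``tail_errors`` is set).  Stage and gene are encoded in the record id.
    """
    require(truth.counts is not None, "counts must be sampled before synthesizing ESTs")
    rng = config.rng(3)
    lo, hi = config.polya_len_params
    records: list[EstRecord] = []
    sites_by_gene = {
        gene_id: [int(s) for s in str(row["sites"]).split(",")]
        for gene_id, row in truth.genes.iterrows()
    }
    for stage in STAGES:
        serial = 0
        for gene_id in truth.counts.index:  # type: ignore[union-attr]
            n = int(truth.counts.loc[gene_id, stage])  # type: ignore[union-attr]
            if n == 0:
                continue
            transcript = models[gene_id].transcript_seq or ""
            sites = sites_by_gene[gene_id]
            for _ in range(n):
                site = sites[int(rng.integers(len(sites)))]
                body = transcript[max(0, site - config.read_length) : site]
                if config.error_rate > 0:
                    arr = np.array(list(body))
                    hit = rng.random(arr.size) < config.error_rate
                    for pos in np.nonzero(hit)[0]:
                        choices = [b for b in "ACGT" if b != arr[pos]]
                        arr[pos] = choices[int(rng.integers(3))]
                    body = "".join(arr)
                tail_len = int(rng.integers(lo, hi + 1))
                tail = "A" * tail_len
                if config.tail_errors and config.error_rate > 0:
                    arr = np.array(list(tail))
                    hit = rng.random(arr.size) < config.error_rate
                    for pos in np.nonzero(hit)[0]:
                        arr[pos] = "CGT"[int(rng.integers(3))]
                    tail = "".join(arr)
                records.append(
                    EstRecord(
                        id=f"{gene_id}|{stage}|{serial:06d}",
                        sequence=body + tail,
                        stage=stage,
                    )
                )
                serial += 1
    return records


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full generator pipeline: models, profiles, counts, EST reads."""
    genome, models, truth = generate_gene_models(config)
    truth = simulate_stage_profiles(config, truth)
    truth = sample_counts(config, truth)
    ests = synthesize_ests(config, models, truth)
    return SimulatedDataset(config=config, genome=genome, models=models, truth=truth, ests=ests)


def synthesize_qpcr(
    truth: TruthTable,
    gene_ids: Sequence[str],
    rng: np.random.Generator,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.25,
    spike_noise_sd: float = 0.15,
    base_ct: float = 22.0,
    spike_ct: float = 18.0,
    detection_floor: float = 1e-3,
    spike_gene_id: str = "hba_spike",
) -> pd.DataFrame:
    """Emulate spike-in qPCR of the true stage profiles.

    Gene Ct follows -log2 of the gene's true stage proportion (floored at a
    detection limit) plus replicate noise; the spiked reference sits at a
    constant Ct with smaller noise.  Returns a table compatible with
    :class:`estmzt.qpcr.QpcrTable`.
    """
    rows = []
    for stage in STAGES:
        for rep in range(n_replicates):
            rows.append(
                {
                    "gene_id": spike_gene_id,
                    "stage": stage,
                    "replicate": rep,
                    "ct": spike_ct + rng.normal(0.0, spike_noise_sd),
                }
            )
    for gene_id in gene_ids:
        p = truth.stage_proportions(gene_id)
        for k, stage in enumerate(STAGES):
            level = max(p[k], detection_floor)
            for rep in range(n_replicates):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "stage": stage,
                        "replicate": rep,
                        "ct": base_ct - math.log2(level) + rng.normal(0.0, ct_noise_sd),
                    }
                )
    return pd.DataFrame(rows)


def write_gene_models_gff3(
    models: dict[str, GeneModel], truth: TruthTable, path: str | Path
) -> None:
    """Gene models as GFF3 (gene, CDS and three_prime_UTR features).

    Internal coordinates are 0-based half-open in transcript orientation;
    GFF3 output is 1-based inclusive on the forward strand of each contig.
    """
    max_site = truth.isoforms.groupby("gene_id")["site"].max().to_dict()
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id in sorted(models):
            m = models[gene_id]
            t_len = len(m.transcript_seq or "")
            off = m.contig_offset

            def to_contig(t_start: int, t_end: int) -> tuple[int, int]:
                # transcript interval [t_start, t_end) -> 1-based contig interval
                if m.strand == "+":
                    return off + t_start + 1, off + t_end
                return off + t_len - t_end + 1, off + t_len - t_start

            utr_end = int(max_site.get(gene_id, m.cds_end))
            gs, ge = to_contig(0, t_len)
            cs, ce = to_contig(0, m.cds_end)
            us, ue = to_contig(m.cds_end, utr_end)
            attrs = f"ID={gene_id};is_mito={int(m.is_mito)}"
            fh.write(
                f"{m.contig}\testmzt\tgene\t{gs}\t{ge}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{m.contig}\testmzt\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t0\tParent={gene_id}\n"
            )
            if utr_end > m.cds_end:
                fh.write(
                    f"{m.contig}\testmzt\tthree_prime_UTR\t{us}\t{ue}\t.\t{m.strand}\t.\t"
                    f"Parent={gene_id}\n"
                )
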