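"""Spike-in normalized comparative-Ct qPCR and EST/qPCR concordance.

Each RNA sample receives a fixed amount of foreign rabbit alpha-hemoglobin
(hba) mRNA before cDNA synthesis, sidestepping unstable endogenous reference
genes: per replicate, dCt = Ct_gene - Ct_spike, and relative quantity per
stage is 2^-(mean dCt - calibrator dCt) with the calibrator being the stage
of lowest mean dCt (so its quantity is exactly 1).  Amplification efficiency
comes from a standard-curve dilution series.  Concordance between a gene's
four-stage EST count profile and its qPCR profile (Spearman by default)
quantifies how reliable low-copy EST profiles are, supporting the choice of
a copy-number threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr, spearmanr

from estmzt.core import STAGES, ValidationError, require

__all__ = [
    "QpcrTable",
    "StandardCurve",
    "RelativeExpression",
    "amplification_efficiency",
    "relative_expression",
    "est_qpcr_concordance",
    "threshold_analysis",
]


@dataclass
class QpcrTable:
    """Replicate Ct values: rows (gene_id, stage, replicate, ct)."""

    data: pd.DataFrame
    spike_gene_id: str

    def __post_init__(self) -> None:
        needed = {"gene_id", "stage", "replicate", "ct"}
        require(needed <= set(self.data.columns), f"qPCR table needs columns {sorted(needed)}")
        require((self.data["ct"] > 0).all(), "all Ct values must be > 0")
        spike = self.data[self.data["gene_id"] == self.spike_gene_id]
        require(not spike.empty, f"spike gene {self.spike_gene_id!r} absent from table")

    @classmethod
    def from_csv(cls, path: str | Path, spike_gene_id: str) -> "QpcrTable":
        return cls(data=pd.read_csv(path, dtype={"gene_id": str, "stage": str}),
                   spike_gene_id=spike_gene_id)

    def genes(self) -> list[str]:
        return sorted(g for g in self.data["gene_id"].unique() if g != self.spike_gene_id)


@dataclass
class StandardCurve:
    """Dilution series of (input amount in ng, Ct) pairs."""

    amounts_ng: Sequence[float]
    cts: Sequence[float]

    def __post_init__(self) -> None:
        require(len(self.amounts_ng) == len(self.cts), "amounts and Cts must align")
        require(len(set(self.amounts_ng)) >= 3, "need >= 3 distinct input amounts")
        require(all(a > 0 for a in self.amounts_ng), "amounts must be > 0")


@dataclass
class RelativeExpression:
    gene_id: str
    calibrator_stage: str
    mean_dct: dict[str, float]
    quantity: dict[str, float]
    sem: dict[str, float]
    n_replicates: dict[str, int]


def amplification_efficiency(curve: StandardCurve) -> dict:
    """Efficiency from the standard-curve slope: E = 10^(-1/slope) - 1.

    A slope of -3.3219 (= -1/log10(2)) corresponds to perfect doubling,
    i.e. 100% efficiency.  Returns slope, intercept, R^2 and E.
    """
    x = np.log10(np.asarray(curve.amounts_ng, dtype=float))
    y = np.asarray(curve.cts, dtype=float)
    fit = linregress(x, y)
    if fit.slope == 0:
        raise ValidationError("standard curve slope is zero; efficiency undefined")
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "efficiency": float(efficiency),
    }


def relative_expression(table: QpcrTable, gene_id: str) -> RelativeExpression:
    """Comparative-Ct relative quantities for one gene across stages.

    dCt is computed per replicate (gene and spike paired by replicate index
    within a stage; unpaired replicates are dropped with a warning); the
    calibrator is the stage with the lowest mean dCt and the quantity for a
    stage is 2^-(mean dCt - calibrator dCt).  SEM is propagated from the
    replicate dCt spread via the delta method: sem(q) = q * ln2 * sem(dCt).
    """
    df = table.data
    gene_rows = df[df["gene_id"] == gene_id]
    require(not gene_rows.empty, f"gene {gene_id!r} absent from qPCR table")
    spike_rows = df[df["gene_id"] == table.spike_gene_id]

    mean_dct: dict[str, float] = {}
    sem_dct: dict[str, float] = {}
    n_reps: dict[str, int] = {}
    for stage in STAGES:
        g = gene_rows[gene_rows["stage"] == stage].set_index("replicate")["ct"]
        s = spike_rows[spike_rows["stage"] == stage].set_index("replicate")["ct"]
        if g.empty:
            continue
        if s.empty:
            warnings.warn(f"gene {gene_id}: spike missing in stage {stage}; stage dropped")
            continue
        common = g.index.intersection(s.index)
        if len(common) < len(g):
            warnings.warn(
                f"gene {gene_id}, stage {stage}: {len(g) - len(common)} unpaired "
                "replicate(s) dropped"
            )
        if len(common) == 0:
            continue
        dct = (g.loc[common] - s.loc[common]).to_numpy(dtype=float)
        mean_dct[stage] = float(dct.mean())
        sem_dct[stage] = float(dct.std(ddof=1) / math.sqrt(len(dct))) if len(dct) > 1 else 0.0
        n_reps[stage] = int(len(dct))
    require(len(mean_dct) >= 1, f"gene {gene_id!r}: no stage with paired gene and spike Cts")

    calibrator = min(mean_dct, key=lambda s: (mean_dct[s], STAGES.index(s)))
    cal_dct = mean_dct[calibrator]
    quantity = {s: 2.0 ** (-(m - cal_dct)) for s, m in mean_dct.items()}
    sem_q = {s: quantity[s] * math.log(2.0) * sem_dct[s] for s in mean_dct}
    return RelativeExpression(
        gene_id=gene_id,
        calibrator_stage=calibrator,
        mean_dct=mean_dct,
        quantity=quantity,
        sem=sem_q,
        n_replicates=n_reps,
    )


def est_qpcr_concordance(
    counts: Sequence[int],
    expression: RelativeExpression | Sequence[float],
    method: str = "spearman",
) -> float | None:
    """Rank correlation between a 4-stage EST count profile and qPCR quantities.

    Returns None (undefined) when either profile is constant — a flat
    profile carries no ranking information and must not masquerade as
    zero correlation.  With only four stages the coefficient is coarse;
    ``method="pearson"`` is available.
    """
    require(len(counts) == 4, "need 4 stage counts")
    if isinstance(expression, RelativeExpression):
        require(
            set(expression.quantity) == set(STAGES),
            "expression must cover the same 4 stages as the count profile",
        )
        quantities = [expression.quantity[s] for s in STAGES]
    else:
        quantities = list(expression)
        require(len(quantities) == 4, "need 4 stage quantities")
    x = np.asarray(counts, dtype=float)
    y = np.asarray(quantities, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    if method == "spearman":
        rho = spearmanr(x, y).statistic
    elif method == "pearson":
        rho = pearsonr(x, y).statistic
    else:
        raise ValidationError(f"unknown concordance method {method!r}")
    return float(rho)


def threshold_analysis(
    gene_scores: Sequence[tuple[int, float | None]],
    thresholds: Sequence[int] = (5, 9, 12),
) -> pd.DataFrame:
    """Median EST/qPCR concordance above and below candidate copy-number thresholds.

    ``gene_scores`` pairs each gene's total EST count with its concordance
    score (None scores are excluded).  The table supports — it does not
    automate — the choice of a reliability threshold.
    """
    defined = [(t, s) for t, s in gene_scores if s is not None]
    require(len(defined) >= 1, "need at least one gene with a defined concordance score")
    rows = []
    for thr in thresholds:
        above = [s for t, s in defined if t >= thr]
        below = [s for t, s in defined if t < thr]
        rows.append(
            {
                "threshold": thr,
                "n_above": len(above),
                "median_above": float(np.median(above)) if above else float("nan"),
                "n_below": len(below),
                "median_below": float(np.median(below)) if below else float("nan"),
            }
        )
    return pd.DataFrame(rows)
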