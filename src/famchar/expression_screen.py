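"""Expression-rule screening over FPKM matrices and qPCR relative expression.

Rules: FPKM strictly greater than the threshold (default 1.0) counts as
effective expression; fold changes use a pseudocount; clustering is average-
linkage hierarchical clustering on 1 - Pearson correlation of log2 profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionMatrix",
    "QpcrMeasurement",
    "ScreenResult",
    "effective_expression",
    "tissue_specificity",
    "fold_change_screen",
    "cluster_profiles",
    "relative_expression",
    "aggregate_ct",
]

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.1


@dataclass
class ExpressionMatrix:
    """Genes x conditions FPKM values with optional condition metadata."""

    values: pd.DataFrame
    condition_meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if df.columns.has_duplicates:
            raise ValueError("duplicate condition ids in expression matrix")
        if (df.values < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.astype(float))

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def effective_expression(
    m: ExpressionMatrix, threshold: float = 1.0
) -> pd.DataFrame:
    """Boolean matrix: entry True iff FPKM > threshold (strict)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return m.values > threshold


def tissue_specificity(
    m: ExpressionMatrix, threshold: float = 1.0
) -> pd.Series:
    """Per-gene category over tissue columns.

    ``all_tissues`` when expressed everywhere, ``single:<tissue>`` when in
    exactly one, ``none`` when nowhere, else ``k_of_n``.
    """
    if len(m.conditions) < 2:
        raise ValueError("tissue specificity needs at least 2 tissues")
    expressed = effective_expression(m, threshold)
    n = expressed.shape[1]
    out = {}
    for gene, row in expressed.iterrows():
        k = int(row.sum())
        if k == n:
            out[gene] = "all_tissues"
        elif k == 0:
            out[gene] = "none"
        elif k == 1:
            out[gene] = f"single:{row.index[row.argmax()]}"
        else:
            out[gene] = f"{k}_of_{n}"
    return pd.Series(out, name="tissue_specificity").reindex(m.genes)


@dataclass(frozen=True)
class ScreenResult:
    gene: str
    direction: str  # "up" | "down"
    max_abs_fold_change: float
    conditions_passing: tuple[str, ...]
    in_band: bool  # max fold within [min_fc, max_fc]

    def __post_init__(self) -> None:
        if self.direction not in {"up", "down"}:
            raise ValueError("direction must be 'up' or 'down'")
        if self.max_abs_fold_change < 1.0:
            raise ValueError("max_abs_fold_change must be >= 1")


def fold_change_screen(
    m: ExpressionMatrix,
    control_condition: str,
    min_fc: float = 2.0,
    max_fc: float = 5.0,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
    expression_threshold: float = 1.0,
) -> list[ScreenResult]:
    """Select genes whose fold change vs the control reaches ``min_fc`` in
    either direction in at least one treated condition.

    FC = (FPKM + pseudo) / (FPKM_control + pseudo). Direction is decided by
    the larger deviation; a gene must additionally be effectively expressed
    in the control or in a passing condition. Fold changes above ``max_fc``
    are still selected but flagged as outside the 2-5x band.
    """
    if control_condition not in m.conditions:
        raise ValueError(f"control condition {control_condition!r} absent")
    if pseudo <= 0:
        raise ValueError("pseudocount must be positive")
    if not (1.0 <= min_fc <= max_fc):
        raise ValueError("need 1 <= min_fc <= max_fc")
    treated = [c for c in m.conditions if c != control_condition]
    expressed = effective_expression(m, expression_threshold)
    results: list[ScreenResult] = []
    for gene in m.genes:
        control = m.values.at[gene, control_condition] + pseudo
        up: list[tuple[str, float]] = []
        down: list[tuple[str, float]] = []
        for cond in treated:
            fc = (m.values.at[gene, cond] + pseudo) / control
            if fc >= min_fc:
                up.append((cond, fc))
            elif 1.0 / fc >= min_fc:
                down.append((cond, 1.0 / fc))
        if not up and not down:
            continue
        best_up = max((f for _, f in up), default=0.0)
        best_down = max((f for _, f in down), default=0.0)
        direction = "up" if best_up >= best_down else "down"
        chosen = up if direction == "up" else down
        involved = [control_condition] + [c for c, _ in chosen]
        if not any(expressed.at[gene, c] for c in involved):
            continue
        best = max(f for _, f in chosen)
        results.append(
            ScreenResult(
                gene=gene,
                direction=direction,
                max_abs_fold_change=best,
                conditions_passing=tuple(c for c, _ in chosen),
                in_band=best <= max_fc,
            )
        )
    return results


def cluster_profiles(
    m: ExpressionMatrix,
    k: int = 4,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, int]:
    """Group genes by average-linkage hierarchical clustering with distance
    1 - Pearson correlation of log2(FPKM + pseudo) profiles.

    Constant-profile genes (undefined correlation) are assigned to the
    nearest group centroid by Euclidean distance, with a log record.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(m.genes) < k:
        raise ValueError("need at least k genes")
    log_vals = np.log2(m.values.to_numpy(dtype=float) + pseudo)
    genes = m.genes
    sd = log_vals.std(axis=1)
    variable = np.where(sd > 0)[0]
    constant = np.where(sd == 0)[0]

    groups: dict[str, int] = {}
    if len(variable) >= 2:
        sub = log_vals[variable]
        corr = np.corrcoef(sub)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2.0  # enforce exact symmetry
        kk = min(k, len(variable))
        labels = fcluster(
            linkage(squareform(dist, checks=False), method="average"),
            t=kk,
            criterion="maxclust",
        )
        for idx, lab in zip(variable, labels):
            groups[genes[idx]] = int(lab)
    elif len(variable) == 1:
        groups[genes[variable[0]]] = 1

    if len(constant):
        logger.warning(
            "cluster_profiles: %d constant-profile gene(s) assigned by "
            "Euclidean fallback", len(constant)
        )
        if groups:
            centroids = {
                lab: log_vals[[i for i, g in enumerate(genes)
                               if groups.get(g) == lab]].mean(axis=0)
                for lab in sorted(set(groups.values()))
            }
            for idx in constant:
                dists = {
                    lab: float(np.linalg.norm(log_vals[idx] - c))
                    for lab, c in centroids.items()
                }
                groups[genes[idx]] = min(dists, key=lambda l: (dists[l], l))
        else:
            # Everything constant: cluster on raw Euclidean distance.
            kk = min(k, len(constant))
            labels = fcluster(
                linkage(log_vals[constant], method="average"),
                t=kk,
                criterion="maxclust",
            )
            for idx, lab in zip(constant, labels):
                groups[genes[idx]] = int(lab)
    return groups


@dataclass(frozen=True)
class QpcrMeasurement:
    gene: str
    condition: str
    ct_target: float
    ct_reference: float  # reference/housekeeping gene Ct

    def __post_init__(self) -> None:
        for ct in (self.ct_target, self.ct_reference):
            if not (0.0 < ct < 50.0):
                raise ValueError("Ct values must lie in (0, 50)")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def relative_expression(
    sample: QpcrMeasurement, control: QpcrMeasurement
) -> float:
    """2^-(ddCt) relative expression of the sample vs the control."""
    if sample.gene != control.gene:
        raise ValueError(
            f"gene mismatch: {sample.gene!r} vs {control.gene!r}"
        )
    ddct = sample.delta_ct - control.delta_ct
    return 2.0 ** (-ddct)


def aggregate_ct(
    replicate_cts: Sequence[float], min_replicates: int = 3
) -> tuple[float, float]:
    """(mean, sample SD) of replicate Ct values; at least 3 required."""
    if len(replicate_cts) < min_replicates:
        raise ValueError(f"need >= {min_replicates} replicate Ct values")
    arr = np.asarray(replicate_cts, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))
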