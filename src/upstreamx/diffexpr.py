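"""Differential expression calling on a read-count matrix.

The stage normalizes libraries by median-of-ratios size factors, estimates a
common negative-binomial dispersion by the method of moments, and tests each
gene with a two-sided exact conditional NB test (conditioning on the total
count of the two groups at equalized library size). Genes are then
partitioned into up / down / unchanged sets by the printed thresholds
(|logFC| > 0.7 at raw p < 0.05, strict inequalities).

The test is a self-contained substitute with the same interface and
thresholds as the common exact-test workflow for small replicated designs;
a pre-computed DEG table can be supplied downstream instead (see
``DegTable.from_frame``), which bypasses this stage entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix

logger = logging.getLogger("upstreamx")

#: pseudo-count added to group means before the log2 ratio
LOGFC_PSEUDOCOUNT = 0.5

THETA_UP = 0.7
THETA_DOWN = -0.7
ALPHA = 0.05


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    logFC: float
    p_value: float
    mean_expr: float

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")
        if not np.isfinite(self.logFC):
            raise ValueError(f"non-finite logFC for {self.gene_id}")


@dataclass
class DegTable:
    records: list[DegRecord]
    up_set: set[str] = field(default_factory=set)
    down_set: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            call = ("up" if r.gene_id in self.up_set
                    else "down" if r.gene_id in self.down_set else "none")
            rows.append({"gene_id": r.gene_id, "logFC": r.logFC,
                         "p_value": r.p_value, "mean_expr": r.mean_expr,
                         "call": call})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DegTable":
        """Build from a pre-computed table with gene_id/logFC/p_value columns
        (mean_expr optional); the caller applies thresholds afterwards."""
        records = [
            DegRecord(str(row.gene_id), float(row.logFC), float(row.p_value),
                      float(getattr(row, "mean_expr", 0.0)))
            for row in df.itertuples()
        ]
        return cls(records)


def normalize(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    The reference is the per-gene geometric mean over genes with all-positive
    counts; each sample's factor is the median ratio of its counts to the
    reference. When no gene is positive in every sample, total-count factors
    are used instead (with a warning).
    """
    mat = counts.counts.to_numpy(dtype=float)
    if (mat.sum(axis=0) <= 0).any():
        raise ValueError("every sample must have positive total count")
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        ref = np.exp(np.log(mat[all_pos]).mean(axis=1))
        factors = np.median(mat[all_pos] / ref[:, None], axis=0)
    else:
        logger.warning(
            "no gene with all-positive counts; falling back to total-count "
            "size factors"
        )
        factors = mat.sum(axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def _common_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion on normalized counts.

    Per gene and group: alpha_hat = (var - mean) / mean^2 (NB variance
    mu + alpha*mu^2); pooled as the mean over informative gene/group pairs,
    floored at 0.
    """
    ests = []
    for idx in groups:
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        ok = mu > 0
        ests.append((var[ok] - mu[ok]) / mu[ok] ** 2)
    pooled = np.concatenate(ests)
    if pooled.size == 0:
        return 0.0
    return float(max(np.mean(pooled), 0.0))


def _exact_nb_pvalue(ka: int, kb: int, n_a: int, n_b: int,
                     alpha: float) -> float:
    """Two-sided exact conditional test of equal means.

    Conditions on t = ka + kb; under the null the group-A sum follows the
    conditional law of NB(n_a*mu, alpha/n_a) against NB(n_b*mu, alpha/n_b)
    (binomial/Poisson when alpha = 0). Two-sidedness by the minimum-likelihood
    rule: p = sum of conditional probabilities <= that of the observed sum.
    """
    t = ka + kb
    if t == 0:
        return 1.0
    support = np.arange(t + 1)
    if alpha <= 0:
        # Poisson counts: conditional is Binomial(t, n_a/(n_a+n_b))
        logpmf = stats.binom.logpmf(support, t, n_a / (n_a + n_b))
    else:
        # sum of n iid NB(mu, alpha) is NB with size n/alpha
        r_a, r_b = n_a / alpha, n_b / alpha
        # conditional law ~ product of pmfs; the common p cancels
        logpmf = (stats.nbinom.logpmf(support, r_a, 0.5)
                  + stats.nbinom.logpmf(t - support, r_b, 0.5))
        logpmf -= np.logaddexp.reduce(logpmf)
    obs = logpmf[ka]
    p = float(np.exp(np.logaddexp.reduce(logpmf[logpmf <= obs + 1e-10])))
    return min(p, 1.0)


def test_de(counts: CountMatrix, condition_a: str, condition_b: str,
            ) -> DegTable:
    """Per-gene exact NB test of condition_b vs condition_a.

    logFC = log2((mean normalized count in b + c) / (mean in a + c)) with
    pseudo-count c = 0.5. Genes with zero counts everywhere are retained
    with logFC 0, p 1. Deterministic.
    """
    samples_a = counts.samples_for(condition_a)
    samples_b = counts.samples_for(condition_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    factors = normalize(counts)
    mat = counts.counts.to_numpy(dtype=float)
    norm = mat / factors.to_numpy()[None, :]

    cols = list(counts.sample_ids)
    idx_a = np.array([cols.index(s) for s in samples_a])
    idx_b = np.array([cols.index(s) for s in samples_b])
    alpha = _common_dispersion(norm, [idx_a, idx_b])

    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    logfc = np.log2((mean_b + LOGFC_PSEUDOCOUNT)
                    / (mean_a + LOGFC_PSEUDOCOUNT))

    # equalized pseudo-sums: normalized counts summed per group and rounded
    sum_a = np.rint(norm[:, idx_a].sum(axis=1)).astype(np.int64)
    sum_b = np.rint(norm[:, idx_b].sum(axis=1)).astype(np.int64)

    records = []
    n_a, n_b = len(idx_a), len(idx_b)
    for g, gene in enumerate(counts.gene_ids):
        if sum_a[g] == 0 and sum_b[g] == 0:
            records.append(DegRecord(gene, 0.0, 1.0, 0.0))
            continue
        p = _exact_nb_pvalue(int(sum_a[g]), int(sum_b[g]), n_a, n_b, alpha)
        p = min(max(p, np.finfo(float).tiny), 1.0)
        mean_expr = float((mean_a[g] + mean_b[g]) / 2)
        records.append(DegRecord(gene, float(logfc[g]), p, mean_expr))
    return DegTable(records)


def filter_degs(table: DegTable, theta_up: float = THETA_UP,
                theta_down: float = THETA_DOWN, alpha: float = ALPHA,
                ) -> tuple[set[str], set[str], set[str]]:
    """Partition genes into (up, down, unchanged) by strict thresholds."""
    if not theta_down < 0 < theta_up:
        raise ValueError("thresholds must satisfy theta_down < 0 < theta_up")
    up = {r.gene_id for r in table.records
          if r.logFC > theta_up and r.p_value < alpha}
    down = {r.gene_id for r in table.records
            if r.logFC < theta_down and r.p_value < alpha}
    no = {r.gene_id for r in table.records} - up - down
    table.up_set = up
    table.down_set = down
    return up, down, no
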