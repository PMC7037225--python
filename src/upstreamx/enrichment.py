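"""Per-motif site enrichment in Yes (differentially expressed) vs No
(background) promoter sets.

A promoter counts as "hit" for a PWM when it carries at least one accepted
site for that matrix (presence/absence; a per-kilobase site-density variant
is available behind a flag). Each motif gets a one-sided Fisher exact test
for enrichment in the Yes set, Benjamini-Hochberg adjustment across the
library, and selection at adj. p < 0.01 (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .site_scan import SiteHit

logger = logging.getLogger("upstreamx")

ADJ_P_CUTOFF = 0.01

#: sentinel fold value when the background rate is zero but Yes rate is not
FOLD_INF = float("inf")


@dataclass
class EnrichmentRecord:
    pwm_name: str
    yes_hit: int
    yes_total: int
    no_hit: int
    no_total: int
    fold: float = float("nan")
    p_value: float = float("nan")
    adj_p: float = float("nan")
    selected: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.yes_hit <= self.yes_total
                and 0 <= self.no_hit <= self.no_total):
            raise ValueError(f"{self.pwm_name}: hit counts exceed totals")


def _fold(yes_hit: int, yes_total: int, no_hit: int, no_total: int) -> float:
    if yes_total == 0 or no_total == 0:
        return float("nan")
    yes_rate = yes_hit / yes_total
    no_rate = no_hit / no_total
    if no_rate == 0:
        return FOLD_INF if yes_rate > 0 else float("nan")
    return yes_rate / no_rate


def site_frequency_table(hits: Iterable[SiteHit],
                         yes_genes: set[str], no_genes: set[str],
                         pwm_names: Sequence[str] | None = None,
                         ) -> list[EnrichmentRecord]:
    """Tabulate per-PWM promoter hit frequencies in the Yes and No sets.

    ``pwm_names`` fixes the motif universe (so motifs with zero hits still
    get a record); when omitted it is the set of motifs appearing in hits.
    Hits on genes outside both sets are ignored (debug-logged).
    """
    if yes_genes & no_genes:
        raise ValueError("Yes and No gene sets overlap")
    hit_genes: dict[str, set[str]] = {}
    names = list(pwm_names) if pwm_names is not None else []
    seen_names = set(names)
    for h in hits:
        if h.gene_id not in yes_genes and h.gene_id not in no_genes:
            logger.debug("hit on gene %s outside Yes/No sets; ignored",
                         h.gene_id)
            continue
        hit_genes.setdefault(h.pwm_name, set()).add(h.gene_id)
        if h.pwm_name not in seen_names:
            names.append(h.pwm_name)
            seen_names.add(h.pwm_name)
    records = []
    for name in names:
        genes = hit_genes.get(name, set())
        yh = len(genes & yes_genes)
        nh = len(genes & no_genes)
        records.append(EnrichmentRecord(
            name, yh, len(yes_genes), nh, len(no_genes),
            fold=_fold(yh, len(yes_genes), nh, len(no_genes)),
        ))
    return records


def enrich_test(record: EnrichmentRecord) -> float:
    """One-sided Fisher exact p for enrichment of the motif in the Yes set."""
    if record.yes_total == 0 or record.no_total == 0:
        raise ValueError("totals must be positive")
    table = [[record.yes_hit, record.yes_total - record.yes_hit],
             [record.no_hit, record.no_total - record.no_hit]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def run_enrichment(hits: Iterable[SiteHit], yes_genes: set[str],
                   no_genes: set[str],
                   pwm_names: Sequence[str] | None = None,
                   adj_cut: float = ADJ_P_CUTOFF,
                   ) -> list[EnrichmentRecord]:
    """Full stage: tabulate, test, adjust, flag selections."""
    records = site_frequency_table(hits, yes_genes, no_genes, pwm_names)
    for rec in records:
        rec.p_value = enrich_test(rec)
    if records:
        adj = bh_adjust([rec.p_value for rec in records])
        for rec, a in zip(records, adj):
            rec.adj_p = float(a)
            rec.selected = rec.adj_p < adj_cut
    return records


def select_enriched(records: Sequence[EnrichmentRecord],
                    adj_cut: float = ADJ_P_CUTOFF) -> list[str]:
    """Motif names with adj_p strictly below the cutoff, sorted by
    (adj_p, name)."""
    chosen = [r for r in records if r.adj_p < adj_cut]
    chosen.sort(key=lambda r: (r.adj_p, r.pwm_name))
    return [r.pwm_name for r in chosen]


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"pwm": r.pwm_name, "yes_hit": r.yes_hit, "yes_total": r.yes_total,
         "no_hit": r.no_hit, "no_total": r.no_total, "fold": r.fold,
         "p": r.p_value, "adj_p": r.adj_p, "selected": r.selected}
        for r in records
    ])


def site_density_table(hits: Iterable[SiteHit], yes_genes: set[str],
                       no_genes: set[str], promoter_length: int = 1100,
                       ) -> pd.DataFrame:
    """Per-kilobase site-density variant of the frequency statistic
    (diagnostic alternative to presence/absence; not used for testing)."""
    counts: dict[str, dict[str, int]] = {}
    for h in hits:
        if h.gene_id in yes_genes:
            group = "yes"
        elif h.gene_id in no_genes:
            group = "no"
        else:
            continue
        counts.setdefault(h.pwm_name, {"yes": 0, "no": 0})[group] += 1
    kb_yes = len(yes_genes) * promoter_length / 1000
    kb_no = len(no_genes) * promoter_length / 1000
    return pd.DataFrame([
        {"pwm": name,
         "yes_sites_per_kb": c["yes"] / kb_yes if kb_yes else float("nan"),
         "no_sites_per_kb": c["no"] / kb_no if kb_no else float("nan")}
        for name, c in sorted(counts.items())
    ])
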