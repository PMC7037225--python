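"""Synthetic input generators with the statistical structure the pipeline
assumes: negative-binomial counts with planted log fold changes, promoters
with motif sites planted at elevated density in the foreground set, and a
signaling network with planted regulators a bounded number of steps upstream
of the active TFs.

Every generator is a pure function of its parameters and seed, and each
returns a ``SimTruth`` ground-truth record so recovery can be measured at
every downstream stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (BASES, CountMatrix, PromoterRecord, Pwm,
                         SignalingNetwork)

logger = logging.getLogger("upstreamx")


@dataclass
class SimTruth:
    """Planted ground truth for one simulated dataset."""

    de_genes: dict[str, tuple[str, float]] = field(default_factory=dict)
    #: gene_id -> (direction 'up'/'down', planted log2 fold change)
    planted_sites: list[tuple[str, str, int, str]] = field(default_factory=list)
    #: (gene_id, pwm_name, position, strand)
    planted_regulators: dict[str, dict[str, int]] = field(default_factory=dict)
    #: regulator node -> {active TF -> shortest directed distance}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": {g: list(v) for g, v in self.de_genes.items()},
            "planted_sites": self.planted_sites,
            "planted_regulators": self.planted_regulators,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def simulate_counts(n_genes: int = 2000, n_reps_per_group: int = 3,
                    frac_de: float = 0.1, planted_lfc: float = 2.0,
                    dispersion: float = 0.1,
                    lib_size_range: tuple[float, float] = (0.8e5, 1.2e5),
                    seed: int = 0) -> tuple[CountMatrix, SimTruth]:
    """NB counts for a control vs treatment design.

    Per gene g and sample s the mean is
    mu_gs = lib_size_s * q_g * 2^(+-planted_lfc) for treatment samples of
    DE genes (sign planted per gene), with common dispersion (variance
    mu + dispersion * mu^2); dispersion 0 gives Poisson counts. Relative
    abundances q_g are log-normal and normalized to sum 1.
    """
    if not 0 <= frac_de <= 1:
        raise ValueError(f"frac_de {frac_de} outside [0, 1]")
    if n_reps_per_group < 2:
        raise ValueError("need >= 2 replicates per group")
    if dispersion < 0 or planted_lfc < 0:
        raise ValueError("dispersion and planted_lfc must be >= 0")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    q = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    q /= q.sum()

    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([1.0, -1.0], size=n_de)
    lfc = np.zeros(n_genes)
    lfc[de_idx] = signs * planted_lfc

    n_samples = 2 * n_reps_per_group
    lib = rng.uniform(*lib_size_range, size=n_samples)
    conditions = (["control"] * n_reps_per_group
                  + ["treatment"] * n_reps_per_group)
    mu = np.empty((n_genes, n_samples))
    for s in range(n_samples):
        fc = np.exp2(lfc) if conditions[s] == "treatment" else 1.0
        mu[:, s] = lib[s] * q * fc

    if dispersion == 0:
        mat = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        p = r / (r + mu)
        mat = rng.negative_binomial(r, p)

    samples = [f"{c}_{i % n_reps_per_group + 1}"
               for i, c in enumerate(conditions)]
    cm = CountMatrix(
        pd.DataFrame(mat.astype(np.int64), index=genes, columns=samples),
        dict(zip(samples, conditions)),
    )
    truth = SimTruth(de_genes={
        genes[i]: ("up" if lfc[i] > 0 else "down", float(abs(lfc[i])))
        for i in de_idx
    })
    return cm, truth


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def _sample_site(pwm: Pwm, rng: np.random.Generator) -> str:
    """Draw each base from the raw PWM column distribution (realistic score
    spread, rather than fixed consensus; a pure consensus column always
    emits its consensus base)."""
    f = pwm.counts / pwm.counts.sum(axis=1, keepdims=True)
    return "".join(
        BASES[rng.choice(4, p=row / row.sum())] for row in f
    )


def simulate_promoters(gene_ids: list[str], length: int = 1100,
                       gc: float = 0.41,
                       pwm_library: list[Pwm] | None = None,
                       yes_genes: set[str] | None = None,
                       site_rate_yes: float = 2.0,
                       site_rate_no: float = 0.2,
                       seed: int = 0,
                       ) -> tuple[list[PromoterRecord], SimTruth]:
    """Promoters from an i.i.d. base model at the given GC content, with
    Poisson-many motif sites planted per promoter (rate depends on Yes/No
    membership), at uniform positions on either strand."""
    if not 0 <= site_rate_no <= site_rate_yes:
        raise ValueError("need site_rate_yes >= site_rate_no >= 0")
    pwm_library = pwm_library or []
    yes_genes = yes_genes or set()
    for pwm in pwm_library:
        if len(pwm) > length:
            raise ValueError(
                f"planted site from {pwm.name} (length {len(pwm)}) longer "
                f"than promoter ({length} bp)"
            )
    rng = np.random.default_rng(seed)
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    from .io_formats import reverse_complement

    records = []
    truth = SimTruth()
    for gene in gene_ids:
        seq = list("".join(
            BASES[i] for i in rng.choice(4, size=length, p=base_p)
        ))
        rate = site_rate_yes if gene in yes_genes else site_rate_no
        n_sites = rng.poisson(rate) if pwm_library and rate > 0 else 0
        for _ in range(n_sites):
            pwm = pwm_library[rng.integers(len(pwm_library))]
            site = _sample_site(pwm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                site = reverse_complement(site)
            pos = int(rng.integers(0, length - len(pwm) + 1))
            seq[pos:pos + len(site)] = site
            truth.planted_sites.append((gene, pwm.name, pos, strand))
        records.append(PromoterRecord(gene, "".join(seq),
                                      tss_offset=max(length - 100, 0)))
    return records, truth


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def simulate_network(n_nodes: int = 200, n_tfs: int = 30,
                     edge_density: float = 0.02,
                     planted_mr_count: int = 1,
                     max_planted_radius: int = 3,
                     active_tf_count: int | None = None,
                     planted_coverage: float = 1.0,
                     seed: int = 0,
                     ) -> tuple[SignalingNetwork, SimTruth, set[str]]:
    """Random acyclic background graph plus planted regulators wired
    upstream of a designated active-TF set.

    Background: Erdős–Rényi over a fixed topological order (edges only from
    lower to higher order), keeping the background acyclic so planted
    shortest paths are unambiguous. TFs occupy the downstream end of the
    order. Each planted regulator gets directed paths of length
    <= max_planted_radius (short-biased: mostly direct or one relay) to a
    ``planted_coverage`` fraction of the active TFs -- at least 80%, by
    default all of them (paths may reuse intermediate relay nodes). Truth
    records the realized
    shortest-path distances (recomputed on the final graph). Returns
    (network, truth, active_tf_set).
    """
    if not 1 <= max_planted_radius <= 12:
        raise ValueError("max_planted_radius must be in 1..12")
    if planted_mr_count < 1:
        raise ValueError("planted_mr_count must be >= 1")
    if not 0.8 <= planted_coverage <= 1.0:
        raise ValueError("planted_coverage must be in [0.8, 1.0]")
    if not 0 <= edge_density <= 1:
        raise ValueError(
            f"edge density {edge_density} incompatible with an acyclic "
            "background (must be a probability in [0, 1])"
        )
    if n_tfs + planted_mr_count > n_nodes:
        raise ValueError("n_tfs + planted_mr_count exceeds n_nodes")
    rng = np.random.default_rng(seed)
    names = [f"n{i:04d}" for i in range(n_nodes)]
    net = SignalingNetwork()
    for name in names:
        net.graph.add_node(name)

    # TFs sit at the downstream end of the topological order
    tf_names = names[-n_tfs:]
    for tf in tf_names:
        net.flag_tf(tf)
    if active_tf_count is None:
        active_tf_count = max(2, n_tfs // 2)
    active = set(rng.choice(tf_names, size=min(active_tf_count, n_tfs),
                            replace=False).tolist())

    # acyclic ER background
    upper = np.triu_indices(n_nodes, k=1)
    mask = rng.random(len(upper[0])) < edge_density
    for i, j in zip(upper[0][mask], upper[1][mask]):
        net.add_edge(names[i], names[j])

    # planted regulators: early nodes, wired to >= 80% of active TFs
    planted = [names[i] for i in range(planted_mr_count)]
    truth = SimTruth()
    relay_pool = names[planted_mr_count:n_nodes - n_tfs]
    for reg in planted:
        n_target = max(int(np.ceil(planted_coverage * len(active))), 1)
        targets = rng.choice(sorted(active), size=n_target, replace=False)
        for tf in targets:
            # short-biased path lengths: a master regulator mostly acts
            # directly or through one relay on its target TFs
            path_len = int(1 + rng.binomial(max_planted_radius - 1, 0.25))
            prev = reg
            for _ in range(path_len - 1):
                relay = relay_pool[int(rng.integers(len(relay_pool)))]
                net.add_edge(prev, relay)
                prev = relay
            net.add_edge(prev, tf)

    # truth distances = realized shortest paths on the final graph
    for reg in planted:
        dists = nx.single_source_shortest_path_length(
            net.graph, reg, cutoff=12)
        truth.planted_regulators[reg] = {
            tf: d for tf, d in dists.items() if tf in active
        }
    net.validate()
    return net, truth, active


# ---------------------------------------------------------------------------
# Coherent end-to-end study
# ---------------------------------------------------------------------------

def make_sharp_pwm(name: str, length: int, rng: np.random.Generator,
                   consensus_weight: float = 97.0) -> Pwm:
    """A near-deterministic motif: one dominant base per position."""
    counts = np.full((length, 4), 1.0)
    for i in range(length):
        counts[i, rng.integers(4)] = consensus_weight
    return Pwm(name, counts)


def simulate_study(n_genes: int = 400, n_reps_per_group: int = 3,
                   frac_de: float = 0.1, planted_lfc: float = 2.0,
                   dispersion: float = 0.1,
                   n_motifs: int = 12, motif_length: int = 12,
                   site_rate_yes: float = 4.0, site_rate_no: float = 0.2,
                   n_nodes: int = 200, n_tfs: int = 30,
                   seed: int = 0) -> dict:
    """Generate a linked expression/promoter/network dataset.

    The motif library is named after active TF nodes of the simulated
    network; motif sites are planted at elevated rate in the promoters of
    the planted *up-regulated* genes; the planted regulator sits a bounded
    number of steps upstream of the active TFs. Recovering the regulator
    therefore requires every pipeline stage to work.

    Returns a dict with counts, promoters, pwms, network, active TFs and
    the three SimTruth records.
    """
    rng = np.random.default_rng(seed)
    network, net_truth, active = simulate_network(
        n_nodes=n_nodes, n_tfs=n_tfs, seed=seed)
    counts, de_truth = simulate_counts(
        n_genes=n_genes, n_reps_per_group=n_reps_per_group, frac_de=frac_de,
        planted_lfc=planted_lfc, dispersion=dispersion, seed=seed)
    motif_tfs = sorted(active)[:n_motifs]
    pwms = [make_sharp_pwm(tf, motif_length, rng) for tf in motif_tfs]
    up_genes = {g for g, (d, _) in de_truth.de_genes.items() if d == "up"}
    promoters, site_truth = simulate_promoters(
        counts.gene_ids, pwm_library=pwms, yes_genes=up_genes,
        site_rate_yes=site_rate_yes, site_rate_no=site_rate_no, seed=seed)
    return {
        "counts": counts, "promoters": promoters, "pwms": pwms,
        "network": network, "active_tfs": active,
        "de_truth": de_truth, "site_truth": site_truth,
        "network_truth": net_truth,
    }
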