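"""Master-regulator search on a directed signaling network.

Candidate regulators are nodes with a directed path of at most R steps
(default 12) down to members of the active transcription-factor set. Each
candidate gets a key-node score

    S(v) = [ sum over reached TFs t of beta^d(v, t) ] / log2(2 + outdeg(v))

-- a distance-decayed reach count (beta in (0, 1], default 0.5) with a
logarithmic hub penalty, so that nodes specifically upstream of many of the
input TFs rank highest. The score formula itself is this package's own
definition; the surrounding protocol (bounded upstream radius, permutation
null over random same-size TF sets, Z-scores and rank-based empirical FDR,
selection at FDR < 0.05) follows the published workflow.

The permutation null redraws the TF set uniformly from all TF-flagged nodes
(set size preserved), rescores every node, and yields per-node Z-scores and
a per-rank empirical FDR (monotonized by cumulative max).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import SignalingNetwork

logger = logging.getLogger("upstreamx")


@dataclass
class MrSearchParams:
    radius: int = 12
    decay: float = 0.5
    n_permutations: int = 1000
    fdr_cut: float = 0.05
    seed: int = 0
    #: minimum permutations for which an FDR column is emitted
    min_permutations_for_fdr: int = 100
    #: rank the input TF-set members themselves as candidates. Off by
    #: default: a set member reaches itself at distance 0 and its decayed
    #: reach score is therefore inflated relative to genuine upstream
    #: nodes, which degenerates the rank-based FDR for small TF sets
    #: (each null permutation's own members outscore all downstream
    #: candidates). TFs outside the input set remain candidates.
    include_input_tfs: bool = False

    def validate(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if not 0 < self.decay <= 1:
            raise ValueError("decay must be in (0, 1]")


@dataclass
class MasterRegulatorRecord:
    node_id: str
    score: float
    n_tfs_reached: int
    z_score: float
    fdr: float
    rank: int
    direction: str = ""


# ---------------------------------------------------------------------------
# Reachability and scoring
# ---------------------------------------------------------------------------

def upstream_reach(network: SignalingNetwork, tf_set: set[str],
                   radius: int) -> dict[str, dict[str, int]]:
    """node -> {tf -> shortest directed distance <= radius}.

    Reverse BFS from each TF along reversed edges; a node reaches a TF iff
    a directed path node -> ... -> tf of length <= radius exists. A TF
    reaches itself at distance 0.
    """
    if not tf_set:
        raise ValueError("empty TF set")
    missing = tf_set - network.tf_nodes
    if missing:
        raise ValueError(f"TFs not flagged in network: {sorted(missing)[:5]}")
    rev = network.graph.reverse(copy=False)
    reach: dict[str, dict[str, int]] = {}
    for tf in sorted(tf_set):
        dists = nx.single_source_shortest_path_length(rev, tf, cutoff=radius)
        for node, d in dists.items():
            reach.setdefault(node, {})[tf] = d
    return reach


def _tf_distance_maps(network: SignalingNetwork, radius: int,
                      ) -> dict[str, dict[str, int]]:
    """tf -> {node -> distance}; precomputed once so permutations are cheap."""
    rev = network.graph.reverse(copy=False)
    return {
        tf: nx.single_source_shortest_path_length(rev, tf, cutoff=radius)
        for tf in sorted(network.tf_nodes)
    }


def key_node_score(node: str, distances: dict[str, int],
                   out_degree: int, decay: float = 0.5) -> float:
    """Distance-decayed TF reach with logarithmic hub penalty."""
    if not distances:
        return 0.0
    total = sum(decay ** d for d in distances.values())
    return total / np.log2(2 + out_degree)


def score_all_nodes(network: SignalingNetwork, tf_set: set[str],
                    params: MrSearchParams,
                    dist_maps: dict[str, dict[str, int]] | None = None,
                    ) -> tuple[dict[str, float], dict[str, int]]:
    """(node -> S, node -> #TFs reached) for all nodes reaching >= 1 TF."""
    if dist_maps is None:
        reach = upstream_reach(network, tf_set, params.radius)
    else:
        reach = {}
        for tf in tf_set:
            for node, d in dist_maps[tf].items():
                reach.setdefault(node, {})[tf] = d
    out_deg = dict(network.graph.out_degree())
    scores = {
        node: key_node_score(node, dists, out_deg.get(node, 0), params.decay)
        for node, dists in reach.items()
    }
    n_reached = {node: len(dists) for node, dists in reach.items()}
    return scores, n_reached


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

@dataclass
class PermutationNull:
    """Null key-node scores from random same-size TF sets.

    ``node_scores``: (n_permutations, n_nodes) matrix over ``nodes`` (all
    network nodes, fixed order); ``sorted_desc``: each permutation's scores
    sorted descending (for the per-rank FDR).
    """

    nodes: list[str]
    node_scores: np.ndarray
    sorted_desc: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.sorted_desc = -np.sort(-self.node_scores, axis=1)


def permutation_null(network: SignalingNetwork, set_size: int,
                     params: MrSearchParams,
                     dist_maps: dict[str, dict[str, int]] | None = None,
                     ) -> PermutationNull:
    tf_pool = sorted(network.tf_nodes)
    if set_size > len(tf_pool):
        raise ValueError(
            f"set size {set_size} exceeds TF pool of {len(tf_pool)}"
        )
    rng = np.random.default_rng(params.seed)
    if dist_maps is None:
        dist_maps = _tf_distance_maps(network, params.radius)
    nodes = sorted(network.nodes)
    node_pos = {n: i for i, n in enumerate(nodes)}
    mat = np.zeros((params.n_permutations, len(nodes)))
    for k in range(params.n_permutations):
        tf_set = set(rng.choice(tf_pool, size=set_size, replace=False))
        scores, _ = score_all_nodes(network, tf_set, params, dist_maps)
        for node, s in scores.items():
            if not params.include_input_tfs and node in tf_set:
                continue
            mat[k, node_pos[node]] = s
    return PermutationNull(nodes, mat)


# ---------------------------------------------------------------------------
# Ranking, Z-scores, FDR
# ---------------------------------------------------------------------------

def rank_and_select(scores: dict[str, float], n_reached: dict[str, int],
                    null: PermutationNull, params: MrSearchParams,
                    direction: str = "") -> list[MasterRegulatorRecord]:
    """Rank observed scores, attach null-based Z and rank FDR, select.

    z = (S - mean_null) / sd_null per node; a node never scored by the null
    (sd 0) with S above the null mean gets a +inf sentinel. FDR at rank r
    is the permutation-mean count of null nodes at rank <= r scoring at
    least the observed rank-r score, divided by r, clipped to [0, 1] and
    monotonized by cumulative max down the ranking. Ties in S break by
    node id.
    """
    emit_fdr = params.n_permutations >= params.min_permutations_for_fdr
    if not emit_fdr:
        logger.warning(
            "only %d permutations (< %d): FDR column withheld, Z-scores "
            "still reported", params.n_permutations,
            params.min_permutations_for_fdr,
        )
    node_pos = {n: i for i, n in enumerate(null.nodes)}
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    records: list[MasterRegulatorRecord] = []
    fdrs = []
    for rank, (node, s) in enumerate(ordered, start=1):
        col = null.node_scores[:, node_pos[node]]
        mean, sd = float(col.mean()), float(col.std(ddof=0))
        if sd == 0:
            z = float("inf") if s > mean else 0.0
            if s > mean:
                logger.debug("node %s unseen in null; z set to +inf", node)
        else:
            z = (s - mean) / sd
        if emit_fdr:
            top = null.sorted_desc[:, :rank]
            exceed = (top >= s).sum(axis=1)
            fdr = float(np.clip(exceed.mean() / rank, 0.0, 1.0))
        else:
            fdr = float("nan")
        fdrs.append(fdr)
        records.append(MasterRegulatorRecord(node, s, n_reached.get(node, 0),
                                             z, fdr, rank, direction))
    # monotone FDR down the ranking
    if emit_fdr:
        running = 0.0
        for rec in records:
            running = max(running, rec.fdr)
            rec.fdr = running
    return records


def select_regulators(records: list[MasterRegulatorRecord],
                      fdr_cut: float = 0.05) -> list[MasterRegulatorRecord]:
    return [r for r in records
            if np.isfinite(r.fdr) and r.fdr < fdr_cut and r.score > 0]


def find_master_regulators(network: SignalingNetwork, tf_set: set[str],
                           params: MrSearchParams | None = None,
                           direction: str = "",
                           ) -> list[MasterRegulatorRecord]:
    """Full stage: score, permutation null, rank, Z, FDR."""
    params = params or MrSearchParams()
    params.validate()
    if not tf_set:
        raise ValueError("empty TF set")
    dist_maps = _tf_distance_maps(network, params.radius)
    scores, n_reached = score_all_nodes(network, tf_set, params, dist_maps)
    if not params.include_input_tfs:
        scores = {n: s for n, s in scores.items() if n not in tf_set}
    null = permutation_null(network, len(tf_set), params, dist_maps)
    return rank_and_select(scores, n_reached, null, params, direction)


def records_to_frame(records: list[MasterRegulatorRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"node": r.node_id, "score": r.score,
         "n_tfs_reached": r.n_tfs_reached, "z": r.z_score, "fdr": r.fdr,
         "rank": r.rank, "direction": r.direction}
        for r in records
    ])
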