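"""End-to-end orchestration: counts -> DEG sets -> promoter scanning ->
motif enrichment -> composite module -> master regulators, run independently
for the up- and down-regulated gene sets, with a manifest recording
parameters and seeds so re-runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, composite_module, diffexpr, enrichment
from . import master_regulators as mr
from . import site_scan
from .io_formats import (read_counts, read_fasta, read_network,
                         read_transfac_matrices, write_table)

logger = logging.getLogger("upstreamx")


@dataclass
class PipelineConfig:
    counts: str
    design: str
    promoters: str
    pwms: str
    network: str
    out_dir: str
    condition_control: str = "control"
    condition_treatment: str = "treatment"
    # DEG thresholds
    theta_up: float = diffexpr.THETA_UP
    theta_down: float = diffexpr.THETA_DOWN
    deg_alpha: float = diffexpr.ALPHA
    # optional pre-computed DEG table (bypasses the built-in test)
    deg_table: str | None = None
    # scan cutoffs
    mss_cutoff: float = site_scan.DEFAULT_MSS_CUTOFF
    css_cutoff: float = site_scan.DEFAULT_CSS_CUTOFF
    # enrichment
    adj_cut: float = enrichment.ADJ_P_CUTOFF
    # composite-module GA
    ga: composite_module.GaParams = field(
        default_factory=composite_module.GaParams)
    run_cma: bool = True
    #: which motif set feeds the TF mapping for the regulator search
    tf_source: str = "union"  # enriched | module | union
    # master-regulator search
    radius: int = 12
    decay: float = 0.5
    n_permutations: int = 1000
    fdr_cut: float = 0.05
    seed: int = 0
    #: pwm name -> TF node id in the network (identity when omitted)
    pwm_to_tf: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for key in ("counts", "design", "promoters", "pwms", "network"):
            path = getattr(self, key)
            if not Path(path).exists():
                raise FileNotFoundError(f"{key} file not found: {path}")
        if self.tf_source not in ("enriched", "module", "union"):
            raise ValueError(f"bad tf_source {self.tf_source!r}")
        if not self.theta_down < 0 < self.theta_up:
            raise ValueError("DEG thresholds must bracket zero")

    def param_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _map_tfs(pwm_names: list[str], config: PipelineConfig,
             network_tfs: set[str]) -> set[str]:
    mapped = {config.pwm_to_tf.get(name, name) for name in pwm_names}
    present = mapped & network_tfs
    dropped = mapped - network_tfs
    if dropped:
        logger.warning("%d TFs not flagged in network; dropped: %s",
                       len(dropped), sorted(dropped)[:5])
    return present


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the three analysis stages for both DEG directions.

    Writes stage outputs under ``config.out_dir`` and a ``manifest.json``;
    re-running with an identical config reproduces identical outputs.
    Returns the manifest dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "stages": {},
    }

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        logger.info("stage %s: %s", stage, info)

    # ------------------------------------------------------------------ DEGs
    stage = "diffexpr"
    try:
        counts = read_counts(config.counts, config.design)
        if config.deg_table:
            table = diffexpr.DegTable.from_frame(
                pd.read_csv(config.deg_table, sep="\t", comment="#"))
        else:
            table = diffexpr.test_de(counts, config.condition_control,
                                     config.condition_treatment)
        up, down, no = diffexpr.filter_degs(
            table, config.theta_up, config.theta_down, config.deg_alpha)
        write_table(table.to_frame(), out / "degs.tsv",
                    params={"theta_up": config.theta_up,
                            "theta_down": config.theta_down,
                            "alpha": config.deg_alpha},
                    seed=config.seed)
        record(stage, n_genes=len(table.records), n_up=len(up),
               n_down=len(down), n_background=len(no))
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        _fail(manifest, out, stage, exc)

    # ------------------------------------------------------------------ scan
    stage = "site_scan"
    try:
        promoters = read_fasta(config.promoters)
        pwms = read_transfac_matrices(config.pwms)
        hits = site_scan.scan_promoters(promoters, pwms,
                                        config.mss_cutoff, config.css_cutoff)
        write_table(site_scan.hits_to_frame(
            hits, {p.name: len(p) for p in pwms}), out / "hits.tsv",
            params={"mss_cutoff": config.mss_cutoff,
                    "css_cutoff": config.css_cutoff}, seed=config.seed)
        record(stage, n_promoters=len(promoters), n_pwms=len(pwms),
               n_hits=len(hits))
    except Exception as exc:  # noqa: BLE001
        _fail(manifest, out, stage, exc)

    network = read_network(config.network)
    promoter_length = len(promoters[0]) if promoters else 1100
    pwm_names = [p.name for p in pwms]
    hit_index = composite_module.index_hits(hits)

    results: dict[str, list[str]] = {}
    for direction, yes_set in (("up", up), ("down", down)):
        tag = f"[{direction}]"
        if not yes_set:
            logger.warning("%s empty DEG set; direction skipped", tag)
            continue
        # -------------------------------------------------------- enrichment
        stage = f"enrichment_{direction}"
        try:
            records = enrichment.run_enrichment(
                hits, yes_set, no, pwm_names, config.adj_cut)
            enriched = enrichment.select_enriched(records, config.adj_cut)
            write_table(enrichment.records_to_frame(records),
                        out / f"enrichment_{direction}.tsv",
                        params={"adj_cut": config.adj_cut}, seed=config.seed)
            record(stage, n_enriched=len(enriched))
        except Exception as exc:  # noqa: BLE001
            _fail(manifest, out, stage, exc)

        # ------------------------------------------------------------- CMA
        module_members: list[str] = []
        if config.run_cma and enriched:
            stage = f"composite_module_{direction}"
            try:
                yes_list = sorted(yes_set)
                no_list = sorted(no)
                module = composite_module.optimize_module(
                    enriched, hit_index, yes_list, hit_index, no_list,
                    config.ga, seed=config.seed,
                    promoter_length=promoter_length)
                module_members = sorted(module.member_names)
                (out / f"module_{direction}.json").write_text(json.dumps({
                    "members": [
                        {"pwm": m.pwm_name, "weight": m.weight,
                         "max_count": m.max_count} for m in module.members],
                    "window_width": module.window_width,
                    "p_value": module.p_value,
                    "fitness": module.fitness,
                }, indent=1))
                record(stage, n_members=len(module_members),
                       fitness=module.fitness)
            except Exception as exc:  # noqa: BLE001
                _fail(manifest, out, stage, exc)

        # ------------------------------------------------- master regulators
        stage = f"master_regulators_{direction}"
        try:
            if config.tf_source == "enriched":
                tf_pwm_names = enriched
            elif config.tf_source == "module":
                tf_pwm_names = module_members
            else:
                tf_pwm_names = sorted(set(enriched) | set(module_members))
            tf_set = _map_tfs(tf_pwm_names, config, network.tf_nodes)
            if not tf_set:
                logger.warning("%s no network TFs for direction; skipped", tag)
                record(stage, skipped="no TFs mapped")
                continue
            params = mr.MrSearchParams(
                radius=config.radius, decay=config.decay,
                n_permutations=config.n_permutations,
                fdr_cut=config.fdr_cut, seed=config.seed)
            recs = mr.find_master_regulators(network, tf_set, params,
                                             direction=direction)
            selected = mr.select_regulators(recs, config.fdr_cut)
            write_table(mr.records_to_frame(recs),
                        out / f"master_regulators_{direction}.tsv",
                        params={"radius": config.radius,
                                "n_permutations": config.n_permutations,
                                "fdr_cut": config.fdr_cut},
                        seed=config.seed)
            results[direction] = [r.node_id for r in selected]
            record(stage, n_tfs=len(tf_set), n_candidates=len(recs),
                   n_selected=len(selected))
        except Exception as exc:  # noqa: BLE001
            _fail(manifest, out, stage, exc)

    manifest["selected"] = results
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _fail(manifest: dict, out: Path, stage: str, exc: Exception) -> None:
    """Abort with the stage name, keeping partial outputs on disk."""
    manifest["failed_stage"] = stage
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    raise StageError(stage, exc) from exc
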