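import json

import networkx as nx
import numpy as np
import pytest

from upstreamx.io_formats import reverse_complement
from upstreamx.site_scan import match_score
from upstreamx.synthetic_data import (make_sharp_pwm, simulate_counts,
                                      simulate_network, simulate_promoters,
                                      simulate_study)


class TestSimulateCounts:
    def test_shape_design_and_determinism(self):
        cm, truth = simulate_counts(n_genes=100, n_reps_per_group=3, seed=1)
        assert cm.counts.shape == (100, 6)
        assert sorted(set(cm.condition_of.values())) == ["control",
                                                         "treatment"]
        cm2, truth2 = simulate_counts(n_genes=100, n_reps_per_group=3, seed=1)
        assert cm.counts.equals(cm2.counts)
        assert truth.de_genes == truth2.de_genes

    def test_planted_fraction(self):
        _, truth = simulate_counts(n_genes=500, frac_de=0.1, seed=2)
        assert len(truth.de_genes) == 50

    def test_planted_fold_change_realized_in_group_means(self):
        cm, truth = simulate_counts(n_genes=800, n_reps_per_group=10,
                                    planted_lfc=2.0, dispersion=0.02, seed=3)
        ctrl = cm.counts[cm.samples_for("control")].mean(axis=1)
        trt = cm.counts[cm.samples_for("treatment")].mean(axis=1)
        for gene, (direction, lfc) in list(truth.de_genes.items()):
            if ctrl[gene] < 20:  # skip genes too lowly expressed to measure
                continue
            ratio = np.log2((trt[gene] + 0.5) / (ctrl[gene] + 0.5))
            expected = lfc if direction == "up" else -lfc
            assert ratio == pytest.approx(expected, abs=1.0)

    def test_zero_dispersion_gives_poisson_variance(self):
        cm, _ = simulate_counts(n_genes=2000, n_reps_per_group=10,
                                frac_de=0.0, dispersion=0.0, seed=4,
                                lib_size_range=(1e5, 1e5))
        mat = cm.counts.to_numpy(dtype=float)[:, :10]
        mu = mat.mean(axis=1)
        var = mat.var(axis=1, ddof=1)
        keep = mu > 50
        # variance/mean ratio concentrates near 1 for Poisson
        assert np.median(var[keep] / mu[keep]) == pytest.approx(1.0, abs=0.1)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_counts(frac_de=1.5)
        with pytest.raises(ValueError):
            simulate_counts(n_reps_per_group=1)
        with pytest.raises(ValueError):
            simulate_counts(dispersion=-0.1)


class TestSimulatePromoters:
    def test_lengths_ids_and_gc_content(self):
        genes = [f"g{i}" for i in range(40)]
        recs, _ = simulate_promoters(genes, length=1100, gc=0.41, seed=5)
        assert [r.gene_id for r in recs] == genes
        assert all(len(r.sequence) == 1100 for r in recs)
        allseq = "".join(r.sequence for r in recs)
        gc = (allseq.count("G") + allseq.count("C")) / len(allseq)
        assert gc == pytest.approx(0.41, abs=0.02)

    def test_planted_sites_score_high_under_their_pwm(self):
        rng = np.random.default_rng(6)
        pwms = [make_sharp_pwm(f"M{k}", 10, rng) for k in range(3)]
        genes = [f"g{i}" for i in range(30)]
        yes = set(genes[:10])
        recs, truth = simulate_promoters(
            genes, pwm_library=pwms, yes_genes=yes,
            site_rate_yes=3.0, site_rate_no=0.1, seed=6)
        seq_of = {r.gene_id: r.sequence for r in recs}
        pwm_of = {p.name: p for p in pwms}
        assert truth.planted_sites
        scores = []
        for gene, pwm_name, pos, strand in truth.planted_sites:
            window = seq_of[gene][pos:pos + len(pwm_of[pwm_name])]
            if strand == "-":
                window = reverse_complement(window)
            mss, _ = match_score(pwm_of[pwm_name], window)
            scores.append(mss)
        # sites are drawn from the PWM (not fixed consensus) and later
        # plantings can overwrite earlier ones, so scores cluster high
        # rather than at exactly 1
        assert np.mean(scores) > 0.85
        assert np.mean(np.array(scores) > 0.85) > 0.7

    def test_yes_promoters_carry_more_sites(self):
        rng = np.random.default_rng(7)
        pwms = [make_sharp_pwm("M0", 10, rng)]
        genes = [f"g{i}" for i in range(200)]
        yes = set(genes[:100])
        _, truth = simulate_promoters(
            genes, pwm_library=pwms, yes_genes=yes,
            site_rate_yes=2.0, site_rate_no=0.2, seed=7)
        n_yes = sum(1 for g, *_ in truth.planted_sites if g in yes)
        n_no = len(truth.planted_sites) - n_yes
        assert n_yes > 3 * max(n_no, 1)

    def test_site_longer_than_promoter_rejected(self):
        rng = np.random.default_rng(8)
        pwm = make_sharp_pwm("LONG", 30, rng)
        with pytest.raises(ValueError, match="longer"):
            simulate_promoters(["g1"], length=20, pwm_library=[pwm])

    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError):
            simulate_promoters(["g1"], site_rate_yes=0.1, site_rate_no=0.5)


class TestSimulateNetwork:
    def test_structure_and_truth(self):
        net, truth, active = simulate_network(n_nodes=150, n_tfs=25, seed=9)
        assert nx.is_directed_acyclic_graph(net.graph)
        assert len(net.tf_nodes) == 25
        assert active <= net.tf_nodes
        (reg, dists), = truth.planted_regulators.items()
        assert reg not in net.tf_nodes
        # default coverage 1.0: every active TF reachable within the radius
        assert set(dists) == active
        assert all(1 <= d <= 3 for d in dists.values())

    def test_truth_distances_are_real_shortest_paths(self):
        net, truth, active = simulate_network(n_nodes=120, n_tfs=20, seed=10)
        for reg, dists in truth.planted_regulators.items():
            for tf, d in dists.items():
                assert nx.shortest_path_length(net.graph, reg, tf) == d

    def test_determinism(self):
        a = simulate_network(n_nodes=80, n_tfs=12, seed=11)
        b = simulate_network(n_nodes=80, n_tfs=12, seed=11)
        assert set(a[0].edges) == set(b[0].edges)
        assert a[2] == b[2]

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_network(max_planted_radius=0)
        with pytest.raises(ValueError):
            simulate_network(planted_coverage=0.5)
        with pytest.raises(ValueError):
            simulate_network(n_nodes=10, n_tfs=10, planted_mr_count=1)
        with pytest.raises(ValueError):
            simulate_network(edge_density=1.5)


class TestSimulateStudy:
    def test_components_are_linked(self):
        study = simulate_study(n_genes=120, n_motifs=6, seed=12)
        # motif names are active TF node ids
        names = {p.name for p in study["pwms"]}
        assert names <= study["active_tfs"]
        # promoters cover exactly the count matrix genes
        assert [r.gene_id for r in study["promoters"]] == \
            study["counts"].gene_ids
        # elevated-rate sites go to the up-regulated gene promoters
        up = {g for g, (d, _) in study["de_truth"].de_genes.items()
              if d == "up"}
        n_up = sum(1 for g, *_ in study["site_truth"].planted_sites
                   if g in up)
        n_bg = len(study["site_truth"].planted_sites) - n_up
        rate_up = n_up / len(up)
        rate_bg = n_bg / (len(study["counts"].gene_ids) - len(up))
        # per-promoter site rate far higher in up-regulated foreground
        assert rate_up > 5 * rate_bg

    def test_truth_serializes_to_json(self, tmp_path):
        study = simulate_study(n_genes=60, n_motifs=4, seed=13)
        out = tmp_path / "truth.json"
        study["network_truth"].to_json(out)
        payload = json.loads(out.read_text())
        assert set(payload) == {"de_genes", "planted_sites",
                                "planted_regulators"}
        assert payload["planted_regulators"]
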