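# upstreamx

Master-regulator inference from expression data: differential expression →
promoter motif enrichment → composite cis-regulatory modules → signaling-network
key-node search.

## Scientific problem

When macrophages are exposed to modified low-density lipoprotein (LDL) —
desialylated, acetylated, or oxidized — they accumulate lipids and turn into
foam cells, a hallmark of early atherosclerosis. Bulk expression profiling of
such treated cells yields a list of differentially expressed genes (DEGs), but
the list itself does not say *which upstream signaling proteins drive the
response*. Upstream analysis closes that gap in three inference stages:

1. **Differential expression.** Call up- and down-regulated gene sets from a
   read-count matrix (exact conditional negative-binomial test, |log2 FC| > 0.7
   at p < 0.05).
2. **Promoter analysis.** Scan the 1100-bp promoters of the DEGs for
   transcription-factor binding sites with position weight matrices
   (MATCH-style matrix/core similarity scores), test each motif for
   enrichment in DEG promoters versus background promoters (one-sided Fisher
   exact, Benjamini-Hochberg adjusted p < 0.01), and search for a *composite
   module* — up to 10 motifs co-occurring in a 200–300 bp window — that best
   separates DEG promoters from background (genetic algorithm minimizing a
   Wilcoxon rank-sum p-value).
3. **Master-regulator search.** In a directed signaling network, score every
   node by how specifically it sits upstream (≤ 12 steps) of the
   transcription factors found in stage 2, against a permutation null of
   random same-size TF sets; nodes at empirical FDR < 0.05 are the candidate
   master regulators.

The package also ships the published regulator lists for the four LDL
treatment arms and their functional annotations, and reproduces the printed
overlap arithmetic (e.g. TRAF6 as the single regulator common to all
treatments).

Because the original expression dataset is not publicly deposited, the
statistical machinery is validated on synthetic data with planted ground
truth: the generators in `upstreamx.synthetic_data` produce linked
counts / promoters / network inputs in which the true DEGs, binding sites and
upstream regulator are known, so recovery can be measured at every stage.

## Worked example

Generate a linked synthetic study (400 genes, 3+3 replicates, 12 motifs named
after active TF nodes of a 200-node signaling network, one planted regulator
`n0000` wired upstream of the active TFs), then run the full pipeline:

```bash
upstreamx simulate --preset all --out-dir sim --seed 13 --n-genes 400
cat > run.cfg <<EOF
counts=sim/counts.tsv
design=sim/design.tsv
promoters=sim/promoters.fasta
pwms=sim/pwms.transfac
network=sim/network.tsv
out_dir=results
seed=13
EOF
upstreamx run --config run.cfg
```

This prints `{"up": ["n0000"]}` — the planted regulator is the single
selection in the up direction. The manifest (`results/manifest.json`) records
per-stage accounting for this run:

| stage | result |
|---|---|
| diffexpr | 400 genes → 30 up, 25 down, 345 background |
| site_scan | 400 promoters × 12 PWMs → 144 hits |
| enrichment (up) | 10 of 12 motifs at adj. p < 0.01 |
| composite module (up) | 4 members, fitness 26.97 (−log10 Wilcoxon p) |
| master regulators (up) | 107 candidates, 1 selected at FDR < 0.05 |

Comparing the packaged published regulator lists against the
naturally-occurring-LDL reference:

```bash
upstreamx compare --tables <pkg>/data/table3_regulators.tsv \
    --reference naturally_occurring_LDL
```

| treatment | matched (direction-matched) | of |
|---|---|---|
| desialylated LDL | 12 | 19 |
| acetylated LDL | 7 | 18 |
| oxidized LDL | 10 | 20 |

with 18 distinct regulators matched in at least one comparison and `TRAF6`
the only regulator common to all three — the printed counts. The packaged
annotation table tallies 15 innate-immunity, 9 lipid-metabolism and
10 phagocytosis regulators.

## Reproduction

`scripts/acceptance.py` recomputes the headline quantities (published-table
arithmetic, DEG type-I error rate, scanner-vs-reference agreement, planted
module / regulator recovery rates, full-pipeline recovery) from scratch at a
given seed:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runtime is roughly 3–4 minutes on one CPU. All stochastic quantities are
functions of `--seed`; the published-table quantities are exact. Note that
full-pipeline recovery (unlike the per-stage recovery rates) is
seed-sensitive — see `docs/methods.md` for why.

## Layout

| module | contents |
|---|---|
| `upstreamx.io_formats` | FASTA / TRANSFAC / network / count-matrix readers and writers |
| `upstreamx.diffexpr` | size factors, common dispersion, exact NB test, DEG thresholds |
| `upstreamx.site_scan` | MATCH-style PWM scanning (mss/css) |
| `upstreamx.enrichment` | Yes/No site frequencies, Fisher test, BH adjustment |
| `upstreamx.composite_module` | windowed module scoring, Wilcoxon fitness, genetic algorithm |
| `upstreamx.master_regulators` | bounded upstream reach, key-node score, permutation FDR |
| `upstreamx.synthetic_data` | planted-truth generators (counts, promoters, network, linked study) |
| `upstreamx.compare_report` | direction-matched overlaps, Venn counts, annotation tallies, packaged tables |
| `upstreamx.pipeline` / `upstreamx.cli` | end-to-end orchestration, manifest, `upstreamx` command |

Methodological details, parameter defaults and their rationale, and known
limitations are documented in `docs/methods.md`.
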