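# ripenet

Transcript–metabolite integration pipeline for ripening mutant panels.

Given replicate-level metabolite and transcript abundance tables (with
explicit not-detected flags), sample/feature metadata and a mutant-to-wild-type
design map, `ripenet` computes:

- **Differential tables** — per-mutant, per-stage log2 fold changes versus the
  matched wild-type background, with two-tailed Student's *t*-test stars
  (`*` p ≤ 0.05, `**` p ≤ 0.01, `***` p ≤ 0.001), ND propagation, and a
  one-way ANOVA + Tukey HSD comparison across genotypes.
- **Stage-specific hierarchical clustering** of genotypes in the joint
  metabolite + transcript space (1 − Pearson or Euclidean distances;
  average/complete/ward linkage; Newick + merge-table output).
- **Pearson correlation matrices** per stage, pairwise-complete over ND cells
  with per-pair sample counts.
- **Hub-centered correlation networks** around each mutated gene's transcript,
  thresholded at |r| ≥ τ (default 0.88), with node strength (sum of |r| over
  incident edges), GraphML/edge-TSV export, and per-hub stage-trajectory
  summaries (expanding / contracting / stable / rewired).

A synthetic-data module generates the whole design from scratch — a
steady-state flux model on a carotenoid pathway DAG with loss-of-function
(leaky block + substrate backlog) and gain-of-function (branch redirection)
mutations, stage-dependent input flux, planted correlation modules via shared
latent factors, log-normal multiplicative noise, and limit-of-detection
censoring — together with a ground-truth record for recovery testing.

## Test

```bash
python -m pytest -q tests/
```

The suite includes a property-based acceptance module
(`tests/test_acceptance.py`): Pearson/t-test/ANOVA oracle equivalence and
calibration, flux-model exactness, planted hub-module recovery, threshold
monotonicity, clustering oracle equivalence and pair recovery, differential
exactness, and end-to-end determinism.

## CLI

```bash
# generate the default 7-genotype x 3-stage x 3-replicate synthetic panel
ripenet simulate --out data/ --seed 1

# per-stage analyses from TSV inputs
ripenet diff   --table data/abundance.tsv --samples data/samples.tsv \
               --features data/features.tsv --design data/design.json \
               --stage FR --out diff_FR.tsv
ripenet hcl    --table ... --design ... --stage MG --out hcl_MG.nwk
ripenet corr   --table ... --stage FR --pathway-class CAR --out corr_FR.tsv
ripenet hubnet --table ... --stage FR --hub CYC-b --tau 0.88 --out net.graphml

# end-to-end (simulate -> differential -> clustering -> correlation -> networks)
ripenet run-all --config run.yaml
```

A minimal `run.yaml`:

```yaml
outdir: out
seed: 1
stages: [MG, Br, FR]
tau: 0.88
```

`run-all` writes a deterministic directory tree (`differential/`,
`clustering/`, `correlation/`, `networks/`, `inputs/`) plus `provenance.json`
(config snapshot, package version, output digests, seed) and `run.log`.
Re-running with the same config and seed reproduces every non-timestamp file
byte-identically.

## File formats

- **Abundance matrix** — TSV, row 1 = sample ids, column 1 = feature ids,
  cells = decimal or the sentinel `ND` (not detected — distinct from zero).
- **Sample metadata** — TSV: `sample_id genotype background stage replicate`.
- **Feature metadata** — TSV: `feature_id display_name kind pathway_class
  branch_id step_index` (kind ∈ metabolite|transcript).
- **Pathway map** — JSON: `nodes`, `edges` (`substrate`/`product`/`gene`),
  `branch_fractions` (per branching node, summing to 1).

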