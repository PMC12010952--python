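# hdxdock

HDX-MS-guided antibody–antigen docking restraints, rescoring, and model
evaluation.

Hydrogen–deuterium exchange mass spectrometry (HDX-MS) maps antibody
epitopes at peptide resolution: antigen peptides whose deuterium uptake
drops when the antibody binds mark the likely binding surface. `hdxdock`
turns such peptides into soft distance restraints for protein–protein
docking and uses them to score, select, and audit docked models. It is
aimed at structural bioinformaticians who have (a) an ensemble of docked
antibody–antigen poses with a per-model interface energy and (b) an HDX-MS
peptide list, and who want HDX-consistent model selection without trusting
any single pose.

## The model

Each HDX-interacting peptide on the antigen becomes a restraint: at least
*k* (default 1) of its non-proline residues must place a Cα within *d*
(default 10 Å) of any Cα in the antibody CDRs. For a docked model, the
effective shortest Cα–Cα distance *x* between peptide and CDRs is scored
with a flat harmonic,

    f(x) = 0           for x ≤ d
    f(x) = (x − d)²    for x > d,

and the per-model HDX score is the sum of f over all peptides. Because the
HDX score (Å²) and the interface energy (REU) live on different scales, the
HDX score is normalized by the ratio of the two columns' trimmed ranges
(means of the top and bottom 10 % of each), weighted by 4.5, and added to
the interface score:

    combined = 4.5 × normalized_HDX + interface_score.

Lower is better throughout; a model satisfying every restraint keeps its
interface score unchanged.

Three auxiliary components close the loop:

* **Evaluation** — CAPRI-style fnat / L-RMSD / iRMSD and quality classes
  against a reference complex, plus the enrichment statistic
  (TP/(TP+FP))·((P+N)/P) over top-10 % selections (max 10) and a
  two-sample Kolmogorov–Smirnov test between iRMSD distributions.
* **Allostery detection** — an allosteric peptide (protected but far from
  the epitope) leaves even the best-scoring models with a residual HDX
  penalty. If the mean weighted HDX score of the top-10 models exceeds
  0.75, the dataset is flagged and a leave-one-out exclusion scan names
  the peptide; the scan repeats while the mean stays above threshold.
* **Sampling** — a toy rigid-body Metropolis sampler that adds the HDX
  penalty to a coarse contact score at a 1:1 ratio, demonstrating how the
  restraints steer conformational search.

A deterministic fixture module generates toy complexes, decoy ensembles
with controlled iRMSD/score correlation, and uptake tables with planted
truth, so everything is testable offline.

## Worked example

```
hdxdock make-fixtures --seed 7 --n-decoys 50 --out demo
hdxdock rescore  --config demo/config.yaml --models demo/decoys.pdb \
                 --scores demo/base_scores.tsv --out demo/rescored
hdxdock evaluate --config demo/config.yaml --reference demo/reference.pdb \
                 --models demo/decoys.pdb --scores demo/base_scores.tsv \
                 --out demo/eval
```

`demo/rescored/top10.tsv` begins

```
model_id  interface_score  hdx_raw  hdx_normalized  hdx_weighted  combined  rank
3         -30.978          0.0      0.0             0.0           -30.978   1
15        -30.376          0.0      0.0             0.0           -30.376   2
14        -30.303          0.0      0.0             0.0           -30.303   3
```

— the top-ranked decoys all have `hdx_raw = 0` (every restraint satisfied),
so their combined score equals their interface score. `demo/eval/summary.json`
reports

```
"class_counts": {"high": 20, "medium": 2, "acceptable": 14, "incorrect": 14},
"enrichment": 4.0
```

meaning 36 of the 50 decoys are near-native (acceptable or better) and the
base-score ranking concentrates accurate models 4× over random in its top
10 % (the maximum being 10). Every run also writes a `manifest.json` with
the resolved configuration (all defaults materialized: weight 4.5,
d = 10 Å, allostery threshold 0.75, top-10 selection), input digests, and
seeds.

Other subcommands: `penalty` (per-peptide distance/penalty table),
`detect-allostery` (flag + leave-one-out identification),
`filter-hdx` (uptake-table significance filter: ≥ 0.5 Da and ≥ 3 pooled SD
at some timepoint, cumulative > 1.1 Da), `sample` (toy Metropolis runs).

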