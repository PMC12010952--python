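# Methods

## Restraints and penalty

An HDX-interacting peptide is a contiguous antigen residue range in author
numbering (inclusive on both ends, the way HDX peptides are quoted). Its
restraint is evaluated on Cα atoms only: for each eligible peptide residue
the minimum distance to any CDR Cα is computed, and the *k*-th smallest of
these per-residue minima is the effective distance *x* fed to the flat
harmonic `f(x) = max(0, x − d)²`. At the default `k = 1` this is the global
shortest Cα–Cα distance between peptide and CDRs; `k = 2, 3` with
`d ∈ {5, 8, 10}` Å form the supported stringency grid. The per-model HDX
score is the plain sum of peptide penalties (Å²).

Prolines are excluded on the peptide side only: proline has no exchangeable
backbone amide, so it carries no HDX signal, whereas CDR residues serve
purely as geometric anchors. Peptide residues absent from a model (e.g.
unresolved loops or cross-strain numbering gaps) drop out of the distance
search with a log note; a peptide with no eligible residues at all is an
error naming the peptide. `percent_normalize` expresses a penalty column as
a percentage of the ensemble maximum (all-zero columns map to zero), which
is how stringency settings are compared across ensembles.

## Normalization and combination

With interface energies around −30…−5 REU and penalties anywhere from 0 to
thousands of Å², the HDX column is rescaled by

    scale = (iface_high − iface_low) / (hdx_high − hdx_low)

where each `high`/`low` is the mean of the top/bottom `ceil(0.10·N)` values
of that column (minimum one element; the rounding is a package choice).
`normalized = scale × hdx_raw`, `weighted = 4.5 × normalized`,
`combined = weighted + interface_score`. If every model carries the same
penalty the scale is undefined; normalized scores are then set to zero so
the combined score degrades gracefully to the base score (logged). Ranking
is ascending by combined score with lexicographic model-id tie-breaks so
orderings are identical across platforms and hash seeds.

The default weight 4.5 balances HDX guidance against over-penalizing good
models when the restraint set contains false positives; `weight_sweep`
re-runs selection over 0.5–15.0 in 0.5 steps on any ensemble with known
iRMSDs for sensitivity analysis.

## Evaluation

fnat uses a 5 Å heavy-atom contact cutoff (CAPRI convention); the interface
is every residue with a heavy atom within 10 Å of the partner. The antigen
is the receptor: L-RMSD superposes model on reference over antigen Cα and
measures over antibody Cα; iRMSD superposes on, and measures over, the
reference-defined interface Cα. Superposition is a hand-rolled Kabsch fit
(SVD with a determinant correction so reflections are never returned),
which lets tests check it against a black-box numerical minimizer. Quality
classes are the standard cumulative CAPRI gates — high: fnat ≥ 0.5 and
(L ≤ 1 or I ≤ 1); medium: fnat ≥ 0.3 and (L ≤ 5 or I ≤ 2); acceptable:
fnat ≥ 0.1 and (L ≤ 10 or I ≤ 4) — taking the best class satisfied.
"Near-native" means acceptable or better; a run is "successful" when the
top 10 contains at least one near-native model.

Enrichment counts the overlap between the `ceil(0.10·N)` best-scored models
and the `ceil(0.10·N)` lowest-iRMSD models: (TP/(TP+FP))·((P+N)/P), i.e. 1
in expectation for a random ranking and 10 at the default fraction for a
perfect one. The KS statistic and asymptotic p-value come from
`scipy.stats.ks_2samp`.

## Allostery detection

The weighted HDX scores of the top-10 models by combined score are
averaged; a mean above 0.75 flags the dataset as containing an allosteric
peptide. Identification is leave-one-out on the stored per-model,
per-peptide penalty matrix: excluding a peptide re-sums the raw column,
renormalizes over the full ensemble (a new scale — exclusion changes the
penalty range), recombines, reselects a top-10, and records its mean; the
argmin names the candidate and the scan repeats while the mean stays above
threshold and at least two peptides remain (with one peptide, exclusion
would empty the restraint set and the metric is undefined). The whole
report is a pure function of the score and penalty tables.

The metric has a documented blind spot, reproduced by the failure-mode
fixture: when the base score happens to favor decoys that satisfy the
allosteric restraint, the top-10 mean is near zero and the dataset is not
flagged even though the selected models are wrong.

## Uptake filter

`diff_t = unbound_mean_t − bound_mean_t` (protection positive),
`pooled_sd_t = sqrt(unbound_sd_t² + bound_sd_t²)`. A peptide is interacting
iff some timepoint has `diff ≥ 0.5 Da` **and** `diff ≥ 3.0 × pooled SD`
(the conjunctive, stricter reading of the significance rule; both
thresholds configurable) and the signed cumulative difference over all
timepoints exceeds 1.1 Da. Signed summation means deprotection can cancel
protection, so mixed-direction peptides are conservatively rejected.

## Sampler

Only the antibody moves, as a rigid body about its Cα centroid (relative
motion is equivalent to moving either partner; this convention keeps the
antigen frame fixed for analysis). Scrambled starts displace the antibody
by exactly 10 Å along a uniform random direction, draw a uniform random
orientation (normalized Gaussian quaternion), then apply one Gaussian
perturbation — axis-uniform rotation with angle ~ N(0, 8°), direction-
uniform translation with length ~ N(0, 3 Å) — the same move used as the
Metropolis proposal. The acceptance energy is `surrogate + 1.0 × hdx`
(ratio configurable), temperature 1.0 in surrogate units.

The surrogate score is declared non-physical: +10 per inter-partner Cα pair
under 3.5 Å, −1 per pair in [3.5, 8) Å. It exists only to give sampling a
contact funnel to balance against the restraints; its constants are fixture
calibrations, not energies. Trajectories are bit-reproducible from the
seed, which also stamps each pose's provenance.

## Synthetic fixtures

The toy complex is a Cα-trace construction: a 60-residue antigen chain
along x (zig-zagged ±0.6 Å in y — a perfectly collinear receptor would
leave the superposition roll undetermined), two 24-residue antibody chains
above it with CDR residues (10–15 on each chain) dipped to ~6.7 Å of the
antigen and framework held beyond 12 Å, so only CDRs can satisfy the
10 Å restraint. Each residue carries CA, CB, and O pseudo-atoms; CDR
pendants reach under 5 Å of antigen atoms so the reference has a
well-defined native contact set. Planted interacting peptides span the
epitope (residues 27–40); allosteric peptides sit down-chain (residues
48–58, > 10 Å from any CDR in the reference; the failure-mode case uses
43–47 so a +x-shifted non-native pose can satisfy the full set, found by a
deterministic grid search with a 0.75 Å slack margin).

Decoys are rigid perturbations of the antibody: a 40 % near-native cluster
(≤ 2 Å, ≤ 5°) and a 60 % scattered tail (≤ 20 Å, ≤ 40°), chosen so
ensembles contain both recoverable signal and realistic junk. Each decoy's
iRMSD is computed through the evaluation module itself (an internal
cross-check of the superposition code against the known construction), and
its base score is `−30 + 1.0 × iRMSD + 0.5 × N(0,1)` REU-like units —
correlated but noisy, as interface energies are in practice; zero noise
makes score order equal iRMSD order exactly. Uptake fixtures use two
exposure times (100 s, 1000 s) with planted protections of 0.8/0.9 Da
against 0.03 Da replicate SDs, comfortably clearing every gate, and
zero-mean ~0.05 Da wiggle for filler peptides.

What the fixtures do **not** emulate: real protein shapes, secondary
structure, side-chain packing, self-avoidance, back-exchange, or uptake
kinetics. Passing tests therefore demonstrate the correctness of the
scoring, selection, and detection machinery under controlled geometry, not
docking accuracy on real antibodies.

## Problem sizes and numerical choices

Default study sizes: 120–200-decoy ensembles for allostery recovery
(20 seeds), 200 Metropolis runs × 500 steps for the sampling-shift
comparison, 1000 synthetic (score, iRMSD) pairs for enrichment extremes.
These sizes give stable statistics (the measured sampling shift is
D ≈ 0.28 at p ≈ 2×10⁻⁷) while keeping the full suite around a minute of
compute plus the sampling study. Distance comparisons are strict
inequalities at cutoffs exactly as stated; rigid-motion invariance holds to
1e-6 Å²; penalties and scores are float64 throughout. Degenerate inputs —
all-zero penalty columns, short ensembles (top-n returns all rows),
all-proline peptides, missing residues — are handled as described above
rather than erroring where a convention exists.

## Known limitations

* No mmCIF input; PDB only, single altloc conformer, author numbering.
* `k > 1` stringency penalizes the k-th smallest per-residue minimum
  through the same flat harmonic — a package choice where only the
  requirement ("k residues within d") is standard, reducing to the plain
  shortest-distance form at k = 1.
* The allostery scan rescores only; optional re-docking after each
  exclusion is available through the sampler but is not the default.
* The sampler is rigid-body and Cα-based; it demonstrates restraint-guided
  acceptance, not docking energetics.
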