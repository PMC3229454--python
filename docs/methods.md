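# Methods

## Data model

The unit of observation is the *event*: one (cell line, ligand, time point)
triple. A dataset is a probes × events matrix of log2(treatment/vehicle)
ratios with the six canonical time points 0.5, 1, 3, 6, 12, 24 h. Column
headers use the token grammar `CELLLINE_LIGAND_TIMEh` (e.g.
`HCC1954_BMP4_0.5h`), which encodes the event key losslessly; a reader for
GEO series-matrix-style files (metadata lines prefixed `!`, quoted fields)
accepts the same tokens. Reading validates uniqueness, column grouping by
cell line and ascending time; completeness of the 5 × 6 grid is checked
separately (`validate_grid`) because sub-matrices (one cell line, one time
point) are legitimate intermediates. Gene identifiers are opaque strings;
probe→gene annotation is a user-supplied table whose status per probe
(`unique` / `multiple` / `unannotated`) follows from the gene count. No
live annotation lookups are performed.

Missing values are allowed on input. A probe with a missing value within a
cell line is excluded from that cell line's filter and temporal clustering;
in event counting and the general filter a missing event simply never
counts as regulated. Both choices are conservative: they can only shrink
retained sets and counts.

## Normalization

"Linear normalization" is implemented as a per-array (per-column) affine
map in log2-ratio space: `median_center` subtracts the column median
(default); `median_center_scale` additionally rescales the column MAD to
the grand median MAD. Both are invertible with positive scale, hence
rank-preserving and idempotent; the report stores the offsets and scales
needed to reconstruct the input exactly. Location-only adjustment is the
default because fold-change thresholds downstream operate on the ratios
themselves and a scale change would silently alter effective cutoffs.

## Fold-change filters and event counting

All calls are symmetric and inclusive: `up` iff log2 ratio ≥ log2(FC),
`down` iff ≤ −log2(FC). The general filter retains a probe when it reaches
≥ 3-fold in ≥ 3 events **or** ≥ 2-fold in ≥ 4 events ("and/or" read as
logical OR); an event beyond the 3-fold cutoff also counts toward the
2-fold clause, since a ≥ 3-fold change is by definition ≥ 2-fold. Event
counts per gene use the 2-fold cutoff; with five cell lines the total is
bounded by 30. Ranking is by total events descending, ties broken by up
events descending then gene id ascending (the tie rule is this package's
own; none is standard). When several uniquely annotated probes map to one
gene, the probe with the largest total represents the gene (ties:
lexicographically first probe id) — a deterministic stand-in for manual
curation of multi-probe genes. Probes with `multiple` status are excluded
from gene-level ranking and enrichment unless the caller supplies a
resolved mapping.

## Synexpression groups

Probes surviving the general filter are clustered by UPGMA (agglomerative,
unweighted average linkage) on correlation distance `d = 1 − Pearson r`
across all of a ligand's events. Pearson rather than rank correlation is
used, the conventional metric for log-ratio profile clustering;
zero-variance profiles are dropped with a warning. The implementation
delegates to `scipy.cluster.hierarchy`; tests verify it against a naive
O(n³) re-computation of average linkage.

The original visual delineation of co-expression blocks on a heat map has
no printed threshold, so "tight clusters" are operationalized as connected
components of the dendrogram below a cut height (default 0.3, i.e. mean
within-component correlation around 0.7 or better) that have ≥ 20 members
and mean pairwise correlation ≥ 0.8. All three parameters are exposed; the
defaults are a design choice of this package, not a claim about the
original analysis. The shared synexpression group is the probe-level
intersection of one tight cluster per ligand, with a uniquely-annotated
gene subset for enrichment. Sample-level (column) clustering with the same
metric is provided to verify that samples co-cluster by cell line when
within-line correlation exceeds between-line correlation.

## Temporal mixture model

Profiles (six log2 ratios, one cell line) are scaled to unit Euclidean
norm so that clustering groups by shape rather than amplitude; all-zero
profiles are excluded. Gaussian mixtures are fitted by EM for every
combination of K (default 2–25, capped at n/2) and five covariance
families: spherical or diagonal with shared ("equal") or per-component
("varying") volume, and unconstrained full covariance. Free-parameter
counts are (K−1) + K·d plus 1, K, d, K·d, or K·d(d+1)/2 respectively, and
the selected model maximizes BIC = 2·logL − p·ln(n) (larger is better).
The family set mirrors the classical model-based-clustering repertoire;
the EM is authored in-package because no installed Python library offers
the equal-volume spherical/diagonal families, and `sklearn.mixture`
serves as an independent cross-check in the tests for the families both
implement.

Numerical choices: seeded k-means initialization with 10 restarts per
(family, K) by default, run as short EM bursts (25 iterations) with only
the best start polished to convergence (relative log-likelihood change
< 1e-8, max 500 iterations); responsibilities computed in log space; a
variance floor of 1e-6 guards singular components. The floor makes the
M-step inexact for degenerate components, so if an iteration would lower
the likelihood the fit stops and keeps the previous parameters — the
recorded trace is therefore always non-decreasing, and this is asserted on
every fit. All randomness derives from one seed; fits are bit-reproducible.

Each probe joins its maximum-responsibility cluster. Categories are
assigned at cluster level from the cluster's *original-scale* mean
profile: the earliest time with |mean log2 ratio| ≥ log2(2) determines
early (0.5/1 h), early-intermediate (3/6 h), late-intermediate (12 h) or
late (24 h, i.e. regulated exclusively at the final point); clusters never
crossing the threshold are undetermined. The source analysis states the
rule for gene elements but tabulates categories per cluster; cluster-mean
classification reconciles the two, and a per-probe mode
(`classify_mode="probe"`, majority vote per cluster) is provided. The
2-fold threshold for "first regulated" is a default of this package — the
original threshold is not stated.

## Enrichment

One-sided over-representation only (the analysis reports enriched terms):
for a term with m background genes out of N, and k of the K study genes,
p = P(X ≥ k) for X hypergeometric — computed with `scipy.stats.hypergeom`
and verified against exact rational enumeration in tests. The background
universe is an explicit argument (conventionally all uniquely annotated
genes on the array); genes count once per term regardless of probe
multiplicity; terms with fewer than 5 background genes are skipped
(conventional noise guard). No multiple-testing correction is applied by
default, matching the raw-p reporting style of this analysis genre; BH
q-values are an opt-in column. The term→gene map is flat: no ontology-DAG
ancestor propagation — callers must pre-propagate if they want it.

## Synthetic data generator

The generator emulates the study design: per-ligand 2000 × 30 matrices
over five cell lines (three treated with both ligands), i.i.d.
Normal(0, σ²) nulls with σ = 0.25 log2 units, and 20% responders carrying
a sustained step response of A = 1.5 log2 units (≈ 2.8-fold) from an onset
time drawn from one of the four categories (uniform mixture by default).
Response sign flips to repression independently per (probe, cell line)
with probability 0.3, reproducing the observed cell-line-dependent
direction of regulation; a transient pulse shape is available as an
option, but the sustained step is the default because the category rule
ignores expression after first regulation. A 40-probe synexpression group
shares one latent step profile per (cell line, ligand) plus halved probe
noise; 80% of the group is common to both ligands, and in the three
doubly-treated cell lines the common probes reuse identical latent
profiles, making the shared block recoverable by cluster intersection.
Annotation proportions default to 66% unique / 16% multiple / 18%
unannotated; planted-structure probes are always uniquely annotated so
that the gene-level stages can see them. The ontology is flat: 200
uniform-random 20-gene terms plus one planted term drawn from the early
responder genes. All randomness flows from a single seed and regenerating
with the same seed is byte-identical.

Noise and effect sizes were chosen so that per-event miscalls are rare
(P(|N(0, 0.25²)| ≥ 1) ≈ 6e-5) — the regime in which the fold-change
machinery is meant to operate. What passing recovery tests do *not* show:
real two-color arrays have intensity-dependent bias, correlated probe
noise, transient and ramping response shapes, and annotation errors, none
of which are simulated; recovery rates here are upper bounds on real-data
performance, and the generator's purpose is correctness testing, not
benchmarking.

## Pipeline and reproducibility

`run_pipeline` executes normalize → filter → rank → cluster →
synexpression → temporal → enrichment from one YAML config (defaults
merged with overrides), writing every artifact plus a `manifest.json`
holding the config snapshot, SHA-256 digests of inputs and outputs, and
per-stage parameters. Output paths are recorded relative to the run
directory and no timestamps are written, so a rerun with the same config
and seed produces a byte-identical manifest. A stage failure aborts with
the stage name and leaves a partial manifest.

## Problem sizes in tests

The test and acceptance workloads use the generator's default study
conditions (2000 probes) for filtering, synexpression and temporal
recovery; mixture-recovery checks use K ∈ {3, 5} components at 100 points
each with 6σ separation; the linkage oracle runs at n ≤ 12 leaves where
the O(n³) reference is exact; end-to-end determinism runs a 600-probe
study with a reduced temporal search (K ≤ 5, three families) — the
orchestration being checked is identical at every scale. Temporal searches
in tests cap K at 16, comfortably above the planted cluster structure
(roughly 8 shape classes per cell line) and in line with the 12–22
clusters such data typically yields.

## Known limitations

- The three filters are pure fold-change rules; no variance-based testing.
- Tight-cluster extraction partitions leaves below one global cut height;
  nested or overlapping co-expression blocks are not modelled.
- Cluster-level categorization can mislabel probes inside heterogeneous
  clusters when BIC favors a coarse model; the per-probe mode trades this
  for sensitivity to single-probe noise.
- The enrichment test treats terms independently; overlapping terms are
  not decorrelated, and the discrete hypergeometric tail makes the null
  mildly conservative for small term sizes.
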