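# Methods

`ctdnet` turns z-scored untargeted metabolomics profiles into ranked
differential diagnoses for inborn errors of metabolism (IEMs).  This note
records the models implemented, the parameters that matter, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Data model

A profile is a vector of per-analyte z-scores: abundances expressed in
reference-population standard deviations.  Cells are missing when the
platform detects no peak.  Analytes that are essentially absent from
healthy plasma (argininosuccinate is the canonical case) cannot be z-scored
and are carried as 0/1 presence flags ("binary analytes"); they never enter
network learning but are injected into a patient's perturbation set when
present, because presence alone is strong evidence.

Preprocessing before network learning:

* **Presence filter** — keep metabolites observed in strictly more than
  `min_frac` (default 0.5) of both the disease and the reference cohort.
  Inconsistently detected analytes would contribute mostly imputed values.
* **Minimum-z imputation** — missing cells are filled with the analyte's
  minimum observed z-score in the reference population, the conservative
  reading of "below detection limit".  Binary analytes impute to 0
  (absent).  Imputation is idempotent and applied to reference profiles
  with the same rule.

A patient's **perturbation set** is the metabolites with |z| >= 2.0 (the
conventional two-SD clinical abnormality bound) restricted to a network's
nodes, plus present binary analytes, capped at the 30 largest |z| (binary
presences rank first; ties break by metabolite id).  Threshold and cap are
parameters (`z_threshold`, `max_set_size`); the defaults are package
choices, not values with an external anchor.

## Co-perturbation networks

A disease-specific co-perturbation network is a Gaussian graphical model:
edges are nonzero entries of the precision matrix Θ, weighted by partial
correlation w(i,j) = −Θᵢⱼ/√(Θᵢᵢ·Θⱼⱼ).  Θ is estimated by the graphical
lasso (scikit-learn's coordinate-descent solver) on column-standardized
data, so the penalty acts on the correlation scale.

Two networks are learned: one from pooled disease + control samples and one
from controls alone.  Pooling puts the disease state into the data as a
hidden variable, so metabolites that move with the disease become
conditionally dependent; the control network captures background
physiology.  Every pooled-network edge whose node pair also appears in the
control network is pruned (support membership only — weight sign and
magnitude are ignored).  The pruned network is the disease-specific model.
Treatment-specific networks use the same construction with the roles
treated/contrast/untreated-same-disease.

**Penalty selection (StARS).**  The path is 30 log-spaced penalties from
λ_max (the largest absolute off-diagonal sample correlation, where the
graph is empty) down to 0.01·λ_max.  For each penalty, the glasso is fit on
20 random subsamples; per-edge instability is 2f(1−f) for selection
frequency f, averaged over all pairs; the average is monotonized from the
sparse end, and the smallest penalty with monotonized instability <= 0.1 is
selected.  Subsamples contain floor(0.8·n) observations — the 10·√n rule
exceeds n itself below n = 145, where 80% subsampling is the standard
fallback.  Penalties at which any subsample fit is numerically
ill-conditioned (the dense end when p approaches the subsample size) are
scored at the maximal instability 0.5 and can never be selected; since the
monotonized instability only grows toward the dense end, the path walk
stops as soon as it crosses the threshold, which skips most of the dense
fits without changing the selection.  Subsample fits use a loose tolerance
(1e-3, 100 iterations) because only the support matters; the final fit at
the selected penalty uses 1e-4/200.  Cohorts below 10 samples cannot be
subsampled meaningfully; they skip StARS and use the rate-based penalty
√(log p / n), flagged in provenance.

Recommended cohort sizes are at least 5 disease and 25 reference profiles;
the learner warns below these.  Surrogate profiles (bootstrap-resampled
disease columns plus Gaussian noise, sd 0.1) can be appended via
`n_surrogates`, but are off by default: on the synthetic benchmarks they
duplicate outlier cells and stabilize spurious edges more than true ones.

## The connectedness score (CTD)

Given a network with n nodes and a node set S with k members, the score
asks whether S is more tightly connected than a random size-k set, phrased
as code lengths:

* **Fixed code**: any size-k subset can be named in log2 C(n,k) bits.
* **Adaptive code**: name a start node (log2 n bits), then walk the network
  by probability diffusion — each anchor spreads unit mass to unvisited
  neighbours in proportion to |weight|, a node keeps half of what it
  receives and passes on the rest, dead ends and mass below 1e-4 are
  retained — always stepping to the highest-scoring unvisited node, and
  re-anchoring on every member of S found.  The transcript is one
  found/not-found bit per ranked node and stops at the k-th member, so the
  cost is log2 n plus the position of the last found member.  Members the
  walk cannot reach (disconnected remainder) are named by fixed log2 n
  pointers instead.  I(S) is the minimum over start choices.

Edge signs are ignored throughout: co-perturbation strength, not direction,
drives connectedness.  All ties break lexicographically by node id, so the
scorer is fully deterministic.

Because the adaptive code is prefix-free and uniquely decodable (a decoder
can replay the walk, re-anchoring as it learns which ranked nodes are
members), Kraft's inequality bounds how many subsets can compress well:

    #{S of size k : bits_saved(S) >= b} <= C(n,k) · 2^(−b),

with bits_saved(S) = log2 C(n,k) − I(S).  Hence p = 2^(−bits_saved) is an
honest connectedness p-value with no permutation testing.  The enumerative
baseline log2 C(n,k) (rather than the ordered-code k·log2 n) is what makes
the bound exact; the test suite verifies it by exhaustively enumerating
every subset of size <= 5 on five graphs.  Two limits are exact by
construction: singletons save nothing (p = 1, also on edgeless networks),
and a k-clique found consecutively costs log2 n + (k−1) bits.

`ctd_pvalue` additionally scans every walk prefix: the first j members
found form their own encodable subset, and the prefix maximizing bits saved
is reported as the **optimal highly connected subset** with its p-value
(ties prefer larger subsets, then lexicographic order).  Both the
optimal-subset p and the full-set p are exposed; scoring uses the
optimal-subset p, which is what "module detected" refers to.

## Distances

With I(·) as above and I(S₁,S₂) := I(S₁ ∪ S₂),

    ncd(S₁,S₂) = max(I(S₁,S₂) − I(S₁), I(S₁,S₂) − I(S₂)) / max(I(S₁), I(S₂)),

clipped to [0,1] (the pre-clip value is kept in a diagnostic field).  The
patient-patient distance (CTDncd) applies this to two perturbation sets;
the patient-disease distance (CTDdm) applies it to a perturbation set and
the disease's **main disease module**: the CTD optimal subset of the
metabolites perturbed in more than half of the disease cohort (fallback:
top 10 by median |z| when nothing recurs).  For treatment modules the
recurrence is differential — candidates recurrent in treated patients are
dropped if they also recur in untreated patients with the same disease —
which isolates treatment signal even when the treatment network retains
residual disease edges.

CTDdm distances are converted to probabilities by an add-one left-tail
empirical percentile against the reference cohort's distances to the same
module: p_dm = (#{reference <= d} + 1)/(n_ref + 1).  Small distance means
disease-like, hence a left tail.

Cohort geometry: pairwise CTDncd matrices are embedded by classical
(Torgerson) MDS — double-center −D²/2, top eigenpairs, axis signs fixed by
the largest-magnitude loading, eigenvalues below 1e-12 of the largest
treated as rank noise — chosen over stress-based MDS for determinism.
Cluster quality is k-means purity (50 seeded restarts): the fraction of
samples whose cluster's majority class is their own.  Centroid separation
is the Euclidean distance between group means in the embedding.

## Diagnosis

Each disease model carries its network, main module, the reference null of
module distances, and per-reference (p_ctd, p_dm) pairs.  A sample scored
against a model yields p_ctd (optimal-subset connectedness p), d_dm and
p_dm, combined by **Brown's method**: T = −2(ln p_ctd + ln p_dm) compared
to a scaled chi-square with f = 2E²/Var and c = Var/(2E), where E = 2k and
Var = 4k + 2·cov, cov being the sample covariance of the (−2 ln p) pairs
across reference samples.  With fewer than 10 reference pairs the
covariance is unreliable and the combiner falls back to Fisher's method
(zero covariance), to which Brown reduces exactly.  p-values are floored at
1e-300 before taking logs.

Diseases are ranked by combined p (ties by label).  The differential
diagnosis (DD) list holds diseases with p below the Bonferroni-corrected
threshold α/n_models (α = 0.05); correction applies only at DD membership,
not to the ranking itself.  Evidence grades for variant re-interpretation:
HIT below 0.05, BORDERLINE HIT in [0.05, 0.15), NONE otherwise.  The
five-class genotype categorization (pathogenic/VUS counts by zygosity under
an autosomal recessive model) is a pure rule table, evaluated in order
from class 1 to 5 with an explicit "unclassified" fallback.

Cohort metrics: top-1/top-3/in-DD fractions over disease samples,
DD-length median with 5th/95th percentiles, per-disease
sensitivity/specificity/accuracy from HIT calls, and the median DD length
of reference samples as the specificity proxy (a perfectly specific method
assigns healthy profiles an empty DD).

## Synthetic cohorts

Reference samples are independent standard normals per metabolite.  Disease
samples replace the module rows with effect + √ρ·f + √(1−ρ)·ε, where f is a
per-sample latent severity factor: the mean shift (default 3 SD) makes the
module clinically abnormal, and the latent factor (ρ = 0.6 by default)
makes it *co*-perturbed, which is the structure the network learner
presupposes — independent shifts would move means but give the glasso
nothing to find.  Missingness is uniform at 10% by default, except that a
module node never loses more than half its disease observations (a module
absent from the data would make recovery ill-posed rather than hard).
Optional layers: treatment overlays (the same latent-factor construction on
a node subset of a sample subset, with a metadata flag), and binary
analytes with disease-conditional presence probabilities.  All randomness
derives from one seed; identical specs produce byte-identical cohorts.

What the generator does *not* emulate: batch and platform effects,
anticoagulant differences, value-dependent (informative) missingness,
heavy-tailed analyte distributions, or correlated background metabolism.
Passing benchmarks therefore demonstrate that the pipeline recovers planted
structure under idealized noise, not clinical performance.  One concrete
consequence of uniform missingness is worth recording: constant minimum-z
imputation of randomly missing cells plants ~−2 outliers that produce
heavy-tailed spurious correlations, which subsampling cannot destabilize
(the outliers persist in 80% subsamples); on the recovery benchmark this
costs edge precision (median ~0.49 across seeds) while recall stays high.
In real data missingness is concentrated near the detection limit, where
the minimum-z fill is consistent with the truncated distribution rather
than an outlier.

## Benchmark scenarios and sizes

Scenario runners in `ctdnet.benchmark` use desk-scale sizes chosen to keep
a full run in minutes on one core while preserving the qualitative regime
(p comparable to n, modules a small fraction of the namespace):

* **Recovery**: 6-node module, effect 3 SD, 20 disease / 40 reference,
  p = 30, 20 seeds; reports planted-edge recall and precision of the pruned
  network (planted truth = the within-module clique).
* **Ranking**: 5 diseases with disjoint 6-node modules, 8 patients each,
  25 shared references, p = 34, one shared control network, a 20-penalty
  path; reports top-1/in-DD and the reference DD-length median.
* **Treatment censoring**: disease A (30 patients, 2/3 on a treatment with
  a 4-node overlay) and disease B (10 patients) whose module contains the
  overlay; the treatment network is learned treated-vs-untreated, its main
  module censored from A's network; reports B→A false HITs and A's top-1
  before/after.
* **Geometry**: three 12-patient cohorts with distinct modules on a fixed
  three-clique network; reports CTDncd→MDS→k-means purity.

## Known limitations

* The walk costs grow with set size and network density; the 30-node cap
  on perturbation sets keeps scoring fast but discards weaker perturbations
  in profiles with massive disruption.
* The optimal-subset p-value is a maximum over prefix subsets of all walk
  starts; the per-size Kraft bound applies to each candidate subset, but
  the scan across sizes is not additionally corrected (the same choice the
  ranking inherits).
* Gaussianity is assumed after standardization; no nonparanormal
  transformation is applied.
* Brown's covariance is a two-test scalar; combining more than two
  evidence channels would need the full covariance matrix.
* Binary analytes contribute to perturbation sets only; a mixed graphical
  model over continuous and binary nodes is out of scope.
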