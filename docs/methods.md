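# Methods

## Model and procedure

The analysis treats a set of 26 default-mode-network (DMN) regions of
interest — Brainnetome parcels 11–188, 13 per hemisphere, identified by
their atlas integer throughout — as nodes of an undirected graph.  Each
group × modality input is a symmetric weighted connectivity matrix:
structural (SC) weights are non-negative streamline-derived edge weights,
functional (FC) weights are Fisher-z-transformed Pearson correlations of
regional time series.  The diagonal carries no edge information and is
zeroed on ingestion; asymmetry up to 1e-6 is treated as export rounding and
symmetrized by averaging, anything larger is rejected as corrupt.

The procedure is: **threshold → binary graph → controllability and
robustness**.

### Graph construction

*Percentage (proportional) thresholding.*  With m strictly-positive
off-diagonal magnitudes of the reference matrix sorted ascending, the
cutoff for removal fraction f is the value at rank ⌈f·m⌉ — the largest
magnitude among the removed fraction — and an edge survives iff its own
magnitude strictly exceeds the cutoff.  Consequences of this convention:
exactly the weakest fraction is removed when values are distinct, ties at
the cutoff are all removed (deterministic and conservative), and f = 0
degenerates to the zero-threshold method (keep every non-zero connection).
Cutoffs are computed from the *control* group's matrix per modality and
fraction and applied to all groups — the comparison convention of the study
design — with a per-graph mode available for sensitivity analysis.  The
canonical sweep is f ∈ {0.025, 0.05, 0.10, 0.20, 0.30}, and the headline
driver statistic is the arithmetic mean of the five per-fraction counts.
Thresholds operate on magnitudes |w|: FC matrices contain negative
correlations, and magnitude thresholding is the common connectomics
convention; a signed mode exists behind a flag.

*Adaptive thresholding (ATH).*  Bisection on t over [0, max|w|] for the
largest cutoff whose graph (edges where |w| > t) is still connected, to an
absolute accuracy of 1e-4 on t.  "Connected" means one component, not
complete; a disconnected zero-threshold input is refused rather than
silently processed.

*Partial correlation (PCM).*  Defined on FC only.  The stored Fisher-z
values are mapped back to correlations (tanh), the unit diagonal restored,
and the precision P = R⁻¹ normalized to partial correlations
ρᵢⱼ = −Pᵢⱼ/√(Pᵢᵢ Pⱼⱼ); edges where |ρ| exceeds a soft threshold
(default 0.1, configurable — the literature recommends soft thresholding
without a canonical value).  A correlation matrix whose smallest eigenvalue
is ≤ 1e-10 raises an error naming that eigenvalue; ridge regularization is
suggested in the message, never applied silently.

*Chow-Liu tree (CLA).*  The maximum-weight spanning tree over |w|, Kruskal
on descending magnitude with ties broken by ascending (label_i, label_j),
which makes the tree canonical.  Always N − 1 = 25 edges at N = 26.
Disconnected inputs are refused: a silently returned spanning forest would
report spurious dependencies.

### Controllability

For the linear dynamics x(t+1) = A x(t) + B_K u_K(t) on a symmetric 0/1
adjacency A, the minimum number of driver nodes equals the maximum
eigenvalue multiplicity of A (geometric = algebraic for symmetric
matrices).  Eigenvalues are clustered with a scale-aware tolerance
N·ε·max|λ| (floor 1e-9): integer-matrix spectra at N = 26 are
well-conditioned, and the floor merges the near-degenerate pairs that
binarized connectomes produce.  The concrete driver set comes from the
column canonical form of M = λ_M·I − A for the class λ_M of maximum
multiplicity (smallest representative on ties): rows are eliminated in
ascending ROI-label order with partial pivoting on magnitude (lowest label
wins exact ties), and the rows left without a pivot — the linearly
dependent rows — index the drivers.  This fixes one canonical set among
the generally non-unique minima; the report also carries λ_M and the
multiplicity so non-uniqueness is visible.

Every returned driver set is verified against the PBH criterion
rank([λI − A, B]) = N for all eigenvalue classes, which for symmetric A
reduces to the driver-indexed rows of each eigenvector block having full
column rank.  A subtlety handled explicitly: with one unit input column per
driver node, a λ_M-derived set of size max-multiplicity is *not* always
controllable — for some degenerate spectra (e.g. a triangle plus an
isolated node) no set of that size is, which we verified by exhaustive
subset search on all 208 graphs with ≤ 6 nodes (70 such cases, all with
the degeneracy structure above).  `identify_drivers` then searches for a
valid set by greedy joint coverage of all eigenspaces at the same size,
then bounded exhaustive search by ascending size (globally minimal when it
runs, budget 20 000 candidate subsets), then greedy augmentation; the
result is flagged `augmented` whenever it exceeds the max-multiplicity
count, which remains the reported controllability statistic.  No subset
smaller than the max multiplicity can ever pass PBH (the λ_M block cannot
reach full column rank), so minimality of unflagged sets is structural.
The dynamics are never numerically integrated: controllability is assessed
algebraically, avoiding Gramian conditioning issues.

### Critical nodes

Each node is deleted in turn (with its incident edges; nodes isolated by
the deletion remain) and the driver count of the reduced graph recomputed.
A node is critical iff the count strictly exceeds the *original* graph's
count, even though N has shrunk by one.  Closed-form anchors: a star's hub
is critical (removal leaves the empty graph, count N−1 > N−2), its leaves
are not, and no node of a complete graph is.  By default critical nodes
are evaluated on the 30%-threshold graph, the study's illustrated
operating point; the method is available for any constructed graph.

### Robustness

Algebraic connectivity is read directly from the sorted Laplacian spectrum
(L = D − A); no connectivity pre-check, since a disconnected graph scoring
0 is the signal, not an error.  Natural connectivity
ln((1/N)Σ exp(λᵢ)) is evaluated with log-sum-exp: e^λ overflows for large
positive eigenvalues even at modest N.  Both are computed on the
*binarized* graphs, matching the pipeline order; weighted variants are out
of the default path.

## Synthetic data generator

The patient data the design derives from is not public, so a generator
emulates its statistical shape.

*FC.*  Node i's time series is a·lᵢ·f(t) + εᵢ(t): k = 5 shared latent
factors (loadings ~ N(0, 1/k), drawn once per seed), group attenuation a,
independent Gaussian noise of sd 0.1, T = 500 time points.  The sample
correlation of such series is a valid correlation matrix by construction
(symmetric PSD, unit diagonal); it is stored Fisher-z transformed.  The
latent-factor route was chosen over direct matrix sampling precisely for
that PSD guarantee, plus a tunable signal-to-noise knob.  T = 500 matches
a typical resting-state acquisition length after standard preprocessing.

*SC.*  Bernoulli edge presence at density 0.5 (1.5× denser within than
between hemispheres, capped at 1 — bilateral DMN parcels are more densely
tracked intra-hemispherically; the 1.5 factor is a free modeling choice),
gamma(2, 1) weights (non-negative and right-skewed, like streamline-count
ratios), and a connectedness repair that joins components with a random
spanning tree of minimum-weight edges, since ATH and CLA presuppose a
connectable graph.

*Group structure.*  Attenuation control 1.0 / IDHmut 0.8 / IDHwt 0.6
multiplies FC loadings and SC weights; optional lesions halve a node's
loadings/incident weights on top.  The structural base (SC topology and
weights, FC loadings) depends on seed and modality only, so the same seed
gives the same underlying network across groups and the attenuation ratio
is exactly recoverable edge by edge; group identity enters through
attenuation, lesions, and the group's own FC noise realization.  Every
matrix is regenerable in isolation from (seed, group, modality).

*What the generator does and does not show.*  Under the shared control
cutoff, attenuated groups keep fewer edges, so the robustness ordering
control ≥ IDHmut ≥ IDHwt emerges strictly for SC; this is the direction of
effect the pipeline must expose, and the only claim tested.  The
generator's binarized graphs are spectrally generic — sparse random graphs
have mostly simple eigenvalues — so synthetic driver counts sit near 1 and
the driver-count ordering is typically realized with equalities, unlike
real group-averaged connectomes whose structural regularities produce
larger eigenvalue multiplicities and driver counts near 9.  Passing the
trend tests therefore demonstrates the machinery and the direction of the
group effect, not the magnitudes of any real cohort.  Relatedly, a lesion
makes the affected node *need* input in patients: lesioned nodes are
enriched among patient-only ("alternative") SC drivers, rather than
disappearing from control driver sets, and that is the property the test
suite asserts.  Halving FC loadings barely moves strong correlations (the
attenuation largely cancels in a correlation), so group contrast in FC is
intentionally weak at the default noise level.

## Numerical choices and degenerate inputs

- Eigenvalue clustering: N·ε·max|λ| with floor 1e-9; elimination pivot
  threshold 1e-8·N·max|M| with a rank-consistency fallback.
- PBH rank tolerance 1e-8 on eigenvector sub-blocks.
- ATH bisection: absolute 1e-4 on the cutoff; raising the returned cutoff
  by twice the tolerance provably disconnects the graph.
- All-zero matrices threshold to the empty graph (warning, not error); a
  fraction that removes every edge likewise warns.
- Kruskal and elimination tie-breaks are by ascending ROI label, making
  every reported set reproducible bit for bit; report JSON is written with
  sorted keys and 12 significant digits, so identical configurations yield
  byte-identical files.
- noise_sd = 0 with one latent factor yields ±1 correlations; the
  generator warns and clips rather than erroring.

## Problem sizes

Exhaustive oracles run on all 208 non-isomorphic graphs with ≤ 6 nodes
(PBH equivalence) and all subsets at ≤ 5 nodes (minimality); spanning-tree
enumeration at ≤ 7 nodes; Monte-Carlo trend checks over 30 seeds at the
full 26-node default configuration.  These sizes make every oracle exact
or well-converged while keeping the whole suite under a minute.

## Known limitations

- Driver sets are generically non-unique; only one canonical choice is
  reported (count, λ_M and multiplicity disambiguate).
- The generator is uncalibrated against any real cohort — weight
  distributions were never published — so only direction-of-effect claims
  are meaningful on synthetic data.
- Percentage thresholds count fractions among *present* (non-zero)
  connections, not all N(N−1)/2 pairs: an absent connection cannot be
  removed.
- The pipeline analyzes 26-node submatrices; no neuroimaging formats or
  whole-brain parcellations are read.
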