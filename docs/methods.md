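# Methods

`dynmod` implements a dynamic network-reconfiguration analysis for
block-design working-memory fMRI: weighted functional connectivity with
hemodynamic (HRF) weighting, static and multilayer modularity
maximization, module-allegiance cartography, and signal-detection
behavioral scoring — together with a synthetic-data generator that plants
known community structure so every stage can be validated against ground
truth. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Connectivity model

Node signals are ROI-mean time courses annotated per volume with a task
block index and condition label. Because the BOLD response lags and
smears the neural signal, per-condition and per-block connectivity uses a
*weighted* Pearson correlation: the condition (or block) boxcar is
convolved with a canonical double-gamma HRF (peak shape parameter 6 s,
undershoot 16 s, peak:undershoot amplitude ratio 6, 32 s support —
config-exposed as `hrf.peak_s`, `hrf.undershoot_s`, `hrf.ratio`,
`hrf.length_s`), negative lobes are clipped, and the resulting
nonnegative time course weights each retained volume. Weighted moments
use the standard weighted-mean/weighted-covariance definitions, so the
estimator reduces to ordinary Pearson under uniform weights and is
invariant to positive rescaling of the weights.

Correlations are Fisher-z transformed (arctanh; inputs clipped just
inside (-1, 1) so collinear ROIs give a large finite weight rather than
infinity) and negative edges are set to zero. Because arctanh is odd and
monotone, rectifying before or after the transform is equivalent; the
fixed order (correlate, transform, rectify) makes outputs bit-stable.
Self-edges are zero, not one, so modularity never counts self-weight.
Volumes carrying no condition label (instruction screens, rest) belong to
no block mask. Per-block matrices recompute the HRF weights from each
block's own boxcar rather than slicing the condition-level weights; the
two choices differ only at block edges, and recomputation keeps each
layer self-contained.

## Static modularity and its null

Whole-brain segregation is Newman–Girvan modularity

    Q = (1/2mu) * sum_ij (A_ij - gamma * k_i k_j / 2m) * delta(g_i, g_j)

with the configuration null, gamma = 1 by default (config-exposed), and
the double sum running over all ordered pairs including i = j — hence the
all-in-one partition scores exactly 0 and the singleton partition scores
the negative null diagonal. Optimization is a Louvain-style greedy on the
dense modularity matrix: seed-randomized node sweeps (a node joins the
community with maximal positive gain; candidate order randomized, first
maximum wins; gain tolerance 1e-10), aggregation, and — unlike the
textbook two-phase scheme — node-level refinement of the coarse solution,
the whole cycle iterated to a fixpoint. The refinement step matters: on
small graphs the pure two-phase scheme can lock nodes into early merges,
and with it best-of-100 restarts reproduces the exhaustive global maximum
on every random graph up to n = 8 that we test. The best of `n_runs`
restarts (default 100) is kept, ties broken by run index; restart seeds
derive from a master seed by counter, and odd-indexed restarts begin from
a random partition rather than singletons — on some graphs every
singleton-start trajectory shares one suboptimal basin, and start
diversity is what lets the restart protocol escape it. Module labels are
canonicalized by first appearance.

Raw Q depends on the network's total strength, so it is normalized by the
mean Q of `n_null` (default 100) degree-preserving rewired null networks:
Maslov–Sneppen double-edge swaps on the nonzero-edge topology, 10
successful swaps per edge, with weights riding on the swapped edges —
preserving the unweighted degree sequence and the weight multiset
exactly. Each null is scored with the same restart protocol as the
observed network. Graphs too dense or small to swap fall back (with a
warning) to shuffling weights over the fixed topology, which preserves
the same invariants.

## Multilayer modularity

Per-block matrices form the layers of a categorical multilayer network:
every node couples to itself in *all* other layers, with coupling
omega = 1 between same-condition layers and 0.5 between different-
condition layers. All-pairs coupling is the only topology consistent with
condition-dependent coupling in an alternating design, where
same-condition blocks are never adjacent. The quality function is

    Q_ML = (1/2mu) * sum_ijsr [ (A_ijs - gamma_s k_is k_js / 2m_s) delta_sr
                                + delta_ij omega_sr ] * delta(g_is, g_jr)

with a per-slice configuration null; interslice couplings enter as
+omega only (no null penalty) and 2mu sums every node-layer's intra-layer
strength plus its summed couplings. With one layer this reduces exactly
to static Q, and the test suite holds the two implementations to 1e-10
agreement.

Optimization runs the same greedy on the supra-modularity matrix over
(node, layer) pairs. Greedy single-node moves have a known failure mode
here: relabeling one instance of a node is coupling-penalized even when
relabeling all of its same-condition instances together would raise
Q_ML — so a coordinated reconfiguration confined to one condition can be
unreachable from a singleton start. The optimization ensemble (default
100 members, all retained for allegiance) therefore alternates two
starts: singleton, and a condition-wise warm start that partitions each
condition's *mean* connectivity matrix and initializes every layer from
its condition's partition. The warm start is data-derived (it sees only
the observed layers and their condition labels) and the exactly-evaluated
Q_ML still arbitrates; an alternative per-layer-independent warm start
was tried and discarded because it lowered attained Q_ML. When both
couplings are zero the supra problem is block-diagonal and the
implementation factorizes exactly into independent per-layer runs.

## Allegiance cartography

An ensemble of O multilayer partitions over T layers is summarized by the
allegiance matrix P, with P_ij the fraction of the O*T (optimization,
layer) instances co-assigning nodes i and j; the diagonal is identically
1. Recruitment of a system S is the mean of P over S x S (diagonal terms
included, per the plain double-sum definition; a diagonal-excluding
variant is available via the low-level helpers for sensitivity checks),
and integration of two systems is the mean of P over their rectangle.
Both are biased by system size, so each coefficient is divided by its
mean over `n_perm` (default 1000) permutations of the whole ROI-to-system
label vector (system sizes preserved; permutations regenerated, seeded,
per allegiance matrix). A constant P normalizes to exactly 1, and on
label-exchangeable random P the mean normalized recruitment is 1 to
within Monte-Carlo error — the size bias is removed.

## Behavioral scoring

Trial outcomes per subject x session x condition x modality are scored as
d' = Z(H) - Z(F) with Z the standard-normal quantile (scipy), H the hit
rate over targets and F the false-alarm rate over non-targets. Rates of
exactly 0 or 1 — and only those — are replaced by 0.01 / 0.99, making the
clamp idempotent and the attainable ceiling 2 * Z(0.99) ≈ 4.653. The two
modalities are averaged into one cumulative d'. Group-level percent
improvement between two sessions is reported as the percent change of the
group-mean d'; the alternative aggregation (mean of per-subject percent
changes) is exposed behind `per_subject=True` because group summaries of
relative change are not unique, and the two can differ materially.

## Synthetic-data generator

The generator emulates one scanning run of the dual n-back design: 20
alternating 1-back/2-back blocks, 15 volumes per block at TR = 2 s, with
a planted node-to-module partition per block. Block samples are drawn
from a zero-mean Gaussian whose correlation matrix is compound-symmetric
on the partition: unit diagonal, `rho_within` on same-module pairs,
`rho_between` elsewhere — positive definite for all admissible
0 <= rho_between <= rho_within < 1, by the decomposition into PSD parts
plus (1 - rho_within) I. The rho parameters are therefore the *observed*
correlations of the generated signal; `noise_sd` adds optional
independent measurement noise on top (the pipeline's demo study default
is 1.0, which attenuates a planted 0.6 to an observed ~0.3, a realistic
ROI-correlation magnitude; the recovery benchmarks use 0 so they run at
their stated correlation structure). Blocks are clean by default; an
optional `hrf_smear` flag convolves the latent signals with the canonical
HRF so block boundaries bleed as in BOLD data. All streams derive from
one master seed by counter. Trial outcomes are Bernoulli: binomial hits
over targets and false alarms over non-targets with controllable rates.
The pipeline's default rate trajectories describe a six-week adaptive
training course (experimental group improving strongly on 2-back,
passive controls mildly); they were fixed once as plausible values, not
fitted to any dataset.

What the generator does *not* emulate: voxel-level structure, realistic
fMRI noise spectra (drift, physiological), motion, or preprocessing
artifacts. Passing benchmarks therefore show that the estimators recover
the structure the analysis model assumes, under that model; they do not
validate the upstream preprocessing of real data.

## Benchmark problem sizes

The recovery benchmarks use 60 nodes in 4 equal systems (rho 0.6/0.05, 20
blocks x 15 samples, 20 generator seeds), the package's chosen desk
scale. Restart/null/ensemble counts follow the defaults (100 restarts,
100 rewired nulls, ensembles of 25–100, 100–1000 permutations as noted in
each test). One relevant scale effect: with N = 60 the summed interslice
couplings (~14 per node-layer) are comparable to intra-layer node
strength, so the multilayer optimum is closer to the coupling-dominated
(layer-constant) regime than at a 264-node parcellation where intra-layer
strength is several times larger. The planted stable-vs-splitting
recruitment contrast is detected in ~95% of generator seeds; in the
remaining panels the layer-constant solution genuinely attains the higher
Q_ML and non-detection is the correct answer to the optimization problem
as posed.

## Known limitations

- The greedy optimizer is a local method; outside the tested small-graph
  regime global optimality is not guaranteed, only restart-stabilized.
- The rewiring null preserves the degree sequence and weight multiset but
  not the node strength sequence.
- Multilevel (nested random-effects) inference is out of scope; the
  statistical layer provides the planned follow-up contrasts (paired and
  Welch two-sample t-tests, Pearson correlations) with Bonferroni and
  Benjamini–Hochberg adjustment per contrast family.
- Signed-network variants (negative edges kept) are not implemented;
  negative correlations are rectified away.
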