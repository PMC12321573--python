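# Methods

This note documents the models, statistical procedures and design choices
behind `l5et`, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what passing the test suite does and does
not demonstrate.

## Scientific setting

Layer-5 extratelencephalic neurons (L5-ET, the thick-tufted pyramidal cells
that project subcortically) distribute their local axonal output in a highly
structured way: proximal synapses go predominantly to specific inhibitory
cell types that reciprocate, while distal and interareal synapses go mostly
to excitatory cells, chiefly L6 pyramids and L5 intertelencephalic (L5-IT)
neurons. The package implements the quantitative machinery needed to
characterize this architecture from a connectome — a neuron table, axon
skeletons and a synapse table — together with a synthetic connectome
generator so that every analysis can be exercised, calibrated and validated
at desk scale without the petascale electron-microscopy volume the
measurements come from.

## Coordinate and data conventions (`core_model`)

Positions are in micrometres; `y` is depth below the pia (positive
downward); the plane `x = 0` separates the primary visual area (VISp,
`x < 0`) from the higher visual area. Skeletons are standard 7-column SWC
rooted trees (1 = soma, 2 = axon, 3 = dendrite). Unknown categoricals are
preserved as `"unknown"`: the accounting of undetermined synapses is part of
the analysis (class partitions must conserve the synapse count), so nothing
is silently dropped. Saving is byte-stable (sorted ids, fixed float
precision) so identical connectomes produce identical files.

## Synthetic connectome generator (`synthetic`)

The generator emulates the statistical structure of the real dataset; it is
not a biophysical growth model.

**Neuron population.** Deterministic largest-remainder apportionment of the
configured mixtures (inhibitory fraction 0.13; L5-IT/L5-ET/L5-NP = 12.4%,
3.5%, 1.5% of excitatory cells), uniform lateral placement, depths drawn
within per-layer bands.

**Axons** are branching persistent random walks (default: 4 primaries,
20-µm steps, persistence 0.85, branch rate 2.5 × 10⁻³ µm⁻¹ per tip,
termination 5 × 10⁻⁴ µm⁻¹), grown until a drawn cable budget
(N(7324, 2128²) µm for ET cells) is spent, reflected at the volume bounds.
An ET axon crosses the area border exactly when its collateral flag (drawn
with probability 10/12) is set. Only summary statistics — cable length,
synapse counts, border crossing, the path-distance distribution of synapses
— are matched to data; the geometry itself is phenomenological.

**Distance rule.** The probability that an output synapse targets an
inhibitory cell is a two-asymptote logistic in axonal path distance,
`p(d) = 0.2 + 0.6·σ((375 − d)/150)` (µm). The asymptotes (≈0.8 proximally,
≈0.2 at 750 µm) are data constraints; the midpoint and slope are free
choices that make the decline essentially monotonic over 0–750 µm. Because
classes are drawn per *connection* while the rule is stated per synapse, and
inhibitory connections carry more synapses (mean 1.9 vs 1.1), the
connection-level probability is inverted from the synapse-level target:
`q = p·m_e / (m_i(1−p) + p·m_e)`. Synapse slots are sampled uniformly per
unit cable and consumed in path-distance order; a connection's synapses
occupy consecutive slots, which shifts realized synapse positions slightly
distal of the draw position and makes the realized proximal fraction land
1–3 percentage points under the rule's value — the test tolerances (±0.08
on the proximal-100 median, ±0.10 on the profile endpoints) cover this
attribution shift plus seed-to-seed sampling spread.

**Multiplicity** is zero-truncated negative binomial, numerically
reparameterized so the truncated mean equals the configured target (1.9 for
inhibitory, 1.1 for excitatory), clipped at the observed ranges (28 and 4).
Each presynaptic cell draws its partners without replacement (falling back
to reuse only when a pool is exhausted) so that pair-level multiplicity
statistics recover the configured distribution.

**Synapse sizes** are lognormal per (pre, post) subclass pair. For the
ET→NP pair the tails are removed by redrawing outside the central
[0.10, 0.90] quantile band, emulating the absence of the very small and very
large synapses seen in ET→ET connections. The band width is a power choice:
truncation at quantile q produces a maximum CDF separation ≈ q, and the
two-sample KS critical value at n = 1000 + 1000 (α = 0.05) is 0.061, so
q = 0.10 yields ≥90% detection power while q = 0.05 would not.

**Interneuron structure.** Each interneuron's ET-targeting output fraction
is drawn from a Beta mixture (Beta(2,18) for group 1, Beta(12,12) for
group 2, group-2 weight 0.35) so the 25% partition threshold separates the
modes. ET→interneuron connections pick a group-2 cell with probability 0.78
(the configured synapse share). Reciprocity is generated explicitly: each
connected (ET, interneuron) pair is flagged reciprocal with a
group-dependent probability (defaults 0.60 group 2, 0.15 group 1), flagged
pairs receive a return connection, and the interneuron's remaining
ET-directed output avoids its presynaptic partners — so the measured
reciprocal rate equals the configured probability rather than being inflated
by accidental returns. Output placement profiles (perisomatic for PeriTC,
distal and apically biased for DistTC, strictly monosynaptic for SparTC,
inhibitory-preferring for InhTC) are what make the six output features
separable.

**What the generator does not emulate:** dendritic morphology (targets have
no dendrite skeletons — distances to the target soma fall back to Euclidean),
realistic axon geometry, correlated spatial clustering of cell types, any
functional (activity) structure, and segmentation artifacts beyond a flat
7% orphan rate. Passing recovery tests therefore shows the *analyses* are
correct and calibrated, not that the generator is a substitute for data.

## Cell typing (`cell_typing`)

**Inhibitory features.** Six fractions of a cell's output synapses: onto
inhibitory targets; onto excitatory somata; onto proximal dendrites (≤50 µm
from the target soma — measured along the target skeleton when one with
dendrite nodes exists, else Euclidean); onto distal apical dendrites
(>50 µm and above the soma, i.e. toward the pia — the compartment labels
carry no explicit apical flag); in multisynaptic (≥2-synapse) connections;
and, of those, within 15 µm of another same-target synapse. Undefined
fractions (empty denominators) are flagged, not zeroed silently. A linear
discriminant over these features separates the perisomatic-targeting and
distal-targeting subclasses with accuracy 1.0 on held-out generator cells.

**Excitatory morphometrics.** Fifteen scalar features (tip distances,
tortuosity, input counts and sizes, depth percentiles, linear synapse
density over 50 depth bins, skeleton radius beyond 30 µm, 97th-percentile
radial extent) plus component loadings: SparsePCA (6 components) of the
z-scored 50-bin depth profile, SparsePCA (5) of 13 soma-adjusted bins
spanning ±100 µm, and truncated SVD (3) of branch counts at ten 30-µm
distance shells. All positions pass through a rigid 5° rotation that
flattens the pia before depth measurements. The decomposition bases are fit
on the analysis cohort and serialized with the pipeline so loadings are
reproducible.

**Consensus clustering.** 100 runs of: subsample 97% of cells, build a
10-nearest-neighbour graph, Leiden community detection at resolution 1.3
(run r seeded with base + r). Co-clustering counts are normalized by
co-occurrence counts; final labels come from agglomerative clustering of the
dissimilarity 1 − frequency, with the cluster count chosen by minimum
Davies–Bouldin score and ties broken by maximum silhouette. Agglomeration
uses **average linkage** by default: at desk scale Leiden produces fine
communities whose boundaries shuffle between runs, so a sizable fraction of
genuinely same-cluster pairs never co-occur; complete linkage pins a
cluster's merge height to those extreme pairs and fails even a
two-well-separated-blob sanity check, while the mean co-clustering frequency
remains a faithful similarity (average linkage is the standard choice in
consensus clustering). Complete linkage remains available via the `linkage`
argument.

**Class consensus.** Two automated class opinions that agree are accepted
(`auto_agree`); otherwise a manual label is used when present (`manual`);
otherwise the cell is `unresolved`. The upstream trained classifiers are
modelled as opinion channels, not reimplemented.

## Connectivity analyses (`connectivity`)

Per-cell excitatory/inhibitory output fractions use classified synapses only
in the denominator; the subclass matrices use all synapses (including an
explicit undetermined column) so rows sum to 1. "Proximal axon" means the
100 output synapses with smallest path distance. A synapse is local when it
lies on the same side of the area border as the presynaptic soma; interareal
rows with fewer than 20 synapses are omitted. Distance profiles default to
50-µm bins over 0–1000 µm, with path distance measured along the axon
skeleton (validated against a Dijkstra oracle) or the Euclidean chord.
The group partition threshold is inclusive (fraction ≥ 0.25 → group 2), and
reciprocity is counted at pair level: a connected pre→post pair is
reciprocal when ≥1 post→pre synapse exists.

Synapse-size comparisons use Kruskal–Wallis with pairwise Conover tests on
ranks (reported only when the omnibus is significant), Holm-adjusted by
default, plus optional two-sample KS tests. The Conover statistic is
implemented directly from the rank-based t formula (no installed package
provides it); its type-I rate is verified by simulation.

## Potential-synapse shuffle (`shuffle`)

A candidate index holds every postsynaptic site on a cell with an assigned
excitatory subclass. For each observed output synapse onto an excitatory
target, the neighbourhood is all candidate sites within 5 µm (a typical
upper bound on spine length); the observed site is included among its own
candidates so the observed profile has nonzero null probability, and sites
on the presynaptic cell itself are excluded by default. Each of 10,000
replicates redraws one candidate uniformly per observed synapse; per-cell
enrichment is observed count over median shuffled count (½ pseudocount on
both when the median is zero, flagged), and the population test is a
two-sided Wilcoxon signed-rank on per-cell log ratios, exact for ≤25 cells.

The calibration cohorts scatter ~3.2 × 10⁵ candidate sites in a 150-µm cube
(≈50 candidates per 5-µm neighbourhood). Density matters: because the
observed site sits in its own neighbourhood, a planted k-fold preference
leaks into the null by a factor ≈ 1 + (k−1)/m for m candidates per
neighbourhood, so sparse site fields bias recovered ratios downward; at
m ≈ 50 a planted 5× preference is recovered as ≈4.6–4.9×. The calibration
suite runs 60 abundance-only and 60 planted cohorts (12 cells × 300
synapses × 10,000 replicates each); the signed-rank rejection rate under the
null is slightly conservative (1–4% at nominal 5%) because the exact n = 12
distribution is discrete.

## Virtual multipatch (`multipatch`)

Lateral distance is Euclidean in the plane orthogonal to depth. The
sampling-distance model is a normal truncated at zero,
`f(d) = φ((d−µ)/σ)/(σ(1−Φ(−µ/σ)))`, fitted by maximum likelihood
(Nelder–Mead on (µ, log σ)); the shipped default (µ = −29.5 µm,
σ = 92.2 µm) is used when no empirical distances are provided. Note (µ, σ)
are weakly identified when µ < 0 — at n = 10⁴ the MLE of µ has a standard
error of roughly 6 µm — so recovery checks use large samples. Virtual
experiments draw pairs with replacement, weighted by the density at each
pair's lateral distance; pairs are ordered (pre→post) and the connected flag
is directional. Empirical p-values count draws meeting the criterion
(≥, ≤, or = 0), with an optional (r+1)/(n+1) correction that is verified
super-uniform under the null.

## Circuit model (`circuit`)

Three populations — L5-ET, L5-PV (basket-like) and L5-SST (Martinotti-like)
— of leaky integrate-and-fire neurons with an optional single after-spike
adaptation current, placed uniformly in a 650-µm-radius cylinder spanning
layer-5 depths (−500 to −660 µm); analyses use the core cylinder
(radius < 200 µm) to avoid boundary artifacts. Full-scale counts are
6,523/2,866/2,537; the suite and the acceptance script run a 20%-scale
network (1,304/573/507), which preserves the expected ~(200/650)² core
fraction. Heterogeneity comes from a library of 40 parameter sets sampled
as lognormal perturbations (σ = 0.12) of per-type defaults with ±1.5 mV
threshold jitter.

**None of the electrophysiological constants are measured values**: this
class of model inherits them from external physiology datasets, so membrane
parameters, connection probabilities (PV→ET 0.40, SST→ET 0.30,
PV→PV 0.30, SST→PV 0.25, PV→SST 0.10, SST→SST 0.05), synaptic weights
(voltage jumps; ET→PV/SST +0.9 mV, ET→ET +0.5 mV, inhibitory −0.2 to
−0.6 mV), the 1.5-ms delay, and target rates (ET 4, PV 10, SST 5 Hz) are
package configuration, chosen for a stable operating point that reproduces
the qualitative phenomena. ET outgoing connectivity is a fixed budget of 60
connections per cell split 8%/49%/43% onto ET/PV/SST in the base model; the
variant parameter f reallocates each connection's target type with the
PV:SST ratio fixed at 49:43 and the total budget held constant. The
out-degree is *not* reduced when the network is scaled down, so the
recurrent loop gain survives scaling.

**Integration** is fixed-step (0.5 ms default; 0.05 ms for oracle checks)
with exact exponential decay between events; synapses are delta-current
voltage jumps delivered through a delay ring buffer. Constant-drive rates
match the closed-form LIF rate
`r = 1/(t_ref + τ ln((RI−(V_reset−V_rest))/(RI−(V_th−V_rest))))`
to <1% at 0.05-ms steps.

**Inputs.** 100 independent 250-Hz Poisson background units, 4 per cell
with optimized per-cell weights; one shared 1-kHz Poisson tuned source whose
per-neuron weight is `w·exp(−Δθ²/(2·60°²))` with wrapped angular difference,
applied to ET cells (preferred angles span 0–360°).

**Weight optimization** follows a two-step scheme: per parameter set,
bisection on the background weight (recurrence off) to within 5% of the
type's target rate; then, with recurrence on, multiplicative updates of the
worst-deviating type until all types are within 10%. Two numerical guards
were necessary under strong recurrence: rates are measured on a fixed noise
realization after discarding a 500-ms transient (otherwise seed noise
dominates the 10% tolerance), and the 5% step is damped near the target and
halved whenever a type's deviation changes sign (the plain rule
limit-cycles).

**Analyses.** Tuning: core-ET mean rates in 10° bins of
preferred-minus-target angle, weighted Gaussian least squares (weights
∝ √bin count; bins with more cells have lower-variance means) with a fitted
baseline, σ bounded to [5°, 200°]. Spectra: core-ET population spike counts
in 2.5-ms windows, Welch with 500-ms segments and 50% overlap (2-Hz
resolution), peak above 4 Hz, FWHM by half-maximum interpolation. The angle
sweep runs both conditions (with/without recurrence, identical input
weights and seeds) across target angles; Δσ = σ_with − σ_without. At the
base connectivity the recurrent E/I loop sharpens tuning
(mean Δσ ≈ −7 to −10° at 20% scale over 6 angles), and the effect shrinks
to ≈ −3° when all ET output is redirected to other ETs (f = 0) — the
sharpening requires stimulus-driven inhibition strong enough to rectify
flank responses, which a fitted baseline cannot absorb. Per-angle Δσ
estimates are noisy (s.e.m. ≈ 1–3° over 6 angles at this scale), so only
the sign and ordering are asserted, not magnitudes. With delta-current
synapses and a 1.5-ms delay the recurrent oscillation sits above the
low-gamma band; its frequency is delay- and kinetics-dependent and is not
matched to data.

## Problem sizes

The suite and `scripts/acceptance.py` use: the default generator at 3,000
neurons (~91 ET cells, ~390 interneurons, ~1.5 × 10⁵ synapses); 60 + 60
shuffle cohorts of 12 cells × 300 synapses × 10,000 replicates; multipatch
fits at 4 × 10⁴ samples and draw sets of 10,000; and the 20%-scale circuit
with 6-angle sweeps. These sizes keep every stage's statistics inside the
stated tolerances while the full run completes on a single CPU.
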