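# Methods

## The generative model

The synthetic clade evolves under a constant-rate fossilized birth–death
(FBD) process started from a single lineage at the origin time `t_origin`
(Ma before present): each alive lineage speciates at rate λ, goes extinct at
rate μ and leaves a fossil sample at rate ψ (all in events/lineage/myr,
simulated by a Gillespie walk), and each lineage alive at the present is
sampled with probability ρ. Speciation is bifurcating and **every edge of
the complete tree is a distinct species**, so each fossil sample belongs to
exactly one species; this is the simplest identity rule that gives every
occurrence an unambiguous taxon. Default study conditions (an entirely
extinct clade, mirroring a trilobite-like group): λ = 0.5, μ = 0.3,
ψ = 0.25, `t_origin` = 20 Ma, ρ = 0, conditioned on at least 30 sampled
species (re-drawn up to 1,000 times). These rates give a few tens of
sampled species over a ~20-Myr window — deliberately desk-scale rather than
the hundreds of species a full empirical dataset would carry; the drivers
state their sizes in their output.

The reconstructed tree spans the sampled taxa only. A species whose lineage
has sampled descendants is a **sampled ancestor** and is serialized as a
zero-length pendant edge (the common tip-dating convention, so plain Newick
round-trips it). A species with several fossil samples appears once, at its
youngest sample; the older samples remain in the occurrence table, which is
the species-level simplification appropriate here since all downstream
analyses are per-species. If nothing is sampled and no conditioning was
requested, there is no reconstructed tree and `None` is returned.

**Genera** are the maximal clades of the true species tree whose stem edge
crosses a time horizon `tau_genus` (an edge spanning [end, start) crosses
iff end ≤ τ < start; a boundary tie therefore goes to the younger edge).
Sampled species extinct before the horizon sit above every such clade and
become singleton genera. Each genus is monophyletic by construction, which
the tests verify by an MRCA check on the reconstructed tree.

**Characters** evolve under a symmetric k-state Markov model with mean-1
gamma rate multipliers; the two-state transition probability
(1 − e^{−2rt})/2 is verified against simulation. This model is a
convenience stand-in — nothing downstream consumes the matrix beyond its
existence at the classic "254 characters" scale, and no claim is made about
matching any particular empirical model configuration (ascertainment
correction, state-space heterogeneity, ...).

**Morphology-taxon selection** draws k species without replacement with
probability ∝ (occurrence count)^β. β = 0 is uniform; β around 1.5 (the
default) concentrates on abundant, well-preserved taxa — the sampling bias
that motivates comparing against an arm that also uses the remaining taxa's
ages.

**Stage binning** replaces each occurrence's age by its containing stage's
bounds on a synthetic uniform timescale (10 stages by default); an age
exactly on a boundary goes to the older stage. With probability `p_coarse`
(default 0.15) the interval widens to a run of adjacent stages (up to 3 each
side, or the whole scale), emulating records correlated only to a coarse
regional scheme. The true age always stays inside the reported interval.

## Pseudo-posteriors

MCMC output is emulated, not run. Each sampled tree is the true tree
perturbed by Poisson(`nni_rate`) rooted nearest-neighbour interchanges plus
multiplicative lognormal jitter (sd `age_jitter_sd` on the log scale) on
internal node ages, applied in pre-order so every node is clamped against
its parent's final age; tips keep their sampled ages, and because each
node's lower bound is the oldest tip age in its own subtree, the clamp is
always feasible. Defaults: `nni_rate` = 2, `age_jitter_sd` = 0.05.

With congruence weight γ > 0, proposals are accepted with probability
min(1, exp(−γ·(MIG − MIG_true))) — an exponential tilt toward
stratigraphically congruent topologies, emulating the way tip ages make
incongruent regions of treespace implausible. The acceptance scale is
anchored at the true tree's own MIG rather than the global minimum Gmin: the
global minimum is generally unattainable from local perturbations of a real
tree shape, and anchoring there would drive every acceptance probability to
zero, reducing the sampler to a take-the-best-of-N draw whose output is
*more* dispersed than the unweighted arm. After 50 rejections the lowest-MIG
proposal seen is kept, preserving the bias direction for extreme γ. γ = 5 is
used for the semi-resolved arm (strong but not degenerate at MIG measured in
myr); γ = 0 for the resolved arm.

In the two-arm pipeline the semi-resolved sample is generated on the **full**
taxon set (ages for every species) and then pruned to the morphology
leafset, exactly as an empirical semi-resolved posterior would be; the
resolved sample is generated directly on the pruned truth. Both arms are
then subsampled to equal size (default 120 trees) before any metric is
computed.

## Conventions and numerical choices

* Ages are in Ma before present; branch lengths are durations
  (parent age − child age); tip ages need not be zero. When both branch
  lengths and an explicit tip-age table are given and disagree by more than
  1e-6 myr, the table wins and a warning is logged (literature ages
  outrank file arithmetic).
* FADs default to the old bound of each taxon's interval; a
  uniform-in-interval resampling variant exists for sensitivity replicates.
* SCI excludes the root (no sister) and counts ties as consistent;
  polytomies take the union of the other children as the sister set.
* GER is undefined when Gmax = Gmin and is reported as a missing value with
  a status code, never silently 0 or 1.
* The majority-rule consensus is built from rooted clades with frequency
  strictly above the threshold (≥ 0.5 enforced; above ½ the clades are
  pairwise compatible, so the tree always exists). Its node count is the
  number of such non-trivial clades. Consensus topologies carry supports
  only, no ages; the MCC tree keeps its own sampled ages.
* The MCC criterion is the product (sum of logs) of clade posterior
  frequencies, ties broken by earliest sample index; a sum criterion is
  available. The reported "sum of posterior probabilities" runs over all
  internal nodes of the winner.
* Split information uses the double-factorial containment fraction; the
  plain consensus information sums h(s) over resolved splits, and the
  support-weighted mode sums max(0, p·h(s) − H₂(p)). Rogue detection
  defaults to the support-weighted mode: under plain scoring, removing any
  taxon shrinks n and with it every split's h(s), so the gain from dropping
  even a maximally unstable leaf is negative and the search would never
  remove anything; the entropy discount is what lets restored support pay
  for the smaller leafset. Reports always name the mode, and no numeric
  identity with any external implementation is claimed.
* PCoA drops negative-eigenvalue axes with a logged warning but reports the
  full spectrum (tree distances are usually non-Euclidean). The landscape
  uses inverse-distance weighting (power 2, 101×101 grid, masked to the
  convex hull) and is exact at the data points; densities use Gaussian KDE
  with Scott's rule; spread statistics use population (1/n) variances, as
  descriptive statistics of a fixed point cloud.
* HPD intervals are the shortest window over ⌈mass·n⌉ order statistics,
  earliest window on ties. "Origin age" is operationalized as the root age
  of each sampled tree, since no FBD origin parameter is inferred here.
* Between-arm tests are two-sided Mann–Whitney U per metric with
  Holm-adjusted p-values reported alongside the raw ones.
* All pipeline randomness flows from one master seed split into named
  substreams (numpy SeedSequence); identical (config, seed) gives
  byte-identical report JSON.
* Occurrence cleaning applies rank → imprecision (default threshold
  15 myr) → exclusion in that order, attributing each dropped record to the
  first matching rule so the audit always partitions the input.

## What the generator does and does not emulate

It reproduces the *structure* of the empirical problem: a dated clade with
fossil and (optionally) extant sampling, sampled ancestors, abundance-biased
morphology subsets, stage-binned and sometimes imprecise age intervals,
genus-level monophyly, and posterior-like tree distributions whose
congruence contrast between arms is controlled. It does **not** run Bayesian
inference, so the arms differ by construction (γ) rather than through a
likelihood; passing tests therefore demonstrate that the *measurement*
machinery (congruence, treespace, consensus, HPD) behaves correctly and
that the comparison detects a planted effect of known direction — not that
any particular empirical dataset will show that effect, nor that effect
sizes transfer. Character matrices are generated but carry no signal into
the pipeline, taxonomy is error-free (no synonymy or misidentification),
fossil ages are known exactly before binning, and fossil recovery is
time-homogeneous.

## Known limitations

* Rogue search is greedy single-taxon removal; taxa that are only jointly
  rogue (pairs) are not found.
* The clustering-information distance is quadratic in splits per pair and
  pure Python; for thousands of trees the Robinson–Foulds metric is the
  practical choice (both are config options, clustering information being
  the default).
* Consensus node ages are not estimated (no common-ancestor heights).
* The occurrence cleaner does no taxonomic reconciliation; it assumes names
  are already resolved.
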