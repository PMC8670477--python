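# Methods

## Network model

KC activity is rate-coded and rectified-linear.  For PN rates `x` (one
column per odor or trial), `e_j = Σ_i w_ji x_i`, APL activity
`A = Σ_j e_j`, and `y_j = max(0, e_j − α_j A − θ_j)`.  Inhibition is
*pseudofeedforward*: instead of simulating recurrent KC↔APL dynamics in
time, APL's drive is the summed unthresholded excitation of all KCs.  This
keeps every KC's activity a monotone function of its own parameters, which
the calibration and tuning procedures exploit.

Parameter distribution families follow the experimental measurements of
PN–KC synaptic strength (log-normal EPSP amplitudes), dendritic claw count
(Gaussian around 6 inputs), and spiking threshold (Gaussian).  The exact
fit parameters are not published as numbers, so the defaults are:

| parameter | family | default | units |
|---|---|---|---|
| w | log-normal | σ_log = 0.8, median 1 | mV-equivalent (scale-free) |
| N | Gaussian, rounded | mean 6, sd 2, clipped to [1, 12] | claws |
| θ | Gaussian, truncated > 0 | mean 10, CV 0.25 | mV above rest |

The absolute scales of `w` and `θ` are immaterial: calibration rescales all
thresholds (bisection on a global multiplier so that 20% of KCs respond per
odor with inhibition off) and then all inhibitory weights (bisection so 10%
respond with inhibition on), each to ±0.005 on a fixed noiseless
calibration odor set.  Dense-coding regimes (coding level > 0.5) skip the
inhibition stage because inhibition is constrained to halve the coding
level, which is impossible above 0.5.

## Synthetic odors

Each of 24 receptor channels has a zero-inflated log-normal tuning
marginal: response probability `p_i ~ U(0.2, 0.95)`, log-amplitude
`N(log 40, 0.5²)` across channels with σ_log = 0.6 across odors.  Draws are
passed through a saturating divisive normalization
(`pn = rmax·o^1.5 / (σ^1.5 + o^1.5 + (0.05·Σo)^1.5)`, rmax = 165 spikes/s),
the standard antennal-lobe transform of receptor input to PN output.  The
saturation matters: without it the heavy-tailed inputs let single strong
channels dominate KC drive and the combinatorial KC code loses most of its
accuracy.  Trial-to-trial noise is Gaussian with a per-PN coefficient of
variation (default 0.25, global scale sweepable 0.5–2×), rectified at zero.
Larger stimulus worlds can be bootstrapped from any PN-by-odor matrix by
resampling each PN's row independently, and odor "chemical groups" are
emulated as convex mixtures (weight ρ) of a group-level and an odor-level
draw.

What the generator does *not* emulate: real odor–odor correlation structure
beyond the group mixture, receptor antagonism/inhibition below baseline,
and concentration series.  Results about absolute accuracies therefore
characterize this synthetic world; the qualitative orderings between models
are the quantities of interest.

## Learning and readout

Training presents each odor's noisy trials once; KCs active during a
rewarded odor depress their synapse onto the avoid-MBON (and vice versa) by
`v ← v·exp(−η y)` — depression only, with commuting updates.  The decision
is `P(avoid) = σ(c·(m_avoid − m_approach))` with `m_k = Σ_j v_k,j y_j / U`.

The drive unit `U` deserves a note.  Simulation activity units are
arbitrary, so `U` is fixed at 0.15 × the expected total KC activity per
odor of the calibrated *homogeneous* reference network at the sparse
operating point (coding level 0.1), computed once per task instance and
shared by every model variant and coding-level regime.  Two properties are
deliberate:

* it is a per-network constant, not per-trial — normalizing each trial
  would erase the decision-margin differences through which silent and
  indiscriminate KCs hurt performance;
* it is anchored to the sparse operating point even for dense-coding
  experiments, so a dense network's much larger total drive translates into
  correspondingly more decisive choices, as it would in fixed physical
  units.

On this scale `c = 10` is near-deterministic for a well-trained sparse
network, `c = 1` markedly stochastic, `c → 0` indifferent.  The constant
0.15 was chosen so the gain axis spans that range; orderings between models
are stable over roughly a three-fold change in either direction.  Accuracy
is scored as the expected probability of the correct action over unseen
noisy trials (a sampled-decision mode exists behind a flag; same mean,
higher variance).  Default η = 1e-4; experiment drivers can select the best
η per condition from a grid, mirroring best-learning-rate reporting.

## Compensation

**Activity-independent.**  `P(w | N, θ)` components are log-normal with
median `κ·θ_b/N` (θ binned into 20 quantile bins) and a shared σ_log; κ and
σ_log are moment-matched in log space so the pooled mixture over the joint
(N, θ) population reproduces the unconditional log-normal `P(w)`
(two-sample KS ≈ 0.012 at 10⁵ draws).  This realizes `w ∝ θ`, `w ∝ 1/N`
without referencing activity.  The fit fails loudly if the target `P(w)` is
narrower than the spread `log θ − log N` already induces.

**Homeostatic.**  Each KC drives its mean activity `Ā_j` over noisy trials
of the tuning odors to a common set point `A₀` (tolerance ±6%) by adjusting
one parameter: excitatory weight scale (multiplicative), threshold
(additive) or inhibitory weight (additive, optionally clamped at zero).
Because inhibition is pseudofeedforward, `Ā_j` is monotone in each KC's own
parameter, so the raise/lower dynamics have a unique fixed point per KC;
the implementation finds it directly by vectorized bisection (the weight
target alternates per-KC solves with updates of the shared APL term, ~4–8
alternations).  `A₀` defaults to the untuned population mean and an outer
loop rescales it until the coding level on the tuning odors returns to the
0.1 target (tolerance 0.005), since equal activity and population
sparseness jointly determine the set point.  Untargeted parameters are
never altered.  A response-probability variant instead places each
threshold between the order statistics of the KC's net drive so that its
response probability equals the coding level to within one sample flip.

KCs with zero drive on the tuning odors (possible when tuning on a small
odor group) are untunable; drivers over small odor sets report them rather
than fail.  Tuning inhibitory weights under realistic thresholds (coding
level 0.2 without inhibition) requires many α < 0; the diagnostic
experiment sets θ = 0, tunes α under a non-negativity clamp, and measures
the coding level with inhibition removed (~97–99%).

## Metrics and ablation

Lifetime sparseness is the Treves–Rolls form on trial-averaged rates per
odor, undefined (NaN) for silent cells and excluded from cdfs but reported
as a silent fraction.  Valence specificity is
`|Σ_rewarded − Σ_punished| / Σ_all`.  Angular distance averages pairwise
angles between odor centroids in the full KC space; dimensionality is the
participation ratio of the covariance spectrum, computed from singular
values of the centered sample matrix.  Ablation replaces the top fraction
of KCs by a metric (NaN ranked last, ties by index) with silent rows or
uniform rows at each cell's own mean activity (preserving total activity
and hence dense-coding level).

## Experiment drivers

All drivers fan per-run seeds out of a master seed with a counter-based
scheme, so any run reproduces in isolation and matched model variants share
odor panels, valence assignments, connectivity seeds and trial noise —
enabling paired signed-rank comparisons (rank-sum for regimes that cannot
share connectivity), Holm–Bonferroni corrected, with a compact-letter
summary.  Default problem sizes: 2000 KCs, 24 PNs, 100 odors (20 for the
dense-coding and sparseness-structure analyses), 15 training / 10 test /
5 tuning trials per odor, 20 instances per comparison.

## Connectome analysis

Synapse tables are plain CSV (`pre_id, post_id, pre_class, post_subtype,
roi, synapse_count`); skeletons standard SWC.  PN–KC connections with fewer
than 3 synapses are treated as annotation errors and dropped (the empirical
count distribution is bimodal with a trough at 3–4).  Per-KC aggregates
(N partners, mean/total synapses, calyx APL synapses) exclude subtypes with
substantial nonolfactory input.  Geodesic synapse-to-boundary distances
snap synapse positions to the nearest skeleton node and measure path length
along the tree from a configurable boundary point (the posterior peduncle
boundary, a proxy for the spike-initiation zone).  The synthetic generator
plants tunable couplings (weight–N exponent, APL–excitation coupling,
distance–N coupling) with a null mode for type-I control; it emulates
hemibrain-like magnitudes, not the real connectome's counts.

## Known limitations

* The softmax gain scale and depression law are minimal forms; absolute
  accuracies depend on them even though model orderings are robust.
* The homogeneous model's response-count dispersion in this synthetic world
  is slightly wider than the real-data-derived panel's, which lowers the
  fraction of cells with lifetime sparseness above 0.85 (≈67% here at 20
  odors) and widens the random model's informative sparse tail under dense
  coding (to roughly the top 20% of cells rather than 10%).
* No spiking, no time-resolved APL feedback, no DAN dynamics, single MBON
  pair, no extinction.
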