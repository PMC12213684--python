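# Methods

## Model

`socnet` simulates a discrete-time stochastic leaky integrate-and-fire (LIF)
network of N excitatory neurons on a directed graph and asks how the network's
topology shapes self-organized criticality (SOC) of its synaptic strengths.

**Membrane dynamics.** Neuron i carries a potential V_i[t] ≥ 0 updated
synchronously:

    V_i[t+1] = mu * V_i[t] + I_ext + (1 / k_i) * sum_j W_ij X_j[t]

where the sum runs over presynaptic neighbours j, k_i is the in-degree and
X_j[t] ∈ {0, 1} is the spike indicator. A neuron that fires is reset to
V = 0 at the next step (spontaneous firings reset too — they are firings;
the two are not distinguished anywhere downstream). Firing is stochastic:

    P(X_i = 1 | V_i) = Gamma (V_i - theta) / (1 + Gamma (V_i - theta))   if V_i - theta > 0
                     = p_spont                                           otherwise

The boundary V = theta takes the spontaneous branch (the above-threshold
branch requires a strictly positive drive). Defaults: mu = 0, I_ext = 0,
Gamma = 0.8, theta = 0, p_spont = 1e-4 per neuron per step; the reference
network size is N = 10,000 with mean total degree 8.

**Plasticity.** Every existing synapse recovers by a fixed increment and is
depressed multiplicatively by presynaptic spikes:

    W_ij[t+1] = W_ij[t] + 1/tau - u * W_ij[t] * X_j[t]

tau (steps) sets the recovery timescale, u ∈ (0, 1) the depression fraction.
The stationary balance for a synapse whose presynaptic neuron fires at rate
rho is W* = 1 / (tau · u · rho): slow recovery or strong depression force low
strengths and sparse firing, fast recovery the opposite. This feedback drags
the network-mean strength toward the critical value W_c without any external
tuning — the SOC mechanism under study.

**Update order within a step.** Spikes are sampled from the current
potentials, then propagated, then fired neurons are reset, then the synaptic
rule is applied with the just-sampled spikes. This is the only ordering
consistent with the indexing above (X at t, V and W at t+1). One seeded
generator drives a simulation; spike sampling consumes one uniform draw per
neuron per step in fixed neuron order, so runs are bitwise reproducible and
the compiled kernel is interchangeable with the pure-Python reference
`step()` (asserted in the tests).

**Initial conditions.** V_i[0] = 0 everywhere (quiescent start; avalanches
then grow from silence) and W_ij[0] = W_init, normally the critical value.

## Topologies

Five directed topologies are built with a *matched edge budget* of
N · ⟨k⟩ / 2 directed edges (⟨k⟩ = mean total degree, in + out): ring lattice
("regular"), Watts–Strogatz small world, Barabási–Albert scale free,
stochastic-block modular, and Erdős–Rényi random. An undirected skeleton is
sampled first (networkx generators), then each edge receives one uniformly
random direction. Orienting a simple skeleton guarantees zero reciprocal
pairs — immediate two-cycles would blur cascade causality, so they are
excluded by construction. Where a generator cannot hit the budget exactly
(preferential attachment falls short by m² edges; the block model is
stochastic), the skeleton is trimmed or augmented with uniformly random
edges to the exact budget, keeping node and edge counts identical across
topologies.

Modular networks default to B = 10 equal blocks with connection
probabilities chosen so that ≈90% of the budget falls within blocks. The
Watts–Strogatz rewiring acts on the undirected skeleton before orientation.
Clustering is reported as the mean local clustering of the undirected
skeleton (ring lattice with k = 8: 3(k−2)/(4(k−1)) = 0.6429, used as a
closed-form test oracle).

## Avalanche analysis

**Extraction.** Activity is monitored on a probe set; an avalanche is a
maximal run of strictly positive per-step probe spike counts, its size s the
summed counts, its duration the run length. A run still open when the
recording ends is discarded. Sizes count total spikes, not distinct neurons
(the standard convention; long cascades revisit neurons).

**Probe.** Generic library operations default to probing all neurons. The
experiment drivers instead count spikes on a fixed 400-neuron random subset.
The probe is what makes the absolute classification thresholds (below)
meaningful: a size measured on a fixed-size probe is a network *fraction*,
comparable across N, and with whole-network probing at desk scales the
CCDF(100) < 1e-2 gate can essentially never fire because merged bulk
activity dominates the catalog.

**Critical point.** The avalanche-size susceptibility chi_s = ⟨s²⟩ − ⟨s⟩²
is computed from fixed-W runs (plasticity off) over a W grid (reference
grid 0.00–4.00 in steps of 0.01; the desk-scale studies bracket the peak
with steps of 0.02); W_c is the argmax. Grid points whose run completed
fewer than 10 avalanches contribute chi = 0: above the critical strength
activity rarely dies out, and the variance of two or three
truncation-shaped monster events would otherwise win the argmax. The floor
makes the estimate reproducible to ±0.05 across seeds at N = 2,000 with
5×10⁴ steps per grid point; pushing the per-point run length much further
re-introduces the drift, because ever-rarer supercritical completions
accumulate (a known limitation of finite-run susceptibility scans).

**Truncated power-law fit.** Catalogs are fit by discrete maximum
likelihood with density p(s) ∝ s^(−alpha) e^(−s/lam) on s ≥ s_min = 1,
normalised by direct summation up to ten times the observed maximum, and
optimised by L-BFGS-B from a 3×3 multistart (alpha ∈ {1.2, 1.5, 2.0},
lam ∈ {1e2, 1e3, 1e4}). The fit is exposed as a results object (`TPLFit`)
carrying the parameters, log-likelihood and a normalised CCDF evaluator, so
the fitting recipe can be swapped without touching the classifier.

**Regime classification.** The ordered size catalog of a completed run
passes through a fixed cascade: (1) five or fewer avalanches →
*supercritical* (activity never dies, so almost nothing completes); (2) the
first five avalanches are dropped as initial-condition transients; (3)
max(s) ≤ 10^2.5 → *subcritical*; (4) if the empirical CCDF at s = 100 is
below 10⁻² and exceeds the fitted CCDF by more than `dk_factor` (default
1.1×, with 1.3×/1.5× as pure configuration variants) → *dragon_king*;
(5) otherwise *critical*.

The Dragon-king deviation is judged at the same locus as the rarity gate
(s = 100) against a *body fit*: the truncated power law re-fit to sizes
≤ 10^2.5 by right-truncated MLE and extrapolated over the full support.
Two alternatives were evaluated and rejected as defaults, both kept as
strategy options. Taking the maximum empirical/fitted ratio over the whole
observed tail (`max-tail`) is dominated by the extreme order statistics:
catalogs *sampled from a clean truncated power law* show maxima of 1.6–9.8
across seeds, so at a 1.1× threshold every critical catalog would be
mislabelled. Comparing at s = 100 against the full-catalog fit
(`at-point`) fails in the opposite direction: the MLE stretches its cutoff
to absorb an injected tail bump and the ratio drops below 1. The body fit
cannot be dragged by the anomalous tail, which is precisely the quantity
under test; with it, clean catalogs sit at ratios 0.99–1.04 and
bump-injected ones at 1.9–2.1. Only excesses count (a Dragon king is an
excess of large events, not a deficit). If the body fit is degenerate the
full fit is used; if no fit is possible at all the Dragon-king test cannot
fire and the catalog falls through to *critical*.

**Size–duration scaling.** Sizes and durations are fit with the same
machinery (duration exponent beta from d ≥ 10, where the power-law
asymptote of duration distributions actually holds; including d = 1..3
biases beta down because those bins reflect the offspring law, not the
scaling regime). The slope gamma_fit of log mean-size-given-duration
against log duration is compared with the crackling-noise prediction
gamma_pred = (beta − 1)/(alpha − 1) — for a critical branching process
alpha = 3/2, beta = 2, slope 2 (sizes grow as the square of durations), a
relation verified in the tests against a Galton–Watson simulator at
offspring mean 1.

## Deviation indices and rates

The network-mean synaptic strength W[t] averages W_ij over edges whose
**presynaptic** neuron has in-degree ≥ 2. A neuron with no afferents fires
only spontaneously (rate p_spont), and one with a single afferent only as
often as that lone input, so their outgoing strengths grow by 1/tau
essentially unopposed (equilibrium 1/(tau·u·p_spont) = 200 at the default
parameters) and would swamp the mean: at N = 2,000 the excluded mean sits
near W_c and is stationary, while the unexcluded mean drifts without bound.

ME and MAE are the signed and absolute means of W[t] − W_c over a window
[t_a, t_b] with inclusive divisor t_b − t_a + 1; the reference window is
[1e4, 1e5], and reduced-scale runs keep the same 1:10 proportion. Firing
rates are spikes per neuron per step over the stated window; ISIs are
successive spike-time differences pooled within neurons. For the
hub-activity analysis, each avalanche inherits a class — Dragon-king if its
size reaches the onset of the anomalous tail (smallest s ≥ 100 where the
empirical CCDF exceeds the body fit by more than dk_factor), power-law
otherwise — its spikes inherit the class, and each class's rate denominator
is the time spent in that class, making rates comparable across classes of
different prevalence.

## Experiments and scale

The experiment drivers reproduce the study designs at a configurable scale:
single-run characterizations (catalog + CCDF with fit overlay + W[t] +
regime + ME/MAE), (tau, u) phase sweeps over 100 ≤ tau ≤ 1000 and
0.1 ≤ u ≤ 0.9 with per-cell seeds derived from (kind, tau, u, replicate,
master seed) so sweeps are resumable and bit-reproducible, repeated-run ME
distributions, and the scale-free hub analysis. W_c is re-estimated per
(kind, N, mean degree) — it is size- and topology-dependent — and cached in
a JSON sidecar.

Defaults run at N = 2,000 and T = 5×10⁴ (full scale N = 10,000, T = 10⁵ is
one configuration away). The desk scale preserves the qualitative
contrasts: self-organization toward W_c from distant initial strengths
(within 4% of W_c from either side), |ME| growing by an order of magnitude
from tau = 100 to tau = 1000, the ring lattice deviating far below the
random network, and hub-dominated anomalous cascades on scale-free graphs.
What it does not preserve are the absolute classification thresholds at
their most sensitive: with only 0.2 expected spontaneous seeds per step the
catalog bulk is thinner than at N = 10,000, so the CCDF(100) < 1e-2 gate
rarely opens for simulated (as opposed to constructed) catalogs and most
near-critical cells label *critical* or *subcritical* rather than
*dragon_king*. The classifier itself is validated on constructed catalogs
where both gate quantities were computed independently beforehand.

## Synthetic inputs in the tests

The test suite generates all data programmatically: truncated power-law
samples by inverse-CDF on the discrete support (the generator is shared
with the acceptance script), Bernoulli rasters for ISI laws, Galton–Watson
avalanches for crackling-noise consistency, and constructed Dragon-king
catalogs (clean bulk at alpha = 1.9, lam = 300 — chosen so the model CCDF
at 100 is ≈ 4×10⁻³, safely inside the rarity gate — plus an injected spike
of system-size events). These emulate the statistical shapes the analysis
stack must recognise, not the biophysics; passing them shows the analysis
chain is correct, while the dynamics are validated separately against
closed-form single-edge balances, conservation identities and the
bitwise-equivalent reference implementation.

## Known limitations

- Excitatory neurons only; no inhibition (which would damp the extreme
  cascades), no conduction delays, no leak heterogeneity.
- The susceptibility argmax inherits finite-run ambiguity near the
  order/disorder boundary; W_c at N = 2,000 is reproducible to ±0.05, which
  bounds how finely signed deviations from W_c (ME at fast recovery, where
  |ME| ≈ 0.03–0.06) can be resolved at this scale.
- The truncated-power-law fit fixes s_min = 1 for sizes; no automatic
  lower-cutoff selection is attempted.
- The phase-diagram drivers sweep tau and u; sweeps over leak, mean degree,
  block count or rewiring probability are possible through the
  configuration but have no dedicated drivers.
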