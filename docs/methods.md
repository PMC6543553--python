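# Methods

This note documents the model implemented in `strfnet`, the parameter
choices that matter, the numerical scheme, and what the synthetic
experiments in the test suite do and do not establish.

## Stimulus synthesis

A TORC (temporally orthogonal ripple combination) is parameterized by six
ripple components. The dynamic spectrum is evaluated analytically,
`S(t, x) = Σ aᵢ cos(2π(ωᵢt + εᵢx) + φᵢ)`, on a 2 ms envelope grid
(500 Hz, comfortably above twice the fastest 48 Hz ripple) and on the
15-channel octave axis x ∈ [0, 5] above 500 Hz. Per stimulus, velocities
are the six harmonics of a base rate Δω alternating between 4 and 8 Hz
(sets spanning 4–24 and 8–48 Hz), with drift direction alternating between
components; densities are drawn uniformly from [0, 1.4] cycles/octave and
phases uniformly from [0, 2π). Durations cycle through 1.0/1.5/2.0 s —
integer multiples of every ripple period, so each channel's envelope is
exactly zero-mean. The overall amplitude prefactor of the ripple expression
is treated as an arbitrary scale (components default to amplitude 1):
reverse correlation divides by stimulus power downstream, so only relative
amplitudes matter.

Audio rendering uses 20 log-spaced tone carriers per octave with fixed
random phases, each amplitude-modulated by `(1 + 0.9·S̄)/2` (S̄ the
peak-normalized envelope at the carrier's octave coordinate, clipped at 0),
peak-normalized and written as 16-bit mono WAV at 48 kHz.

The ensemble autocorrelation Φ(τ, x, x′) is computed directly from the
lagged channel products, exposed both in full and collapsed onto the
channel difference x − x′. For the default 30-TORC set the energy
concentrates at zero lag and zero channel difference (tested), which is the
property that lets reverse correlation skip a full 2-D deconvolution. For
the same reason the optional Φ-deconvolution estimation mode was dropped:
it adds an ill-conditioned spectral division that the delta-like Φ makes
unnecessary.

## Auditory periphery

The periphery's job here is band-pass filtering plus stochastic discharge
generation; detailed hair-cell biophysics are out of scope. Fifteen
channels sit at geometrically spaced center frequencies between 0.5 and
16 kHz. For dynamic-spectrum input, the envelope at the channel's octave
coordinate is half-wave rectified and mapped affinely to a rate,
`λ = clip(r_spont + r_gain·max(0, S), 0, r_max)` with r_spont = 20 /s
(a medium spontaneous level), r_gain = 150 /s per unit envelope, and
r_max = 400 /s. For audio input, each channel applies a 4th-order gammatone
filter at its CF, half-wave rectification, a 250 Hz low-pass, square-root
compression and bank-wide peak normalization before the same affine map.
Spikes are drawn by thinning an inhomogeneous Poisson process against the
channel's peak rate, with a 0.75 ms absolute dead time (set to 0 in the
statistical tests, where exact Poisson behavior and the time-rescaling
property are verified). Each stimulus is presented 4 times by default with
independent discharge seeds; any substitute front end that returns
discharge trains on the same channel bank plugs into the network unchanged.

## Cortical network

One integrate-and-fire neuron per peripheral channel, all 15 mutually
connected (225 recurrent synapses) plus one cochlear input per neuron.
Membrane dynamics are conductance-based,

    τₘ dv/dt = (v_rest − v) + Rₘ [g_E(t)(v_E − v) + g_I(t)(v_I − v)] + tonic,

with τₘ = 10 ms, v_rest = −70 mV, Rₘ = 4 MΩ, v_E = −30 mV, v_I = −90 mV,
g_m = 2 μS, τₛ = 2 ms and a 0.25 ms step. The driving-force form is used
because a current–voltage product of the alternative sign convention would
make excitatory input hyperpolarizing; the stated reversal potentials and
the requirement that positive codes produce EPSPs pin the sign down. g_m is
read as a conductance (μS).

Threshold, reset and refractoriness are free choices of this package:
v_thresh = −50 mV, reset to v_K = −90 mV — which doubles as the
after-hyperpolarization potential and produces the post-spike rebound
structure visible in the STRFs — and a 1 ms refractory period.

Integer codes decode as follows. Synaptic amplitude is `(|code|/5)·g_m`,
i.e. the code grades the synapse up to the maximum conductance g_m at ±5,
and the sign selects the reversal potential. The fractional scaling is
deliberate: at `|code|·g_m` (2–10 μS against Rₘ = 4 MΩ) every nonzero code
is single-event suprathreshold, so codes 1–5 become behaviorally
indistinguishable and input-strength parameters lose all cost sensitivity —
collapsing exactly the parameter axis the sensitivity analysis is meant to
rank. Input delays decode linearly, `25 + 5·code` ms, spanning 0–50 ms.
Recurrent transmission delays grow with tonotopic separation,
`2 + 3·|Δoctave|` ms, reproducing the distance-proportional latency of
lateral interactions.

Optionally a constant depolarizing drive produces tonic firing; its size is
solved in closed form from the target silent rate (default 10 Hz for
fitting runs, where tonic activity makes responses more robust and lets
inhibition show in the STRF; off in the simplified single-input
validation scenarios).

Integration is exponential Euler per step (exact for the passive membrane),
with alpha conductances advanced by their exact two-state recursion and
delayed recurrent events held in a ring buffer. The inner loop is
numba-compiled. Halving the step changes reference spike counts by less
than 5% (tested).

## STRF estimation and cost

Reverse correlation bins spikes on the envelope grid and accumulates
`C(τ, x) = (1/T) Σ_spikes S(t_spike − τ, x)` over stimuli and repetitions,
on a 0–250 ms lag axis at the 2 ms envelope step. The default "power" mode
divides each channel by the ensemble envelope power (the delta-Φ
approximation of deconvolution); "raw" mode divides by total time only and
is exactly linear in the response (tested).

Significance masking is two-sided: a point is significant when
|value − mean| ≥ 3 s.d. over all points. The two-sided reading is required
for inhibitory regions to count as significant; a constant STRF (s.d. = 0)
has an empty mask. The cost sums |M − E| with weight 1 on the target's
significant points and 0.1 elsewhere. For *fitting*, both STRFs are first
scaled to unit maximum absolute value, so the GA matches shape rather than
firing-rate scale. For *sensitivity scoring* the raw, unnormalized cost is
perturbed instead: the fitting normalization is gain-invariant by design,
and under it a bottom-up input-strength change that uniformly scales the
STRF would register as exactly zero sensitivity — an artifact of the
normalization, not a property of the network.

## Genetic algorithm

Elitist GA over integer genomes: stable sort by cost, elite copied
verbatim, crossover children built gene-wise from parent pairs drawn
without replacement from the parent pool (uniform per-gene choice), mutants
built from single parents with per-gene resample probability 0.05 within
[−5, 5]. Full-scale configuration: population 1000, 40 elite, 100 parents,
480 + 480 offspring, 100 generations. The peripheral discharge seeds are
frozen across all evaluations of a run so the cost landscape is
deterministic; without this, elitism would be meaningless under
re-evaluation noise. Elite costs are reused rather than re-evaluated (valid
under determinism), and the recorded neuron is the one whose CF channel
matches the target's best frequency.

The desk-scale preset used throughout the test suite is population 60
(4 elite, 10 parents, 28 + 28 offspring) for 15 generations on a 5-neuron
network with 10 TORCs × 1 repetition × 1 s — sized so that a recovery
experiment (fit a synthetic target generated by a known genome) completes
in seconds while still halving the initial cost and sign-matching the
target's significant regions.

## Sensitivity analysis and state comparison

Each parameter of a fitted genome is stepped ±1 (single-sided at the ±5
bounds, unscaled); the score is the mean absolute change of the raw cost,
normalized so all scores sum to 1. Fits and profiles are repeated five
times (configurable; a ten-repeat variant is the same flag) and averaged
element-wise with renormalization. Parameters in the top two of either
state's averaged profile are "important"; the comparison diagram adds
context edges — cochlear input to every neuron touched by an important
parameter, the synapse from each such neuron to the recorded neuron, and
the recorded neuron's own input — each annotated with the mean ± s.d. of
its integer value across the repeat fits and a solid/dashed flag per state.

The end-to-end two-state demo builds passive/behavioral targets from two
ground-truth networks that differ in exactly one synaptic parameter — the
bottom-up input strength to the recorded neuron (5 → 2), with a moderate
inhibitory lateral synapse present in both states as context. A
lateral-weight difference was tried first and rejected on measurement: at
any setting, one-step perturbations of a lateral weight are dominated by
the recorded neuron's input delay and self-synapse, so no comparison could
flag it; the bottom-up strength change is both detectable and the kind of
change the passive-vs-behavioral comparison is designed to expose. At
master seed 0 the demo flags the changed parameter in 5 of 5 comparison
repeats.

## Determinism and seeding

Every stochastic stage draws its seed from the master seed through a
labeled SeedSequence split (`split_seed(master, label)`), so a rerun with
the same master seed is byte-identical, including all persisted artifacts
(tested). The network simulation itself is deterministic; all noise lives
in the periphery.

## What the synthetic experiments show — and what they do not

The generator produces targets from networks of the same family the fitter
searches, with matched stimulation seeds. Passing recovery tests therefore
demonstrates that the estimation, cost, GA and sensitivity machinery are
correct and internally consistent — not that the model family captures
real cortical dynamics, and not performance on recorded data, where the
periphery is only an approximation of the auditory nerve, response
nonstationarity exists, and the true network is not 15 neurons. Degenerate
inputs are handled explicitly: all-zero STRFs have no defined best
frequency (error), constant STRFs have empty significance masks, silent
rate functions yield empty trains, and best-frequency ties resolve to the
lower channel.
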