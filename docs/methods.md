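# Methods

This note documents the models implemented in `riftsim`, the choices made
where the underlying procedures were genuinely open, and what the test
suite does and does not establish.

## 1. Fractal dendritic tree and network growth

The core neuron's tree has branch lengths `L_n = L_0 r^(n-1)` (defaults
`L_0 = 100 µm`, `r = 0.6`, four levels). Level 1 is the longest, most
*distal* branch; higher levels sit closer to the soma, so the conduction
path of a level-`n` synapse is the tail sum `Σ_{m≥n} L_m` and the internal
delay `T_internal` strictly decreases with level index. Synapse slots are
allocated across levels proportionally to branch length with
largest-remainder rounding (1000 slots split 460/276/165/99). The
self-similarity dimension `log N / log(1/r)` is 1.357 for binary branching
at `r = 0.6`.

Conduction parameters are not biological measurements but chosen once to
give loop times of tens of milliseconds for peripherals 0.5–2 mm away:
dendritic speed 0.05 mm/ms, axonal speed 0.2 mm/ms, synaptic delay
0.5 ms. Peripheral distances are uniform in [0.5, 2.0] mm with isotropic
3-D directions.

Growth proceeds in firing cycles. Each cycle the core neuron fires, every
established loop echoes back after its round trip
`T_external = 2d/v_axon + δ_syn` plus the branch's internal delay, and a
fresh cohort of 20 random peripherals probes every branch level that still
has vacant slots. Coincidence groups (greedy earliest-first, pairwise
spacing ≤ 2.0 ms, deterministic tie-breaks, at most one arrival per
peripheral per group) are the only selection mechanism; the timing rule
`T_total ≈ const` is an emergent statistic, never imposed. Two committed
choices shape the dynamics:

- **Transient-phase seeding.** Cycle 1 has no rhythm to lock onto; the
  group whose time lies closest to the median candidate arrival seeds it.
  This keeps every branch level timing-feasible (an extreme early group
  would make the longest branch unreachable).
- **Dominant-group consolidation.** From cycle 2 on, only the group
  carrying the most returning loop signals consolidates new connections —
  the coincidence that actually triggers the somatic spike. Allowing every
  echo-anchored group to consolidate lets the loop-time band diffuse and
  destroys the inverse internal/external correlation.

Grown networks show `corr(T_internal, T_external) ≈ −0.88`,
`CV(T_total) ≈ 0.07`, 100 % of connections within one window of the median
loop time, and mean external distance increasing monotonically from the
distal to the proximal level. The oscillation frequency is the reciprocal
of the median inter-fire interval after discarding the first quarter of
fire events; its absolute value depends entirely on the assumed conduction
speeds and is treated as qualitative.

## 2. Integrated-information proxy and fractal metrics

`phi_dyn` is a sliding-window statistic of branch-resolved firing:
events are binned at a 2.0 ms grain, and per window
`φ = I − I*` with `I` the entropy of the pooled firing-time distribution
(branches intact) and `I*` the event-weighted mean entropy of branches
analyzed independently — the mutual information between branch identity
and firing-window position. This form was chosen because it reproduces the
three qualitative regimes exactly: φ ≈ 0 when branch windows merge within
the grain, φ maximal at intermediate gaps, φ → 0 when windows separate
beyond the analysis span. (A shift-nulled total-correlation variant was
tried first and rejected: identical firing windows maximize total
correlation instead of nulling it.) Branch event times are taken at the
*branch* (before dendritic conduction), where the level structure lives —
soma arrivals are coincident by construction.

A consequence worth stating plainly: this estimator is robust to the
probing noise that the somatic delay modulates, so in the delay sweep the
φ series' volatility and prediction error are nearly delay-invariant
(volatility ≈ 0.003, prediction error ≈ 0.001 at all delays) while the
lag-1 autocorrelation is uniformly high (≈ 0.995 at 19 ms). The package
reports these as measured; the trade-off between regime semantics and
delay-gradient sensitivity is intrinsic to the estimator choice.

For the sweep, the series has one value per firing cycle, computed over
the trailing 10 oscillation periods and normalized by (active levels − 1);
the sweep runs 500 cycles so the post-completion echo plateau is included.

`kl_phi_star(whole, parts)` is the shared irreducibility primitive:
KL divergence between the whole distribution over (part, position) cells
and the composition `w_k · Σ_j w_j parts_j(u)` — part masses times the
mixture shape. It vanishes exactly when all part shapes agree, is
non-negative (ε = 10⁻¹² regularization, base-2 logs), and is invariant
under part relabeling.

Fractal estimators: box-counting of the min–max-normalized series graph
with dyadic boxes; Higuchi with k = 1…10; DFA with log-spaced box sizes
from 8 to n/4 (≥ 10 sizes) and per-segment linear detrending. Calibration:
white noise α = 0.5 ± 0.05, spectrally synthesized 1/f noise
α = 1.0 ± 0.1, straight line Higuchi FD ≈ 1.

## 3. Theoretical somatic multifractal (GFM)

EPSP events use a unit-peak dual-exponential kernel
(τ_rise = 0.3 ms, τ_decay = 4.0 ms; peak time
`τ_r τ_d ln(τ_d/τ_r)/(τ_d − τ_r) = 0.840 ms`), with level amplitudes
`A_0 r^(i−1)` (A₁ = 0.15 … A₄ = 0.0324). Peak amplitudes are written onto
a 243×243 grid following the nested Sierpinski-carpet rule: the level-i
amplitude paints every cell that survives i carpet subdivisions, so levels
superpose into a multifractal hierarchy (the depth-1 support covers 8/9 of
the grid; the level-4 support has box dimension ≈ log 8/log 3).

Each uploaded EPSP pattern is rescaled to a fixed total intensity budget
of 550 units. This is the one free constant of the generational cycle and
was calibrated once so that the prescribed growth rule (one 3×3 smoothing
pass plus a conservative transfer of 8 % of off-center mass per step into
the central ninth) crosses the firing threshold of 180 every 3–4 steps.
Growth conserves total intensity to < 10⁻⁹ relative error between
collapses. At collapse the most information-rich (maximum-entropy)
peripheral quadrant becomes the seed (ties resolved NW→NE→SW→SE), and the
daughter is `q·expand(seed) + (1−q)·fresh` with nearest-neighbour seed
expansion and q = 0.6 by default (matching the tree's r, which makes the
generational information sum identical to the infinite spatial
downscaling sum).

Whole-in-part metrics compare parent and expanded seed: SSIM, Pearson
correlation, entropy-density ratio, and a radial-profile cosine as the
pattern-preservation stand-in (no formula is given for it anywhere; ours
is documented, not canonical). Default runs give collapse intervals
≈ 3.6 steps and parent/seed SSIM ≈ 0.70. The quadrant φ* peaks at collapse
steps because the centripetal growth concentrates mass at each quadrant's
inner corner — different positions within each quadrant — and resets after
the seed is re-expanded.

## 4. Ising lipid membrane

100×100 lattice of ±1 lipid states, ~400 channels (4 % density) at
distinct sites with a 3-site influence radius and 10 % mobility. Channel
opening is `P = S(E + 0.25 γ ⟨spin⟩_r3 + 0.5 · open-site fraction_r3)`;
the cooperative term uses the open-channel *site* fraction in the disk so
it stays a small logit correction. EPSP fields are level-wise Gaussians
(radius `size/4 − (level−1)·5`, centers: level 1 at the lattice center,
levels 2–4 offset by `(level−1)·size/8` at 0°/120°/240°), driven by
dual-exponential bursts (combined peak ≈ 2.3) that restart every 15 steps
and at each action potential.

Lipid dynamics: sequential Metropolis over a random 5 % of sites per step,
`ΔE = 2s(Σ neighbours + h)`, acceptance `exp(−ΔE·0.5)` (the base rule;
ΔE < 0 always accepted) or `exp(−ΔE/T_local)` when a spatial temperature
field is supplied. The external-field term `h = E(x,y)` is our addition:
the substrate must be programmable by EPSPs for blocked-mode lipid memory
to exist at all; with no field and no temperature map the model reduces to
a standard Ising relaxation, verified against exhaustive Boltzmann
enumeration on a 3×3 periodic lattice.

Center activity is the open-channel occupancy of the central 20×20 block
accumulated over a 5-step window (opening-*transition* counts cannot reach
the stated threshold range with 16 channels in the center, so occupancy is
the workable reading); threshold 30 then fires APs at refractory-limited
cadence. `refractory_steps = int(consciousness_level × 25)` (12 at the
default 0.5). APs redistribute channel positions and log a peripheral
seed record; the lipid field is never reset.

Substrate φ*: each substrate's activity distribution is compared with its
substrate-isolated null, which carries no spatial preference — i.e. φ* is
the spatial negentropy (bits) of the activity map, with a multinomial
noise-floor correction `(K−1)/(2N ln 2)`. Lipid activity is the
accepted-flip (reorganization) map at 2-px blocks; channel activity the
opening-event map at 5-px blocks with effective N equal to independent
position spells (positions persist between repositionings). Defaults give
blocked ≈ 0.12, continuous ≈ 0.18, channels 2–3× lower. Contribution
fractions decompose the opening logit at center channels during
refractory periods into |E|, |lipid bias| and |cooperative| shares
(blocked: lipids ≈ 82 %; continuous: EPSPs ≈ 93 %). Lipid FD is the
box-counting dimension of the domain-boundary set.

## 5. Holographic pipeline and feedback

EPSP→IFS (stage 1): the top 4–6 peaks, sorted by amplitude, map to
rotation-scalings with `s = 0.3 + 0.5·â` and `θ = 2π t̂`; translations
encode the normalized inter-peak interval (x) and amplitude (y).
Everything is deterministic and contractive by construction, with
selection probabilities ∝ |det| = s².

The chaos-game density of those transforms, binned on the lattice, 3×3
smoothed and peak-scaled to 0.5, gives the temperature field
`T = 0.5 + 0.2·density − 0.06`, i.e. hot fractal islands around
0.52–0.54 in a matrix cooled to ≈ 0.44. (The raw density is sharply
peaked; without the peak rescaling the hottest cell would sit at 0.64,
inconsistent with the intended hot-island morphology.)

Lattice→IFS (stage 3) fits one affine map per large connected +1 domain
(bounding-box scales, principal-axis rotation canonicalized to
(−π/4, π/4], centroid translation, all in [−1, 1] frame coordinates).
The differential set `H = T_temperature − T_blocked` subtracts
*corresponding* domains, matched by Hungarian assignment on translations;
rank-by-determinant pairing was tried and rejected because subtracting
unrelated domains leaves large translation residues that scatter the
regional attractors and destroy the whole-in-part signature. Differential
sets that are not contractive are jointly rescaled to spectral norm 0.9
(extraction is unique only up to scale).

Stage 4 positions 5000 sources (500 burn-in) by chaos game on H; phases
follow the geometric formula over the transforms' fixed points, with
`w_j = |det_j| s_j`; per-source frequency `50/(1+s)` Hz from the
generating transform; `k = 2πf/100`. The field is the coherent sum
`Σ A_i e^{i(k_i r_i + φ_i)}/(1+r_i²)` on a 24×24×12 grid over
[−2,2]²×[−1,1] with z-weight 0.5, |Ψ| min–max normalized. Control
strategies: `grid` keeps the geometric phases on a fixed reference lattice
over [−1,1]²; `random` is the fully incoherent null (random positions
*and* phases). Regional analysis uses eight regions (full, center half,
four quadrants, center core, periphery); similarity is the *median*
pairwise composite `0.5·Pearson(|Ψ|) + 0.5·SSIM(mid-plane)` (median
because one degenerate region should not mask the signature), attractor
dissimilarity the mean pairwise `1 − cosine` of lightly smoothed 64×64
density histograms. Defaults give endospace similarity ≈ 0.94 with
attractor dissimilarity ≈ 0.8 and the strict ordering
chaos > grid > random. Our differential attractors are near-point
clusters, so their histogram overlap is lower than the printed ≈ 0.5
dissimilarity; the similarity/dissimilarity contrast — the holographic
signature — is preserved.

Stage 5: `γ = γ_0(1 + α·Ψ̄)` with Ψ̄ the mean normalized magnitude over
the central half-box. The dose-response sweep runs nine γ in [1, 3],
ten 100-step blocked-mode trials each with the temperature field on,
reporting the refractory-period open-channel fraction (monotone in γ) and
the percentage of channels whose state agrees with the local lipid sign
(+5 to +7 points from γ = 1 to γ = 3).

## 6. Connectivity cloning

Method 1 copies the 3-D positions of all connected peripherals; their
loop delays still align, so coincidence detection rewires every copy
(100 % utilization), after which growth continues for the source's cycle
budget and appends rhythm-compatible extra connections up to capacity.
Method 2 reserves the source's (level, loop-time)-stamped slots; each
random peripheral contacts one vacant reserved position per cycle and
stabilizes only if its loop time falls within half a coincidence window
of the recorded stamp; the target runs for the source's wall-clock
duration (fewer cycles at its longer period) and both methods are
entrained to the source rhythm. The transfer experiment uses source delay
6 ms, target 15 ms, and a 100-cycle source budget so the source occupies
a minority of its 1000 slots, leaving room for later integration.
Signature similarity is `100·(1 − ½·L1)` between amplitude-weighted
branch-level histograms (`A_0 r^(level−1)` weights). Method 2 fills
≈ 25 % of reserved slots but preserves the signature better
(≈ 95 vs ≈ 92) because Method 1's extra connections can only occupy
whatever capacity the copies left free, skewing the level profile.

## 7. Seeding, sizes and limitations

All randomness flows from one master seed through named child streams
(`_seeding.named_rng`), so every sub-experiment is independently
reproducible and bit-identical under a fixed seed. Default problem sizes
(1000 synapses, 100 growth cycles for transfer, 100×100 lattice,
100 steps, 5 repetitions, 5000 sources) are the standard operating points
of the simulator; the acceptance script runs them unchanged.

What the synthetic inputs do not capture: EPSP trains are homogeneous
Poisson-like bursts without synaptic depression or adaptation; the
membrane has no leak, voltage, or real lipid thermodynamics; peripherals
are points with straight-line delays. Passing tests therefore establish
internal consistency of the models and reproduction of the stated
simulation phenomenology, not biological validity. Known limitations are
flagged inline above: the φ_dyn estimator's delay-robustness, the
point-like differential attractors, and the qualitative treatment of the
absolute oscillation frequency.
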