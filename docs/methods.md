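# Methods

This note documents the models, algorithms and numerical choices behind
`smftnmr`. The package is a desk-scale re-creation of a carbon-detected
NUS-NMR assignment workflow for disordered proteins: synthetic ground truth
in, simulated multidimensional time-domain data, sparse Fourier processing,
and automatic sequence-specific assignment out.

## Synthetic shift tables

Ground truth is a per-residue table of HN, N, CO, CA, CB, HA and HB
chemical shifts. Each present shift is drawn from a normal distribution
centred on a fixed random-coil reference mean (shipped with the package,
`refshifts.py`) and truncated to ±4 reference SDs. The user-facing width
parameter `jitter_sd` (default 0.3 ppm) is scaled per element class —
×1 for ¹³C, ×4.5 for ¹⁵N, ×0.08 for ¹H — reflecting that amide nitrogen is
by far the most sequence-context-sensitive backbone nucleus in disordered
chains while proton dispersions are tiny. Prolines carry no HN, glycines no
CB/HB; glycine's two alpha protons are modelled as a single HA coordinate.

**Collision-free condition.** Exact automatic assignment is only a
well-posed target when the shift draw is collision-free. The generator can
enforce this (`ensure_pair_separation`): no two sequential CO–N anchor
pairs (CO_{i−1}, N_i) may coincide within twice the matching tolerances
(0.1 ppm ¹³C, 0.2 ppm ¹⁵N), and the two carbonyls of one basis peak
(CO_{i−1}, CO_i) must differ by ≥ 0.2 ppm — roughly one indirect ¹³C
linewidth — because below that the different fixing variants of a basis
peak stop addressing distinct planes. Offending residues are redrawn
individually and deterministically. Partial overlaps above these scales
but below the point-spread widths still occur (they must, geometrically,
for realistic sequence lengths) and are handled downstream (see
*interference-aware routing*).

## Experiments and signal model

Three experiments are defined (`experiments.py`), with acquisition-scale
defaults: 4D (HACA)CON(CA)NCO — CO(28 ms/2.2 kHz), N(28 ms/2.8 kHz),
N(28 ms/2.8 kHz), direct CO; 2400 increments. 5D HabCabCO(CA)NCO —
Hab(10 ms/6 kHz), Cab(7.1 ms/15 kHz), CO, N, direct CO; 1800 increments.
5D HNCO(CA)NCO — HN(10 ms/5.2 kHz), N, CO, N, direct CO; 1800 increments.
The direct carbonyl dimension is acquired for 106 ms and processed at
599.6/150.8/60.8 MHz (¹H/¹³C/¹⁵N) base frequencies.

`shift_synth.enumerate_peaks` lists every peak each experiment produces,
with signs: 4D sequential CO_i–N_{i+1}–N_i–CO_{i−1} (negative, positive if
residue i is Gly) and diagonal CO_i–N_{i+1}–N_{i+1}–CO_i (opposite);
aliphatic HA/CA and HB/CB families (HB always positive, HA negative only
for Gly); amide HN–N pairs (negative if residue i−1 is Gly). Peaks whose
coordinates do not exist (termini, Pro HN, Gly CB/HB) are omitted.

A peak of amplitude ±1 contributes a product of cos/sin modulations (States
quadrature; 2^(D−1) stored components per schedule point) with exponential
decay per dimension, times a complex direct-dimension evolution, times
cos(πJt) for the in-phase and sin(πJt) for the anti-phase part (J = 53 Hz
CA–CO coupling). Defaults: R2 = 47 s⁻¹ in indirect dimensions (~15 Hz
lines) and R2 = 10 s⁻¹ for the direct carbonyl — IDP CO lines are only a
few Hz wide, which is precisely what a 106 ms acquisition is meant to
resolve. Complex Gaussian noise of configurable SD is added to every
stored value. No pulse-sequence physics (transfer efficiencies, phase
cycling) is modelled; relative family amplitudes are equal by default and
exposed as `family_scale`.

## Sampling schedules

On-grid Poisson-disk dart throwing: a candidate grid point is accepted with
probability Π_d exp(−(t_d/(0.5·t_max,d))²) and rejected when closer (in
t_max-normalised Euclidean distance) than the disk radius to an accepted
point. The initial radius follows the covered-volume heuristic
0.7·(0.441^D/n)^(1/D) (0.441 is the per-dimension integral of the Gaussian
envelope) and relaxes ×0.9 whenever the try budget is exhausted; the final
radius is reported. The first increment (t = 0) is always included. The
full-grid request returns the Cartesian grid directly.

## Processing

**Virtual decoupling.** The anti-phase component is phase-rotated by 90°
(×i); IP + iAP and IP − iAP are frequency-shifted by ∓J/2 through
time-domain multiplication by e^(∓iπJt), then averaged. For the ideal
signal model the CA–CO doublet collapses exactly to a single line at the
shift position with twice the amplitude of one doublet component; the
measured residual at ±J/2 (~1 % with default linewidths) is the tail of
the collapsed line itself.

**Direct dimension.** cos²(πt/(2t_acq)) weighting, first point halved,
zero-fill to 2048 complex points, FFT, real (absorptive) part. Bin m maps
to carrier + sw·(m/2048 − 1/2).

**MFT / SMFT.** The NUS Fourier sum is evaluated with unit weights (no
density compensation — the Gaussian schedule itself acts as apodization;
no apodization is applied in indirect dimensions). Hypercomplex
demodulation combines each dimension's cosine/sine parts as
cos·cos(ωt) + sin·sin(ωt), i.e. the absorptive part. `mft` evaluates
arbitrary indirect grids at one direct bin (O(n_points × grid)); 
`smft_plane` pins the fixed dimensions of a fixing variant to a basis
peak's frequencies and evaluates only the 2D plane. A fixed direct
frequency is read at the nearest of the 2048 bins (bins ≈ 1 Hz are far
finer than any linewidth); a free direct dimension contributes its
(windowed) frequency axis. Both routes perform identical arithmetic, and
the test suite checks plane ≡ hyperplane-slice agreement to 1e−9 relative
on every variant.

**Free-grid steps.** Cross-section grids default to the full spectral
window at step 1/(divisor·t_max). The pipeline uses divisor 2 for CO, 4
for ¹⁵N and Cab, and 6 for ¹H axes: parabolic peak interpolation must
reach a fraction of the matching tolerances (0.01 ppm for ¹H), which two
points per resolution element cannot deliver on proton axes.

## Peak picking

2D planes: signed 3×3 local extrema above `threshold_sigma` (default 6) ×
a robust noise level (1.4826·MAD), refined by per-axis three-point
parabolas. On noiseless data the MAD floor is the sampling-artifact level,
so picking thresholds adapt automatically.

4D basis spectrum: full 4D grids are deliberately avoided. The direct
power projection selects candidate bins (local maxima plus a 12 Hz-strided
fill of the above-threshold region); for each, a 3D indirect cube is
evaluated on windows spanning the plausible CO/N ranges (from the
reference table, or from the synthetic table when given) at step
1/(2·t_max). Cube extrema above a relative floor (25 % of the global
maximum) are refined by pointwise re-evaluation of the Fourier sum
(indirect dims: shrinking three-point parabolas; direct dim: fine-axis
re-location), deduplicated across cubes, and classified: a peak with
dim1 ≈ dim4 (0.1 ppm) *and* dim2 ≈ dim3 (0.25 ppm) is diagonal and
excluded; the rest form the basis peak list, signs retained. The ratio of
the strongest peak to the artifact floor is logged and reported (~60 on
the bundled example), not asserted.

## Assignment

**CSSS formation.** Each basis peak's ten planes are routed into 18 shift
slots (CO_{i−2..i+1}, N_{i−1..i+2}, CA/CB/HA/HB of i−1 and i, HN of i and
i+1). Templates whose positions are predictable from already-filled slots
consume their picks first (consumption tolerance 2× matching tolerance —
overlap can pull apparent maxima); templates with unknown positions take
the strongest remaining pick that is *not* within a point-spread exclusion
radius (0.15 ppm C, 0.4 ppm N, 0.06 ppm H) of a known or consumed peak —
such picks are shoulders or artifact ridges, not independent resonances.

Aliphatic planes carry no predictable positions; picks are first cut at
the first >2× intensity gap (true alpha/beta peaks have comparable
amplitude; leaked foreign peaks are point-spread-attenuated), classified
against the joint (H, C) random-coil ranges (negative intensity forces
alpha — only glycine alpha peaks are negative), and the (alpha, beta)
combination with the largest summed |intensity| among class-compatible
ones wins. Ties between different contents mean the data cannot decide: a
lone peak compatible with both classes leaves both slots empty.

**Interference-aware routing.** The fixing variants (2i)/(2iii) and
(3i)/(3iii) expect identical peak types from different fixed frequencies —
redundancy intended as a cross-check for overlapping planes. The package
quantifies each 5D plane's contamination as the summed point-spread-kernel
overlap between its fixed frequency triple and every *other* basis peak's
two family triples (Gaussian kernels of width 0.151/0.374/0.08 ppm for
indirect C / indirect N / direct C; near-exact matches are the plane's own
content and are skipped). Slot conflicts are resolved by this penalty
(in 0.05 buckets) first, then by |intensity|; the final per-residue shift
consensus uses the same rank. This is what keeps partially overlapping
cross-sections (unavoidable at realistic sequence lengths) from
contaminating the spin systems.

**Linking.** A successor hypothesis A→B is scored by the three shared
CO–N pairs — A's (CO_{i−1},N_i),(CO_i,N_{i+1}),(CO_{i+1},N_{i+2}) against
B's preceding triple — plus shared aliphatic/amide slots. Comparisons use
a hysteresis band: within tolerance = match, beyond 2× tolerance =
contradiction (veto), in between = uninformative, because position
estimates on coarse indirect grids do not support a hard veto at exactly
the matching tolerance. A link needs ≥ 2 pair matches, no contradiction,
and mutual-best uniqueness (deterministic; no probabilistic scoring).
Chains are maximal paths of unambiguous links; chain ends separated by
exactly one missing basis peak are joined when the two surviving pair
comparisons (offset 2) match, and all seven shifts of the bridged residue
are recovered from the flanking spin systems.

**Recognition and mapping.** Candidate amino acids per residue are those
whose reference CA/CB (and HA/HB when observed) lie within k_sd = 3 SDs of
the observations; an amino acid lacking an observed nucleus (Gly vs CB) is
excluded, and an empty observation admits all twenty. Chains map at
positions where every member's candidate sets contain the corresponding
letters (member residues are confined to 2..L−1 by construction of the
basis experiment); chains with exactly one admissible position are
assigned, longest first, later chains blocked by occupied positions.
Evaluation reports per-nucleus correct/incorrect/unassigned fractions over
the *observable* resonances (those some theoretically existing spin system
covers). Correctness is judged at the matching tolerances for CO, N and
the protons, and at 0.1 ppm for CA/CB: those are measured on the wide
aliphatic-carbon dimension (7.1 ms evolution, 0.47 ppm resolution
element), whose achievable position precision — wide lines displaced by
the sparse-sampling background — is of that order.

## Overlap resolution

Basis peaks whose (N_i, CO_{i−1}) pairs coincide within tolerance produce
identical (1i) planes carrying the union of their peaks. Each member's
(1iv) plane — different fixed frequencies, same expected peak types — is
used as the cross-check: (1i) picks without a counterpart (within
tolerance) among the (1iv) plane's comparable-intensity picks are
attributed to the overlapping partner. The (1iv) confirmation list is
first trimmed at a 3× intensity gap because direct-free planes carry
artifact ridges (many weak spurious local maxima along the indirect axis).
If all members retain an identical excess set, the group is flagged
ambiguous and nothing is guessed.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `jitter_sd` | 0.3 ppm | shift dispersion scale (×1 C, ×4.5 N, ×0.08 H) |
| `j_caco` | 53 Hz | CA–CO scalar coupling (IPAP) |
| `r2_indirect` | 47 s⁻¹ | indirect linewidth ≈ 15 Hz |
| `r2_direct` | 10 s⁻¹ | direct CO linewidth ≈ 3 Hz |
| `noise_sd` | 0 | complex noise SD per stored point |
| `threshold_sigma` | 6 | picking threshold over MAD noise |
| tolerances | 0.05/0.1/0.01 ppm | ¹³C/¹⁵N/¹H matching tolerances |
| `k_sd` | 3 | recognition width in reference SDs |
| `step_divisors` | CO 2, N 4, Cab 4, Hab/HN 6/4 | free-grid steps 1/(d·t_max) |

## Problem sizes and noise regimes used in the studies

The bundled worked example is a 60-residue sequence with six glycines and
six prolines, simulated noiselessly at the full acquisition-scale schedules
(2400/1800/1800 increments); it runs in a few minutes on one CPU. The
subsampling study (re-transforming a 5D from the first 2/3 of its
schedule) uses a 14-residue peptide with time-domain noise SD 10, which
puts the cross-sections at SNR ≈ 15 with thermal noise ~3× the sampling-
artifact floor — the regime the method is designed for, where artifacts
are a tiny proportion of the spectral noise. The overlap study engineers
two residues with identical (N_i, CO_{i−1}) anchors inside a 14-mer.

## What the synthetic data does and does not show

The generator reproduces the *structure* of IDP spectra: narrow
random-coil-centred dispersion, proline/glycine absences, correct peak
families and signs, hypercomplex IPAP acquisition, NUS artifacts. It does
not model sequence-dependent secondary-shift trends, differential transfer
efficiencies or relaxation losses across pathways, solvent/artifact lines,
temperature/pH effects, or peak-intensity heterogeneity beyond the decay
model. Passing the end-to-end studies therefore demonstrates the
correctness and internal consistency of the processing and assignment
machinery under the stated conditions — not assignment performance on any
particular real protein.

## Known limitations

* Sequential and diagonal 4D peaks that overlap (opposite signs) can
  cancel; the basis list then misses that residue and only the gap-bridging
  machinery compensates. The pipeline reports, but cannot repair, such
  losses.
* Fully degenerate overlap groups (identical on both 1i and 1iv fixings)
  are flagged and left unresolved by design.
* The amino-acid recognition uses per-kind global SDs rather than
  amino-acid-specific ones, which makes candidate sets slightly generous.
* `assembled` shift values inherit the digital resolution of whichever
  plane supplied them; proton values are good to a few thousandths of a
  ppm only because matched comparisons cancel grid bias.
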