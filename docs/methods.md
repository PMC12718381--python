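# Methods

This note records the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Intensity model and synthetic trajectories (`stimfret.sim`)

A molecule carries one donor and one acceptor dye.  Per frame, before any
photobleaching, with background b, summed signal T, state FRET E and the
per-molecule detection correction γ:

    acceptor = b + T·E
    donor    = b + T·(1−E)/γ

so that the ratio estimator E = I_A/(I_A + γ·I_D), applied to
background-subtracted channels, is exactly the generating E.  After
acceptor bleach the excitation reappears in the donor channel
(donor = b + T/γ, acceptor = b); after donor bleach both channels are at
background.  Bleaching is single-step and irreversible with independent
per-frame hazards (geometric bleach frames); blinking is not simulated
because the analysis does not use it.  Channel noise is additive Gaussian —
enough to stress the estimators while keeping closed forms checkable; there
is no EMCCD gain model, pixelation, spectral crosstalk or direct-excitation
term (the only channel correction carried through the analysis is γ).

Conformational switching is a discrete-frame Markov chain: per frame the
exit probability is 1 − exp(−k_exit·Δt) with destinations proportional to
the off-diagonal rates.  This is exact at the sampling resolution of the
data.  The default frame interval is 0.1 s and every time-windowed analysis
takes seconds, not frames.

Per-molecule γ is drawn log-normally (median 1.0, σ_log = 0.2): strictly
positive, mild spread, consistent with γ being measured molecule by
molecule.

`simulate_state_ensemble` generates the *static* ensembles used for
occupancy studies from a list of (peak FRET, fractional area) components.
Each molecule gets one state for its whole trace.  The ≈0.07-wide histogram
components are realized as per-molecule static heterogeneity
(sd 0.04 around the component mean) plus intensity noise sized to give
≈0.055 E-units of frame-to-frame spread (γ-estimation scatter contributes
another ≈0.01).  This split keeps histograms smooth (each molecule's frames
fill in a bump) without making the intensity ratio noticeably biased or
skewed.  Defaults: 300 frames, T = 400 counts/frame, background 40,
acceptor/donor bleach hazards 0.01/0.0025 per frame — about 60% of
molecules survive QC, the rest bleaching too early, never bleaching, or
bleaching donor-first.  What the generator does **not** emulate: diffusing
background, multi-molecule spots, dye blinking and reactivation, slow drift
or focus loss.  Tests passing on these ensembles therefore demonstrate the
estimators' correctness under the stated model, not robustness to every
microscope artifact.

The trace store is a tidy CSV (molecule_id, frame, donor, acceptor, and a
`state` column when simulation truth is attached) with a JSON sidecar for
frame intervals and truth scalars, or a single HDF5 file with one group per
molecule.

## Photobleaching QC and γ (`stimfret.qc`)

Change points are found by exact dynamic programming over all piecewise-
constant segmentations with an L2 cost (minimum segment four frames),
rather than greedy binary segmentation: at trace lengths of a few hundred
frames the O(m·n²) solve is cheap, and optimality lets the detector be
verified against exhaustive search.  The number of steps is chosen by a
penalized cost; the default penalty 10·σ̂²·ln(n) uses a robust noise
estimate from first differences (median |Δy| / (0.6745·√2)), so clean level
shifts of a few σ are found and pure noise yields none.

Molecule selection: exactly one acceptor down-step, at most one donor
down-step, acceptor first, at least 20 pre-bleach frames, and
donor–acceptor anticorrelation (Pearson r ≤ −0.2) over the pre-bleach
window.  Two details matter in practice:

- *Bleach order* is decided by the sign of the donor mean-level change
  across the acceptor bleach frame, not by whether a donor down-step was
  detected.  A donor-first bleach collapses both channels at once; at high
  FRET the donor drop is small and step detection alone misses it, which
  would bias acceptance in favor of high-FRET molecules.  The sign test is
  reliable at any FRET value.
- *Anticorrelation* is waived for single-state traces, judged by comparing
  each channel's variance with its first-difference noise estimate
  (waived when below 3× the noise variance): a static molecule has no
  signal variance to correlate.

γ = |ΔI_A|/ΔI_D with mean levels over 30 frames on each side of the
acceptor bleach (truncated at donor bleach).  Thirty frames keeps the
ratio's sampling noise near ±5%, small enough not to distort the histogram
shape; backgrounds cancel in the differences.  Unusable steps (no bleach,
non-positive donor rise, too few post-bleach frames) fall back to the
ensemble median of successful estimates and are flagged.  Background is the
post-donor-bleach mean per trace when observed, else the dataset median of
those means, else a configured constant.

E is computed per frame after background subtraction; frames with a
non-positive denominator are excluded and counted; raw values are stored
alongside a copy clipped to [−0.1, 1.1].

## Histograms, mixtures, occupancy, transitions (`stimfret.states`)

Histograms span [−0.1, 1.1] in 0.02 bins.  With per-molecule weighting each
molecule's frames are normalized to unit mass so long-lived molecules do
not dominate; per-frame pooling is available.  Whether the original
analysis pooled frames or molecules is not stated anywhere; both are
config.

The mixture Σ w_k·N(μ_k, σ_k) is fit to the binned density by nonlinear
least squares (matching the practice of fitting curves to the displayed
histogram), weighted per bin by a molecule-level bootstrap sd of the
density — without this weighting the residual scale is misjudged and model
selection is unstable.  Restarts (20, deterministic sub-seeds) mix
peak-based and uniform-random mean initializations, plus a hierarchical
start that seeds the k-component fit with the best (k−1) fit and one
component at the largest positive residual; that start is what reliably
isolates small shoulders.  Component count is selected by
BIC = χ² + p·ln(n_bins), accepting a larger k only for a > 10-unit
improvement, ties toward smaller k.  An optional shared-σ mode fits one
common width — appropriate when all states broaden identically (as in the
generator) and markedly more stable for components holding a few percent of
the mass; parameter-recovery studies use it with the component count fixed
to that of the reference fit, and match fitted to reference components by
nearest mean (`match_mixture_to_reference`) so near-duplicate components
pool instead of corrupting the comparison.

Occupancy is the fractional area of the designated resting-state component
— by default the lowest-μ component, overridable per dye pair (for some
pairs, e.g. 242:431′, the resting state is the high-FRET peak); the rule is
explicit configuration, never inferred from the data.

Distances use E = 1/(1 + (R/R₀)⁶) with R₀ = 5.8 nm; the forward and inverse
maps are closed-form and mutually inverse to 1e-12 relative.

Transitions: frames are assigned to components via midpoint thresholds
between adjacent μ_k; the running assignment changes only when the value
clears the threshold by more than one σ of the component on the far side
(hysteresis), and a change must persist ≥ 3 frames (default) to count.
Counting is restricted to the first window (default 5 s).  The dwell filter
deliberately drops one-or-two-frame excursions, so counted transitions are
a slight undercount of raw chain switches; quantitative comparisons against
the closed-form Markov expectation (n−1)·(1−e^{−kΔt}) therefore use
min_dwell_frames = 1, where the identity is exact.

## Dye clouds and model distances (`stimfret.structure`)

The accessible volume of a dye is enumerated on a cubic grid (default 1 Å)
inside the linker-length ball around the attachment atom (Cβ of the labeled
residue, Cα fallback).  A position is allowed if its center keeps
dye_radius + clash_distance from every heavy atom (the labeled residue's
own atoms excluded) and the straight segment back to the attachment atom
keeps linker_width/2 clearance — the standard single-radius AV
simplification; no flexible-path search, no rotamer-library (AV3) dye
model.  Defaults: linker 20 Å, width 4.5 Å, dye radius 3.5 Å, clash 1 Å,
all configurable, chosen as conventional values for maleimide-linked
cyanine dyes; the original dye-position computation is described only by
the software used, so model–experiment agreement is a qualitative, not
bit-exact, target.  A Monte-Carlo rejection sampler applies the identical
predicate to uniform points in the ball and serves as the independent check
on the grid enumeration.

Inter-dye distance is either the distance between cloud centroids or the
FRET-averaged distance (the distance whose efficiency equals the mean of
1/(1+(r/R₀)⁶) over sampled position pairs) — the latter is what an
intensity-averaged measurement actually reports.  Model distances are
reported in nm (coordinates are Å; the factor is 10).  Pair labels follow
the dimer convention: "242:400′" pairs site 242 on one chain with 400 on
the partner chain.

## Crosslinking statistics (`stimfret.crosslink`)

Lanes carry (species, channel, intensity) with species ∈ {monomer,
homodimer, heterodimer}.  The heterodimer band contains one subunit of each
channel per dimer, so scaling ch1 by s = I_het(ch2)/I_het(ch1) puts both
channels in common units, and the heterodimer band's normalized intensity
*is* its dimer count.  Subunit totals are monomer + heterodimer +
2·homodimer per channel; whether homodimer bands should count double is not
settled, so it is a toggle (default on).  Random assembly of pools M and H
expects M·H/(M+H) heterodimers; efficiency is the observed crosslinked
heterodimer band over that expectation.  Efficiencies above 1 are flagged,
never clipped — they falsify the random-assembly assumption for that lane.
Uncertainty over replicate lanes is a percentile bootstrap (resampling
lanes); intervals require ≥ 2 replicates, and coverage approaches nominal
by around ten replicates.  Band tables are taken as background-corrected;
densitometry is upstream.

## Problem sizes and tolerances in the tests

The recovery suite simulates each reference histogram fit at its printed
molecule count (184–437) over 10 seeds and requires fractional areas within
±6 percentage points and means within ±0.03 of the generating values;
measured errors are ≈2 pp and ≈0.01.  γ recovery uses 500–1,000 molecules
(median within 2%); transition counting uses 1,000 molecules of 60 frames;
accessible-volume checks use 20 random obstacle scenes with 1 Å grids
against ≥ 1.2×10⁵ Monte-Carlo samples (agreement within 0.02 absolute);
crosslinking recovery uses 10⁴-dimer lanes with 2% band noise (efficiency
within ±0.02 per seed).  These sizes were chosen so the whole suite runs in
a few minutes on one core while keeping sampling error well inside every
tolerance.

## Known limitations

- The generator's noise and bleaching are idealized (see above); QC
  thresholds are explicit configuration, not a claim about the original
  study's selection protocol, which is described elsewhere.
- Mixture fitting on binned densities cannot resolve components much
  smaller than the molecule-sampling noise in their bins; with ~200
  accepted molecules, components below ~2% of the mass are unidentifiable
  in a single dataset.
- The AV model treats the linker as a straight tether and the dye as a
  sphere; occluded-but-reachable pockets are excluded and anisotropic dye
  orientation (κ²) effects are outside scope.
- No kinetic (HMM/dwell-time) inference: transition counting is a summary
  statistic, not a rate estimator.
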