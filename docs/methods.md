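# Methods

## Scope and model

`mrf3d` simulates and analyzes a 3D MR fingerprinting (MRF) acquisition
that quantifies proton density (PD), T1, T2, T1ρ and the transmit-field
scale B1+ in a single sequence.  The sequence model is:

1. a 10 ms adiabatic inversion (instantaneous rotation with an efficiency
   parameter, default 1.0, followed by a 10 ms relaxation delay inserted by
   the schedule builder);
2. a T1/T2 module of two FISP segments — 250 excitations each, flip-angle
   ramps peaking at 20° and 60°, one unit of unbalanced gradient dephasing
   per TR, 50 ms recovery delay between segments;
3. a T1/B1 module of two FLASH segments with the same flip-angle patterns,
   modeled with ideal spoiling (transverse magnetization zeroed every TR);
4. a T1ρ module of six spin-lock preparations with lock times spanning
   2–45 ms, each followed by 125 excitations (ramp to 20°) and a 500 ms
   recovery delay.

TR = 7.5 ms, TE = 3.5 ms, one readout per excitation: 1750 samples per
fingerprint.  All flip angles are multiplied by the voxel's B1+ scale.

### EPG engine

Magnetization is propagated with the extended phase graph formalism:
ladders of configuration states (F+k, F−k, Zk) over integer dephasing
orders.  The phase convention is F ≡ Mx + iMy with RF phase 0 meaning a
right-handed rotation about +x; `f_minus[k]` stores conj(F−k) so that
`f_minus[0] == conj(f_plus[0])` is an invariant.  The default maximum
retained order is 250 (the longest segment length); states shifted beyond
it are truncated.  The truncation error is far below the 10⁻³ oracle
tolerance because configuration states need many TR periods of T2 decay to
reach high orders and as many again to refocus.

The test suite validates the engine against a brute-force isochromat Bloch
simulation (2048 spins whose per-TR dephasing increments uniformly span one
gradient cycle, replaying the identical event table through plain 3-vector
rotations).  Agreement is at machine precision, not merely within the
10⁻³ tolerance, because with ≥ 1251 equally spaced isochromats the
discrete ensemble average is an exact quadrature of the EPG orders
populated by this sequence.

### T1ρ preparation model

The composite preparation (hard 90°y tip-down, four balanced
alternating-phase spin-lock pulses with paired 1 ms 180°±x refocusing
pulses, tip-up, crusher) is modeled as mono-exponential rotating-frame
decay of the stored longitudinal magnetization, `Z ← Z·exp(−TSL/T1ρ)`,
with residual transverse magnetization crushed.  The balanced design
exists precisely to cancel B0/B1 errors inside the preparation, and a
dictionary that carries T1ρ as a single parameter cannot represent
anything finer; this is the standard dictionary model for spin-lock MRF.
The spin-lock amplitude (500 Hz nominal) is carried as metadata only.

The exact six lock durations are not prescribed beyond their 2–45 ms span;
the default is six values log-uniform on [2, 45] ms, which spreads the
sampled attenuations evenly for mid-range T1ρ.  The ramp shape of the
flip-angle trains is likewise only constrained by its 0°→20°/60° span;
the default is the half-sine lobe conventional for FISP-MRF trains
(normalized so the peak equals the nominal maximum also for even train
lengths), with a linear ramp selectable.  Both choices are recorded in the
schedule hash so dictionaries can never be mixed across schedules.

## Dictionary

Parameter axes are geometric progressions with 6% steps over T1 50–3000 ms,
T2 2–200 ms, T1ρ 2–200 ms (71 × 80 × 80 values).  Combinations with
T2 > T1, and by default also T1ρ > T1, are removed as unphysical.  The B1+
axis is off (single value 1.0) by default and configurable (e.g. 0.7–1.3
in 0.1 steps); none of the desk-scale studies here enable it.  Atom
fingerprints are simulated in chunks (bounded memory), unit-L2-normalized,
and stored with their norms so matching recovers PD as the inner-product
amplitude.

SVD compression projects fingerprints onto the top right-singular
subspace.  The default matching rank is 30.  This is a deliberate choice:
normalized MRF fingerprints are extremely correlated, so the *minimal*
rank retaining 99.9% of the energy is ~3, which destroys matching fidelity
— the information that discriminates neighboring atoms lives in the
spectral tail.  Rank 30 (the scale used in compressed-MRF practice)
retains ≥ 99.9% energy with orders of magnitude to spare and reproduces
uncompressed matching exactly in our tests.  For atom counts larger than
twice the timepoint count the right singular vectors are computed from the
chunk-accumulated timepoint Gram matrix (mathematically identical to a
thin SVD; the tail of the spectrum then carries half-mantissa noise, which
is irrelevant at any usable rank).

## Matching

Per voxel, the matched atom maximizes |⟨atom, signal⟩| over unit-norm
atoms; the magnitude (not the real part) makes matching invariant to the
arbitrary global phase of a simulated or reconstructed acquisition.
PD = |⟨·⟩| / atom norm; the match score is |⟨·⟩| / ‖signal‖ ∈ [0, 1].
Ties break to the lowest atom index, making noiseless matching
bit-reproducible.  Voxels below 1% (configurable) of the volume's
99th-percentile signal norm are masked and carry NaN.

The optional refinement pass — the iterative stage — evaluates the 3×3×3
neighborhood of the matched atom in (T1, T2, T1ρ) grid indices, fits a
full 10-term quadratic (including cross terms) to the scores in
log-parameter offsets, and moves to its stationary point clamped to one
grid step per axis.  The cross terms matter: T1 and T1ρ scores are
coupled, and independent per-axis parabolas can move an estimate a full
grid step away from the truth, while the joint fit recovers noiseless
off-grid tissues to a few percent of a grid step.  Edge atoms with
incomplete neighborhoods are left unrefined.  Refinement defaults off; all
headline numbers are computed with pure grid matching.

## Digital phantoms and simulated acquisition

The system-phantom analogue places 14 disjoint spheres (radius 5 mm) on a
circle in a 64×64×8 volume of 1×1×3 mm voxels, with T1 geometrically
spaced over 200–2500 ms, T2 over 5–600 ms, and T1ρ over 5–450 ms (the
short ends clamped at 5 ms so every sphere is simulable).  The top T2/T1ρ
spheres deliberately exceed the dictionary range and saturate at its
boundary, as the corresponding physical spheres do for this dictionary.
The brain-like phantom is concentric elliptical CSF/GM/WM compartments
(literature-plausible 3 T values: WM 850/70/90 ms, GM 1400/90/110 ms,
CSF 3000/500/400 ms for T1/T2/T1ρ) plus focal lesions inside WM whose
three relaxation times are elevated by a common factor (default 1.3).

Direct-mode acquisition assigns every foreground voxel its region's
fingerprint (one EPG simulation per label) scaled by PD, plus i.i.d.
complex Gaussian noise; an n-shot acquisition is the complex average of n
independently noisy shots, so the averaged noise SD falls as 1/√n — the
direct-mode stand-in for the k-space coverage benefit of extra shots.  The
default noise level sets the single-shot per-sample SNR (RMS signal over
RMS complex noise) to 6.5, the single-shot image-SNR scale this sequence
family exhibits in vivo; 2-shot studies (the clinically chosen setting)
then sit near SNR 9.  All randomness flows from one seed.

k-space mode samples each frame's image along golden-angle
(111.246…°) radial spokes — shot s offset by s·180°/n — with Cartesian,
center-out-ordered kz.  The transform is an exact direct non-uniform DFT
(adjoint exact by construction), which is entirely adequate at the grid
sizes this package simulates and keeps the forward/adjoint pair free of
gridding approximations.  Reconstruction is ramp-density-compensated
adjoint gridding with an area-matched center weight, normalized so
absolute image intensities are preserved.  Radial trajectories never
sample the Cartesian corner frequencies, so reconstructions are assessed
against the dense-DFT reference restricted to the sampled circular
k-support (for a sharp 32×32 disk that band limit alone accounts for ~10%
NRMSE; the reconstruction adds ~3.5%).

## Statistics

ROI summaries use the population SD.  Bland–Altman limits are
bias ± 1.96 × sample SD of the paired differences.  The intraclass
correlation is σb²/(σb²+σw²) with a one-way decomposition: σw² from
test-retest differences (mean d²/2) and σb² from the variance of subject
means minus its within-subject share, floored at zero; the ratio is
clamped to [0, 1].  The paired t-test is the standard statistic with
df = n−1 and a two-tailed p from the t-distribution survival function; a
zero difference variance is an error rather than p = 0.  The SNR estimator
is mean(signal ROI)/SD(noise ROI) with an optional Rayleigh correction for
magnitude-image background noise (off by default, matching common
practice).

## Study problem sizes

Desk-scale studies are sized to run on one CPU in minutes while preserving
the relationships under test: the system-phantom multi-shot study uses the
full published ranges at a coarsened 25% geometric step (≈ 6.4k atoms) —
the shot-dependence of ROI noise does not depend on grid resolution — while
the brain lesion study keeps the published 6% step over the ranges its
parenchymal tissues span (T1 600–1600 ms, T2 40–160 ms, T1ρ 50–160 ms,
≈ 8.2k atoms), since its claim (ratio recovery within one grid step) is a
statement about the 6% grid.  CSF saturates at those range boundaries by
design and is not part of any quantitative claim.  Matching-robustness
metrics use a 6%-step mid-range dictionary (T1 500–1500, T2 40–120,
T1ρ 50–140 ms; ≈ 6.5k atoms).

## What the synthetic studies do and do not show

The generator reproduces the acquisition's signal model, its noise-vs-shots
arithmetic, and the grid-matching estimator, so passing tests validate the
physics engine, the dictionary/matching machinery and the statistics
exactly as implemented.  They do not probe effects absent from the model:
B0 off-resonance, slab excitation profiles, magnetization transfer,
partial-volume voxels, coil sensitivities, motion, undersampling artifacts
of single-spoke-per-frame radial imaging, or imperfect spin-lock
compensation.  Real-scanner biases arising from those mechanisms are
invisible here by construction.

## Known limitations

- The FLASH module's ideal-spoiling model is dictionary-equivalent to RF
  phase cycling only under complete spoiling; strong stimulated-echo
  regimes are not represented.
- One fingerprint models one kz-partition train with a fresh inversion;
  steady-state carry-over between partitions is assumed fully reset.
- k-space simulation is 2D-per-partition (stack-of-stars separability) and
  computationally intended for small grids; it exists to validate the
  trajectory and reconstruction operators, not to emulate full-resolution
  scans.
- The ICC decomposition assumes exchangeable scan order and homoscedastic
  within-subject error across subjects.
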