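# mrf3d

3D MR fingerprinting (MRF) with T1ρ encoding, at desk scale: an extended
phase graph (EPG) simulator for an inversion / FISP / FLASH /
spin-lock-prepared fingerprinting sequence, geometric-grid dictionary
generation with SVD compression, dictionary pattern matching to voxelwise
PD / T1 / T2 / T1ρ / B1+ maps, digital phantoms with golden-angle
stack-of-stars acquisition simulation, and the repeatability statistics
(ROI summaries, Bland–Altman, ICC, paired t-tests) used to evaluate such
sequences.

The package is for researchers prototyping or teaching quantitative
multi-parameter brain mapping — in particular T1ρ-MRF, where the rotating-
frame relaxation time T1ρ (sensitive to kHz-range water–macromolecule
interactions, with applications in multiple sclerosis, Alzheimer's and
stroke) is quantified simultaneously with T1 and T2 — without requiring
scanner data: every experiment runs end-to-end on simulated digital
phantoms.

## The method

A fingerprint is the complex signal series a tissue produces under a
deliberately varied pulse train.  The default schedule is an adiabatic
inversion; two FISP segments (250 excitations each, flip-angle ramps
0→20° and 0→60°, unbalanced gradient per TR) encoding T1/T2; two
ideally-spoiled FLASH segments with the same ramps encoding T1/B1+; and six
spin-lock preparations (lock times 2–45 ms, each modeled as
Z ← Z·exp(−TSL/T1ρ) with a crusher) each followed by 125 excitations —
1750 readouts at TR 7.5 ms / TE 3.5 ms.

A dictionary of EPG-simulated fingerprints is computed on a geometric grid
(T1 50–3000 ms, T2 2–200 ms, T1ρ 2–200 ms, 6% steps), unit-normalized, and
optionally SVD-compressed.  Each voxel's signal s is matched to the atom
maximizing |⟨d_j, s⟩| (phase-invariant); the amplitude yields PD, the
atom's coordinates yield T1/T2/T1ρ/B1+, and an optional second pass refines
the estimate inside the local 3×3×3 grid neighborhood.

## Worked example

```python
import numpy as np
from mrf3d import (SequenceConfig, TissueParams, build_schedule,
                   build_dictionary, compress, default_grid, match_volume,
                   simulate_fingerprint)

schedule = build_schedule(SequenceConfig())          # 1750 readouts
grid = default_grid(t1_range=(500, 1500), t2_range=(40, 120),
                    t1rho_range=(50, 140))           # 6% steps, 6498 atoms
dictionary = build_dictionary(grid, schedule)
compressed = compress(dictionary, rank=30)

wm = TissueParams(t1=850, t2=70, t1rho=90, pd=0.75)
signal = simulate_fingerprint(schedule, wm).values
maps = match_volume(signal[None, :], compressed, mask=np.ones(1, bool))
print(f"T1 = {maps.t1[0]:.0f} ms, T2 = {maps.t2[0]:.1f} ms, "
      f"T1rho = {maps.t1rho[0]:.1f} ms, PD = {maps.pd[0]:.2f}, "
      f"score = {maps.match_score[0]:.4f}")
```

prints

```
T1 = 845 ms, T2 = 71.6 ms, T1rho = 94.9 ms, PD = 0.74, score = 1.0000
```

i.e. the white-matter tissue (T1 = 850, T2 = 70, T1ρ = 90 ms) is matched to
a grid atom with each parameter within one 6% grid step of the truth, the
proton density recovered as the match amplitude, and a perfect match score
for this noiseless signal.

A complete phantom → acquisition → matching → statistics run:

```bash
mrf end2end --kind brain --shape 32 32 4 --out out/ --seed 3 --shots 2
```

writes NIfTI parameter maps (`out/maps/*.nii`), an ROI table
(`out/roi_stats.csv`) and a provenance record (`out/run.json`).  Library
pipelines for the three bundled studies (multi-shot system phantom, brain
lesion versus contralateral white matter, scan-rescan repeatability) live
in `mrf3d.pipeline`.

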