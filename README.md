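# ultratrack

Landmark tracking in 4D ultrasound via latent representations from a
sliced-Wasserstein autoencoder.

## The problem

Image-guided interventions — ultrasound-guided radiotherapy in particular —
need an anatomical target (say, a vessel branching in the liver) followed
through a stream of 3D ultrasound volumes while the organ translates,
rotates and deforms with breathing. Classical template matching compares
image patches voxel by voxel, which is brittle under elastic deformation
and expensive in 3D. `ultratrack` implements an alternative: compare
patches by the distance between their codes in a learned representation
space.

## The method

An autoencoder maps a 24×24×24 patch `X` to a code `z ∈ R^k`
(k = 8…512, a 96.3–99.9 % data reduction) and back, trained unsupervised
with

```
loss = α·MSE(X, X̂) + β·SW(p_z, p_γ)
```

where `SW(p_z, p_γ)` is the sliced-Wasserstein distance between the latent
batch distribution and a uniform ball ("hyperball") prior — estimated by
projecting both samples onto random 1D directions and sorting. Tracking
then runs per frame as an iterative greedy search on the voxel lattice:
encode all patches in the 12-neighbourhood of the current position, move to
the candidate whose code is closest (L2) to any of four reference codes
captured at distinct breathing phases, repeat until no neighbour improves.
Each frame's search starts from the previous frame's result, exploiting the
slow, continuous character of respiratory motion.

Three training regimes support cross-patient transfer: subject-individual
models, generalized models trained on the pooled patches of the *other*
subjects, and generalized models fine-tuned on a small subject-specific
patch set where only the fully connected layers are updated.

Everything runs on plain CPU: the 3D convolutional autoencoder is
implemented in NumPy with numba-jitted gather/scatter kernels and manual
backpropagation (gradient-checked in the test suite). A synthetic 4D
speckle phantom with known landmark trajectories (breathing translation +
rotation + smooth deformation) makes the full pipeline runnable and
testable without any clinical data. See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
import ultratrack as ut
from ultratrack import swae

# a 20 s breathing phantom: 64^3 voxels at 1 mm, 5 volumes/s
seq, track = ut.generate_sequence(ut.PhantomConfig(seed=7))
split = ut.split_sequence(seq.n_frames)
l1, l2 = ut.annotate_short_term_windows(seq, track, window_s=3.0, every_n=2)

model = ut.train(
    ut.sample_patches(seq, split.training_frames, 1500, seed=1),
    k=32,
    config=ut.TrainingConfig(max_epochs=2, seed=0),
    arch=swae.ArchitectureConfig(half_resolution=True),
)

refs = ut.select_references(l2, seq, model.encode)   # references from the OTHER window
frames = range(int(l1.frame_index[0]), int(l1.frame_index[-1]) + 1)
result = ut.track_sequence(seq, frames, l1.position_vox[0], refs,
                           model.encode, truth=l1)
print(ut.summarize(result, l1).mean_error_mm)
```

Running `python examples/03_track_landmark.py` (this exact pipeline)
prints:

```
reference frames by phase: {'end_inhale': 85, 'end_exhale': 95, 'mid_inhale': 99, 'mid_exhale': 89}
tracked 15 frames, mean error 0.72 +/- 0.60 mm, mean greedy iterations 2.3
```

A mean error below one voxel (1 mm spacing) means the greedy latent-space
search follows the ~13 mm breathing excursion without losing the target;
the four reference frames sit a quarter breathing cycle apart, spanning the
target's deformation range. The other scripts in `examples/` demonstrate
phantom generation, autoencoder training with the two loss components, and
the documented failure mode under a 20 mm single-frame target jump.

The same pipeline is scriptable from the shell:

```bash
ultratrack simulate --subjects 2 --seed 0 --out runs/sim
ultratrack sample-patches --sequence runs/sim/subject00.nii.gz --n 2000 --out runs/t0.npz
ultratrack train --patches runs/t0.npz --k 32 --epochs 2 --out runs/model.npz
ultratrack track --sequence runs/sim/subject00.nii.gz --checkpoint runs/model.npz \
    --references runs/sim/subject00_L2.csv --window runs/sim/subject00_L1.csv --out runs/trk
ultratrack evaluate --tracking runs/trk/tracking.csv --truth runs/sim/subject00_L1.csv \
    --out runs/summary.json
ultratrack sweep --k 8,64 --subjects 2 --out runs/sweep.csv   # regimes x k x subjects
```

Every command writes a JSON run manifest (config, seeds, file hashes) next
to its outputs.

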