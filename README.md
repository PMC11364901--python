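# rotovol

Label-free 3-D tomography of rotating single cells.

A cell trapped in an acoustofluidic chip can be rotated through full
revolutions while an ordinary bright-field camera films it.  `rotovol`
turns such rotation videos into quantitative 3-D morphology: a 3-D
convolutional network, trained against confocal z-stacks, regresses a
volumetric reconstruction directly from ten frames spanning one rotation
period; gray-level co-occurrence (GLCM) texture features of the
reconstructed volumes then feed cell-type classification and drug
time-course scoring.  Because public recordings for this problem are not
available, the package ships a synthetic phantom generator — ellipsoidal
cells with preset-dependent surface texture, rigid rotation rendering, and
confocal-like ground-truth stacks — so every stage is testable offline with
exactly known geometry.

Intended users: microscopy and image-analysis researchers prototyping
rotation-based single-cell tomography, and anyone needing a reference
implementation of the video → volume regression pipeline with its
surrounding morphometric statistics.

## The model

The regression network maps a 100×100×10 input stack (ten ROI-cropped,
resized frames sampled over one rotation period) to a 100×100×10 volume.
Each stage is a 3×3×3, stride-1, zero-padded convolution

    Z_ijk = Σ_{l,m,n} W_lmn · X_(i+l)(j+m)(k+n) + b

followed by an elementwise ReLU `A = max(0, Z)`, with filter counts
64, 32, 16, 8, 4 and a final linear 1×1×1 convolution to one channel.
Training minimizes voxelwise MSE with Adam.  Downstream, volumes are
quantized to 8 gray levels and the symmetric 3-D GLCM (13 unit offsets,
Otsu-masked foreground) yields six texture scalars — contrast, correlation,
energy, homogeneity, dissimilarity, entropy — which drive PCA, a
leave-one-out linear SVM, and coefficient-of-variation / paired-t drug
time-course statistics.  See `docs/methods.md` for formulas, parameter
defaults and design rationale.

## Worked example

```python
import numpy as np
from rotovol import phantom, preprocess, stability, reconstructor, morphometrics

# a rough (macrophage-like) synthetic cell with a nucleolus-like landmark
ph = phantom.make_phantom(seed=3, preset="rough", grid_size=48,
                          radii_um=(9, 12, 10), granule_contrast=1.0)
video = phantom.render_rotation_video(ph, axis="in_plane",
                                      frames_per_rev=60, n_frames=241, seed=0)

series = stability.correlation_series(video)
period = stability.estimate_period(series)
print(f"estimated period: {period:.2f} frames")   # estimated period: 60.26 frames

stack = preprocess.video_to_input_stack(video, period)
print(stack.shape, stack.source_frame_indices[:4])
# (100, 100, 10) (0, 6, 12, 18)

feats = morphometrics.volume_glcm_features(ph.membrane_field)
print(f"contrast={feats.contrast:.2f} entropy={feats.entropy:.2f} "
      f"homogeneity={feats.homogeneity:.2f}")
# contrast=0.74 entropy=2.89 homogeneity=0.77
```

The period estimate recovers the ground-truth 60 frames per revolution to
a quarter frame from the correlation series alone; the input stack samples
exactly one revolution; and the texture scalars separate the presets (the
same cell with the smooth preset scores contrast 0.39, entropy 0.68,
homogeneity 0.95 — lower disorder, higher homogeneity).

A `rotovol` command-line tool wraps the same stages
(`rotovol phantom`, `render`, `preprocess`, `stability`, `train`,
`predict`, `features`, `mesh`, `classify`, `timecourse`); run
`rotovol --help` for details.

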