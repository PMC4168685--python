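# sockeica

ICA-based denoising of 4D fMRI followed by event-related ICA of
FIR-deconvolved peri-event responses.

The pipeline:

1. **spatial ICA** (`sockeica.spatial_ica`) — PCA reduction with an
   explicit order rule, FastICA with tanh contrast and restarts, z-scaled
   spatial maps with time courses and power spectra;
2. **artifact classification** (`sockeica.sock`) — per-component features
   (spatial smoothness / small-cluster fraction, edge-mask fraction,
   CSF-mask fraction, temporal-frequency-noise fraction above 0.08 Hz)
   combined with per-family 2-means clustering and absolute floors to
   label components *artifact* vs *unlikely artifact*;
3. **aggressive regression filtering** (`sockeica.denoise`) — per-voxel
   OLS removal of all variance explained by the rejected component time
   courses;
4. **event-related ICA** (`sockeica.eica`) — FIR deconvolution over a
   ±30 s peri-event window (21 bins at TR = 3 s, no assumed response
   shape, pre-onset bins included), FastICA of the response matrix with
   ICASSO-style stability clustering across restarts, two-Gaussian
   mixture-model z-maps, and uncorrected / BH-FDR thresholding. Group
   analyses temporally concatenate per-subject responses (with optional
   left-right flips) and return common maps with per-subject time
   courses;
5. **phantom generator** (`sockeica.phantom`) — seeded synthetic 4D
   series with event-locked sources (canonical-like, early-onset,
   undershoot-dominant shapes), structured artifacts (edge ring, CSF
   pulsation, near-Nyquist machine noise, spotty voxels, slow drift), and
   smoothed white noise, with full ground truth for every stage.

## Command line

```sh
# generate a phantom dataset
sockeica simulate --out scratch/demo --seed 1 --grid 24,24,12 --n-volumes 200

# run the full pipeline from a YAML config
sockeica pipeline config.yaml

# individual stages
sockeica ica --fmri fmri.nii --mask brain.nii --out ica_out --order fixed:10
sockeica filter --fmri fmri.nii --time-courses ica_out/time_courses.tsv \
    --reject sock_out/rejected_components.txt --out denoised.nii
sockeica eica --fmri denoised.nii --mask brain.nii --events events.txt --out eica_out
```

A minimal config:

```yaml
subjects:
  - fmri: sub01/fmri.nii
    events: sub01/events.txt
    brain_mask: sub01/brain.nii
    csf_mask: sub01/csf.nii
output_dir: out
tr: 3.0
mode: with_sock        # or without_sock (skips the filter stage)
ica_order_rule: variance:0.995
eica_components: 10
```

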