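# dganet

A dual-branch encoder–decoder segmentation toolkit for liver/tumor CT,
implemented entirely in NumPy (including training — the package ships its own
small reverse-mode autodiff engine, so no deep-learning framework is needed).

The network combines:

- a **spectral branch**: an FFT-convolution stem plus Fourier
  spectrum-learning units that run 1×1-conv bottlenecks on the real/imaginary
  parts of the 2-D DFT, followed by multi-scale residual fusion
  (`dganet.fourier_blocks`);
- a **spatial branch**: multi-axis Hadamard-product attention blocks that
  split channels into four groups and normalize element-wise attention maps
  along height–width, channel–height and channel–width planes — no L×L score
  matrix is ever materialized, so cost is linear in pixel count
  (`dganet.maha_attention`);
- a **cross-attention decoder**: per-stage group fusion with layer norm, a
  four-branch dilated-convolution aggregation block (dilations 1, 2, 5, 7)
  and a two-arm multi-head cross-attention fusion block
  (`dganet.gmca_decoder`, wired in `dganet.network_assembly`).

Around the model the package provides the composite cross-entropy + Dice
training loss (`dganet.losses`), a spacing-aware evaluation suite — Dice,
DPC/DG, VOE, RAVD, ASSD, HD95 (`dganet.metrics`), triplicate-run statistics
with paired t-tests (`dganet.replicate_stats`), a synthetic CT-phantom
generator with size-stratified tumors and optional Gaussian noise
(`dganet.synthetic_phantoms`), and a full preprocess/train/predict/evaluate
pipeline with CLI (`dganet.pipeline_cli`).

The shipped default configuration (`src/dganet/default_config.json`) is
calibrated to the published 13.91M-parameter budget (±1%).

## CLI

```sh
# generate 4 synthetic phantom cases
dganet synth --seed 42 --cases 4 --out scratch/data

# train a small model (YAML overrides for the architecture config)
printf 'stage_widths: [8, 8, 8, 8, 8]\nnominal_size: [96, 96]\ntoken_budget: 256\n' > scratch/net.yaml
dganet train --data scratch/data --config scratch/net.yaml --seed 42 --epochs 5 --out scratch/ckpt.npz

# predict and evaluate (optionally under additive Gaussian HU noise)
dganet predict --checkpoint scratch/ckpt.npz --data scratch/data --out scratch/preds
dganet evaluate --checkpoint scratch/ckpt.npz --data scratch/data --out scratch/report.csv
dganet evaluate --checkpoint scratch/ckpt.npz --data scratch/data --out scratch/noisy.csv --noise-sd 10

# percentage-point deltas between two aggregate metric JSON files
dganet ablate --full full.json --variant variant.json
```

Phantom specs and architecture overrides are plain YAML mirroring the
`PhantomSpec` / `NetConfig` dataclass fields; ablation variants are selected
with the `disable_convfft`, `disable_fsmf`, `disable_maha`, `disable_gmca`,
`single_branch` and `gmca_combine` config switches.

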