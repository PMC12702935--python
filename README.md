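# iap-transunet

A tested, CPU-friendly implementation of an attention-and-pyramid-pooling
hybrid CNN–transformer network for 2-D medical-image segmentation, together
with everything needed to train and evaluate it at desk scale: a combined
cross-entropy + Dice objective, Dice/Hausdorff evaluation, a synthetic
multi-organ phantom generator, and a command-line pipeline.

## Who this is for

Researchers and students who want a readable, fully self-contained
reference implementation of this architecture family — one that runs on a
laptop CPU with no datasets to download and no deep-learning framework to
install (the network runs on a small NumPy reverse-mode autodiff engine
shipped in `iap_transunet.nn`) — for studying the architecture, its
structural ablations, and its cost model.

## The model

A U-shaped encoder–decoder in the TransUNet lineage:

- **Hybrid encoder** — a ResNet-50-style CNN pyramid yields skip features
  at 1/2, 1/4 and 1/8 resolution; the 1/16 map is tokenised, positionally
  encoded and passed through a 12-layer transformer encoder
  (`Attention(Q,K,V) = softmax(QKᵀ/√d_k)V`, multi-head, two-layer ReLU
  MLP).
- **ECA** — efficient channel attention `ω = σ(C1D_k(GAP(χ)))` with the
  kernel size chosen adaptively from the channel count,
  `k = |log2(C)/γ + b/γ|_odd` (γ=2, b=1; k=5 at C=256), applied in the
  CNN encoder and after each decoder block.
- **CBAM-ASPP bottleneck** — atrous spatial pyramid pooling at dilation
  rates [1, 2, 4, 8] fused 1×1, refined by CBAM channel and spatial gates
  `M_C = σ(MLP(F_avg) + MLP(F_max))`, `M_S = σ(f⁷ˣ⁷([AvgPool; MaxPool]))`.
- **Separable decoder** — decoder convolutions are depthwise-separable
  (cost `Dk²·M·Df² + M·N·Df²` vs `Dk²·M·N·Df²` standard, ratio
  `1/N + 1/Dk²`), cutting decoder parameters while preserving the exact
  rank-1 convolution semantics.
- **Objective** — `L = (L_CE + L_Dice)/2`; **metrics** — per-class Dice
  coefficient `2|A∩B|/(|A|+|B|)` and symmetric Hausdorff distance between
  boundary point sets.

Three independent build toggles (`use_eca`, `use_cbam_aspp`, `use_dsc`)
span the eight-variant structural ablation grid from the plain baseline to
the full model. See `docs/methods.md` for every design decision and its
rationale.

## Worked example

```sh
# 60 synthetic 64x64 phantoms (background + 3 organs), split 70/10/20
iap-transunet generate --n 60 --out data/phantoms --seed 0

# desk-scale model: width multiplier 0.25, all three refinements on
iap-transunet example-config > run.yaml
iap-transunet train --config run.yaml --data data/phantoms --out runs/demo --epochs 30
iap-transunet evaluate --checkpoint runs/demo/last.npz --data data/phantoms --out runs/demo/eval
```

The train command prints one line per epoch and the evaluation prints the
held-out summary; a run of exactly the commands above produced:

```
epoch 1/30  loss 1.1186
epoch 2/30  loss 0.8123
...
epoch 30/30  loss 0.0876
trained 330 steps; final epoch loss 0.0876; checkpoints in runs/demo
mean foreground DSC 0.8863  mean HD 7.273591244882887  (12 cases)
```

`loss` is the combined (CE + Dice)/2 objective averaged over the epoch.
`DSC` is the mean foreground Dice coefficient over the 12 test phantoms
(1.0 = perfect overlap); `HD` is the mean Hausdorff boundary distance in
pixels (lower is better). More phantoms and more epochs improve both.

Other commands: `predict` writes label-map PNGs, `inspect` prints the
per-layer parameter/MAC table, and `ablate` builds (and optionally
trains) all eight structural variants into a CSV.

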