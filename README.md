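# nbac — narrow-band active-contour segmentation toolkit

Segmentation losses for the two failure modes that dominate medical
imaging: **class imbalance** (background-dominated masks) and **weak
boundaries** (adjacent tissues with heavily overlapping intensity
distributions).  Pixel-wise losses such as cross-entropy, Dice and focal
average over the whole grid, so the abundant easy pixels swamp the gradient
precisely where segmentation is hardest — at the boundary.

The core of the package is the **narrow-band active-contour (NB-AC) loss**:
a Chan–Vese-style region energy restricted to a fixed-width band around the
ground-truth boundary, plus a contour-length term.  For one class with
prediction `p`, contour map `F_LC` and band width `B`,

```
L2 = μ·mean|F_LC| + λ_in·mean_{B_in}(p − b_in)² + λ_out·mean_{B_out}(p − b_out)²
```

where the band `F_ζχy = ζ(χ(y))` is the morphological dilation (ζ, a B×B
window maximum) of the edge map (χ, a fixed gradient-magnitude stencil) of
the ground-truth mask `y`, `B_in`/`B_out` are its inner and outer halves,
and `b_in`/`b_out` are the mean responses of `p` over them.  Ignoring every
pixel outside the band makes the loss an implicit under-sampler, and the
two-sided homogeneity energy supervises exactly the weak-boundary pixels.
The total training loss combines the first-branch region loss L1
(categorical cross-entropy) with L2 as `0.5·L1 + 0.5·L2`.

The package provides, each as plain Python on numpy (a small reverse-mode
autodiff core is included — no deep-learning framework required):

- `nbac.band_operators` — smooth Heaviside, signed distance, edge
  extraction χ, band dilation ζ, ground-truth narrow bands (2D and 3D);
- `nbac.losses` — the NB-AC band loss (three band semantics), region loss,
  CE / Dice / focal baselines, the offset-curve (OsC) loss, and the classic
  Chan–Vese energy as an evaluation-only reference;
- `nbac.networks` — two-branch U-Net (2D/3D) and FCN backbones whose second
  branch produces `F_LC`/`F_LN` through transitional gates;
- `nbac.metrics` — Dice / IoU / precision / recall per class with macro
  averages;
- `nbac.synthdata` — a seeded phantom generator (blobs, nested rings,
  vessels) with controllable class proportions and boundary contrast;
- `nbac.experiment` + a `nbac` CLI — seeded training, evaluation and a
  multi-loss comparison harness;
- `nbac.oracles` — brute-force scalar-loop references used by `nbac audit`
  and the test suite.

## Worked example

Train the two-branch U-Net with the NB-AC loss on weak-boundary phantoms
and evaluate on held-out phantoms:

```python
from nbac.experiment import ExperimentConfig, train
from nbac.networks import BackboneConfig
from nbac.synthdata import PhantomConfig

cfg = ExperimentConfig(
    backbone=BackboneConfig(kind="unet2d", depth=2, base_width=8, num_classes=3),
    loss="nbac",
    steps=150, batch_size=8, seed=0, n_train=64, n_val=16,
    phantom=PhantomConfig(dims=(64, 64), num_classes=3,
                          contrast_gap=0.1, noise_sigma=0.05),
    out_dir="runs/demo",
)
result = train(cfg)
print(result.log[result.log.val_dice.notna()][["step", "region_l1", "band_l2", "val_dice"]])
print("best validation Dice:", round(result.best_val_dice, 4))
```

```
     step  region_l1   band_l2  val_dice
0       0   1.356234  0.663673  0.237140
25     25   0.251563  0.069796  0.753637
50     50   0.113164  0.074412  0.936666
75     75   0.080777  0.067092  0.951957
100   100   0.072355  0.060342  0.952939
125   125   0.065685  0.055730  0.956718
149   149   0.055167  0.047630  0.947033
best validation Dice: 0.9567
```

`region_l1` is the first-branch categorical cross-entropy, `band_l2` the
narrow-band energy of the second branch (both logged every step, here shown
at validation steps), and `val_dice` the foreground macro-Dice on the 16
held-out phantoms: the phantoms' two foreground classes differ in mean
intensity by only 0.1 with noise σ = 0.05, yet the model segments them with
Dice ≈ 0.95 after 150 steps on a CPU.

The same experiment from the shell:

```bash
nbac synth cfg.yaml data/phantoms --n 64    # write a phantom dataset
nbac train cfg.yaml                          # train, log, checkpoint
nbac eval runs/demo/best.npz data/phantoms   # metrics CSV
nbac compare cfg.yaml --losses ce,dice,focal,nbac --seeds 0,1,2
nbac audit                                   # run the brute-force oracle suites
```

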