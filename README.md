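# fretleaf

Cell-type-resolved quantification of a nuclear-localised ratiometric FRET
biosensor for abscisic acid (ABA) in leaf tissue, together with the leaf
morphometrics that surround such an experiment: stomatal aperture and
density from epidermal impressions, and histochemical stain areas (trypan
blue cell death, DAB/H₂O₂, chlorosis) from leaf-disk images.

## Who this is for

Plant cell biologists quantifying hormone dynamics at cellular resolution
with FRET biosensors (e.g. during herbivore infestation or water stress),
and anyone who needs a fully testable, deterministic re-implementation of
the segment → ratio → classify → compare workflow. Because raw confocal
data of this kind is rarely deposited, the package ships a synthetic
phantom generator with exact ground truth, so every stage of the pipeline
is validated end to end without any download.

## The measurement

A confocal z-stack is acquired in three channels: donor-excitation
donor-emission (**DxDm**, 460–500 nm), donor-excitation acceptor-emission
(**DxAm**, 525–560 nm) and acceptor-excitation acceptor-emission
(**AxAm**). The AxAm channel marks total sensor abundance and drives 3D
nucleus segmentation (Gaussian smoothing → global threshold → connected
components → volume filter). For each nucleus *k* the emission ratio

&nbsp;&nbsp;&nbsp;&nbsp;R<sub>k</sub> = (⟨DxAm⟩<sub>k</sub> − b<sub>DxAm</sub>) / (⟨DxDm⟩<sub>k</sub> − b<sub>DxDm</sub>)

is the ratio of background-corrected mean intensities over the nucleus —
a monotone readout of nuclear ABA concentration. Nuclei are then assigned
to one of five leaf cell types (stomata, pavement, spongy mesophyll,
bundle sheath, vascular bundle) by a deterministic cascade over shape and
position features: depth below the shallowest nucleus, equivalent
diameter, second-moment elongation, and local neighbour density (vein
nuclei cluster along the vein axis). Group comparisons use Welch/Student
t tests, two-way factorial ANOVA (type-II SS) with Tukey or Sidak
post-hoc, and Benjamini–Hochberg FDR q-values; nucleus counts per class
double as a cell-viability readout.

## Worked example

```python
import fretleaf as fl

cfg = fl.default_scene_config("infested", seed=42)   # 512x512x40 phantom
truth = fl.generate_leaf_scene(cfg)                  # ground-truth table
stack = fl.render_stack(truth, cfg)                  # DxDm/DxAm/AxAm stack
labels = fl.segment_nuclei(stack)
features = fl.extract_features(labels, stack)
background = fl.estimate_background(stack, labels)
records = fl.add_emission_ratios(features, background)
records, counts = fl.classify_all(records)
print(fl.summarize_ratios(records, by="cell_type"))
```

prints (35 nuclei segmented — this infested scene dropped 5 mesophyll
nuclei, the simulated feeding-damage viability effect):

```
       cell_type  n  mean_ratio  sem_ratio
   bundle_sheath  5      0.7384     0.0164
        pavement 10      0.7083     0.0119
spongy_mesophyll  5      0.7330     0.0153
         stomata 10      0.8858     0.0173
 vascular_bundle  5      0.8633     0.0149
```

Stomatal and vascular-bundle nuclei show the highest emission ratios —
exactly the pattern this infested scene was configured with (baseline
0.60 everywhere, largest deltas in stomata and vasculature). Scoring
against the ground truth (`fl.confusion_matrix(records, truth)`) gives
accuracy 1.000 on this scene.

The full experiment — n images per condition, ratio summaries and deltas
per class, condition × cell-type ANOVA, FDR-corrected per-class ratio and
count comparisons — is one call (`fl.run_pipeline(fl.PipelineConfig(seed=1))`)
or one shell command:

```bash
fretleaf run --seed 1 --out report/
fretleaf simulate scene --condition infested --seed 7 --out scenes/
fretleaf segment --stack scenes/scene_infested_seed7.tif --out seg/
fretleaf stomata --image impression.png --pixel-size 0.7 --out pores/
fretleaf stain --image disk.png --stain trypan_blue --pixel-size 10 --out quant/
```

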