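# marrowdose

Voxel-based red-marrow (RM) dosimetry for ¹⁷⁷Lu radioligand therapy.

Red marrow is the dose-limiting tissue for hematological toxicity in
¹⁷⁷Lu-PSMA-617 therapy of metastatic castrate-resistant prostate cancer.
Because the tracer has no specific marrow uptake but bone metastases
frequently infiltrate the spongiosa, marrow dose estimates differ sharply
depending on whether activity and active marrow are localized.  This
package implements four image-based RM absorbed-dose methods on a common
voxel pipeline, together with synthetic digital phantoms that provide exact
ground truth for every stage:

1. **MIRD** — total spongiosa time-integrated activity (TIA) with a
   skeletal-average self-dose S-value and a phantom/patient mass scaling:

   *D* = Ã · *S*<sub>RM←RM</sub> · *m*<sub>RM,phantom</sub> / *m*<sub>RM</sub>,
   with *S*<sub>RM←RM</sub> = 1.07·10⁻⁵ mGy/(MBq·s),
   *m*<sub>RM,phantom</sub> = ρ<sub>RM</sub> · 1170 mL and
   *m*<sub>RM</sub> = ρ<sub>RM</sub> · *v*<sub>RM</sub> · *f*<sub>RM</sub>
   (*f*<sub>RM</sub> = 0.52).

2. **MIRD_aorta** — a blood surrogate: the aorta TIA concentration mapped to
   marrow with the hematocrit-based red-marrow-to-blood ratio
   RMBLR = 0.19/(1 − HCT), then *D* = [Ã]<sub>RM</sub> · *m*<sub>RM</sub> · *S*<sub>RM←RM</sub>.

3. **MC** — Monte Carlo electron transport over the CT density map with a
   micro-scale three-compartment spongiosa model (trabecular bone / RM /
   yellow marrow).  Whenever an electron enters a spongiosa voxel its
   energy is apportioned through pre-computed electron energy absorption
   fraction (EAF) tables indexed by energy, bone volume fraction
   BVF = (ρ<sub>voxel</sub> − ρ<sub>marrow</sub>)/(ρ<sub>bone</sub> − ρ<sub>marrow</sub>),
   marrow cellularity CF, and electron source class (initial emission,
   boundary crossing, secondary).

4. **MC_SC+PET** — the same engine informed by ⁹⁹ᵐTc-sulfur-colloid SPECT
   (per-voxel RM mass) and ⁶⁸Ga-PSMA PET (tumor voxels, SUV > 3): per-voxel
   (BVF, CF) are jointly inverted from the CT density and the SC-derived RM
   mass, tumor-overlapped voxels use four-compartment EAFs with a 50% tumor
   share and tumor-borne activity, and the ¹⁷⁷Lu TIA map is pre-corrected
   for partial-volume spill between marrow and tumor using the blood-derived
   marrow expectation.

A dose–hematotoxicity statistics layer (relative blood-count change,
Spearman correlation with Bonferroni adjustment, Lin's concordance
correlation coefficient) completes the workflow.

Intended users: medical-physics and nuclear-medicine researchers studying
marrow dosimetry methodology; the synthetic phantoms make every algorithm
testable without patient data.

## Worked example

Run the full synthetic pipeline (phantom → serial-image TAC fits → marrow
model → EAF tables → four dose methods) from Python:

```python
from marrowdose.cli_config import load_config, run_pipeline

cfg = load_config(overrides={
    "seed": 1, "outdir": "demo_run",
    "eaf": {"grid": "tiny", "histories_per_node": 300},
    "dose": {"n_histories": 50_000},
})
manifest = run_pipeline(cfg)
for method, vals in manifest["doses"].items():
    print(f"{method:10s} FOV RM dose = {vals['fov_rm_dose_gy']:.3f} Gy "
          f"({vals['gy_per_gbq']:.4f} Gy/GBq)")
```

which prints (tumor-free default phantom, 7.07 GBq administered):

```
mird       FOV RM dose = 0.012 Gy   (0.0017 Gy/GBq)
mird-aorta FOV RM dose = 0.001 Gy   (0.0001 Gy/GBq)
mc         FOV RM dose = 0.014 Gy   (0.0019 Gy/GBq)
mc-sc-pet  FOV RM dose = 0.010 Gy   (0.0014 Gy/GBq)
```

The three image-based methods agree to within tens of percent on this
tumor-free phantom, while the blood surrogate underestimates them by an
order of magnitude — blood carries only the extracellular-fluid share of
the marrow activity concentration.  The same pipeline is available from the
shell (`marrowdose run --seed 1 --out demo_run`), alongside subcommands
`phantom`, `tia`, `marrow`, `eaf-build`, `dose` and `stats`
(`marrowdose --help`).

Dose maps are written as NIfTI (Gy), reports as CSV/JSON, and every run
produces a manifest with SHA-256 hashes: reruns with the same seed are
bitwise identical.

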