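# mitoscore

Patch-based CNN scoring of mitochondrial fission/fusion morphology in
live-cell fluorescence microscopy fields, with a classical morphometry
baseline, a Monte-Carlo multi-patch ensemble scorer, grouped
cross-validation / ROC evaluation, and a synthetic field simulator that
stands in for unreleased imaging data.

## Who this is for

Cell biologists and image analysts who quantify the mitochondrial
fission–fusion balance from single-channel fluorescence fields
(MitoTracker-type staining): detecting drug-induced hyperfission or
hyperfusion, dose–response profiling, and screening patient-derived cells
for morphology shifts. The package is used from Python (see `examples/`);
a thin `mitoscore` CLI covers the same steps for shell pipelines.

## The method

A field is never classified whole. It is percentile-normalized, its cell
regions segmented, tiled into 112×112 windows at stride 100, and windows
with < 50 % foreground discarded. A residual CNN classifies patches into
hyperfission (CCCP-like), normal (NC) or hyperfusion (FL3-like). The field
score is a Monte-Carlo ensemble: for r = 1…100 rounds, draw k = 4 patches
uniformly from the filtered pool and average their softmax vectors, then
average over rounds —

    score(field) = (1/R) Σ_r (1/k) Σ_{i∈S_r} p_θ(class | patch_i)

yielding the field's CCCP-/FL3-/NC-scores. Participants are scored by the
unweighted mean of their field scores, and group separation is read out by
Mann-Whitney tests and ROC/AUC (threshold-sweep AUC equals Mann-Whitney
pair counting). Cross-validation folds are partitions of acquisition
batches, never of fields. The classical baseline computes form factor
P²/(4πA), moment-ellipse aspect ratio, and skeleton branch/junction
statistics — strong on hyperfission, weak on hyperfusion, which is the gap
the classifier closes.

Because the original imaging data are not public, the package ships a
stochastic-geometry simulator with a single fission–fusion coordinate
φ ∈ [0, 1] (0 = all puncta/rings, 0.5 = mixed tubules, 1 = long
interconnected filaments) that provides ground truth for every claim the
test suite makes. See `docs/methods.md` for the full model.

## Worked example

```sh
python examples/04_train_and_score.py
```

trains the three-class patch classifier on a small synthetic field set and
Monte-Carlo-scores the held-out fields (about two minutes on one CPU):

```
36 training fields, 9 held-out fields
final training accuracy: 0.752
 field_id label  score_CCCP  score_FL3  score_NC
CCCP_0002  CCCP    0.903773   0.002591  0.093636
CCCP_0007  CCCP    0.917914   0.009153  0.072933
CCCP_0012  CCCP    0.952208   0.002857  0.044935
 FL3_0002   FL3    0.000134   0.965711  0.034155
 FL3_0007   FL3    0.000347   0.977252  0.022401
 FL3_0012   FL3    0.001570   0.940842  0.057588
held-out field accuracy: 0.78
```

Each row's three probabilities are the field's CCCP-, FL3- and NC-scores;
the argmax is the predicted morphology class of the whole field. A
CCCP-treated field scoring `score_CCCP ≈ 0.95` is confidently
hyperfissioned; patch-level accuracy is modest at this tiny training size,
but the 100-round multi-patch average still classifies most fields
correctly — the benchmark scale in `scripts/acceptance.py` (30 fields per
condition, 10 epochs) reaches ~0.9 or better. `examples/05_cohort_roc.py`
shows the participant-level readout (fusion-score AUC 1.0 on a small
synthetic cohort).

Other examples: `01_simulate_fields.py` (the generator and its ground
truth), `02_patch_extraction.py` (segmentation/tiling/filtering),
`03_classical_morphometry.py` (the baseline metrics).

## Command line

```sh
mitoscore simulate --out data --seed 0 --n-per-class 30
mitoscore patch --manifest data/manifest.csv --out patches
mitoscore morphometry --manifest data/manifest.csv --out metrics.csv
mitoscore train --task CCCP-FL3-NC --manifest data/manifest.csv --out model
mitoscore score --model model --manifest data/manifest.csv --out scores.csv
mitoscore run --config run.yaml --out rundir     # the whole pipeline
```

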