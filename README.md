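# wsirisk

Patch-based whole-slide image risk classification, end to end:

- **synthetic slides** — procedural pseudo-WSIs with four distinguishable
  tissue textures (`punlmp`, `low_grade`, `high_grade`, `invasive`), white
  background, optional marker-ink stripes, ASAP-style box annotations, and a
  risk truth label (high risk iff the high-grade + invasive share of tissue
  area is ≥ 5%), plus linked survival cohorts with group-dependent hazards;
- **tiling** — tissue/marker masking, 224-px sliding-window extraction with
  1/3 overlap (stride 149), per-channel color normalization, seeded
  augmentation;
- **patch classifiers** — four one-vs-rest CNNs (NumPy backbone, no GPU or
  torch needed) with class-balanced weighted sampling, cross-entropy, and an
  exponential lr schedule (0.005 × 0.9^epoch);
- **slide inference** — per-patch fusion of the four binary outputs (one-hot
  resolves, anything else is eliminated), per-slide ratio vectors, and an
  RBF-kernel Gaussian-process classifier giving the low/high-risk call;
- **survival** — Kaplan–Meier curves, two-group log-rank test, and univariate
  Cox proportional-hazards fits (Breslow ties, Newton iteration, Wald CIs);
- **evaluation** — per-class and support-weighted precision/recall/F1 with
  percentile-bootstrap confidence intervals (10 000 iterations by default).

## Test

```sh
python -m pytest tests/
```

The suite includes unit tests per module, property tests (hypothesis), and
`tests/test_acceptance.py` with one test per acceptance criterion; the
end-to-end criterion trains the full pipeline on 90 synthetic slides and
takes a few minutes on one CPU.

## CLI

```sh
wsirisk simulate --out data --n-train 60 --n-test 30 --size 1024 --seed 7
wsirisk run-all --data data --out results --seed 7 --epochs 10
# or stage by stage:
wsirisk tile --image data/slides/train_0000.png --out patches
wsirisk train --data data --out models --epochs 10
wsirisk infer --data data --models models --out results
wsirisk evaluate --predictions results/predictions.csv --out metrics.json
wsirisk survival --patients results/patient_predictions.csv \
    --survival-csv data/survival.csv --out survival.json
```

`run-all` writes `predictions.csv`, `patient_predictions.csv`,
`metrics.json`, `survival.json`, Kaplan–Meier tables, model checkpoints, and
a `run_manifest.json` (config hash + seed + versions). Reruns with the same
config and seed reproduce `predictions.csv` bit for bit.

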