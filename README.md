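# roacnn

Remora-swarm hyperparameter optimization of a small convolutional classifier
for 4-class grayscale CT-like images, with the full supporting pipeline:

- **`roacnn.roa`** — a general bound-constrained remora swarm minimizer
  (whale-style spiral exploitation, sailfish-style elite-following
  exploration, experience-attack host switching, inertia-damped host
  feeding).
- **`roacnn.preprocess`** — salt-and-pepper impulse removal by conditional
  neighbourhood mean, and tile-based adaptive histogram equalization with
  bilinear blending.
- **`roacnn.features`** — the 14-value feature vector per image: 4 Haar
  sub-band means, 5 co-occurrence (Haralick-style) texture features,
  5 first-order histogram statistics.
- **`roacnn.cnn`** — a genome-driven numpy CNN: a 3-value structure genome
  (conv/pool/FC layer counts) and an 8-value shared layer genome decode into
  a runnable network trained by mini-batch gradient descent.
- **`roacnn.search`** — the two-phase search: a 5-agent swarm over the
  structure genome, then a 10-agent swarm over the layer genome (11
  hyperparameters total), with negated validation accuracy as fitness.
- **`roacnn.metrics`** — confusion matrix and macro-averaged accuracy /
  precision / recall / sensitivity / specificity / F-measure.
- **`roacnn.synthetic`** — seeded 4-class phantom generator (lung-like
  low-frequency background plus class-specific elliptical blobs) so the
  whole pipeline is testable offline.
- **`roacnn.cli`** — the `roacnn` command-line front end.

## CLI

Each stage is a subcommand; `run` chains them end to end:

```sh
roacnn run --seed 1 --out results/run1           # synthesize -> preprocess -> features -> search -> metrics
roacnn simulate --seed 1 --out data/images       # phantoms only
roacnn preprocess --input data/images --out data/clean
roacnn features --input data/clean --out data/features.csv
roacnn search --input data/features.csv --out results/search.json
roacnn evaluate --input data/features.csv --genomes results/search.json --out results/metrics.json
```

Defaults can be overridden with `--config config.yaml` (flat keys, see
`roacnn.cli.DEFAULTS`); every artifact embeds the config hash and seed, and
reruns with the same config and seed are bit-identical.

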