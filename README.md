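# angioseg

Hybrid GA–FCM seeded region growing for segmenting dark target regions
(e.g. the foveal avascular zone or hypofluorescent lesions) in grayscale
retinal angiography images, together with an eight-metric evaluation
suite and a synthetic phantom generator for fully reproducible testing.

## Method overview

1. **Fuzzy C-means** clusters the image intensities (default K=6,
   fuzzifier 2) and the clusters are grouped into three tiers
   (dark / mid / bright) forming a tri-class reference decomposition.
2. A **genetic algorithm** (population 20, mutation rate 0.2, elitist)
   searches over seed-point sets; each candidate is scored by growing
   regions from its seeds and measuring the squared mismatch between the
   grown tier images and the reference tiers.
3. **Seeded region growing** expands each seed over the 8-connected
   lattice, accepting a frontier pixel when it lies strictly inside
   `mu ± X*sigma` (and/or `mu ± X` gray levels) of the region's running
   statistics, which are updated online with a numerically stable
   mean/variance recurrence.
4. The final mask is the union of grown regions whose mean intensity
   falls in the target tier (dark by default).

Evaluation reports sensitivity, specificity, precision, FPR, accuracy,
Dice, VOE and RVD. Note that `fpr` uses the formula `FP/(FP+FN)` for
fidelity with the method's source definition; the conventional
`FP/(FP+TN)` is reported alongside as `fpr_conventional`.

## CLI

```sh
# generate synthetic phantoms (image + exact ground-truth mask + manifest)
angioseg phantom --out-dir phantoms --count 5 --seed 1

# segment an image (writes mask.png, labels.png, cost_history.csv, run_log.txt)
angioseg segment --image phantoms/phantom_000.png --out-dir out --seed 1

# evaluate a predicted mask against ground truth (eight-metric CSV row)
angioseg evaluate --pred out/mask.png --truth phantoms/phantom_000_mask.png --out report.csv

# GA seeding vs a manual seed, side by side
angioseg compare --image phantoms/phantom_000.png \
    --truth phantoms/phantom_000_mask.png --manual-seed 5,5 --out-dir cmp
```

All flags can also be given in a flat YAML config file (`--config`),
keys mirroring the flags 1:1 (`clusters`, `population`, `mutation_rate`,
`generations`, `x_sd`, `x_mean`, `criterion`, `target_tier`, `seed`,
...). Unknown keys are rejected with exit code 2. Every stochastic
stage takes an explicit seed; defaults are fixed constants.

## Layout

- `src/angioseg/image_io.py` — image/mask/config/report I/O
- `src/angioseg/fcm.py` — fuzzy C-means on intensities
- `src/angioseg/region_growing.py` — online stats, criteria, BFS growth
- `src/angioseg/genetic_optimizer.py` — chromosomes, cost, GA loop
- `src/angioseg/pipeline.py` — end-to-end segmentation
- `src/angioseg/metrics.py` — confusion-matrix rates and overlap metrics
- `src/angioseg/phantom.py` — synthetic angiography phantoms
- `src/angioseg/cli.py` — `angioseg` command-line front end
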