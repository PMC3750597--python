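#!/bin/sh
# End-to-end shell pipeline: simulate -> inject -> fit -> evaluate -> compare.
# Writes everything under ./scratch/cli_demo.
set -e

DEMO=scratch/cli_demo
mkdir -p "$DEMO"

cat > "$DEMO/sim.cfg" <<EOF
n_channels=16
n_trials_per_class=20
class_variance_ratio=2
snr=2
n_background_sources=8
mixing_seed=1
noise_seed=2
EOF

robustcsp simulate --config "$DEMO/sim.cfg" --out "$DEMO/clean"
robustcsp inject --in "$DEMO/clean" --rate 0.05 --seed 3 --out "$DEMO/noisy"
robustcsp fit --in "$DEMO/noisy" --method csp_l1svd --pairs 3 --out "$DEMO/filters.json"
robustcsp evaluate --in "$DEMO/clean" --methods csp_l2,csp_l1svd \
    --rates 0.0,0.05 --reps 5 --folds 5 --seed 4 --out "$DEMO/results.tsv"
robustcsp compare --results "$DEMO/results.tsv" \
    --pairs csp_l1svd:csp_l2 --out "$DEMO/mcnemar.json"

echo "Artifacts in $DEMO: results.tsv (per-repetition accuracies)," \
     "mcnemar.json (paired significance tests), filters.json (spatial filters)."
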