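# burstdict

Unsupervised burst-dictionary learning and temporal marked point process
(TMPP) encoding for single-channel electrophysiology (ECoG/EEG/LFP).

## The problem

Rhythm-specific oscillatory bursts — high-gamma micro-events, sleep
spindles, ripples — ride on a featureless, approximately Gaussian background.
Conventional time–frequency analysis blurs their timing behind window-length
trade-offs. `burstdict` instead treats a band-limited trace ỹ(t) as a
two-regime process: background noise z(t) ~ N(μ_Z, σ_Z) when the local
network rests, and a sparse sum of prototypical waveforms when it is active:

    y(t) = Σ_ω Σ_i  α_i^ω · d_ω(t − τ_i^ω)  +  ε(t)

where D = {d_1 … d_K} is a *dictionary* of unit-ℓ2-norm atoms of
heterogeneous durations, and each event is a point of a temporal marked
point process with timing τ (resolution = one sample period, 2 ms at
500 Hz), weight α, and atom index ω.  Both the dictionary (including K and
the atom durations) and the TMPP are learned from data:

1. **Detection** — every M-sample snippet of the filtered trace is mapped to
   its ℓ2-norm (β_M space).  Under the Gaussian background β_M is
   chi-distributed with M degrees of freedom; snippets whose norm exceeds
   γ = μ_ZM + γ′·σ_ZM are candidate micro-events (columns of X).
2. **Dictionary learning** — X is compressed by a greedy
   minimum-description-length clustering: create a cluster from a motif
   pair, add a snippet to a cluster, or merge clusters, always applying the
   operation that saves the most bits.  K emerges from the compression;
   durations drift freely off the initial grid Δ.
3. **Encoding** — each selected snippet gets the atom with the highest
   normalized cross-correlation; the best lag gives τ, the inner product
   with the unit-norm atom gives α.
4. **Evaluation** — per-trial features (event rate, log inter-burst
   intervals, mean τ, mean log α²) enter one-way MANOVA with sequential
   dimensionality tests, silhouette scores, and a label-shuffle
   randomization test; detection quality is scored sample-wise (TPR/FPR)
   against ground-truth spans.

A fully ground-truth-annotated simulator generates burst-laden ensembles so
every stage is testable without any recording.

## Worked example

The command-line pipeline on a synthetic four-class ensemble (burst rate
depends on the class, as in a movement-direction task):

```bash
cat > config.json <<'EOF'
{"M": 50, "delta_grid_ms": [80, 100], "n_permutations": 200, "seed": 7}
EOF
burstdict simulate  --config config.json --out data --n-trials 20 --trial-len-s 2.5
burstdict learn     --config config.json --input data --out dictionary.json
burstdict encode    --config config.json --input data --dictionary dictionary.json --out events.csv
burstdict features  --config config.json --input data --events events.csv --out features.csv
burstdict discriminate --config config.json --features features.csv --out report.json --n-perm 200
```

prints

```
wrote 80 trials to data/traces.csv
learned K=2 atoms from 534 snippets (gamma=7.822); wrote dictionary.json
encoded 534 events; wrote events.csv
wrote 5 feature columns to features.csv
wrote report to report.json
```

The simulator planted two atoms (80 ms @ 115 Hz, 100 ms @ 100 Hz) and the
MDL clustering recovered exactly K = 2 from the 534 selected snippets, with
the detection threshold γ ≈ 7.8 fitted from the background mode of the
snippet norms.  `report.json` then summarizes discriminability per feature
family (p-value of the highest-dimension MANOVA null, mean silhouette):

```
rate       p(highest dim): 1.54e-05   mean silhouette: -0.124
ibi        p(highest dim): 0.000704   mean silhouette: -0.131
tau        p(highest dim): 0.829      mean silhouette: -0.163
tau_alpha  p(highest dim): 0.667      mean silhouette: -0.079
power      p(highest dim): 2.83e-12   mean silhouette: -0.017
```

Burst *rate* separates the classes decisively while raw timing (τ) alone
does not — the hallmark result of the TMPP representation.  (Power also
separates here because the simulation modulates only the rate, which scales
band power directly.)

The same stages are available as library calls (`burstdict.synthesize`,
`build_snippet_index`, `embed`, `fit_background`, `select_snippets`,
`learn_dictionary`, `encode`, `one_way_manova`, …); see `docs/methods.md`
for the model, the bit-accounting, every tunable parameter, and known
limitations.

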