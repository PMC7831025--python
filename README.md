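# patchprint

Cell-type fingerprinting of mitoBK channels from single-channel
patch-clamp recordings.

Large-conductance Ca²⁺- and voltage-activated potassium channels of the
inner mitochondrial membrane (mitoBK, ~300 pS) are co-assembled with
tissue-specific auxiliary β subunits, and the resulting differences in
gating kinetics leave a signature in the raw current trace.  `patchprint`
implements a complete, tested pipeline that recognizes the cell type of
origin (endothelium, fibroblast or hippocampal neuron) from short excerpts
of single-channel current recordings, without any prior kinetic modelling
of the data:

1. **Anomaly rejection** — per (cell type, potential) category, a symmetric
   sigmoid autoencoder (widths 200–100–50–2, mirrored decoder) is trained to
   reconstruct all preprocessed windows; recordings whose mean reconstruction
   error `J = (1/N) Σᵢ ‖x′ᵢ − xᵢ‖²` clearly stands out (robust z-score > 3.5)
   are removed.
2. **Preprocessing** — recordings are truncated to the shortest length,
   cut into windows of *l* = 1000 points at stride *r* = 200 (exactly
   ⌊(L−l)/r⌋ windows each), compressed to *w* = 200 points by Piecewise
   Aggregate Approximation (equal-frame means), and min–max scaled to [0, 1].
3. **Classification** — K-nearest neighbors (K = 5, Euclidean metric
   `d(x, y) = √Σⱼ(xⱼ−yⱼ)²`) on the 200-dimensional samples, cross-validated
   by holding out one recording per class in every round; per-fold confusion
   matrices are summed and `Acc = 100 · tr(C)/ΣC` reported per pipette
   potential ∈ {−60, −40, −20, +20, +40, +60} mV.
4. **Latent geometry** — test samples are compressed to the 2-D bottleneck
   of an autoencoder, clustered with K-means (K = 3), clusters are mapped
   to their majority class, and the pairwise Euclidean centroid distances
   (Dist FH, Dist FE, Dist HE) quantify class separation per potential.

Because real mitoBK recordings are not publicly deposited, the package
ships a first-class synthetic-data generator: exact (Gillespie)
continuous-time Markov gating with tissue-specific two-state kinetics,
Boltzmann voltage dependence `p_op(U) = 1/(1 + exp(−(U−V½)/s))`, 300 pS
open-channel amplitude, Gaussian instrument noise, optional 1 kHz one-pole
low-pass filtering, and planted anomalous recordings for validating the
outlier-rejection stage.  Classical kinetic analysis is included as well:
threshold current from the intersection of two power-law fits to the
Epanechnikov-kernel log–log amplitude density, open probability `p_op`,
and sigmoidal activation-curve fitting.

## Worked example

```bash
# simulate 3 cell types x 3 recordings x 6 potentials (20k points each)
cat > sim.json <<'JSON'
{"profiles": "well_separated", "n_points": 20000,
 "anomaly": {"cell_label": "hippocampus", "potential_mV": 40.0}}
JSON
patchprint simulate --config sim.json --out demo/ --seed 1
patchprint validate-manifest demo/manifest.json
patchprint classify --manifest demo/manifest.json --potential 40 \
    --no-anomaly-detection --out result.json
```

prints

```
potential_mV  -60.0  -40.0  -20.0   20.0   40.0   60.0
cell_label
endothelium       3      3      3      3      3      3
fibroblast        3      3      3      3      3      3
hippocampus       3      3      3      3      4      3
ok: 55 recordings
accuracy: 86.26% -> result.json
```

The extra hippocampal recording at +40 mV is the planted anomaly (a
shifted-p_op, slowed-gating variant); `result.json` carries per-fold and
overall confusion matrices.  Re-running `classify` without
`--no-anomaly-detection` trains a per-category autoencoder, flags that
recording (its mean reconstruction error is ~3x the category median),
removes it, and prints `accuracy: 93.33%`.  At the full experimental trace
length (2×10⁵ points per recording, the generator default) the same
contrast is 87.2% → 95.7%.  `patchprint run` executes the whole experiment
and writes a per-potential table (accuracy with and without anomaly
detection plus the three centroid-distance columns).

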