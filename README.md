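# songgrammar

Grammatical analysis of animal song as a reusable pipeline:

1. **Acoustic front-end** — detect song regions in mono WAV recordings by
   the ratio of song-band (500–1500 Hz) to total-band energy, locate
   syllable-like peaks on a six-band Hilbert wideband envelope, extract one
   13-coefficient MFCC vector per peak, and group the vectors into strings
   by region.
2. **Grammar induction** — fit an HDP-PCFG (variable root, Gaussian
   emissions conditioned on latent terminals) and an HDP-HMM baseline to
   those strings by truncated mean-field coordinate-ascent variational
   inference with multi-restart best-ELBO selection.
3. **Posterior diagnostics** — expected counts of left-branching,
   right-branching and non-regular parses (totals, Bayes-optimal, uniform
   baseline), per-point posterior predictive densities, and expected
   rule-type counts under step/tanh activations, comparing the grammar's
   compactness and predictive power against the regular (HMM) baseline.

Because no recordings ship with the package, the `synth` module generates
every input with known ground truth: corpora from explicit right-/left-
branching, centre-embedding (matched aᵐbᵐ pairs, depth ≤ 3), random PCFG
and HMM generators with Gaussian emissions, plus pulse-train audio for
front-end tests.

## CLI

```bash
# WAV -> feature strings (JSON Lines; one record per string)
songgrammar preprocess --in song.wav --config cfg.yaml --out strings.jsonl

# synthetic corpus with known ground truth
songgrammar simulate --kind center_embedding --n 500 --seed 7 --out synth.jsonl

# variational fits (multi-restart; state saved as an .npz archive)
songgrammar train-pcfg --strings strings.jsonl --restarts 10 --seed 0 --out pcfg_state.npz
songgrammar train-hmm  --strings strings.jsonl --restarts 10 --seed 0 --out hmm_state.npz

# parse-count / predictive / rule-count reports (JSON + CSV)
songgrammar evaluate --pcfg pcfg_state.npz --hmm hmm_state.npz \
    --strings strings.jsonl --out report/

# everything from one experiment file (deterministic given config + seed)
songgrammar run --config experiment.yaml --out results/
```

Every constant of the preprocessing and inference recipe (band edges, the
0.6 ratio threshold, 500 ms region minimum, 300 ms peak search window,
1.0 prominence, 150 ms refractory, 100 ms MFCC window, 13 coefficients,
concentration 1 priors, truncations 40/100/100, 500 restarts, tolerance
0.1, 300 iterations) is a config default and can be overridden in the YAML
experiment file; tests and examples use desk-scale truncations.

## Package layout

| module | role |
| --- | --- |
| `songgrammar.frontend` | band-energy ratio, song regions, wideband envelope, peak detection, MFCCs, string assembly |
| `songgrammar.grammar` | parse trees, branching taxonomy, Catalan counting, inside/Viterbi charts, enumeration oracles |
| `songgrammar.pcfg` | HDP-PCFG generation and CAVI (inside–outside E step, conjugate M step, stick ascent, predictive) |
| `songgrammar.hmm` | HDP-HMM baseline (forward–backward CAVI) and its right-branching PCFG compilation |
| `songgrammar.stats` | parse-count, predictive and rule-compactness reports |
| `songgrammar.synth` | ground-truth grammars and pulse-train audio |
| `songgrammar.cli` / `config` | subcommands, YAML experiment schema, orchestration |
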