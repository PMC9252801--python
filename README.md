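# protloc

Multi-label prediction of protein subcellular localization and sorting-signal
types from sequence, with an interpretable attention layer that points at the
residues responsible for the prediction.

## The problem and the model

Many proteins reside in more than one cellular compartment, and the routing
decision is usually encoded in short contiguous sequence elements (sorting
signals): N-terminal signal and transit peptides, internal nuclear
localization/export signals, C-terminal peroxisomal and GPI-anchor signals.
`protloc` treats localization as a multi-label classification problem over
ten compartments (Cytoplasm, Nucleus, Extracellular, Cell membrane,
Mitochondrion, Plastid, Endoplasmic reticulum, Lysosome/Vacuole, Golgi
apparatus, Peroxisome) and signal detection as a second multi-label problem
over nine signal types (SP, TM, MT, CH, TH, NLS, NES, PTS, GPI).

The model pipeline is:

1. **Per-residue embedding** `H ∈ R^{L×d}` from one of three interchangeable
   providers: one-hot, a small trainable convolutional encoder, or
   precomputed matrices (e.g. from a protein language model).
2. **Attention pooling**: raw scores `s_t = v·h_t` with a learnable vector
   `v`; a 5-tap Gaussian smoothing (σ = 2 positions, so the support is
   clipped at one standard deviation) encodes the prior that signals are
   contiguous; softmax gives weights `a` with `Σ a_t = 1`; the sequence
   representation is `z = Σ_t a_t h_t`.
3. **Two MLP heads** with per-label sigmoid outputs: 10 localization labels
   and 9 signal types. Training is sequential: the localization head (plus
   `v` and the encoder) is trained first with a weighted focal loss
   `FL_c = −α_c (1−p_t)^γ log p_t` plus an attention-supervision term
   `KL(q‖a)` (`q` uniform over annotated signal residues); the signal head
   is then trained with everything else frozen.
4. **Decision rule**: a per-label threshold `τ_c` maximizing the Matthews
   correlation coefficient on training data; a label is on when
   `p_c ≥ τ_c`, and if no label crosses, the label closest to its threshold
   is chosen, so the predicted set is never empty.

Supporting machinery includes corpus curation filters (eukaryotic,
non-fragment, nucleus-encoded, >40 aa, experimentally evidenced terms mapped
into the class vocabulary), homology-aware cross-validation (no two folds
share a pair above 30% Needleman–Wunsch global identity), the full
multi-label metric suite, and a synthetic planted-signal generator that
makes the whole pipeline trainable and testable at desk scale.

## Worked example

```python
import numpy as np
from protloc import synthetic
from protloc.benchmark import run_desk_experiment

result = run_desk_experiment(seed=1, n=2000)
print(f"held-out localization macro-F1: {result['loc_macro_f1']:.3f}")
print(f"held-out signal-type macro-F1:  {result['sig_macro_f1']:.3f}")
print(f"attention mass enriched >3x in planted regions: "
      f"{result['attention_enriched_fraction']:.3f}")
print(f"KL(signal||attention) {result['kl_attention_mean']:.3f} "
      f"vs uniform baseline {result['kl_uniform_mean']:.3f}")
```

prints (seed 1):

```
held-out localization macro-F1: 0.972
held-out signal-type macro-F1:  0.990
attention mass enriched >3x in planted regions: 0.963
KL(signal||attention) 0.169 vs uniform baseline 2.108
```

That is: on a 2000-protein synthetic corpus whose labels are driven by
planted signal motifs, the trained model recovers held-out localization and
signal-type label sets almost perfectly, and its attention concentrates
inside the planted signal regions (mass more than 3× the region's length
fraction on 96% of signal-bearing held-out proteins; the mean KL divergence
from the planted-signal distribution is an order of magnitude below the
uniform-attention baseline).

The same workflows are available from the shell:

```bash
protloc generate --n 500 --seed 1 --preset desk --out-dir data/
protloc partition --fasta data/sequences.fasta --out-dir data/
protloc train --fasta data/sequences.fasta --annotations data/annotations.csv \
              --folds-csv data/folds.csv --out-dir model/
protloc predict --fasta data/sequences.fasta --model model/model.npz \
                --attention --out-dir out/
protloc evaluate --fasta data/sequences.fasta --annotations data/annotations.csv \
                 --model model/model.npz --out out/metrics.json
```

`predict` writes a summary CSV (one row per sequence: decided labels and all
per-label scores) and, with `--attention`, a long-format per-residue
attention CSV.

## Annotation table dialect

Annotation tables are comma-delimited with semicolon-separated lists:
column `localization` holds labels (`Nucleus;Cytoplasm`), column `signals`
holds 1-based closed intervals (`SP:1-22;TM:30-48`). See
`docs/methods.md` for coordinate conventions, model details, and known
limitations.
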