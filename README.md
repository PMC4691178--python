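# nucfuse

Predicting where a protein resides **within the cell nucleus** (nucleolus,
chromatin, nuclear speckle, nuclear pore complex, ...) from its sequence is
a standard multi-class problem in protein bioinformatics: mislocalized
nuclear proteins are implicated in genetic disease, and wet-lab
localization is slow and expensive. `nucfuse` is a library + command-line
tool for building and evaluating such predictors from **fused sequence /
evolutionary-profile representations**.

## The method

Each protein is encoded three ways:

* **DipC** (420D) — 20 residue frequencies `aa_i / L` plus 400
  ordered-dipeptide frequencies `cr_i / (L−1)`;
* **PseAAC** (20+2λ D, λ = 10 → 40D) — residue frequencies plus λ tiers of
  sequence-order correlation factors built from standardized
  hydrophobicity/hydrophilicity scales, all sharing one normalizing
  denominator;
* **compressed PSSM** (210D) — from an L×20 position-specific scoring
  matrix `P` (e.g. PSI-BLAST output), the lower triangle of the symmetric
  20×20 matrix `M = PᵀP`, which is independent of sequence length.

A composition-type block `A` (DipC or PseAAC) is fused with the PSSM block
`B` per sub-nuclear location `i` using a **balance factor** `r_i ∈ (0,1)`:

```
V_i = [ r_i · A_i , (1 − r_i) · B_i ]        (DipPSSM: 630D, PseAAPSSM: 250D)
```

The balance vector `R = (r_1 … r_n)` is optimized by a **greedy-initialized
real-coded genetic algorithm** minimizing cross-validated prediction error:
50 restarts of a coordinate scan over the grid 0, 0.01, …, 1 (starting from
r = 0.5) seed the GA population, followed by tournament selection,
arithmetic crossover, Gaussian mutation and elitist replacement. The fused
vectors are optionally projected to at most C−1 dimensions by **linear
discriminant analysis** (generalized eigenproblem `S_B w = λ S_W w`, with a
small ridge on `S_W` for the high-dimensional case) and classified with a
**cosine-similarity KNN**. Evaluation reports per-location SE, SP, ACC, MCC
and the overall success rate `Σ T(i) / Σ N(i)` under repeated stratified
K-fold cross-validation or the jackknife.

A synthetic-data module generates labeled sequence + PSSM datasets with a
controllable per-class split of discriminative signal between the
composition and PSSM blocks, so the whole pipeline — including
balance-factor search — is testable without external databases.

## Worked example

```python
import numpy as np
from nucfuse import (SyntheticSpec, generate, encode_all, cross_validate,
                     CosineKNN, BalancedFusionKNN)

ds = generate(SyntheticSpec(n_classes=3, per_class=15,
                            composition_concentration=0.5,
                            pssm_profile_shift=0.8, pssm_noise_sd=2.0,
                            seed=5))
ids = ds.ids()
A = np.vstack([encode_all(ds, "dipc")[i] for i in ids])   # (45, 420)
B = np.vstack([encode_all(ds, "pssm")[i] for i in ids])   # (45, 210)
X = np.hstack([A, B])
y = ds.y()

for name, M in [("DipC", A), ("PSSM", B)]:
    rep = cross_validate(CosineKNN(), M, y, K=5, repeats=5,
                         k_grid=range(1, 11), seed=0)
    print(f"{name:8s} overall success rate {rep.overall_success_rate:.4f}")

fused = cross_validate(BalancedFusionKNN(split=420), X, y, K=5, repeats=5,
                       k_grid=range(1, 11), seed=0)
print(f"DipPSSM  overall success rate {fused.overall_success_rate:.4f}")
```

prints

```
DipC     overall success rate 0.4978
PSSM     overall success rate 1.0000
DipPSSM  overall success rate 1.0000
```

i.e. on this draw the composition block alone is weakly informative
(~50 % of 45 proteins correctly located, best k chosen from 1–10), the
evolutionary block separates the classes, and the fused representation
matches the stronger block. Adding the discriminant projection
(`BalancedFusionKNN(split=420, use_lda=True)`) gives per-location metrics
such as

```
           SE      SP     ACC     MCC
class
1      1.0000  0.9467  0.9644  0.9253
2      0.8533  1.0000  0.9511  0.8917
3      1.0000  0.9800  0.9867  0.9712
```

where SE is the per-location success rate, SP the rate of correctly
rejected non-members, and MCC the confusion-matrix correlation (1 =
perfect, 0 = random).

The same workflow is available from the shell:

```bash
nucfuse simulate --classes 3 --per-class 10 --seed 42 --out demo/
nucfuse optimize --fasta demo/sequences.fasta --pssm-dir demo/pssm \
    --labels demo/labels.tsv --out-r demo/R.tsv --seed 42
nucfuse evaluate --fasta demo/sequences.fasta --pssm-dir demo/pssm \
    --labels demo/labels.tsv --representation dippssm --r-file demo/R.tsv \
    --lda --out demo/run --seed 42
```

`evaluate` writes `metrics.tsv` (per-location SE/SP/ACC/MCC + overall) and
a `manifest.json` sufficient to reproduce the run bit-identically. Real
data enter through FASTA, PSI-BLAST ASCII PSSM files (`--dialect
psiblast-ascii`) and a two-column id → location TSV.

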