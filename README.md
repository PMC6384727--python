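# dsite

Ensemble SVM prediction of dihydrouridine (D) modification sites in RNA.

Dihydrouridine is one of the most abundant post-transcriptional tRNA
modifications: a saturated, non-aromatic uridine derivative that cannot
stack, locally destabilizes structure, and concentrates in the flexible
D-loop. Because experimental mapping of D sites is slow and expensive,
`dsite` predicts, for a uridine of interest, whether it is a D site — from a
41-nt sequence window centered on that uridine.

## Method

A candidate is a window `s = n₋₂₀ … n₋₁ U n₊₁ … n₊₂₀` (length 41, center
uridine). Three heterogeneous feature encodings each feed an RBF-kernel SVM
with probability output, and the final call is the majority vote of the
three base predictors:

* **NPCP** (123 dims): each base is a 3-bit chemical-property code
  (ring count, H-bond strength, amino/keto): A=(1,1,1), C=(0,0,1),
  G=(1,0,0), U=(0,1,0).
* **PseDNC** (16+λ dims): pseudo dinucleotide composition
  `d_u = f_u / (Σf + wΣθ)` for the 16 dinucleotide frequencies, followed by
  λ tiers `d_{16+j} = wθ_j / (Σf + wΣθ)`, where
  `θ_j = mean_i C(D_i, D_{i+j})` and the coupling factor
  `C(D, D′) = (1/μ) Σ_g (P_g(D) − P_g(D′))²` compares μ=3 standardized
  thermodynamic properties (enthalpy, entropy, free energy) of the
  dinucleotide steps. Defaults `w = 0.5`, `λ = 4` → 20 dims.
* **SSC** (32 dims): the window is folded (ViennaRNA, or a builtin
  maximum-pairing folder), brackets are collapsed (`)` → `(`), and every
  overlapping trinucleotide contributes a mode = (first nucleotide ×
  3-character paired/unpaired status): 4 × 8 = 32 mode frequencies.

A base predictor calls a window positive when its probability exceeds 0.5;
the ensemble returns the class supported by at least 2 of the 3 votes.
Hyperparameters are grid-searched over C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and
γ ∈ {2⁻¹⁵, …, 2⁻⁵}. Evaluation is jackknife (leave-one-out)
cross-validation with sensitivity, specificity, accuracy and the Matthews
correlation coefficient.

## Worked example

Generate a separable synthetic benchmark, evaluate it by jackknife, then
train a model and predict:

```sh
dsite synth --n-pos 30 --n-neg 30 --separability 1.0 --seed 7 \
      --fasta-out bench.fa --labels-out bench.tsv
dsite jackknife --fasta bench.fa --labels bench.tsv \
      --out report.tsv --seed 7
```

which prints:

```
jackknife (paper-parity) on 60 windows:
  Sn = 86.67%  Sp = 86.67%  Acc = 86.67%  MCC = 0.73
report written to report.tsv
```

Sn is the fraction of true D-site windows recovered, Sp the fraction of
non-site windows correctly rejected, Acc their prevalence-weighted mean, and
MCC the chance-corrected correlation between calls and truth (0 = chance,
1 = perfect). `report.tsv` holds one row per window with the three base
probabilities, votes and the final call, followed by a summary block.

```sh
dsite train --fasta bench.fa --labels bench.tsv --model-out model.joblib --seed 7
dsite predict --fasta bench.fa --model model.joblib --out calls.tsv
dsite encode --fasta bench.fa --kind PseDNC --out psednc.tsv
```

Every command writes a `.meta.json` sidecar (seed, grids, folding engine,
property-table hash) sufficient to reproduce the run.

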