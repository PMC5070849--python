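# ssx — internal vs external drivers of time-course gene expression

`ssx` decomposes the temporal expression dynamics of a gene group into the
part driven by the group's own regulatory network and the part driven by an
external group of regulators. Typical use: an *internal* group Ω of genes of
interest (e.g. genes conserved across two species) and an *external* group Ψ
of regulators outside it (e.g. species-specific transcription factors), each
measured over the same T time points of a developmental time course.

## Model

Expression is modelled as a linear time-invariant state-space system

```
X_{t+1} = A X_t + B U_t ,        t = 1 .. T
```

where `X_t ∈ R^{N1}` holds the internal group's expression, `U_t ∈ R^{N2}`
the external regulators' expression, `A` the internal interaction matrix and
`B` the external control matrix. Unrolling the recursion splits every
trajectory into three algebraically exact components:

```
X_t = A^{t-1} X_1            (internal)
    + B U_{t-1}              (external, t ≥ 2)
    + Σ_{k=1}^{t-2} A^k B U_{t-1-k}   (interaction, t ≥ 3)
```

With N genes and only tens of samples, `A` and `B` are not estimable at the
gene level, so both groups are first projected onto a handful of SVD
*metagenes* (`X̃_t = W_X^T X_t`, `Ũ_t = W_U^T U_t`, with `W` the top left
singular vectors). The effective metagene-level model `[Ã B̃]` is then the
least-squares solution `Z Υ⁺`, where `Z = [X̃_2 … X̃_T]` and `Υ` stacks the
lagged states and inputs — estimable whenever `M1 + M2 ≤ T − 1`.

Eigendecomposing `Ã` turns the internal component into a sum of **internal
principal dynamic patterns (iPDPs)**: canonical trajectories `λ_p^1 … λ_p^T`
per eigenvalue (complex-conjugate pairs merged into one real oscillation),
classified as growing / constant / decaying / alternating / oscillatory by
the eigenvalue's position relative to the unit circle. Each external
metagene's time profile is an **external pattern (ePDP)** weighted by the
columns of `B̃`. Per-gene coefficients come from back-projection
(`C_p = W_X K̃_p`, `D = W_X B̃`) and feed cross-dataset comparison: class-based
pattern matching, Spearman rank correlation of coefficients over shared
genes, and a pooled-rank Welch t-test asking whether a gene set loads more on
internal than external patterns.

## Worked example

```python
import numpy as np
from ssx import (make_synthetic_dataset, fit_metagenes, estimate_model,
                 extract_ipdps, decompose)

lam = 0.8 * np.exp(1j * np.pi / 5)
ds, truth = make_synthetic_dataset(
    N1=200, N2=40, M1=4, M2=3, T=15,
    eigen_spec=[0.95, 0.5, lam, lam.conjugate()], noise_sd=0.0, seed=42)

bx = fit_metagenes(ds.internal_matrix, 4)
bu = fit_metagenes(ds.external_matrix, 3)
model = estimate_model(bx.scores, bu.scores)
for p in extract_ipdps(model.A_tilde, bx.scores[:, 0], 15):
    print(f"iPDP{p.index}: eigenvalue {p.eigenvalue:.4f}  class {p.class_label}")
print("conservation check:",
      f"{decompose(model, bx.scores[:, 0], bu.scores).total_check:.2e}")
```

prints

```
iPDP1: eigenvalue 0.9500+0.0000j  class decaying
iPDP2: eigenvalue 0.6472+0.4702j  class damped-oscillation
iPDP3: eigenvalue 0.5000+0.0000j  class decaying
conservation check: 7.11e-15
```

The estimator recovers the planted spectrum exactly on noiseless data: two
slowly decaying patterns (eigenvalues 0.95 and 0.5) and one damped
oscillation from the conjugate pair `0.8 e^{±iπ/5}` (reported once, merged to
a real trajectory; `0.6472 + 0.4702i = 0.8 e^{iπ/5}`). The conservation check
is the maximum deviation between the summed internal + external + interaction
components and the propagated trajectory — zero up to round-off, by
construction.

## Command line

The `ssx` entry point exposes the pipeline as subcommands: `load`,
`metagenes`, `fit`, `simulate`, `run` (full five-stage pipeline from a flat
`key = value` config file, emitting delimited-text artifacts plus a
`manifest.json` with every tolerance and artifact hash; reruns are bitwise
reproducible) and `compare` (cross-dataset pattern matching and statistics).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
generates a synthetic dataset with a known mixed spectrum, runs the complete
five-stage pipeline on it and writes the target report. See `docs/methods.md`
for the modelling assumptions and numerical choices.
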