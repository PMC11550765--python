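# fodm — fuzzy-oil-drop hydrophobicity analysis of protein structures

`fodm` characterizes how closely a folded protein realizes the *micelle-like*
ideal of globular structure — hydrophobic residues buried in the center,
polar residues exposed to water — and, when it does not, quantifies how
strong a non-aqueous environmental field (membrane, chaperone cavity) is
needed to explain the observed arrangement. It is aimed at structural
bioinformaticians studying hydrophobic-core formation, membrane-protein
organization, catalytic-pocket localization, and environment-dependent
folding.

## The model

Every residue is reduced to an **effective atom** at the mean position of
its heavy atoms, carrying an intrinsic hydrophobicity *H* from a
min-max-rescaled amino-acid scale (Kyte–Doolittle by default). Four
normalized per-residue distributions are compared:

- **T** (theoretical): the structure is encapsulated in a 3D Gaussian whose
  σ per principal axis follows the three-sigma rule (farthest effective
  atom at 3σ);
  `T_i ∝ exp(−x_i²/2σ_x²) · exp(−y_i²/2σ_y²) · exp(−z_i²/2σ_z²)`.
- **O** (observed): pairwise hydrophobic contacts with Levitt's distance
  weight, `O_i ∝ Σ_j (H_i + H_j) · w(r_ij)` for `r_ij ≤ 9 Å`, where
  `w(r) = 1 − ½(7t² − 9t⁴ + 5t⁶ − t⁸)`, `t = r/c`.
- **R** (uniform): `R_i = 1/N`.
- **M** (environment-modified): `M(K) = norm(T + K · norm(T_max − T))` — the
  aqueous field blended with its complement, the field a hydrophobic
  environment would impose.

Distributions are compared by Kullback–Leibler divergence (bits),
`D_KL(O|T) = Σ O_i log₂(O_i/T_i)`, and summarized by the **relative
distance**

```
RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R))
```

RD < 0.5 means a hydrophobic core is present. The **environment parameter
K ≥ 0** is fitted per structure as the minimizer of `D_KL(O|M(K))` over a
grid: K ≈ 0 indicates water-dominated folding; K roughly 0.5–1.5 covers
enzymes with functional mismatches and membrane-chaperone influence; K
beyond 3 marks chaperonin-grade external fields. Residues that locally
break the ordering (catalytic cavities, interfaces) are localized by
stepwise elimination of the largest |T_i − O_i| gap until RD < 0.5.

## Worked example

```python
from fodm import FixtureSpec, analyze, generate, load_structure, write_pdb

model, _ = generate(FixtureSpec(n_residues=100, mode="ideal-micelle", seed=1))
write_pdb(model, "ideal_micelle.pdb")
ana = analyze(load_structure("ideal_micelle.pdb"))
print(ana.result.rd, ana.kfit.k_rounded, ana.environment)
```

Running `python examples/01_profile_ideal_micelle.py` prints:

```
structure: ideal_micelle  (N = 100 residues)
envelope sigmas (A): 6.18, 4.57, 3.66
D_KL(O|T) = 0.0347 bits
D_KL(O|R) = 1.4198 bits
RD        = 0.0239
K         = 0.0
class     = hydrophobic-core-present, environment WATER
```

The observed distribution is 0.035 bits from the Gaussian ideal but 1.42
bits from uniform, so RD = 0.024 — a clean hydrophobic core — and no
environmental modification is needed (K = 0). The other scripts in
`examples/` show K fitting across environment classes, elimination of a
planted outlier residue, and fragment-level RD plus the CLI.

Real structures work the same way: `load_structure("file.pdb",
selection="A:10-120")` accepts PDB/mmCIF files with chain and residue-range
selections, and the `fodm` CLI (`fodm profile|fitk|eliminate|batch|synth`)
wraps the library for shell use.

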