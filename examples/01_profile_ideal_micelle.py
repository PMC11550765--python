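"""Profile a water-soluble-like synthetic structure and read off RD and K.

Generates an ideal-micelle fixture (hydrophobic center, polar surface),
writes it as a PDB file, loads it back through the regular structure
reader, and computes the T/O/R/M profiles with the RD statistic and the
fitted environment parameter K.
"""

import tempfile
from pathlib import Path

from fodm import FixtureSpec, analyze, generate, load_structure, write_pdb

model, _ = generate(FixtureSpec(n_residues=100, mode="ideal-micelle", seed=1))
pdb_path = Path(tempfile.gettempdir()) / "ideal_micelle.pdb"
write_pdb(model, pdb_path)

loaded = load_structure(pdb_path)
ana = analyze(loaded)

print(f"structure: {ana.model.id}  (N = {len(ana.model)} residues)")
print(f"envelope sigmas (A): "
      + ", ".join(f"{s:.2f}" for s in ana.envelope.sigmas))
print(f"D_KL(O|T) = {ana.result.dkl_ot:.4f} bits")
print(f"D_KL(O|R) = {ana.result.dkl_or:.4f} bits")
print(f"RD        = {ana.result.rd:.4f}")
print(f"K         = {ana.kfit.k_rounded:.1f}")
print(f"class     = {ana.status}, environment {ana.environment}")
print()
print("RD < 0.5 means the observed hydrophobicity follows the centric")
print("Gaussian (a hydrophobic core exists); K = 0.0 means no non-aqueous")
print("environmental field is needed to explain the distribution.")
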