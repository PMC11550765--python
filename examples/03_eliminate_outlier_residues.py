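"""Localize the residues that break micelle-like ordering.

A planted-outlier fixture hides one fully hydrophobic residue at the
surface of an otherwise ordered structure — the signature of a binding
patch or catalytic site. Stepwise elimination of the largest |T_i - O_i|
gap finds it, and RD drops below 0.5 once it is removed. The same question
can be asked declaratively with an explicit exclusion list.
"""

from fodm import FixtureSpec, compute_profiles, eliminate_until, generate, rd_excluding

model, expect = generate(FixtureSpec(n_residues=20, mode="planted-outlier", seed=7))
t, o, r, _ = compute_profiles(model)

trace = eliminate_until(o, t, r, target=0.5)
print(f"initial RD = {trace.initial_rd:.3f} (no hydrophobic core)")
for i, step in enumerate(trace.steps, start=1):
    print(f"  step {i}: removed {step.ref}  |T-O| gap = {step.gap:.4f}"
          f"  -> RD = {step.rd_after:.3f}")
print(f"converged = {trace.converged}; planted outlier was {expect['planted']}")

res = rd_excluding(o, t, r, [expect["planted"]])
print(f"RD excluding the planted residue outright: {res.rd:.3f} ({res.scope})")
print()
print("The single surface hot spot carried the whole divergence: without")
print("it the remaining structure is micelle-like (RD < 0.5).")
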