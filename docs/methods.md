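# Methods

## Model and assumptions

The package treats a folded protein (or any selected fragment or complex)
as a cloud of *effective atoms*, one per residue at the arithmetic mean of
the residue's heavy-atom positions. Hydrogens are ignored; this heavy-atom
convention is a deliberate choice — it is reproducible across deposition
conventions, whereas restricting to backbone atoms or including hydrogens
would tie results to how a particular structure was refined.

The idealized aqueous fold is a 3D Gaussian: hydrophobicity maximal at the
centroid, decaying to zero at the surface. The structure is centered and
rotated to the principal axes of the effective-atom position covariance
(largest variance along x), and σ per axis is set by the three-sigma rule:
σ_a = max_i |coordinate_a| / 3, with no padding margin. Principal-axis
alignment is itself a modeling choice: the per-axis σ of an ellipsoidal
envelope are only meaningful in a frame where the molecule's extents are
axis-aligned, and the covariance eigenbasis is the canonical such frame.
Eigenvector signs are fixed deterministically (the atom farthest from the
center along each axis gets a non-negative coordinate; det = +1 restored by
flipping z), so profiles are bit-reproducible across platforms. In the rare
case where the variance ordering of axes disagrees with the max-extent
ordering, axes are re-sorted by extent so that σx ≥ σy ≥ σz always holds.

The observed distribution uses Levitt's empirical contact weight with a
9 Å cutoff (configurable). The self pair (j = i, distance 0, weight 1,
contributing 2H_i) is included by default; the contact sum as written
places no j ≠ i restriction, and including it keeps isolated residues from
having an undefined observed level. Both behaviors are implemented
(`include_self` flag) because conventions differ across the literature.

All profiles are normalized to unit sum and compared with Kullback–Leibler
divergence in log base 2 (bits), with the 0·log 0 = 0 convention. T is
strictly positive by construction and R is never zero; the only reference
that can reach zero is M (when K is large and the complement vanishes at
the T maximum), so an epsilon floor of 1e-12 is applied to the M reference
inside the K fit and logged when triggered.

## The environment field and the K fit

The non-aqueous field is the complement c_i = max(T) − T_i. The printed
form of the modified distribution nests two normalizations; the reading
implemented here is: normalize c to unit sum, scale by K, add to T
(already unit sum), renormalize. This makes K = 1 weight the aqueous and
complement fields equally and keeps K dimensionless and comparable across
proteins of different sizes. The reading is isolated in one function
(`field.modified_profile`) so an alternative normalization order can be
swapped in without touching anything else.

K is fitted by exhaustive grid search over [0, 10] in steps of 0.001
(configurable; very large chaperonin-class complexes can need a higher
upper bound). A 1-D grid is cheap, derivative-free and robust to the flat
plateaus the divergence curve develops at large K. Ties break toward
smaller K — the water-dominant explanation — and an argmin at the upper
grid edge is flagged `boundary`. K is reported both at grid resolution and
rounded to one decimal, the customary reporting precision.

Environment classification bins K into half-open ranges
[0, 0.5) WATER, [0.5, 0.9) INTERMEDIATE, [0.9, 1.5) MEMBRANE-CHAPERONE,
[1.5, 3.0) MEMBRANE, [3.0, ∞) CHAPERONIN-LIKE. The published range
taxonomy prints overlapping interval endpoints; half-open bins make the
classification total and deterministic, which matters more for a software
contract than the (empirically fuzzy) boundary placement. The
hydrophobic-core verdict is RD < 0.5.

## Residue elimination

Stepwise elimination ranks residues by |T_i − O_i| on the current
(renormalized) profiles, removes the largest gap (ties: larger O_i, then
sequence order), renormalizes the surviving T/O/R and recomputes RD, until
RD < target (default 0.5). Re-ranking after each renormalization is the
default; a frozen-initial-ranking variant and a per-residue
KL-contribution criterion are exposed as flags for sensitivity analysis.
A guard stops the loop after removing 50 % of residues and flags the
result non-convergent rather than hollowing out the structure — weakly
ordered proteins can otherwise absorb unbounded removals.

## Hydrophobicity scales

The intrinsic scale is configurable; Kyte–Doolittle, Eisenberg consensus
and Fauchère–Pliška are built in, each min-max rescaled to [0, 1] so every
level is non-negative and normalized distributions are well defined. RD
and K are invariant to positive rescaling of the raw scale (normalization
absorbs it) but not to the scale's rank ordering, so any comparison of
printed RD/K values across studies must record the scale used; the default
here is Kyte–Doolittle.

## Synthetic fixtures

The generator produces seeded point clouds uniformly filling a 3σ
ellipsoid (default aspect 1.6 : 1.25 : 1.0) at a globular-protein packing
density of about 160 Å³ per effective atom, which gives each residue
several neighbors inside the 9 Å contact cutoff. Residue identities — and
hence intrinsic hydrophobicities under the active scale — are chosen by
inverting the contact operator: the observed profile is linear in the
hydrophobicity vector, O_raw = (diag(Σ_j w_ij) + w) h, so solving this
system for a target profile (the structure's own T, its complement, or the
uniform distribution), clipping at zero and quantizing to the nearest of
the 20 discrete residue levels makes O track the target as closely as the
scale's granularity allows. Ideal-micelle fixtures reach RD ≈ 0.02–0.06
and fitted K = 0.000; inverted fixtures reach RD > 0.9 with the K fit
pinned at the grid boundary; uniform fixtures reach RD > 0.99.

The planted-outlier mode multiplies the solved background by 0.35 and sets
one residue — the most surface-exposed (minimum-T) position — to full
hydrophobicity. The muting is what lets a single residue carry the
majority of D_KL(O|T): at 20 residues this construction yields initial
RD ≥ 0.5, a unique maximal |T_i − O_i| gap at the planted residue, and
RD < 0.5 after its single removal, across all tested seeds. At realistic
protein sizes (N ≥ 50) one swapped residue cannot push RD above 0.5 — the
statistic is an average over the whole body — so the planted fixtures are
deliberately small.

Fixtures are written as single-model PDB files with one CA record per
effective atom, so they exercise the same parsing and scale-lookup path as
real input. What the fixtures do **not** emulate: backbone connectivity
and realistic bond geometry, side-chain packing, secondary structure,
sequence-local correlation of hydrophobicity, missing atoms/altlocs, and
crystallographic artifacts. Passing tests therefore validate the
mathematics of the pipeline and its invariances, not agreement with any
particular experimental structure; RD/K values for real PDB entries also
depend on the intrinsic scale chosen, which published analyses typically
leave unstated.

## Numerical choices and problem sizes

- T is evaluated in log space and shifted by its maximum before
  exponentiation, so extreme aspect ratios cannot underflow the profile.
- The K-grid evaluation is vectorized in chunks of 1024 grid points to
  bound memory at large N.
- Degenerate inputs fail loudly: collinear clouds (no envelope), planar
  clouds (σ = 0), uniform T with K > 0 (zero complement), and exact
  O = T = R coincidences (RD undefined) each raise a specific exception.
- Test and acceptance runs use fixture sizes of 20–100 residues and grid
  searches of ≤ 10⁴ points; the full suite completes in seconds. The
  per-structure cost is O(N²) for contacts and O(N · grid) for the K fit,
  so chains of thousands of residues remain well within interactive use.

## Known limitations

- The K fit is a descriptive repartition between two fixed fields, not a
  physical free-energy decomposition; K values are comparable across
  structures only under the same scale, cutoff and self-pair convention.
- Fragment RD inherits the whole-structure envelope; a fragment is judged
  within the parent body's field, by design, so analyzing a domain as an
  independent body requires loading it as its own selection.
- The elimination procedure is greedy; it identifies a sufficient
  disrupting set, not a minimal one.
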