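# Methods

## Model

`volindex` estimates a compound's vapor pressure P (atm) by additive group
contribution, `log10 P = b0 + Σk vk·bk` with `b0 = 1.79`. Every occurrence
of a functional group multiplies in its term `bk` (log10 atm per
occurrence); the carbon term (−0.438 per atom) encodes the decrease of
volatility with molecular size, and every other counted term is negative —
functionality "taxes" volatility — so log10 P is linear and non-increasing
in every count. The method needs only the functional-group inventory, not
full 3D structure, which is what makes it automatable at database scale;
the price is roughly an order of magnitude of uncertainty in P (about one
RVI unit), and systematic overestimation for compounds with many
hydrogen-bonding groups (amino acids, sugars) whose intramolecular
interactions the additive model ignores.

The terms table (`src/volindex/data/groups.yaml`) carries 31 groups. 24
are counted; seven (hydroperoxide, nitrophenol, nitroester, alicyclic
ether, aromatic ether, aromatic amine, generic phosphate) are carried with
their terms but never counted because no reliable automated detection rule
exists for them — their count is pinned to zero and a molecule containing
one simply contributes nothing for it. Nine terms are not empirically
fitted but assigned by structural analogy (amide, phosphoric
acid/ester/phosphate ≈ nitrate via the P~N group-15 analogy; sulfate,
sulfonate ≈ nitrate via the S~N heteroatom analogy; thiol ≈ hydroxyl and
carbothioester ≈ ester via the C~S analogy). These are the weakest numbers
in the model; the table is runtime-editable (`ContributionTable.with_terms`)
precisely so they can be replaced when experimental values appear.

## Group counting

Counting is SMARTS-based (RDKit) over a precedence-ordered registry:

* **Primitive counts.** Carbon = number of C atoms. Rings = SSSR; an
  aromatic ring is an SSSR ring whose bonds are all aromatic. Bridged and
  fused systems therefore count one per SSSR ring — a deterministic
  convention for structures where "the number of rings" is genuinely
  ambiguous. Raw C=C is counted on the Kekulé structure, so each
  six-membered aromatic ring contributes three; the correction below
  removes them again. This mirrors how such counts arrive from generic
  cheminformatics primitives and keeps every intermediate inspectable.
* **Masking.** SMARTS groups are matched in precedence order (nitrate >
  nitro > phosphoric ester > phosphoric acid > sulfate > sulfonate >
  carboxylic acid > carbothioester > ester > amide > peroxide > aldehyde >
  ketone > phenol > hydroxyl > thiol > ether > amines); atoms consumed by
  an earlier group are masked from later patterns. This is what prevents a
  carboxylic acid from also scoring as hydroxyl + ketone, or an ester's
  alkoxy oxygen from scoring as an ether. Patterns are written so that
  only the essential heteroatoms/carbonyl carbons are match atoms;
  anchoring carbons appear as recursive constraints and are not masked.
* **Correction rules.** Four overlaps are deliberately left in the raw
  counts and resolved arithmetically afterwards, floored at zero:
  non-aromatic rings = rings − aromatic rings; hydroxyls = hydroxyls −
  phenols; C=C = Kekulé C=C − 3×aromatic rings; phosphoric acids =
  phosphoric acids − phosphoric esters (same coefficient, count only one).
  The raw/corrected pairs are exempt from masking against each other so
  the arithmetic sees both counts. Flooring matters: pyridine's Kekulé
  structure has only two C−C double bonds and naphthalene's two fused
  rings share one, so the subtraction legitimately goes below zero. The
  test suite cross-checks the Kekulé-minus-3-per-ring arithmetic against a
  direct count of non-aromatic C=C bonds.
* **Conventions.** Ring oxygens (sugar ethers) count as generic ethers;
  the distinct alicyclic/aromatic-ether terms are carried but not counted.
  Amines are classed primary/secondary/tertiary by the carbon-neighbour
  count of a non-amide nitrogen; a nitrogen attached to an aromatic ring
  is an aromatic amine and yields no count. A phenol is one count per OH
  on an aromatic carbon — multiple phenolic OH groups on one ring each
  count once, with the hydroxyl subtraction preventing double counting.
  Charged species are counted as drawn; there is no protonation or
  tautomer normalisation (environmental pH effects are out of scope).

## Mass and RVI

Molecular mass is the *average* molecular weight computed from the Hill
formula with a fixed table of the older IUPAC single-value atomic weights
(C 12.0107, H 1.00794, N 14.0067, O 15.9994, ...), reported to 4 decimals.
This revision reproduces database-style molecular weights such as
CH5N = 31.0571 Da; other revisions can differ in the fourth decimal, and
the table is overridable per call. Which revision a given external
database used is not knowable in general — this is a documented source of
≤1e−3 Da discrepancies.

RVI = log10 C\* = log10 P + log10(M/RT) + 9 with T = 298.15 K and
R = 0.0820574 L·atm·mol⁻¹·K⁻¹ (standard conditions; using 298 K instead
would shift RVI by ~3e−4, far below reporting precision). No van der
Waals correction is applied — a few-percent effect against the model's
order-of-magnitude uncertainty. RVI is reported to 2 decimals in
user-facing output and kept at full precision internally.

Category thresholds are environment profiles, boundary values going to the
upper bin (the threshold *is* the lower edge of its category): clean
atmosphere (−2, 0, 2; ~1 μg m⁻³ condensed organics), polluted atmosphere
(0, 2, 4; two decades more organic particulate shifts each cut-point up by
two), soil (0, 4, 8; an upper-bound scenario where <0.1% of soil carbon is
available for partitioning — only the low/high cut-points 4 and 8 are
anchored, and 0 was chosen as the nonvolatile boundary so the soil scale
nests the atmospheric ones). Custom triples are accepted anywhere an
environment is.

The partitioning helper returns `ξ = 1/(1 + C*/C_total)` exactly as this
formula is conventionally printed. Note the orientation tension: the
formula as written *decreases* with C\*, i.e. it reads naturally as the
condensed-phase fraction of absorptive partitioning theory, while prose
descriptions of ξ often call it the gas-phase fraction. The implementation
evaluates the printed formula verbatim and leaves the interpretation to
the caller rather than silently flipping it.

## Uncalculable compounds

Three conditions make a record uncalculable, and all fold into a
per-record `status`/`reason` instead of an exception so batch runs degrade
row by row: a generic R substituent (pseudo-atom in a MOL block, `*` in
SMILES, `R` in a formula), an undefined repeat unit (`(...)n` or a
trailing `n` in a formula), and a missing mass. Pathway profiles report
both the total member count and the percentage with a calculated RVI, so
the exclusions stay visible.

## Reference suite and the two-path discipline

The builtin fixture suite (`volindex.fixtures`) holds 38 calculable
molecules covering all 24 counted groups plus the correction-rule edge
cases (fused aromatics, heteroaromatics, sugar rings, phenol/hydroxyl and
phosphoric acid/ester overlaps) and two uncalculable stubs. Expected
counts were enumerated by hand per structure and the expected log10 P/RVI
computed by direct summation over the printed terms — an arithmetic path
independent of the production counter — then frozen as literals.
`compose_molecule` extends the same discipline to generated
chain-plus-substituent molecules: the request *is* the oracle count, and
its log10 P is summed directly from the terms table and compared against
the production pipeline.

What the suite does and does not show: these are small, mostly
monofunctional molecules with unambiguous structures. Passing it
demonstrates that the counting rules, corrections and arithmetic are
implemented correctly; it does not bound the model's accuracy on large
polyfunctional metabolites (CoA esters, glycosides, phosphorylated
intermediates), where both the additive model's physics and the counting
conventions (bridged rings, interacting groups) carry real uncertainty.
Benchmarking against an external, manually computed RVI database is the
job of the `benchmark` module, which reports the three standard agreement
metrics — identical RVI (|Δ| < 0.01, the 2-decimal reporting precision),
within 0.5 units (a quarter of a 2-unit category bin), same category —
plus a paired Wilcoxon signed-rank test (delegated to scipy) as
supplementary output.

## Numerical and design notes

* All counting is deterministic for a fixed registry; symmetry-duplicate
  SMARTS matches are collapsed to unique atom sets.
* The ketone pattern is a carbonyl flanked by two carbons; the aldehyde
  pattern admits formaldehyde (H2C=O).
* `molecular_weight` signals an undefined repeat with `None` rather than
  raising, because "cannot be computed" is an expected data condition, not
  a programming error; malformed formulas and unknown elements do raise.
* The KEGG fetch adapter (MOL by compound ID over REST, with a mandatory
  on-disk cache and an offline mode) is strictly optional; nothing in the
  package or its tests requires network access.
* MOL support is V2000 only; V3000 input is rejected with a clear error.
  Explicit hydrogens are folded into implicit counts before counting.
* A half-stated historical correction rule for "additional functional
  groups on a functionalized ring" (divide by two and subtract hydroxyl−1)
  is not implemented: it is not interpretable as written, and direct
  SMARTS matching of phenols with the phenol/hydroxyl subtraction covers
  the double counting it aimed at. Flagged here for review.
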