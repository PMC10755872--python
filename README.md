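# volindex

Estimate the volatility of metabolites — and of small organic molecules in
general — directly from their molecular structure.

Volatility is a fundamental but rarely catalogued trait of metabolites: it
decides whether a compound diffuses away as a gas or stays condensed, which
biological roles it can play (signalling between organisms, extending the
rhizosphere) and whether standard metabolomics workflows will even detect
it. `volindex` automates the volatility estimate for any compound that has
a structure file (MOL V2000 / SDF) or SMILES string, so that whole pathway
databases can be screened instead of evaluating molecules one at a time.

## The model

Vapor pressure is estimated by group contribution:

```
log10 P = b0 + Σk vk·bk          (P in atm, b0 = 1.79)
```

where `vk` is the number of occurrences of functional group *k* and `bk`
its fitted contribution term (carbon −0.438 per atom, hydroxyl −2.23,
carboxylic acid −3.58, ...; the full table, including terms assigned by
structural analogy for phosphorus- and sulfur-containing groups, lives in
`src/volindex/data/groups.yaml`). Vapor pressure converts to a saturation
mass concentration C\* by the ideal gas law, giving the **relative
volatility index**

```
RVI = log10 C* = log10 P + log10(M / RT) + 9      (μg m⁻³, 298.15 K)
```

which is binned into `nonvolatile / low / moderate / high` categories using
environment-dependent thresholds: clean atmosphere (−2, 0, +2), polluted
atmosphere (0, 2, 4), soil (0, 4, 8), or any custom triple. Gas–particle
partitioning against a condensed organic pool follows
`ξ = 1 / (1 + C*/C_total)`.

Functional groups are counted from the structure with SMARTS patterns under
a precedence/masking scheme (so an ester is never also counted as an ether
plus a ketone), followed by four explicit corrections that remove known
double counting: aromatic rings vs rings, phenols vs hydroxyls, Kekulé
aromatic C=C (3 per ring), and phosphoric esters vs phosphoric acids.

## Worked example

```python
>>> from volindex import parse_smiles, calc_vol
>>> est = calc_vol(parse_smiles("CCC", id="propane"))
>>> round(est.log10_p, 3), round(est.rvi, 2), est.category
(0.476, 9.73, 'high')
```

Propane has three carbons and no other functional groups, so
`log10 P = 1.79 − 3×0.438 = 0.476`; with M = 44.0956 Da this converts to
RVI = +9.73, high volatility in a clean atmosphere. A sugar sits at the
other end of the scale:

```python
>>> est = calc_vol(parse_smiles("OCC1OC(O)C(O)C(O)C1O", id="glucose"))
>>> round(est.rvi, 2), est.category
(-2.85, 'nonvolatile')
```

The same runs from the shell, including batch input, pathway profiling and
benchmarking against a reference table of manually computed RVIs:

```
volindex calc -s CCC -s "Oc1ccccc1" --env clean --out results.csv
volindex pathway --members members.csv --structures structures.smi --out profiles.csv
volindex benchmark --structures structures.smi --reference manual_rvi.csv
```

Structures that cannot be estimated — generic "R" substituents, undefined
"(...)n" repeat units, missing mass — are reported with
`status=uncalculable` and a reason rather than failing the batch.

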