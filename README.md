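# venompep

Computational toolkit for viper venom peptidomics and intact-mass
proteoform profiling. It is written for venomics researchers who have
(a) de-novo-annotated peptide sequences and want exact ion masses,
(b) deconvoluted intact-mass lists from top-down LC–MS and want proteoform
structure, and (c) the three classic evidence layers of "snake venomics"
(RP-HPLC peak integrals at 214 nm, SDS-PAGE densitometry, top3 ion
intensities) and want a whole-venom toxin-family composition.

## What it computes

**Peptide masses.** Viper venom peptides — svMP-inhibitor tripeptides,
bradykinin-potentiating peptides (BPP), natriuretic peptides (NP) — are
usually blocked N-terminally by pyroglutamate (pE, C5H5NO2, 111.03203 Da
mono). `venompep` treats pE as a first-position residue and computes

- neutral masses `M = Σ residues + Σ modification deltas + H2O`,
- ion m/z `(n·M + z·1.00728)/z` for charge `z` and noncovalent multimer
  count `n` (e.g. the 2M+H⁺ dimer ion of pEKW),
- singly charged b/y fragment ladders with `b_i + y_(n−i) = M + 2·1.00728`,
  plus greedy peak matching and an exhaustive short-peptide de novo search
  (Leu/Ile reported as isobaric).

**BPP grammar.** Viperine BPP follow the modular consensus
`pE X W (P Z){1,2} P (EI|KV) P P L E` with X mainly K/N/R, Z ∈ {G,S,V}
and free C-terminal truncation. `parse_bpp` classifies a peptide into the
K/N/R-related families and reports repeat count, branch, truncation and
tolerated deviations; `enumerate_bpp` generates the grammar;
`name_substitutions` names NP variants against references such as
lebetin 1β (DNKPPKKGPPNG).

**Intact-mass inference.** From deconvoluted mass lists:
glycoform ladders with steps HexNAc 203.08, Hex 162.05, NeuAc 291.10 Da;
named small shifts (O +15.99, CO +27.99, H2O +18.01 Da); and disulfide
counts from reduced/nonreduced pairs, `n = round(Δm / 2.01565)`.

**Quantification.** Composition percent of family f:
`% f = 100 · Σ_bands (fraction area share × densitometric band share ×
top3 share of f in band)` — a partition of 100% at every stage, with
`peptides` and `unknown` buckets.

## Worked example

```bash
$ venompep pepmass pEKW
444.224
$ venompep pepmass pEKW --multimer 2
887.441
$ venompep disulfides --nonred 6414.61 --red 6424.68
{"accepted": true, "delta_mass": 10.07..., "n_bridges": 5, "residual": -0.008...}
$ venompep motif pENWPSPKVPP
{... "family": "N", "branch": "KV", "repeat": 1, "truncation": 2 ...}
```

Reading: the svMP-inhibitor tripeptide pEKW has [M+H]⁺ 444.224 and a
dimer ion 2M+H⁺ at 887.441; a protein fragment observed at 6414.61 Da
nonreduced and 6424.68 Da reduced carries five disulfide bridges
(Δ10.07 ≈ 5·2.01565 Da); and pENWPSPKVPP is an Asn-family BPP with one
(P,S) repeat, the KV branch, and two residues truncated from the
full-length consensus.

End-to-end on synthetic data:

```bash
$ venompep simulate --kind venom --seed 1 -o demo/
$ venompep quantify --chrom demo/chromatogram.csv --bounds demo/boundaries.csv \
    --bands demo/bands.tsv --assign demo/assignments.tsv \
    --peptide-fractions F7 --baseline none -o demo/composition.json
```

`demo/composition.json` then matches the planted truth in
`demo/truth.json` to well under half a percentage point per family.

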