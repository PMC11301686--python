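# Methods

## Mass model

Peptide masses are sums of residue masses (pyroglutamate included as a
compound residue code `pE`, formula C5H5NO2) plus modification deltas
plus one water for the termini. Residue and modification masses derive
from elemental compositions (pyteomics), so monoisotopic and average
modes are always consistent with the same formulas. Fixed constants:
proton 1.00728 Da, water 18.01056 Da mono / 18.0153 Da average. pE is a
residue, not a modification delta, because the −17.03 (from Gln) and
−18.01 (from Glu) routes give the identical cyclized product and MS
cannot tell which precursor was cyclized; modelling the residue avoids
asserting a precursor.

Ion arithmetic is `(n·M + z·1.00728)/z` throughout (precursor multimer
count `n ≥ 1` only for precursor ions). Fragment ladders are singly
charged-convention b/y series only: b_i is the first i residues plus z
protons, y_i the last i residues plus water plus z protons, with
positional modifications carried to the fragment that contains them.
a/c/x/z ions and neutral losses beyond the registered modification set
are out of scope. Leu/Ile are distinct codes with identical mass; parse
results expose the isobaric positions rather than guessing.

Display rounds to 3 decimals; all comparisons are done at full precision.
Default match tolerances: 10 ppm for monoisotopic peptide-level data,
0.5 Da for deconvoluted average masses; both are arguments everywhere.

The de novo helper does an exhaustive depth-first search over prefix
(b-ion) masses and validates the complementary y ladder; it is meant for
the short (≤ 8 residue) venom peptides this package targets, where the
search space is trivial, and collapses I to L.

## BPP grammar

The consensus is modelled generatively: full-length templates
`pE X W (P Z)^r P B PPLE` with X ∈ {K,N,R} (other residues allowed but
flagged rare), Z ∈ {G,S,V}, r ∈ {1,2}, branch B ∈ {EI,KV}; truncation is
a C-terminal prefix cut, never internal. Parsing is longest-prefix match
against the enumerated templates:

- strict mode: the (modification-stripped) sequence must be an exact
  prefix of some template; `truncation = len(template) − len(sequence)`,
  minimized over consistent templates.
- lenient mode: up to one substitution outside the pE/W anchors is
  tolerated and recorded. If even that fails but the pEXW core is intact,
  the sequence is still accepted (`core_only=True`) with all mismatches
  against the closest template listed as deviations and `truncation`
  unset. This fallback exists because observed venom peptidomes contain
  exclusive variants (e.g. pEKWLDPEIPP) that deviate at two positions yet
  are unambiguously pEXW-family peptides; rejecting them would misreport
  the peptidome's family structure. Trp at position 3 remains mandatory
  in both modes — pEXY-type peptides are a different class.

Substitution naming against NP references is ungapped with an integer
offset; labels use 1-based reference numbering (`K3E` on DNKPPKKGPPNG).
The venom NP literature mixes numbering conventions (the same variant may
be written K2E but G8V), so a 0-based "legacy" label is also emitted;
neither is asserted as canonical. Terminal extensions and truncations are
reported separately from substitutions.

## Intact-mass inference

Inputs are already-deconvoluted mass lists; no raw-spectrum processing is
attempted, and no glycosite localization or disulfide connectivity — only
counts, ladders and named shifts.

Glycan steps (HexNAc, Hex, NeuAc) and small shifts (O, CO, H2O) are
stored as exact composition-derived masses; observed literature values
that differ from the exact mass (e.g. a CO step reported as 27.97 vs the
exact 27.9949) surface in the residual rather than being absorbed into
the registry.

Ladder detection builds chains greedily from entries no other entry can
precede (so hits are maximal on both sides), assigning each gap the
best-fitting registered step. Acceptance is deliberately fit-based rather
than per-gap: a chain is kept when every member lies within `tol` of its
position on the offset-fitted ladder. The reason is statistical — with
independent mass noise σ per entry, an adjacent gap carries noise σ√2,
so thresholding gaps at `tol` rejects ~3% of genuine steps already at
σ = tol/3 and whole-ladder recall of a 3-step ladder drops to ~0.90;
per-member fitted residuals carry noise < σ and keep recall above 0.99
under the same condition. Candidate gaps are searched with a 2× slack for
the same reason; chains failing the fit are split at their worst gap and
the consistent runs reported. Intensity never influences chain building
(no principled rule exists for it here) and is used only to rank reported
hits. Default tolerances: 0.05 Da mono, 0.5 Da average.

Disulfide counting uses the step 2·1.007825 = 2.01565 Da mono (2.01588
average): `n = round(Δm/step)`, accepted when the residual is within
tolerance and the shift is non-negative beyond tolerance. Cross-condition
pairing reports every nonreduced/reduced pair explained by 0 ≤ n ≤
max_bridges bridges and flags one-to-many matches instead of resolving
them. Oxidation and similar shifts are handled as separate mass
relations, not folded into the disulfide estimate, since a shared
modification between conditions cancels in Δm while a one-sided one does
not — the residual exposes the latter.

## Quantification

The three-step partition is: fraction area share (trapezoidal integral
above baseline, normalized over the supplied fraction windows) ×
densitometric band share within the fraction × top3 intensity share
within the band. Each stage partitions the previous one, so the final
percentages sum to 100 by construction (validated to 0.01). Fraction
windows are user-supplied valley-to-valley bounds; a helper suggests cut
points at low local minima but never decides. Baseline options: linear
interpolation between window-edge absorbances (default), none, rolling
minimum; net-negative windows clip to zero. Degenerate bands (all-zero
top3) and unassigned fractions route to `unknown`; fractions flagged as
peptide pool into `peptides`; a fraction both flagged and banded is an
error, not a silent choice. DC proteins are a family of their own and
additionally available summed into the svMP umbrella (P–I + P–III + DC),
matching the dual reporting convention of the field. Percentages display
at 1 decimal; sums are checked before rounding.

## Synthetic data

Generators exist so every inference path is testable with known truth:
Gaussian chromatogram peaks (closed-form areas returned), mass lists with
ladders planted at exact registered steps and disulfide pairs at exact
n·2.01565 offsets before Gaussian mass noise, b/y spectra with uniform
decoy peaks kept 20 ppm away from true peaks, and whole synthetic venoms
(default 7 fractions, 12 bands, 8 protein families plus a peptide
fraction — roughly the scale of one viper venom proteome, so tests run in
seconds) whose composition is drawn from a flat Dirichlet and rendered
backwards into consistent chromatogram/band/top3 tables. All randomness
flows from one seed per generator call; equal seeds give byte-identical
output.

What the noise models are not: there is no isotope-envelope or
profile-mode simulation, no heteroscedastic instrument error, no
correlated densitometry error, no chromatographic tailing. Passing the
round-trip tests therefore demonstrates that the pipeline arithmetic is
exact and the inference robust to idealized noise — not that the package
compensates real-instrument systematics, which remain the operator's
responsibility upstream.

## Numerical and edge-case choices

- Validation tolerance for stored vs recomputed MH⁺ in peptide tables:
  0.005 Da (3-decimal printed values); mismatching rows are flagged, not
  dropped.
- Greedy peak matching takes candidate pairs in order of increasing
  absolute error, each peak used at most once; ties are resolved by that
  ordering deterministically.
- Ladder step ambiguity resolves by smallest residual; chain-start
  maximality is computed against all candidate predecessors, not only
  visited ones.
- `count_disulfides` clamps n at 0 for small negative shifts within
  tolerance; larger negative shifts raise an inconsistency error.
- Empty inputs: empty peak lists match to empty reports; mass lists with
  fewer than two entries yield no ladders; an empty peptide table reads
  as an empty list.

## Limitations

- The grammar is descriptive, not physiological: a match claims nothing
  about bradykinin potentiation or svMP inhibition activity.
- Bottom-up/top-down database search, FDR control and PSM scoring are out
  of scope by design; the package starts where those tools end.
- Gel densitometry is consumed as numbers; image processing is not
  included.
- Compositions are relative; absolute venom yields are not modelled.
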