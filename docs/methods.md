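# Methods

## Error model

Per-interaction errors of a scoring method are treated as draws from a
Gaussian per interaction class: deviation = E_approx − E_ref in kcal/mol,
with E_ref a converged quantum-chemical reference. Deviations are
**signed** throughout. The published composite statistics this package
ships could not arise from absolute deviations (several tabulated class
means are negative), so the signed reading is the only self-consistent
one.

Fitting is by moment matching: μ is the sample mean, σ² the unbiased
(n−1) sample variance. The class samples behind the shipped tables are
small (42 and 50), where the n−1/n distinction is visible, so the
estimator choice is documented to keep refitted and packaged tables
comparable. Whether a least-squares fit to a histogram would differ
materially is not resolvable from published material; moment matching is
the defensible default. At least two records per class are required;
fewer is an error, never a silent zero-variance PDF.

Propagation assumes interactions are independent and electronically
additive:

* systematic: Σ_i N_i μ_i (signed sum — correctable),
* random: sqrt(Σ_i N_i σ_i²) (quadrature — reported as a 1σ bar).

Error bars everywhere are 1σ of the propagated random error. Correction
subtracts the systematic total once; the operation is pure and explicitly
single-application (re-correcting a corrected energy subtracts again).

The R-factor is Σ|E_approx − E_ref| / Σ|E_ref| over a deviation
database. This exact formula is this package's reconstruction of the
crystallographic analogy (the original source states the analogy but not
the formula); treat cross-package comparisons of its absolute value with
care. All reference energies being zero is a guarded error.

Interaction classes are `nonpolar` (van der Waals), `polar` (hydrogen
bond) and `all`. `all` exists for structures whose contacts cannot be
classified; it is never mixed with per-class propagation — a class absent
from a table raises, never contributes zero.

### Packaged tables

Twenty methods' error statistics on the ubiquitin fragment database ship
as YAML files, values exactly as published (n recorded as 0 to mark them
as published rather than fitted). The pooled "all" column of a few rows
differs from the count-weighted combination of the class columns by more
than 0.01 kcal/mol; these are printed-rounding artifacts and the values
are deliberately left as published (the data test carries the explicit
waiver list). One extra table, `B97-D/TZVP (text)`, carries
worked-example-precision values quoted in running text (μ_polar 0.59 vs
the tabulated 0.60); only those reproduce the 17.3 kcal/mol composite to
printed precision. Similarly, the FF99SB composite random error
recomputes to 18.6 from the tabulated (rounded) variances where 18.4 was
published; tests treat that as a ±0.3 rounding artifact.

## Contact detection

Defaults (all configurable via `ContactCriteria`):

* hydrogen bond: donor heavy atom N/O/S carrying ≥1 hydrogen, acceptor
  N/O/S, donor–acceptor distance ≤ 3.5 Å and D–H⋯A angle ≥ 120°. These
  approximate the behaviour of common structure viewers' H-bond finders
  in spirit, not bit for bit; the criteria that produced the original
  42/50 ubiquitin tally were not recorded, so exact reproduction of that
  count on 1UBQ is not claimed.
* van der Waals: heavy-atom distance ≤ sum of Bondi radii + 0.5 Å
  tolerance. The radius table ships as versioned data
  (`data/bondi_radii.yaml`).
* sequence separation: |i − j| ≥ 2 within a chain (author numbering,
  insertion codes preserved); inter-chain pairs always eligible.
* one contact per residue pair per kind, represented by the closest
  qualifying atom pair — error statistics are per interaction, not per
  atom pair. A residue pair carrying a hydrogen bond is classified polar
  only; it is never double-counted as a van der Waals contact.

Hydrogen-bond detection requires explicit hydrogens and refuses to run
without them (the angle criterion is undefined otherwise); the package
deliberately contains no protonation engine — structures are expected
pre-protonated.

Parsing keeps the highest-occupancy altloc conformer (ties broken by
altloc identifier order) and MODEL 1 of multi-model files. Covalent
topology is inferred by distance against single-bond covalent radii
(bond if d ≤ r₁ + r₂ + 0.45 Å), which treats standard residues and the
idealised synthetic groups used in fixtures uniformly; no residue
template library is consulted.

## Fragment capping

Cutting a contact's two residues out of the protein severs covalent
bonds; each severed single bond X–Y (X kept) is replaced by X–H with the
hydrogen placed exactly on the X→Y vector at a standard length (C–H
1.09 Å, N–H 1.01 Å, O–H 0.96 Å, S–H 1.34 Å). Bonds with lengths
indicating double/aromatic character (e.g. C–O < 1.32 Å) refuse to be
capped. Selections must be covalently connected. Net formal charge is
recorded as 0 by default — PDB input carries no reliable charge
information, and charge assignment belongs to the downstream energy
engine.

## Decoy metrics

* "Native" for all three metrics means the lowest-energy member of
  {native, relaxed_native}.
* EGAP = min(decoy energies) − min(native energies); larger/positive is
  better.
* z-score = (min native energy − mean over **all** records) / sd over all
  records, with the n−1 sd; more negative is better. Zero spread is a
  degenerate-input error.
* EBO is true when the lowest record is native-like or the best native
  lies within the random bar of the lowest record. A symmetric two-bar
  variant (both bars added) is available but not the default.
* A system "improves" under correction when EGAP strictly increases or
  the z-score strictly decreases; ties count as no improvement. Favorable
  movement is counted whether or not the metric crosses zero.

## Synthetic generators

The generators exist to give every detector and estimator an input with
analytically known ground truth; they do not attempt realism.

* **Deviation samples**: i.i.d. Gaussian deviations; reference energies
  uniform on [−12, −1] kcal/mol (typical magnitudes for hydrogen bonds
  and dispersion contacts — the value only anchors the R-factor's
  denominator scale).
* **Toy structures**: rigid idealised groups — formamide-like N–H⋯O=C
  pairs (N⋯O 2.9 Å, 180° angle) and methane-like CH probe pairs (C⋯C
  3.6 Å) — on an 18 Å grid with random per-group orientation, so planted
  counts are exactly the detectable counts and nothing else is within any
  criterion's reach. These are not peptides: no backbone, no torsional
  structure, no competing near-threshold geometries. Passing the closure
  tests shows the detectors implement their geometric definitions
  exactly; it does not validate the default criteria against real protein
  crowding.
* **Decoy collections**: per system, chain length uniform on 50–146
  residues (the published decoy-set range) and native contact counts at
  ubiquitin's rates (50 polar, 42 nonpolar per 76 residues). True
  energies form a planted funnel: native at −1.5·L kcal/mol (an arbitrary
  stability scale), relaxed natives up to 2 kcal/mol above, the best
  decoy exactly `margin` (default 10 kcal/mol, the order of a folding
  free energy) above the native, the rest exponentially spread
  (scale 15 kcal/mol). Decoys keep each native contact with probability
  1 − 0.15 and gain spurious contacts at rate 0.05 per native contact, so
  natives systematically carry more contacts — the precondition for
  systematic correction to change relative energies. Observed raw
  energies add one Gaussian error draw per contact from a planted error
  table. Real decoy sets differ: their decoys are near-native with nearly
  identical contact counts, correlated (not independent) errors, and
  solvent contributions; conclusions from the synthetic funnel are
  qualitative.

All randomness flows through `numpy.random.default_rng(seed)`; a given
seed reproduces byte-identical structure files and identical energy
tables.

## Problem sizes

The test suite runs the Monte-Carlo propagation oracle at 10⁵ replicates
(agreement required within 3 standard errors on the mean and 2% on the
sd), parameter recovery at 10⁵ samples per class (within 5 standard
errors, floored at 0.02/0.03), generator–detector closure over 20
structures spanning 0–60 planted contacts, and the full 49 × 121 = 5929
record decoy-collection round trip. These sizes keep the whole suite
under a minute while leaving the statistical assertions comfortably
powered.

## Known limitations

* The package consumes fragment energies and whole-fold scores; it never
  computes quantum-chemical or force-field energies, basis-set
  extrapolations, or solvation terms.
* Error independence across contacts is assumed by both propagation laws;
  correlated errors (shared parameters, cooperative hydrogen bonding)
  violate it in a direction the model cannot see.
* Electronic interaction energies, not free energies: enthalpic
  corrections, folding entropy and solvation are outside the model, so
  propagated estimates are lower bounds on the free-energy error.
* Contact classification is binary (polar/nonpolar); aromatic-specific
  classes are not modelled.
* The geometric contact criteria are reasonable defaults, not a
  re-derivation of any particular published tally.
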