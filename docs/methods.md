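# Methods

This note records the models implemented by the package, the conventions and
numerical choices, and the places where the design was genuinely open.

## Base exchanges and sequence symmetries

The alphabet is RNA {A, C, G, U}; `T` is normalized to `U` on input and an
output alphabet can be selected where sequences are rendered. The Klein
four-group F = {I, SW, YR, KM} acts on bases (SW the complement, YR the
purine/pyrimidine exchange, KM the keto/amino exchange). The action is
regular: `transform_between(b1, b2)` is total and unique, which is the
engine behind tessera recognition and reconstruction. At the sequence level
the four operators {identity, reverse, complement, reverse-complement} form
an isomorphic group; `complement` is SW applied position-wise.

Conventions: positions are 1-based in prose (b₁…b₄) matching subscript
notation, 0-based half-open in anything exported as intervals (scan hits).
Orbit representatives are the lexicographically smallest member under
A < C < G < U. Symmetry labels are `palindromic` (fixed by reverse),
`self_complementary` (fixed by reverse-complement), `asymmetric`; no oligo
can carry both labels because the complement is fixed-point free.

## Tesserae

`generate_tesserae` appends g(d) to each of the 16 dinucleotides d for each
g ∈ F, giving 64 distinct quadruplets; `is_tessera` checks the equivalent
condition transform(b₁→b₃) = transform(b₂→b₄). Only two of the three
adjacent-letter transforms are independent: t₃₄ = t₁₂ always, and
t₂₃ = g ∘ t₁₂.

Reconstruction of a deleted letter uses whichever diagonal pair (1,3) or
(2,4) is intact to identify g and applies it (transforms are involutions, so
no inversion is needed); exhaustive tests confirm that exactly one of the
four candidate bases completes a tessera. Error immunity — minimum pairwise
Hamming distance 2 — is checked by brute force over all 64 × 12 single
mutations.

The canonical in-memory organization is the quartet table keyed by
(t₁₂, t₂₃); the layout keyed by first dinucleotide and generator is a
rendering option. Rows and columns are ordered (I, SW, YR, KM).

## Adaptor reading and degeneracy distributions

Reading modes formalize the pairing geometries of reversible adaptors:

* `unidirectional`: {reverse-complement(anticodon)} — ordinary antiparallel
  pairing;
* `bidirectional`: {complement, reverse-complement} — the adaptor can also
  bind in parallel orientation, still base-wise complementary (this is the
  assumption behind the worked example AUC → {GAU, UAG});
* `dual_anticodon`: the full-group orbit of the reverse complement — an
  adaptor presenting its anticodon in all four spatial configurations.

In dual mode the degeneracy of an anticodon equals the orbit size of the
anticodon itself (proved exhaustively for lengths ≤ 4 in the tests), which
is why degeneracy distributions are computed directly as orbit partitions.
`degeneracy_distribution` requires the input set to be closed under the
chosen group and reports the partition as {orbit size: class count}; the
symmetric count is the number of palindromic plus self-complementary
members. Amino-acid identity is deliberately abstract — classes are
anonymous slots.

## Genetic-code tables

NCBI translation tables 1, 2 and 10 are loaded from Biopython's codon-table
data and validated by spot invariants (e.g. AGA/AGG stop, AUA Met, UGA Trp
in table 2; UGA Cys in table 10). Distributions use the `split6` convention
by default: codons are grouped by (element, box), so a 6-fold amino acid
contributes a quartet plus a pair inside their respective boxes; stop codons
form per-box classes and are counted in distributions. The raw per-element
grouping is available with `split6=False`. Two countings of "number of
amino acids" coexist deliberately: distinct amino-acid symbols
(`amino_acid_count`, 20 for tables 2 and 10) versus synonym classes (24 for
table 2 with split6); both are exposed rather than reconciled.

The Rumer check asks, per box, whether the KM exchange on the first doublet
flips family status (all four codons synonymous vs. not). The vertebrate
mitochondrial code passes 16/16.

## The tessera → codon mapping

The mapping encodes (t₁₂, t₂₃) as the first two codon letters via I→A,
SW→U, KM→C, YR→G, after relocating two pairs of quadrants —
(YR, SW) ↔ (SW, YR) and (KM, SW) ↔ (I, YR) — and maps b₄ to the third
letter with the keto swap: x₃ = KM(b₄) if b₄ ∈ {U, G}, else b₄. The
quadrant swaps express the wobble-strategy asymmetry of extant codes (SUN
boxes are families despite the weak centre; WGN boxes are split despite the
strong centre).

Open points fixed here, validated by `verify_mapping` against table 2:

* the swap is applied at quadrant level, and the within-quartet assignment
  is carried entirely by the b₄ rule;
* the b₄ rule is applied after quadrant relocation (the other order fails
  verification);
* "K" in the b₄ rule is read as the keto bases {U/T, G}.

The verification asserts bijectivity, that the image of each of the 24
tessera orbits is exactly one split6 synonym group of table 2 (8 families, 14
amino-acid pairs, 2 stop pairs), and that Rumer's transformation transports:
KM on a tessera's first doublet flips the family status of the image box for
all 64 tesserae. Other mappings satisfying the same constraints may exist;
the package implements exactly this one and makes no uniqueness claim.

## Non-power representation systems

A system is a non-increasing vector of six non-negative integer weights;
6-bit strings represent Σ sᵢwᵢ. The search space for `search_weights` is:

* total Σw fixed (default 23, so the maximum representable value matches the
  23-amino-acid ceiling);
* completeness — every weight ≤ 1 + the sum of all smaller weights — so the
  representable values are the contiguous range 0…Σw;
* a unimodal multiplicity profile — the per-value representation count rises
  to a central plateau and falls, never dipping and recovering. Together
  with the automatic symmetry count(v) = count(Σw − v) this forces the
  high-degeneracy values into one central block, which is what allows the
  system to be read as two merged dinucleotide half-systems. Zero weights
  are permitted.

Under these constraints the search returns a unique solution for each code
target: (8, 8, 4, 2, 1, 0) for the mitochondrial distribution {2: 16, 4: 8}
and (8, 7, 4, 2, 1, 1) for the euplotid distribution {1: 2, 2: 12, 3: 2,
4: 8}. Dropping the unimodality constraint (`require_unimodal=False`)
admits eight further vectors for the mitochondrial target, which the search
reports verbatim; the sensitivity flag exists precisely because the
constraint set of this model family is a design choice, and the chosen set
is the minimal one under which both code targets have unique solutions.
Candidate enumeration is a few hundred partitions of 23 into ≤ 6 parts;
histograms are exact 64-string enumerations.

## Random-assignment model of a primitive tetracodon code

The 256 tetracodons contain exactly 32 symmetric members (16 palindromic +
16 self-complementary — the symmetric half of the tessera set) and 224
asymmetric ones. The model assigns each of E = 17 elements a distinct
random anchor tetracodon; a symmetric anchor makes the element degeneracy 2,
an asymmetric one degeneracy 4. The number k of degeneracy-2 elements is
then hypergeometric (N = 256, S = 32, E = 17). Because the sampling
protocol of the underlying argument is not fully specified, this
implementation is a reconstruction, and a binomial variant (independent
anchors, p = S/N) is provided as a robustness check: both give modal
composition (2 degeneracy-2, 15 degeneracy-4) — the composition of Jukes'
primitive code, whose codon budget 15·4 + 2·2 = 64 matches a 64-codon code.
Probabilities are exact `Fraction` arithmetic (C(256, 17) ≈ 10²⁵ overflows
nothing), converted to float only on output; ties in the mode would be
reported (none occur at the defaults).

## Sequence scanning and IO

The tetracodon scanner reads non-overlapping 4-base windows at frame
offsets 0–3 (an overlapping sliding mode exists for exploration); hits are
reported with 0-based offsets satisfying offset ≡ frame (mod 4). The FASTA
reader is strict by design — malformed headers and non-ACGU(T) characters
are rejected with line and column numbers. Writers are byte-stable (fixed
column order, sorted JSON keys, LF endings). A YAML run configuration
(output format, alphabet, split6, seed, log level) round-trips losslessly.

## Problem sizes and limitations

Every quantitative claim in the package is a finite exact enumeration — the
largest objects touched by tests are the 4⁵ = 1024 pentanucleotides and the
~200 weight-vector candidates — plus one seeded Monte-Carlo cross-check
(10⁵ draws) of the hypergeometric pmf; the full suite runs in seconds.

What the package does not model: binding thermodynamics and wobble
chemistry, post-transcriptional modifications, the evolutionary dynamics of
adaptor competition (no defined dynamics to implement), circular-code or
frameshift analyses, and statistical testing of real genomes for tessera
enrichment. The scanner annotates windows; it makes no enrichment claims.
Synthetic scan fixtures in the tests are short hand-written oligos chosen to
cover tessera and non-tessera windows; they emulate no genomic base
composition, so scanner tests validate window bookkeeping, not biological
signal.
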