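# tessera

Symmetry and degeneracy calculus for four-base (tessera) genetic codes.

## The problem

The genetic code maps 64 codons onto 20 amino acids plus stop, so most amino
acids are encoded by several codons. One line of explanation treats this
degeneracy the way physics treats degenerate quantum states: as a consequence
of symmetry. If primeval tRNA-like adaptors were reversible — able to pair
with a codon read 5′→3′ or 3′→5′, base-wise complementary in either
orientation — then the set of codons one adaptor can read is an *orbit* of
the sequence-symmetry group {identity, reverse, complement,
reverse-complement}, and orbit sizes are degeneracies.

For trinucleotides this machinery produces degeneracies 1 and 2 (reverse
only) or the distribution {2: 8, 4: 12} (full group) — neither matches the
putative early code, whose degeneracy distribution is that of the present
vertebrate mitochondrial code: **16 classes of degeneracy 2 and 8 of
degeneracy 4**. The unique codon length that reproduces it is four, restricted
to the **tesserae**: quadruplets b₁b₂b₃b₄ over {A, C, G, U} with
b₃b₄ = g(b₁b₂) for one element g of the Klein four-group of base exchanges

    I  : identity            SW : A↔U, C↔G  (complement)
    YR : A↔G, C↔U (purine/pyrimidine)   KM : A↔C, G↔U  (keto/amino, Rumer)

There are exactly 64 tesserae; 16 are palindromic, 16 self-complementary and
32 asymmetric, and the full-group orbit partition gives precisely
{2: 16, 4: 8}. The package implements this calculus end to end:

* `tessera.symmetry` — the Klein group, sequence operators, orbits;
* `tessera.tesserae` — generation, recognition, quartet tables, the
  missing-letter reconstruction and the minimum-Hamming-distance-2 error
  immunity of the tessera set;
* `tessera.adaptors` — adaptor reading modes and orbit degeneracy
  distributions for any codon length;
* `tessera.codes` — NCBI translation tables 1, 2 and 10 with box/family
  analysis and the Rumer-transformation check;
* `tessera.mapping` — an explicit bijection tesserae ↔ trinucleotide codons
  that transports the orbit structure exactly onto the synonym groups of the
  vertebrate mitochondrial code;
* `tessera.nonpower` — redundant 6-weight integer representation systems
  whose multiplicity histograms reproduce the mitochondrial and euplotid
  degeneracy distributions, plus the exhaustive weight search;
* `tessera.jukes` — the random-assignment model for a primitive tetracodon
  code (hypergeometric/binomial anchor statistics);
* `tessera.io` / `tessera.cli` — FASTA/plain input, tetracodon scanning, and
  the `tessera` command-line tool.

## Worked example

Degeneracy distribution of the tessera set under the full symmetry group:

```console
$ tessera degeneracy --set tessera
degeneracy	classes
2	16
4	8
# codon_total	64
# symmetric_count	32
# total_classes	24
```

Sixteen orbits of size 2 (the 32 symmetric tesserae, read pairwise by
adaptors with palindromic or self-complementary antitesserae) and eight
orbits of size 4 (the 32 asymmetric tesserae). The 24 classes require 24
adaptors; discarding the two stop classes leaves 22 — the adaptor count of
the vertebrate mitochondrial code — and with a single stop the ceiling on
representable amino acids is 23.

Classify an oligo and see its orbit:

```console
$ tessera classify CGUA
sequence	CGUA
symmetry	asymmetric
is_tessera	true
generator	YR
orbit	AUGC,CGUA,GCAU,UACG
```

Map a tessera to its codon in the vertebrate mitochondrial code (AUUA lands
in the UAR stop pair, as its partner UAAU lands on UAG):

```console
$ tessera map --direction t2c --input AUUA
UAA
```

Search for 6-weight representation systems with total 23 matching the
mitochondrial distribution — the search recovers a unique solution:

```console
$ tessera nonpower search --total 23 --target mito
8,8,4,2,1,0
```

Random assignment of 17 elements to anchors among 256 tetracodons (32
symmetric) makes the composition of a Jukes-type primitive code the mode:

```console
$ tessera jukes | tail -1
# modal_composition	deg2=2	deg4=15	tied=false
```

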