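# refasm

A toolkit implementing the modern curated reference-assembly model: the
data structures, file formats, and release mechanics used to maintain a
high-quality clone-based reference genome over time.

## The problem

A reference genome is not a single FASTA file. It is built from
*components* (clone, WGS, or PCR-fragment sequences with versioned
accessions), ordered by *tiling paths* (TPF), and assembled into contigs,
scaffolds, and chromosomes by *AGP* instructions that record, for each
junction between overlapping components, the *switch point* — the base at
which sequence generation switches from one component to the next.

A single haploid consensus cannot represent structurally variant regions
(e.g. a locus where one haplotype carries a multi-kilobase insertion and
another does not). The assembly model therefore groups sequences into
*assembly units*: one **primary** unit (the non-redundant haploid
chromosomes plus unlocalized/unplaced scaffolds), any number of
**alt-loci** units holding alternate tiling paths for variant regions, and
a **PATCHES** unit. Alternate loci and patches never get chromosome
coordinates; they get *chromosome context* through a block alignment onto
the primary chromosome, which doubles as a coordinate **liftover** bridge.

Between major releases, the assembly is improved by *minor releases* that
add **FIX** patches (corrections) and **NOVEL** patches (new alternate
loci) without moving a single primary-chromosome base — annotations built
on release *N* remain valid through *N*.p1, *N*.p2, … Minor releases are
cumulative. A major release is triggered by policy (≥ 100 FIX patches
accumulated, or > 1 % of the euchromatic sequence affected): FIX patches
are spliced into the chromosomes and retired, NOVEL patches are promoted
to alt-loci units, and a remap table records the old↔new coordinate
relation.

`refasm` implements this whole model as a library plus a `refasm` CLI,
together with synthetic generators (clone tilings, a dual-haplotype
insertion/deletion region, sequencing reads) that let every contract be
exercised end to end on data built at run time.

## Worked example

Generate a structurally variant region (deletion allele on the primary
chromosome, insertion allele as an alternate locus), simulate reads from
the insertion haplotype, and compare read placement with and without the
alternate locus:

```sh
refasm --seed 11 simulate region --out region
refasm --seed 12 simulate reads --fasta region/haplotypes.fa \
       --sequence insertion --n-reads 500 --out reads.tsv
refasm eval alt-awareness --reads reads.tsv --with-alt region/with_alt \
       --without-alt region/without_alt --report report.tsv
```

which prints

```
alt-specific reads: 76; correct with alt 76, without 0
```

and writes `report.tsv`:

```
#assembly       correct misplaced       unaligned
with_alt        76      0       0
without_alt     0       1       75
#alt_specific_reads     76
#non_alt_agreement      1.0000
```

Of the 500 simulated reads, 76 overlap the 2 kb sequence present only on
the insertion haplotype. With the alternate locus in the assembly, all 76
are placed at their true position on the alt scaffold; without it they
have no correct home — 75 fail to align and 1 lands somewhere wrong.
Reads from the shared flanks place identically in both assemblies
(agreement 1.0000), so adding the alternate locus costs nothing for
ordinary reads. The placement that gives the alt scaffold its chromosome
context is an anchored block alignment:

```
alt_insertion  1  13600  chrS  1  11600  +  1-5800:1-5800;7801-13600:5801-11600
```

two exact blocks whose 2000-base gap on the alt axis is the insertion;
`refasm liftover --placements … --pos alt_insertion:600 --direction
"alt->primary"` maps across it.

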