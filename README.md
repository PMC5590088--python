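# ramdecode

**In-silico decoding of fecundity-gene protein variants from WGS genotypes
in a ram diversity panel.**

Sheep litter size is strongly influenced by coding variants in three
TGF-β-family genes: *GDF9* and *BMP15* (oocyte-secreted ligands) and
*BMPR1B* (their type-1 receptor).  Given whole-genome-sequence genotypes
for a breed diversity panel — here modelled on a 96-ram panel spanning nine
U.S. breeds, a composite line and one Navajo-Churro ram — this package
decodes the protein variants those genotypes encode and asks which are
previously known fecundity alleles, which are novel, and how deeply each
affected residue is conserved across vertebrates.

It is written for geneticists who have per-animal genotypes at candidate
coding sites (VCF) and want the full downstream analysis without touching
raw reads:

* **Consequence calling** — genomic alleles to codon-level calls
  (missense / nonsense / silent / in-frame indel / frameshift / splice
  site), with correct handling of genes oriented opposite to the reference
  assembly (all three genes here are minus-strand in Oar_v3.1).
* **Pedigree-free haplotype phasing** — phase is *unambiguous* for an
  individual homozygous at every variant site or heterozygous at exactly
  one (and always for hemizygous X genotypes in males); individuals
  heterozygous at ≥2 sites are phased by **maximum parsimony**: among all
  2^(h−1) genotype-consistent haplotype pairs, choose the pair requiring
  the fewest haplotypes not already observed in the panel, breaking ties
  toward the larger summed frequency of known haplotypes. Residual ties
  are reported as unresolved, never guessed.
* **Protein-variant trees** — isoforms are arranged in a minimum
  single-substitution tree (every edge one amino-acid change), adding the
  fewest inferred intermediate isoforms needed for connectivity (exhaustive
  search), rooted at the node closest to a related-species outgroup
  profile.
* **Frequency estimation** with chromosome-aware denominators: an autosomal
  site counts 2 alleles per scored animal, an X-linked site 1 per scored
  male.  Site MAFs, panel-wide and per-breed protein-variant frequencies,
  and a site-vs-haplotype consistency check.
* **WGS genotype QC** — call rate under a ≥3-read scoring rule, accuracy
  against consensus reference-SNP genotypes with a strict >97% per-animal
  gate, per-animal bead-array concordance, and a through-origin regression
  of mean depth on sequence yield.
* **Conservation classification** — for each variant residue, the deepest
  clade (Artiodactyla ⊂ Laurasiatheria ⊂ Eutheria ⊂ Theria ⊂ Mammalia ⊂
  Tetrapoda ⊂ Vertebrata) in which the reference residue is strictly
  conserved, an exceptions-tolerant variant of the same call, and whether
  the sheep variant residue occurs in any other species.
* **Synthetic data** — a generator that emulates the panel's statistical
  structure (breed-structured Hardy–Weinberg draws, truncated-normal read
  depth, depth-dependent allele dropout, missing calls below 3 reads), so
  the entire pipeline is testable without any sequence download.

## Worked example

The packaged fixture panel (96 rams, genotypes consistent with the
published site, haplotype and breed tables) decodes in a few seconds:

```bash
ramdecode decode --out out/
```

`out/table3_variants.tsv` then contains the panel-wide protein-variant
frequencies:

```
gene	variant	residues	count	denominator	frequency
GDF9	1	R,E,V,V	133	192	0.693
GDF9	2	R,E,I,V	47	192	0.245
GDF9	3	H,K,V,V	7	192	0.036
GDF9	4	R,E,V,M	5	192	0.026
BMP15	1	L,R,L	63	96	0.656
BMP15	2	ΔL,R,L	24	96	0.250
BMP15	3	ΔL,R,P	8	96	0.083
BMP15	4	ΔL,Q,L	1	96	0.010
BMPR1B	1	M,T	182	192	0.948
BMPR1B	2	I,T	5	192	0.026
BMPR1B	3	M,N	5	192	0.026
```

Reading the GDF9 block: the reference isoform (R87, E241, V332, V371) is
the most frequent at 133 of 192 chromosomes (0.693); the I332 isoform
segregates at 0.245; the rare H87+K241 isoform (0.036) is carried only in
cis; and the M371 isoform (0.026) — the known Finnsheep fecundity variant —
appears in 5 heterozygous Finnsheep rams.  BMP15 denominators are 96, not
192, because the gene is X-linked and all 96 animals are male
(hemizygous).  `out/GDF9_tree.nwk` holds the rooted isoform tree

```
(variant3:1,(variant2:1,variant4:1)variant1:1)inferred1;
```

whose root, `inferred1` = (H87, E241, V332, V371), is an intermediate
isoform required by parsimony but not observed in the panel.
`out/exclusions.tsv` logs every animal dropped at any stage (missing
genotype, unresolved phase) with the reason; it is empty for the fixture
panel.  Other subcommands: `simulate` (synthetic panels on disk), `qc`
(`--wgs/--truth/--array`), `freq`, `tree`, `conserve`, `report`.

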