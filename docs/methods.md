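# Methods

This note documents the models, conventions and design choices behind
`ramdecode`, and what the packaged fixtures and synthetic data do and do
not establish about real data.

## Coordinate model and consequence calling

Coordinates are 1-based inclusive internally, matching how variant
positions are printed in the genetics literature; on-disk BED fixtures are
0-based half-open and converted at the boundary.  A gene model is a set of
sorted, non-overlapping exon intervals plus a coding-strand 5'UTR offset
and a protein length; the invariant `CDS − stop = 3 × protein_length` is
enforced at construction.  For minus-strand genes (all three genes here),
codon indexing runs along the reverse-complemented concatenation of exons
from the highest genomic coordinate downward.

SNV consequences substitute the (strand-corrected) allele into the
reference codon and translate with the standard genetic code (Biopython's
table 1).  Indels are normalised by left-alignment **on the coding
strand** after stripping shared allele prefix/suffix bases; multiples of 3
are `inframe_indel`, everything else `frameshift`.  A clean deletion of
whole codons from a run of identical residues gets the compact repeat
label (e.g. `L11ΔL`) plus an HGVS-style string (`p.(Leu10_11delinsLeu)`);
other in-frame events fall back to a delins label.  Splice-site detection
is limited to the two canonical intronic bases flanking each exon — the
narrowest defensible window when no source defines one.

Known-variant matching keys on (gene, amino-acid position, alternate
residue token, with `stop` normalised to `*` and deletions to `Δ`-prefixed
tokens); anything without an exact key match is novel.

## Phasing and trees

The unambiguous rule (fully homozygous, exactly one heterozygous site, or
hemizygous) is exact, not heuristic.  For ≥2 heterozygous sites the
parsimony score of a candidate haplotype pair is the number of member
haplotypes absent from the known set — the set of haplotypes established
by unambiguous phasing, with their frequencies.  "Simple maximum
parsimony" is operationalised as: minimise novel haplotypes, tie-break by
larger summed known-haplotype frequency, surface residual ties as
`unresolved` rather than guessing.  The tie-break is a flag
(`frequency_tiebreak`), so the stricter behaviour (ties always
unresolved) is one option away.  A brute-force enumeration oracle in the
test suite certifies the argmin for all ≤4-het patterns.

Trees are minimum single-substitution trees: nodes are isoforms, edges are
Hamming-distance-1 pairs.  Inferred intermediates are restricted to
combinations of residues observed at each position (no novel residues) and
are found by exhaustive search over candidate subsets in order of
increasing size, lexicographic within a size — deterministic and provably
minimal at this problem scale (≤6 observed isoforms over ≤5 positions;
the search precomputes the candidate-graph adjacency so each subset test
is a BFS).  The search is exponential in the worst case and is not meant
for genes with many variant positions.  The spanning tree over the chosen
node set is the lexicographic Kruskal tree, and observed nodes are
labelled `variant1, variant2, …` in decreasing frequency order (ties
lexicographic).  Rooting minimises Hamming distance to an outgroup residue
profile (unknown positions ignored; ties prefer observed nodes, then
lexicographic).  For GDF9 the packaged outgroup profile matches the
inferred intermediate (H87, E241, V332, V371) — the orientation consistent
with a root isoform not observed in the panel; the profile is data, not
code, and can be replaced.

The ΔL indel is treated as a single binary character at one haplotype
position throughout.

## Frequencies

MAF is defined against the panel-minor allele, not the reference allele.
Denominators are chromosome-aware: 2 per scored diploid animal, 1 per
scored hemizygous male; missing cells are excluded (never imputed) and
reduce denominators.  Unresolved-phase individuals are excluded from
haplotype numerators *and* denominators (with a logged count) but not from
site MAFs, which need no phase.  Reporting rounds half-up to 3 decimals
(site/panel tables) or 2 (per-breed tables), matching the printed
precision of the corresponding published tables.  `site_maf` can pin the
counted allele, for statements like "frequency 1.0 in four White Dorper"
where the panel-minor allele is locally fixed.

The consistency check compares each site MAF with the summed frequencies
of carrier haplotypes; the default tolerance 0.002 covers printed
rounding (e.g. a 0.344 MAF against 0.250+0.083+0.010).

## WGS QC

Call rate is scored-sites / attempted-sites with a site scored iff depth
≥ 3 reads (or, absent depths, iff the call is non-missing).  Accuracy and
concordance compare unordered genotypes over shared (animal, site) keys,
excluding cells missing or half-missing on either side — the observed WGS
error mode is undetected heterozygosity, i.e. full-call mismatches.  The
per-animal pass gate is strict: accuracy > 97%, which admits at most 4
errors in 163 genotypes.  Pooled concordance is the unweighted mean of
per-animal concordances (per-site pooling is an option).  The
depth-vs-yield regression fixes the intercept at zero (depth is directly
proportional to data collected) and reports the slope, its SE and the
uncentred R².  Depth summaries report mean/min/max/SD over per-animal mean
depths and the mode of the pooled per-cell histogram.

## Conservation

The taxonomy is a nested clade ladder; each species carries the ladder
suffix starting at its narrowest clade.  Strict conservation depth is the
largest clade in which every species with a known residue equals the
reference (unknown tokens `- ? nr nm ni X` are ignored; sheep itself is
excluded when its own variant is assessed) — monotone under adding
conforming/mismatching species and independent of input order.  The
exceptions-tolerant mode returns the largest clade with at most
`max_exceptions` (default 3) deviating species, naming them — the form
needed for statements like "conserved throughout Theria except humans,
manatees and armadillos".  Percent identity excludes gap columns.
Real ortholog retrieval is out of scope; the packaged ortholog set is
synthetic (built by `generate_ortholog_set` to encode the qualitative
conservation structure of the real comparison) and the cross-species
percent-identity figures of the original analysis are therefore not
reproduced here.

## Synthetic data

The generator emulates: breed-structured haplotype draws (independent
within breed — Hardy–Weinberg, no inbreeding, the natural null for a panel
chosen to minimise relatedness); one X haplotype per male; per-cell read
depth as a rounded normal truncated at 1 (defaults location 16.8, spread
3.5 — the coverage regime of ~40 GB of short reads per genome); missing
calls below 3 reads; and heterozygote allele dropout (each of d reads
carries either allele with probability 1/2; the het call requires both
alleles seen, giving error probability 2^(1−d), e.g. 0.25 at d=3).  Reads
carry no base-call error by default; a miscall-rate parameter exists but
defaults to 0 because dropout, not miscalling, is the observed error mode.
Everything is reproducible from a seed.

It does **not** emulate: linkage disequilibrium between genes, pedigree
structure, reference bias, mapping artefacts (e.g. collapsed repeats that
inflate local error), or batch effects.  Tests passing on synthetic data
therefore establish the correctness of the decoding arithmetic and the
calibration of the stated error model — not robustness to real-data
artefacts.

Statistical recovery checks assert a 3-binomial-SE band on the ~11
panel-wide haplotype frequencies (breed-size-weighted truth).  Asserting
the band on every per-breed cell (~65 simultaneous comparisons) would fail
for a sizeable fraction of seeds purely by multiplicity; per-breed
correctness is instead pinned by the exact aggregation identity (breed
counts sum to panel counts).

## Packaged fixtures

The fixture panel holds 96 rams in 11 breed groups with integer haplotype
assignments that reproduce the published site MAFs, panel-wide and
per-breed variant frequencies exactly, including 7 double-heterozygous
GDF9 rams, 5 heterozygous V371M Finnsheep, an M64I Katahdin homozygote, a
T345N Romanov homozygote, one hemizygous Q67 carrier, and White Dorper
fixed for the P252 haplotype.  Gene models use exon intervals constructed
to satisfy every printed (position, exon number, codon, flanking-sequence)
constraint simultaneously; exon boundaries between variant-bearing exons
are otherwise free choices, and one printed exon number (BMP15 L252P
"exon 1") is inconsistent with the printed position, which the model
resolves in favour of the coordinates (exon 2).  Reference slices are
rebuilt at load time from neutral filler plus the published coding-strand
flanking sequences embedded in reverse complement; overlapping embeddings
are asserted to agree.  The flank printed for BMPR1B T345N is a verbatim
duplicate of another row's flank (a typesetting corruption), so that
neighbourhood is synthetic filler constrained to the ACT/AAT codon; the
same row's printed codon-allele lettering contradicts the standard genetic
code and is corrected to ACT = T (reference) / AAT = N (variant).

## Numerical and degenerate-input conventions

Half-up rounding everywhere a printed table is mirrored (banker's rounding
would print 0.1875 as 0.188→0.19 vs 0.18).  Empty inputs raise typed
errors (`UndefinedRateError`, `UndefinedFrequencyError`,
`IncompleteDataError`) rather than returning NaN; an empty panel decodes
to header-only outputs.  All tie-breaks (tree node order, edge selection,
root choice, phasing) are lexicographic and documented, making every
pipeline output byte-reproducible under a fixed seed and configuration.

## Problem sizes used in checks

The packaged panel is decoded at its natural size (96 animals, 9 sites).
Synthetic recovery runs at 10,000 animals per breed (110,000 animals);
the dropout calibration uses 100,000 Monte-Carlo heterozygous cells at
fixed depth 3; unit-level recovery tests use 1,500–2,000 per breed.
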