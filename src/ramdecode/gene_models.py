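"""Gene models and protein-level consequence calling.

The three fecundity genes analysed here (GDF9, BMP15, BMPR1B) all lie on the
minus strand of the Oar_v3.1 sheep reference assembly, so every genomic allele
must be reverse-complemented and re-indexed along the coding strand before a
codon can be read.  This module holds the coordinate arithmetic for that
mapping, the standard-code codon translation, a consequence caller for SNVs
and small indels, and matching of calls against a catalogue of previously
reported fecundity variants.

Coordinates are 1-based inclusive throughout, matching how variant positions
are conventionally printed (e.g. chr5:41,843,258); on-disk BED fixtures are
0-based half-open and converted at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Data.IUPACData import protein_letters_1to3

__all__ = [
    "GenomeSlice",
    "GeneModel",
    "VariantSite",
    "CodonSpec",
    "ProteinVariantCall",
    "CatalogMatch",
    "NON_CODING",
    "map_genomic_to_codon",
    "translate_codon",
    "codon_spec",
    "call_coding_variant",
    "match_known_catalog",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("acgtACGT", "tgcaTGCA")
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: Sentinel returned by :func:`map_genomic_to_codon` for exonic but
#: non-coding (UTR) positions.
NON_CODING = "non_coding"


class OutOfGeneRangeError(ValueError):
    """Position falls outside the gene's exon span (introns included)."""


class InvalidCodonError(ValueError):
    """Codon is not a length-3 string over a/c/g/t."""


class AlleleMismatchError(ValueError):
    """Allele is neither the reference nor a listed alternate of the site."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSlice:
    """A plus-strand slice of the reference genome.

    Addressable positions are ``start .. start + len(seq) - 1`` (1-based
    inclusive).
    """

    chrom: str
    start: int
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("GenomeSlice sequence must be non-empty")
        if self.start < 1:
            raise ValueError("GenomeSlice start must be a positive 1-based position")

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def base(self, pos: int) -> str:
        if pos not in self:
            raise IndexError(f"position {self.chrom}:{pos} outside slice "
                             f"{self.chrom}:{self.start}-{self.end}")
        return self.seq[pos - self.start]

    def subseq(self, start: int, end: int) -> str:
        """Plus-strand subsequence for the closed interval [start, end]."""
        if start > end:
            raise ValueError("subseq start must be <= end")
        if start not in self or end not in self:
            raise IndexError(f"interval {start}-{end} outside slice bounds")
        return self.seq[start - self.start : end - self.start + 1]


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript protein-coding gene.

    ``exons`` are 1-based closed intervals sorted by reference coordinate and
    non-overlapping.  ``cds_offset`` counts the 5'UTR bases that precede the
    start codon within the concatenated *coding-strand* exon sequence, so for
    a minus-strand gene the offset is measured from the highest-coordinate
    exon end.
    """

    symbol: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]
    cds_offset: int
    protein_length: int
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon interval {s}-{e} is inverted")
            if s <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if self.exon_length < self.cds_offset + self.cds_length:
            raise ValueError(
                f"{self.symbol}: exons hold {self.exon_length} bases but "
                f"cds_offset + CDS needs {self.cds_offset + self.cds_length}")

    @property
    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        """CDS length including the stop codon."""
        return 3 * (self.protein_length + 1)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def coding_exons(self) -> Sequence[tuple[int, int]]:
        """Exons ordered 5'->3' along the coding strand."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def coding_index(self, pos: int) -> Optional[int]:
        """0-based index of ``pos`` along the concatenated coding-strand exons.

        Returns None for intronic positions; raises for positions outside the
        gene span entirely.
        """
        lo, hi = self.span
        if not (lo <= pos <= hi):
            raise OutOfGeneRangeError(
                f"{self.chrom}:{pos} outside {self.symbol} span {lo}-{hi}")
        offset = 0
        for s, e in self.coding_exons():
            if s <= pos <= e:
                return offset + (pos - s if self.strand == "+" else e - pos)
            offset += e - s + 1
        return None

    def genomic_position(self, coding_index: int) -> int:
        """Inverse of :meth:`coding_index` for exonic indices."""
        if coding_index < 0 or coding_index >= self.exon_length:
            raise IndexError(f"coding index {coding_index} out of range")
        offset = coding_index
        for s, e in self.coding_exons():
            n = e - s + 1
            if offset < n:
                return s + offset if self.strand == "+" else e - offset
            offset -= n
        raise AssertionError("unreachable")

    def splice_flank_positions(self) -> frozenset[int]:
        """The 2 canonical intronic bases flanking each exon boundary."""
        positions: set[int] = set()
        for i, (s, e) in enumerate(self.exons):
            if i > 0:
                positions.update((s - 2, s - 1))
            if i < len(self.exons) - 1:
                positions.update((e + 1, e + 2))
        return frozenset(positions)

    def coding_base(self, ref: GenomeSlice, pos: int) -> str:
        """Coding-strand base at a reference position."""
        b = ref.base(pos)
        return b if self.strand == "+" else b.translate(_COMPLEMENT)


@dataclass(frozen=True)
class VariantSite:
    """A variant site in plus-strand reference coordinates.

    ``pos`` is the 1-based position of the first reference base of
    ``ref_allele`` (for indels, the first affected base after plus-strand
    left-alignment).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    site_id: str = ""

    def __post_init__(self) -> None:
        if not self.ref_allele:
            raise ValueError("ref_allele must be non-empty")
        if not self.alt_alleles:
            raise ValueError("at least one alt allele required")
        for a in self.alt_alleles:
            if a.lower() == self.ref_allele.lower():
                raise ValueError(f"alt allele {a} identical to ref")
        if not self.site_id:
            object.__setattr__(self, "site_id", f"{self.chrom}:{self.pos}")

    @property
    def site_class(self) -> str:
        if len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles):
            return "SNV"
        return "indel"

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles

    def validate_against(self, ref: GenomeSlice) -> None:
        observed = ref.subseq(self.pos, self.pos + len(self.ref_allele) - 1)
        if observed.lower() != self.ref_allele.lower():
            raise ValueError(
                f"{self.site_id}: ref allele {self.ref_allele!r} does not match "
                f"reference sequence {observed!r}")


@dataclass(frozen=True)
class CodonSpec:
    """One codon of a gene, addressed both in protein and genome space."""

    gene: str
    aa_pos: int
    genomic_positions: tuple[int, int, int]  # ordered 5'->3' along coding strand
    ref_codon: str

    def __post_init__(self) -> None:
        if len(self.ref_codon) != 3:
            raise InvalidCodonError(f"ref_codon {self.ref_codon!r} must be length 3")


@dataclass(frozen=True)
class ProteinVariantCall:
    """Protein-level consequence of one allele at one site."""

    gene: str
    aa_pos: int
    ref_residue: str
    alt_residue: str  # one-letter code, '*' for stop, 'Δ'-prefixed deletion token
    consequence: str  # missense | nonsense | silent | inframe_indel | frameshift | splice_site
    label: str = ""
    hgvs: str = ""

    def __post_init__(self) -> None:
        if self.consequence == "nonsense" and self.alt_residue != "*":
            raise ValueError("nonsense call requires alt residue '*'")
        if self.alt_residue == "*" and self.consequence not in ("nonsense",):
            raise ValueError("stop alt residue implies nonsense consequence")
        if self.consequence == "silent" and self.ref_residue != self.alt_residue:
            raise ValueError("silent call requires identical residues")
        if not self.label:
            object.__setattr__(self, "label", default_label(self))


def default_label(call: ProteinVariantCall) -> str:
    if call.consequence == "silent":
        return f"{call.ref_residue}{call.aa_pos}="
    if call.consequence == "nonsense":
        return f"{call.ref_residue}{call.aa_pos}stop"
    if call.consequence == "frameshift":
        return f"{call.ref_residue}{call.aa_pos}fs"
    if call.consequence == "splice_site":
        return f"splice:{call.gene}:{call.aa_pos}"
    return f"{call.ref_residue}{call.aa_pos}{call.alt_residue}"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def map_genomic_to_codon(model: GeneModel, pos: int):
    """Map a reference position to (aa_pos, offset-in-codon 1..3).

    Offsets count along the coding strand, so for a minus-strand gene offset 1
    is the *highest* reference coordinate of the codon.  Positions in the stop
    codon map to ``aa_pos == protein_length + 1``.  Exonic UTR or intronic
    positions return :data:`NON_CODING`; positions outside the gene span raise
    :class:`OutOfGeneRangeError`.
    """
    c = model.coding_index(pos)
    if c is None:
        return NON_CODING
    cds_idx = c - model.cds_offset
    if cds_idx < 0 or cds_idx >= model.cds_length:
        return NON_CODING
    return cds_idx // 3 + 1, cds_idx % 3 + 1


def translate_codon(codon: str) -> str:
    """Translate one coding-strand codon with the standard genetic code.

    Returns the one-letter residue code or ``'*'`` for a stop codon.
    Ambiguity codes and wrong lengths raise :class:`InvalidCodonError`.
    """
    if len(codon) != 3 or any(b not in "acgtACGT" for b in codon):
        raise InvalidCodonError(f"invalid codon {codon!r}")
    upper = codon.upper()
    if upper in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[upper]


def codon_spec(model: GeneModel, ref: GenomeSlice, aa_pos: int) -> CodonSpec:
    """Extract the reference codon for an amino-acid position."""
    if aa_pos < 1 or aa_pos > model.protein_length + 1:
        raise IndexError(f"aa position {aa_pos} out of range for {model.symbol}")
    base_idx = model.cds_offset + 3 * (aa_pos - 1)
    positions = tuple(model.genomic_position(base_idx + k) for k in range(3))
    codon = "".join(model.coding_base(ref, p) for p in positions)
    return CodonSpec(model.symbol, aa_pos, positions, codon)


def _coding_cds(model: GeneModel, ref: GenomeSlice) -> str:
    """The coding-strand CDS (including stop codon) spelled from the slice."""
    parts = []
    for s, e in model.coding_exons():
        sub = ref.subseq(s, e)
        parts.append(sub if model.strand == "+" else reverse_complement(sub))
    return "".join(parts)[model.cds_offset : model.cds_offset + model.cds_length]


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip shared prefix/suffix bases from a VCF-style allele pair."""
    ref, alt = ref.lower(), alt.lower()
    # suffix first, then prefix, keeping at least one base in the longer allele
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    # pure insertion/deletion keeps its anchor base stripped when possible
    while len(ref) != len(alt) and len(ref) >= 1 and len(alt) >= 1 \
            and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:] or "", alt[1:] or ""
        pos += 1
        if not ref or not alt:
            break
    return pos, ref, alt


def _three_letter(res: str) -> str:
    return protein_letters_1to3.get(res, res)


def call_coding_variant(
    model: GeneModel,
    ref: GenomeSlice,
    site: VariantSite,
    allele: str,
) -> ProteinVariantCall:
    """Call the protein-level consequence of one allele at a variant site.

    The allele is given on the plus strand (as in a VCF); for minus-strand
    genes it is reverse-complemented before codon substitution.  The
    reference allele yields a silent call.  Length-preserving multiple-of-3
    indels are classified ``inframe_indel`` (with the compact repeat label,
    e.g. L11ΔL, when a run of identical residues loses copies), all other
    indels ``frameshift``.
    """
    allele_l = allele.lower()
    if allele_l not in [a.lower() for a in site.alleles]:
        raise AlleleMismatchError(
            f"allele {allele!r} not among {site.alleles} at {site.site_id}")
    site.validate_against(ref)

    if site.site_class == "SNV":
        return _call_snv(model, ref, site, allele_l)
    return _call_indel(model, ref, site, allele_l)


def _call_snv(model, ref, site, allele):
    mapped = map_genomic_to_codon(model, site.pos)
    if mapped == NON_CODING:
        if site.pos in model.splice_flank_positions():
            return ProteinVariantCall(model.symbol, 0, "", "", "splice_site",
                                      label=f"splice:{model.symbol}:{site.pos}")
        raise ValueError(f"{site.site_id} is non-coding in {model.symbol}")
    aa_pos, offset = mapped
    spec = codon_spec(model, ref, aa_pos)
    coding_allele = allele if model.strand == "+" else allele.translate(_COMPLEMENT)
    alt_codon = (spec.ref_codon[: offset - 1] + coding_allele
                 + spec.ref_codon[offset:])
    ref_res = translate_codon(spec.ref_codon)
    alt_res = translate_codon(alt_codon)
    if alt_res == ref_res:
        consequence = "silent"
    elif alt_res == "*":
        consequence = "nonsense"
    else:
        consequence = "missense"
    call = ProteinVariantCall(model.symbol, aa_pos, ref_res, alt_res, consequence)
    return call


def _call_indel(model, ref, site, allele):
    pos, ref_a, alt_a = _trim_alleles(site.pos, site.ref_allele, allele)
    if ref_a.lower() == alt_a.lower():
        # the "allele" was the reference: silent at the first affected codon
        mapped = map_genomic_to_codon(model, pos)
        aa_pos = mapped[0] if mapped != NON_CODING else 0
        res = (translate_codon(codon_spec(model, ref, aa_pos).ref_codon)
               if mapped != NON_CODING else "")
        return ProteinVariantCall(model.symbol, aa_pos, res, res, "silent")

    net = len(alt_a) - len(ref_a)
    cds = _coding_cds(model, ref)

    # coding indices of the affected reference bases
    ref_span = [pos + k for k in range(len(ref_a))]
    coding_idx = sorted(
        model.coding_index(p) - model.cds_offset for p in ref_span
        if model.coding_index(p) is not None)
    if not coding_idx or coding_idx[0] < 0 or coding_idx[-1] >= len(cds):
        raise ValueError(f"indel {site.site_id} does not touch the CDS")
    c_lo, c_hi = coding_idx[0], coding_idx[-1]

    coding_ref = ref_a if model.strand == "+" else reverse_complement(ref_a)
    coding_alt = alt_a if model.strand == "+" else reverse_complement(alt_a)
    new_cds = cds[:c_lo] + coding_alt.lower() + cds[c_hi + 1:]

    # left-align on the coding strand: strip common prefix, then suffix
    old, new = cds.lower(), new_cds.lower()
    p = 0
    while p < min(len(old), len(new)) and old[p] == new[p]:
        p += 1
    s = 0
    while (s < min(len(old), len(new)) - p
           and old[len(old) - 1 - s] == new[len(new) - 1 - s]):
        s += 1

    first_codon = p // 3 + 1

    if net % 3 != 0:
        ref_res = translate_codon(cds[3 * (first_codon - 1): 3 * first_codon])
        return ProteinVariantCall(
            model.symbol, first_codon, ref_res, f"fs", "frameshift",
            label=f"{ref_res}{first_codon}fs",
            hgvs=f"p.({_three_letter(ref_res)}{first_codon}fs)")

    # in-frame: residues of the old and new CDS over the changed window
    start_codon = p // 3
    end_codon_old = (len(old) - s - 1) // 3 if len(old) - s > p else start_codon
    old_res = "".join(translate_codon(old[3 * c: 3 * c + 3])
                      for c in range(start_codon, end_codon_old + 1))
    end_codon_new = (len(new) - s - 1) // 3 if len(new) - s > p else start_codon - 1
    new_res = "".join(translate_codon(new[3 * c: 3 * c + 3])
                      for c in range(start_codon, end_codon_new + 1))

    aa_first = start_codon + 1
    aa_last = end_codon_old + 1

    if net < 0 and not new_res and len(set(old_res)) == 1:
        # clean deletion of whole codons from a homopolymeric residue run
        res = old_res[0]
        prev_res = (translate_codon(old[3 * (start_codon - 1): 3 * start_codon])
                    if start_codon > 0 else "")
        if prev_res == res:
            label = f"{res}{aa_last}Δ{res}"
            hgvs = (f"p.({_three_letter(res)}{aa_first - 1}_{aa_last}"
                    f"delins{_three_letter(res)})")
            return ProteinVariantCall(
                model.symbol, aa_last, res, f"Δ{res}", "inframe_indel",
                label=label, hgvs=hgvs)
        label = f"{res}{aa_first}del" if len(old_res) == 1 else \
            f"{res}{aa_first}_{res}{aa_last}del"
        return ProteinVariantCall(
            model.symbol, aa_first, old_res, f"Δ{old_res}", "inframe_indel",
            label=label, hgvs=f"p.({_three_letter(res)}{aa_first}del)")

    label = f"{old_res}{aa_first}delins{new_res or '-'}"
    hgvs = (f"p.({_three_letter(old_res[0])}{aa_first}_{aa_last}"
            f"delins{''.join(_three_letter(r) for r in new_res) or 'del'})")
    return ProteinVariantCall(
        model.symbol, aa_first, old_res, f"Δ{old_res}" if not new_res else new_res,
        "inframe_indel", label=label, hgvs=hgvs)


# ---------------------------------------------------------------------------
# Known-variant catalogue
# ---------------------------------------------------------------------------

_CATALOG_VARIANT_RE = re.compile(
    r"^(?P<ref>[A-Z])(?P<pos>\d+)(?P<alt>[A-Z]|stop|Δ\w+|=)$")


@dataclass(frozen=True)
class CatalogMatch:
    """Result of looking a call up in the known-variant catalogue."""

    novel: bool
    phenotype: str = ""
    breeds: str = ""
    source: str = ""


def parse_catalog_variant(variant: str) -> Optional[tuple[int, str]]:
    """Parse a catalogue variant label like R87H, Q239stop, W154Δ17, L11ΔL.

    Returns (aa_pos, alt token) with stop normalised to '*'; None when the
    label is not in recognisable form.
    """
    m = _CATALOG_VARIANT_RE.match(variant.strip())
    if not m:
        return None
    alt = m.group("alt")
    if alt == "stop":
        alt = "*"
    return int(m.group("pos")), alt


def match_known_catalog(call: ProteinVariantCall, catalog: pd.DataFrame) -> CatalogMatch:
    """Match a call against the known coding-variant catalogue.

    The catalogue is a table with columns ``gene, variant, phenotype, breeds,
    source`` keyed by (gene, aa_pos, alt residue token); anything without an
    exact key match is reported novel.
    """
    key = (call.gene, call.aa_pos, call.alt_residue)
    for row in catalog.itertuples(index=False):
        if row.gene != call.gene:
            continue
        parsed = parse_catalog_variant(str(row.variant))
        if parsed is None:
            continue
        if (call.gene, parsed[0], parsed[1]) == key:
            return CatalogMatch(False, str(row.phenotype), str(row.breeds),
                                str(row.source))
    return CatalogMatch(True)


# ---------------------------------------------------------------------------
# On-disk formats: BED12-like exon file + sidecar TSV, FASTA slices
# ---------------------------------------------------------------------------


def read_gene_models(bed_path, sidecar_path) -> dict[str, GeneModel]:
    """Read gene models from a BED12-like file plus a sidecar TSV.

    The BED file carries chrom, chromStart (0-based), chromEnd, name, score,
    strand, and block columns; the sidecar TSV carries symbol, strand,
    cds_offset, protein_length, protein_id.
    """
    side = pd.read_csv(sidecar_path, sep="\t", dtype=str)
    side = side.set_index("symbol")
    models = {}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes))
            row = side.loc[name]
            models[name] = GeneModel(
                symbol=name, chrom=chrom, strand=strand, exons=exons,
                cds_offset=int(row["cds_offset"]),
                protein_length=int(row["protein_length"]),
                protein_id=str(row["protein_id"]))
    return models


def write_gene_models(models: Mapping[str, GeneModel], bed_path, sidecar_path) -> None:
    rows = []
    with open(bed_path, "w") as fh:
        for name in sorted(models):
            m = models[name]
            chrom_start = m.exons[0][0] - 1
            chrom_end = m.exons[-1][1]
            sizes = ",".join(str(e - s + 1) for s, e in m.exons)
            starts = ",".join(str(s - 1 - chrom_start) for s, _ in m.exons)
            fh.write("\t".join(map(str, [
                m.chrom, chrom_start, chrom_end, name, 0, m.strand,
                chrom_start, chrom_end, "0", len(m.exons), sizes, starts,
            ])) + "\n")
            rows.append((name, m.strand, m.cds_offset, m.protein_length,
                         m.protein_id))
    pd.DataFrame(rows, columns=["symbol", "strand", "cds_offset",
                                "protein_length", "protein_id"]) \
        .to_csv(sidecar_path, sep="\t", index=False)


def read_slices(fasta_path) -> dict[str, GenomeSlice]:
    """Read reference slices from FASTA with headers formatted 'chrom:start'."""
    from Bio import SeqIO

    slices = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        chrom, start = rec.id.rsplit(":", 1)
        slices[chrom] = GenomeSlice(chrom, int(start), str(rec.seq))
    return slices


def write_slices(slices: Iterable[GenomeSlice], fasta_path) -> None:
    with open(fasta_path, "w") as fh:
        for sl in slices:
            fh.write(f">{sl.chrom}:{sl.start}\n")
            for i in range(0, len(sl.seq), 70):
                fh.write(sl.seq[i : i + 70] + "\n")
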