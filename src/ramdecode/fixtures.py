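"""Packaged study fixtures.

The raw WGS data behind the 96-ram diversity panel is tens of terabytes and
lives in a sequence archive; everything this package needs from it is carried
here as small text fixtures instead:

* the nine coding variant sites with their printed flanking sequences,
* gene models for GDF9 / BMP15 / BMPR1B consistent with the printed
  positions, exon numbers and codons,
* the breed panel (96 rams, 11 breed groups, all male),
* per-breed protein-variant frequencies and the haplotype pairings that
  realise them exactly (integer chromosome counts),
* the catalogue of previously reported fecundity variants,
* outgroup residue profiles for tree rooting, and a synthetic ortholog
  alignment emulating the cross-species conservation comparison.

Reference genome slices are rebuilt deterministically at load time: exons are
filled with neutral filler sequence and the printed coding-strand flanking
sequences are embedded (reverse-complemented) around each variant position.
Overlapping embeddings are asserted to agree.  The T345N neighbourhood is
synthetic filler (its printed flank is corrupt) constrained to the ACT/AAT
threonine/asparagine codon.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Mapping

import pandas as pd

from .gene_models import (
    GeneModel,
    GenomeSlice,
    VariantSite,
    codon_spec,
    read_gene_models,
    reverse_complement,
    translate_codon,
)
from .genotype_io import BreedPanel, GenotypeMatrix, PloidyModel

_COMPLEMENT = str.maketrans("acgtACGT", "tgcaTGCA")

GENES = ("GDF9", "BMP15", "BMPR1B")

#: Nested-clade ladder used for the conservation analysis, narrowest first.
CLADE_LADDER = (
    "Artiodactyla", "Laurasiatheria", "Eutheria", "Theria",
    "Mammalia", "Tetrapoda", "Vertebrata",
)

#: Estimated time to most recent common ancestor per clade (million years).
CLADE_TMRCA = {
    "Artiodactyla": 62, "Laurasiatheria": 76, "Eutheria": 105, "Theria": 159,
    "Mammalia": 177, "Tetrapoda": 352, "Vertebrata": 615,
}

#: Representative species and the narrowest ladder clade that contains them
#: (29 species, emulating the breadth of a vertebrate ortholog comparison).
SPECIES_CLADES = {
    "cattle": "Artiodactyla", "goat": "Artiodactyla", "pig": "Artiodactyla",
    "bison": "Artiodactyla",
    "horse": "Laurasiatheria", "dog": "Laurasiatheria", "cat": "Laurasiatheria",
    "microbat": "Laurasiatheria", "hedgehog": "Laurasiatheria",
    "human": "Eutheria", "chimpanzee": "Eutheria", "mouse": "Eutheria",
    "rat": "Eutheria", "rabbit": "Eutheria", "elephant": "Eutheria",
    "manatee": "Eutheria", "armadillo": "Eutheria",
    "opossum": "Theria", "tasmanian_devil": "Theria", "wallaby": "Theria",
    "platypus": "Mammalia",
    "chicken": "Tetrapoda", "zebra_finch": "Tetrapoda", "anole": "Tetrapoda",
    "painted_turtle": "Tetrapoda", "clawed_frog": "Tetrapoda",
    "zebrafish": "Vertebrata", "coelacanth": "Vertebrata",
    "spotted_gar": "Vertebrata",
}


def _read_data(name: str) -> pd.DataFrame:
    with resources.files("ramdecode.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def sites_table() -> pd.DataFrame:
    df = _read_data("sites.tsv")
    df["pos"] = df["pos"].astype(int)
    df["pos_published"] = df["pos_published"].astype(int)
    df["aa_pos"] = df["aa_pos"].astype(int)
    df["maf_published"] = df["maf_published"].astype(float)
    return df


def variant_sites() -> list[VariantSite]:
    return [
        VariantSite(r.chrom, r.pos, r.ref, (r.alt,),
                    site_id=f"{r.gene}:{r.label}")
        for r in sites_table().itertuples(index=False)
    ]


def catalog(reported_prior_only: bool = True) -> pd.DataFrame:
    """The known fecundity-variant catalogue.

    By default only previously reported variants are included, so that the
    four variants first seen in this panel come back as novel when matched.
    """
    df = _read_data("catalog.tsv")
    if reported_prior_only:
        df = df[df["reported_prior"] == "yes"].reset_index(drop=True)
    return df[["gene", "variant", "phenotype", "breeds", "source"]]


@lru_cache(maxsize=None)
def gene_models() -> dict[str, GeneModel]:
    data = resources.files("ramdecode.data")
    with resources.as_file(data.joinpath("gene_exons.bed")) as bed, \
            resources.as_file(data.joinpath("gene_models.tsv")) as side:
        return read_gene_models(bed, side)


def breed_table() -> pd.DataFrame:
    df = _read_data("breeds.tsv")
    df["n"] = df["n"].astype(int)
    return df


def breed_panel() -> BreedPanel:
    """The default 96-ram panel: 11 breed groups, all male."""
    rows = []
    for r in breed_table().itertuples(index=False):
        for i in range(1, r.n + 1):
            rows.append((f"{r.code}{i:02d}", r.breed, r.sex))
    return BreedPanel(pd.DataFrame(rows, columns=["animal_id", "breed", "sex"]))


def breed_frequencies() -> pd.DataFrame:
    df = _read_data("breed_freqs.tsv")
    df["freq"] = df["freq"].astype(float)
    return df


def haplotype_table() -> pd.DataFrame:
    df = _read_data("haplotypes.tsv")
    df["freq"] = df["freq"].astype(float)
    return df


def gene_positions(gene: str) -> list[int]:
    """Variant amino-acid positions of a gene, ascending."""
    st = sites_table()
    return sorted(st.loc[st["gene"] == gene, "aa_pos"])


def haplotype_vectors(gene: str) -> dict[str, tuple[str, ...]]:
    """variant code -> residue vector over the gene's variant positions."""
    ht = haplotype_table()
    out = {}
    for r in ht[ht["gene"] == gene].itertuples(index=False):
        out[r.variant] = tuple(r.residues.split(","))
    return out


def outgroup_profiles() -> dict[str, tuple[str, ...]]:
    df = _read_data("outgroups.tsv")
    return {r.gene: tuple(r.residues.split(",")) for r in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# Reference slices
# ---------------------------------------------------------------------------

_FILLER = "gca"  # no stop codon in any frame


@lru_cache(maxsize=None)
def reference_slices() -> dict[str, GenomeSlice]:
    """Rebuild plus-strand reference slices around the three genes."""
    models = gene_models()
    st = sites_table()
    slices: dict[str, GenomeSlice] = {}
    for model in models.values():
        lo, hi = model.span
        lo, hi = lo - 120, hi + 120
        n = hi - lo + 1
        seq = list((_FILLER * (n // 3 + 1))[:n])
        written: dict[int, str] = {}

        def put(pos: int, base: str) -> None:
            if pos in written and written[pos] != base:
                raise AssertionError(
                    f"conflicting embeddings at {model.chrom}:{pos}: "
                    f"{written[pos]} vs {base}")
            written[pos] = base
            seq[pos - lo] = base

        rows = st[(st["gene"] == model.symbol) & (st["flank_source"] == "published")]
        for r in rows.itertuples(index=False):
            coding_ref = (r.ref if model.strand == "+"
                          else reverse_complement(r.ref))
            segment = r.flank5 + coding_ref + r.flank3
            plus = segment if model.strand == "+" else reverse_complement(segment)
            # the plus-strand segment covers [pos - len(flank_after), ...]
            if model.strand == "+":
                start = r.pos - len(r.flank5)
            else:
                start = r.pos - len(r.flank3)
            for k, b in enumerate(plus):
                put(start + k, b)
        sl = GenomeSlice(model.chrom, lo, "".join(seq))

        # synthetic neighbourhoods: force the reference codon at sites whose
        # printed flank is unusable
        synth = st[(st["gene"] == model.symbol) & (st["flank_source"] != "published")]
        if len(synth):
            seq2 = list(sl.seq)
            for r in synth.itertuples(index=False):
                ref_codon = _codon_for_residue(r.ref_res, r.var_res)
                base_idx = model.cds_offset + 3 * (r.aa_pos - 1)
                for k in range(3):
                    gpos = model.genomic_position(base_idx + k)
                    b = ref_codon[k]
                    seq2[gpos - lo] = (b if model.strand == "+"
                                       else b.translate(_COMPLEMENT))
            sl = GenomeSlice(model.chrom, lo, "".join(seq2))
        slices[model.chrom] = sl

    # consistency: every site's ref allele and ref residue must check out
    for site, row in zip(variant_sites(), sites_table().itertuples(index=False)):
        model = models[row.gene]
        sl = slices[site.chrom]
        site.validate_against(sl)
        if site.site_class == "SNV":
            spec = codon_spec(model, sl, row.aa_pos)
            assert translate_codon(spec.ref_codon) == row.ref_res, row.label
    return slices


def _codon_for_residue(ref_res: str, var_res: str) -> str:
    """A codon pair differing at one base: currently only T345N needs this."""
    if (ref_res, var_res) == ("T", "N"):
        return "act"  # middle c->a gives aat = N
    raise NotImplementedError(f"no synthetic codon rule for {ref_res}->{var_res}")


# ---------------------------------------------------------------------------
# The study panel: genotypes exactly consistent with the printed tables
# ---------------------------------------------------------------------------


def residue_to_allele(gene: str) -> dict[tuple[int, str], str]:
    """(aa_pos, residue token) -> plus-strand allele for each variant site."""
    st = sites_table()
    out = {}
    for r in st[st["gene"] == gene].itertuples(index=False):
        out[(r.aa_pos, r.ref_res)] = r.ref
        out[(r.aa_pos, r.var_res)] = r.alt
    return out


def study_haplotype_assignments() -> dict[str, dict[str, tuple[str, ...]]]:
    """gene -> animal -> assigned haplotype codes (2 autosomal, 1 on X).

    Pairings are expanded in fixture order and dealt to animals in id order
    within breed, so the assignment is deterministic.
    """
    panel = breed_panel()
    pairings = _read_data("pairings.tsv")
    pairings["count"] = pairings["count"].astype(int)
    by_breed: dict[str, list[str]] = {}
    for r in panel.table.itertuples(index=False):
        by_breed.setdefault(r.breed, []).append(r.animal_id)

    out: dict[str, dict[str, tuple[str, ...]]] = {g: {} for g in GENES}
    for gene in GENES:
        rows = pairings[pairings["gene"] == gene]
        for breed, animals in by_breed.items():
            expanded: list[tuple[str, ...]] = []
            for r in rows[rows["breed"] == breed].itertuples(index=False):
                pair = (r.hap_a,) if r.hap_b == "." else (r.hap_a, r.hap_b)
                expanded.extend([pair] * r.count)
            if len(expanded) != len(animals):
                raise AssertionError(
                    f"{gene}/{breed}: {len(expanded)} pairings for "
                    f"{len(animals)} animals")
            for animal, pair in zip(animals, expanded):
                out[gene][animal] = pair
    return out


def study_panel() -> tuple[BreedPanel, GenotypeMatrix, dict[str, dict[str, tuple]]]:
    """Build the 96-ram genotype matrix realising Tables 1/3/4 exactly.

    Returns (panel, matrix, truth) where truth maps gene -> animal -> tuple of
    haplotype residue vectors (the known phase used to construct genotypes).
    """
    panel = breed_panel()
    sites = variant_sites()
    st = sites_table()
    matrix = GenotypeMatrix(sites, panel.animals, panel=panel, ploidy=PloidyModel())
    assignments = study_haplotype_assignments()

    truth: dict[str, dict[str, tuple]] = {g: {} for g in GENES}
    for gene in GENES:
        vectors = haplotype_vectors(gene)
        positions = gene_positions(gene)
        allele_of = residue_to_allele(gene)
        site_ids = [f"{gene}:{r.label}" for r in
                    st[st["gene"] == gene].itertuples(index=False)]
        pos_order = [r.aa_pos for r in
                     st[st["gene"] == gene].itertuples(index=False)]
        for animal, codes in assignments[gene].items():
            haps = tuple(vectors[c] for c in codes)
            truth[gene][animal] = haps
            for site_id, aa_pos in zip(site_ids, pos_order):
                k = positions.index(aa_pos)
                alleles = [allele_of[(aa_pos, h[k])] for h in haps]
                matrix.set(animal, site_id, alleles)
    return panel, matrix, truth


# ---------------------------------------------------------------------------
# Synthetic ortholog alignment (conservation fixture)
# ---------------------------------------------------------------------------

#: Per-column conservation structure emulated by the ortholog fixture:
#: (gene, aa_pos) -> (sheep reference residue, deepest strictly conserved
#: clade, exception species inside deeper clades -> their residue,
#: species carrying the sheep *variant* residue).
CONSERVATION_SPEC: Mapping[tuple[str, int], tuple[str, str, dict, tuple]] = {
    ("GDF9", 87): ("R", "Artiodactyla", {}, ()),
    ("GDF9", 241): ("E", "Artiodactyla", {}, ()),
    ("GDF9", 332): ("V", "Artiodactyla", {}, ()),
    ("GDF9", 371): ("V", "Eutheria", {}, ()),
    ("BMP15", 11): ("L", "Laurasiatheria", {}, ()),
    ("BMP15", 67): ("R", "Laurasiatheria", {},
                    ("elephant", "manatee", "rabbit")),
    ("BMP15", 252): ("L", "Laurasiatheria", {}, ()),
    ("BMPR1B", 64): ("M", "Theria",
                     {"human": "V", "manatee": "V", "armadillo": "L"}, ()),
    ("BMPR1B", 345): ("T", "Tetrapoda", {}, ()),
}


def ortholog_fixture():
    """Synthetic cross-species residue profiles for the nine variant columns.

    Built by :func:`ramdecode.synthetic_data.generate_ortholog_set` from
    :data:`CONSERVATION_SPEC`; stands in for a curated alignment of real
    ortholog sequences, which is not shipped.
    """
    from .synthetic_data import generate_ortholog_set

    st = sites_table()
    var_res = {(r.gene, r.aa_pos): r.var_res for r in st.itertuples(index=False)}
    columns = {}
    for (gene, aa_pos), (ref, depth, exceptions, carriers) in \
            CONSERVATION_SPEC.items():
        columns[f"{gene}:{aa_pos}"] = {
            "reference_residue": ref,
            "conserved_through": depth,
            "exceptions": exceptions,
            "variant_residue": var_res[(gene, aa_pos)],
            "variant_carriers": carriers,
        }
    return generate_ortholog_set(
        species_clades=SPECIES_CLADES, ladder=CLADE_LADDER, columns=columns,
        seed=20170802)
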