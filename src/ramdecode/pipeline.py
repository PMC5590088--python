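"""End-to-end pipeline orchestration.

Runs the decode stages in order — consequence calling, phasing, tree
building and rooting, frequency estimation, conservation classification —
over a genotype matrix, and wraps the QC and simulation stages.  Every
exclusion (missing data, unresolved phase) is logged with the animal id and
reason.  All stages are deterministic under a fixed seed and configuration.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import fixtures
from .conservation import classify_column
from .frequencies import (
    FrequencyTable,
    haplotype_frequencies,
    maf_consistency_check,
    site_maf,
)
from .gene_models import call_coding_variant, codon_spec, match_known_catalog
from .genotype_io import (
    BreedPanel,
    GenotypeMatrix,
    PloidyModel,
    read_genotypes,
    round_half_up,
    write_tables,
    write_vcf,
)
from .haplotyping import (
    IncompleteDataError,
    ParsimonyTree,
    PhasedIndividual,
    build_parsimony_tree,
    infer_ambiguous_phase,
    phase_unambiguous,
    root_tree,
)
from .wgs_qc import build_report

logger = logging.getLogger("ramdecode")

EXIT_OK, EXIT_CONFIG_ERROR, EXIT_DATA_ERROR = 0, 2, 3


class ConfigError(ValueError):
    """Invalid run configuration (missing paths, bad parameters)."""


@dataclass
class RunConfig:
    """Configuration for a pipeline run."""

    outdir: Path = Path("ramdecode_out")
    seed: int = 0
    min_depth: int = 3
    rounding: int = 3
    frequency_tiebreak: bool = True
    n_per_breed: Optional[int] = None
    vcf: Optional[Path] = None
    panel: Optional[Path] = None
    truth: Optional[Path] = None
    array: Optional[Path] = None

    def require(self, *names: str) -> None:
        for name in names:
            path = getattr(self, name)
            if path is None:
                raise ConfigError(f"missing required input: --{name}")
            if not Path(path).exists():
                raise ConfigError(f"input path does not exist: {path}")


@dataclass
class DecodeResult:
    """Everything the decode stage produces."""

    site_table: pd.DataFrame            # Table-1 analog (per-site MAF)
    variant_table: pd.DataFrame         # Table-3 analog (panel-wide)
    breed_table: pd.DataFrame           # Table-4 analog (per breed group)
    phased: dict[str, list[PhasedIndividual]]
    trees: dict[str, ParsimonyTree]
    hap_tables: dict[str, FrequencyTable]
    consistency: pd.DataFrame
    conservation: pd.DataFrame
    exclusions: list[tuple[str, str, str]]  # (animal, gene, reason)


def _gene_of(site, models) -> str:
    """Assign a variant site to the gene whose exon span contains it."""
    for name, m in models.items():
        lo, hi = m.span
        if m.chrom == site.chrom and lo <= site.pos <= hi:
            return name
    raise ValueError(f"site {site.site_id} is not inside any gene model")


def residue_maps(models=None, slices=None, sites=None):
    """Per gene: site ids, aa positions, and allele -> residue-token maps.

    Derived by running the consequence caller on every site allele, so the
    residue alphabet is the caller's output, not a lookup table.
    """
    models = models or fixtures.gene_models()
    slices = slices or fixtures.reference_slices()
    sites = sites if sites is not None else fixtures.variant_sites()
    out: dict[str, dict] = {}
    for site in sites:
        gene = _gene_of(site, models)
        model = models[gene]
        entry = out.setdefault(gene, {"site_ids": [], "aa_pos": [],
                                      "allele_res": {}, "calls": {}})
        ref_call = call_coding_variant(model, slices[site.chrom], site,
                                       site.ref_allele)
        amap = {site.ref_allele.lower(): ref_call.ref_residue}
        for alt in site.alt_alleles:
            call = call_coding_variant(model, slices[site.chrom], site, alt)
            amap[alt.lower()] = call.alt_residue
            entry["calls"][site.site_id] = call
        entry["site_ids"].append(site.site_id)
        entry["aa_pos"].append(
            entry["calls"][site.site_id].aa_pos)
        entry["allele_res"][site.site_id] = amap
    return out


def phase_gene(
    matrix: GenotypeMatrix,
    gene: str,
    rmap: Mapping,
    frequency_tiebreak: bool = True,
) -> tuple[list[PhasedIndividual], list[tuple[str, str, str]]]:
    """Phase every animal at one gene, grouping identical genotype patterns.

    Two passes: the unambiguous rule first, whose haplotype counts define the
    known set (with frequencies) that the parsimony rule then uses for the
    multi-heterozygous patterns.  Returns (phased individuals, exclusions).
    """
    site_ids = rmap["site_ids"]
    allele_res = rmap["allele_res"]

    patterns: dict[tuple, list[str]] = {}
    exclusions: list[tuple[str, str, str]] = []
    for animal in matrix.animals:
        geno = []
        complete = True
        for sid in site_ids:
            cell = matrix.get(animal, sid)
            if cell is None:
                exclusions.append((animal, gene, f"missing call at {sid}"))
                complete = False
                break
            geno.append(tuple(sorted(allele_res[sid][a] for a in cell)))
        if complete:
            patterns.setdefault(tuple(geno), []).append(animal)

    phased: list[PhasedIndividual] = []
    ambiguous: list[tuple[tuple, list[str]]] = []
    known: Counter = Counter()
    for geno, animals in sorted(patterns.items()):
        result = phase_unambiguous(animals[0], gene, list(geno))
        if result is None:
            ambiguous.append((geno, animals))
            continue
        for animal in animals:
            phased.append(PhasedIndividual(animal, gene, result.haplotypes,
                                           result.status))
        known.update({h: len(animals) for h in result.haplotypes})
        if len(result.haplotypes) == 2 and \
                result.haplotypes[0] == result.haplotypes[1]:
            known[result.haplotypes[0]] += len(animals)  # second copy

    # counts -> frequencies for the tie-break
    total = sum(known.values()) or 1
    known_freq = {h: c / total for h, c in known.items()}
    for geno, animals in ambiguous:
        result = infer_ambiguous_phase(animals[0], gene, list(geno),
                                       known_freq,
                                       frequency_tiebreak=frequency_tiebreak)
        for animal in animals:
            phased.append(PhasedIndividual(animal, gene, result.haplotypes,
                                           result.status))
            if result.status == "unresolved":
                exclusions.append((animal, gene, "unresolved phase"))
    order = {a: i for i, a in enumerate(matrix.animals)}
    phased.sort(key=lambda p: order[p.animal])
    return phased, exclusions


def decode_panel(
    matrix: GenotypeMatrix,
    panel: BreedPanel,
    rounding: int = 3,
    frequency_tiebreak: bool = True,
    with_conservation: bool = True,
) -> DecodeResult:
    """Run the full decode: call -> phase -> tree -> root -> frequencies ->
    conservation."""
    if not matrix.animals:
        empty = pd.DataFrame()
        return DecodeResult(
            pd.DataFrame(columns=["gene", "codon_variant", "position",
                                  "codon", "consequence", "major_allele",
                                  "maf", "novel", "phenotype"]),
            pd.DataFrame(columns=["gene", "variant", "residues", "count",
                                  "denominator", "frequency"]),
            pd.DataFrame(columns=["breed_group", "n"]),
            {}, {}, {}, empty, empty, [])

    models = fixtures.gene_models()
    slices = fixtures.reference_slices()
    catalog = fixtures.catalog()
    outgroups = fixtures.outgroup_profiles()
    rmaps = residue_maps(models, slices, matrix.sites)

    # --- stage 1: per-site calls and MAFs (Table-1 analog) ---
    site_rows = []
    for site in matrix.sites:
        gene = _gene_of(site, models)
        call = rmaps[gene]["calls"][site.site_id]
        model = models[gene]
        maf = site_maf(matrix, site.site_id)
        known = match_known_catalog(call, catalog)
        if site.site_class == "SNV":
            codon = codon_spec(model, slices[site.chrom], call.aa_pos).ref_codon
        else:
            codon = "indel"
        site_rows.append({
            "gene": gene,
            "codon_variant": call.label,
            "position": f"{site.chrom}:{site.pos}",
            "codon": codon,
            "consequence": call.consequence,
            "major_allele": maf["major_allele"],
            "maf": maf["maf"],
            "novel": known.novel,
            "phenotype": "" if known.novel else known.phenotype,
        })
    site_table = pd.DataFrame(site_rows)

    # --- stages 2-4: phasing, trees, rooting ---
    phased: dict[str, list[PhasedIndividual]] = {}
    trees: dict[str, ParsimonyTree] = {}
    hap_tables: dict[str, FrequencyTable] = {}
    exclusions: list[tuple[str, str, str]] = []
    variant_frames = []
    genes = [g for g in fixtures.GENES if g in rmaps] or sorted(rmaps)
    for gene in genes:
        ph, excl = phase_gene(matrix, gene, rmaps[gene], frequency_tiebreak)
        phased[gene] = ph
        exclusions.extend(excl)
        for animal, g, reason in excl:
            logger.info("excluded %s at %s: %s", animal, g, reason)
        counts: Counter = Counter()
        for ind in ph:
            if ind.status != "unresolved":
                counts.update(ind.haplotypes)
        tree = build_parsimony_tree(counts, gene)
        trees[gene] = root_tree(tree, outgroups[gene]) if gene in outgroups \
            else tree
        ft = haplotype_frequencies(ph, panel, by_breed=True)
        hap_tables[gene] = ft
        variant_frames.append(ft.table[["gene", "variant", "residues",
                                        "count", "denominator", "frequency"]])
    variant_table = pd.concat(variant_frames, ignore_index=True)

    # --- stage 5: per-breed table (Table-4 analog) ---
    breed_rows = []
    breed_sizes = panel.breed_counts()
    for breed in dict.fromkeys(panel.table["breed"]):
        row: dict = {"breed_group": breed, "n": breed_sizes[breed]}
        for gene in genes:
            df = hap_tables[gene].table
            for _, r in df.iterrows():
                count = r[f"{breed}_count"] if f"{breed}_count" in df.columns else 0
                label = f"{gene}_v{r['variant']}"
                row[label] = ("-" if count == 0
                              else f"{round_half_up(r[breed], 2):.2f}")
        breed_rows.append(row)
    breed_table = pd.DataFrame(breed_rows)

    # --- consistency: site MAFs vs summed carrier-haplotype frequencies ---
    cons_frames = []
    for gene in genes:
        rmap = rmaps[gene]
        ft = hap_tables[gene]
        site_mafs = {sid: site_maf(matrix, sid)["maf"]
                     for sid in rmap["site_ids"]}
        carriers: dict[str, list[int]] = {}
        vectors = {r.variant: tuple(r.residues.split(","))
                   for r in ft.table.itertuples(index=False)}
        for k, sid in enumerate(rmap["site_ids"]):
            call = rmap["calls"][sid]
            var_token = call.alt_residue
            carriers[sid] = [v for v, vec in vectors.items()
                             if vec[k] == var_token]
        cons_frames.append(maf_consistency_check(site_mafs, ft, carriers))
    consistency = pd.concat(cons_frames, ignore_index=True)

    # --- stage 6: conservation classification ---
    conservation = pd.DataFrame()
    if with_conservation:
        orthologs = fixtures.ortholog_fixture()
        rows = []
        for gene in genes:
            rmap = rmaps[gene]
            for sid in rmap["site_ids"]:
                call = rmap["calls"][sid]
                cc = classify_column(orthologs, gene, call.aa_pos,
                                     call.ref_residue, call.alt_residue)
                rows.append({
                    "gene": gene,
                    "aa_pos": call.aa_pos,
                    "ref_residue": cc.ref_residue,
                    "variant_residue": cc.variant_residue,
                    "conserved_through": cc.deepest_clade or "none",
                    "conserved_with_exceptions": cc.deepest_clade_tolerant or "none",
                    "exception_species": ";".join(cc.exceptions),
                    "variant_seen_elsewhere": cc.variant_seen_elsewhere,
                    "variant_species": ";".join(cc.variant_species),
                })
        conservation = pd.DataFrame(rows)

    return DecodeResult(site_table, variant_table, breed_table, phased,
                        trees, hap_tables, consistency, conservation,
                        exclusions)


# ---------------------------------------------------------------------------
# Top-level runs
# ---------------------------------------------------------------------------


def run_decode(config: RunConfig) -> DecodeResult:
    """Decode a panel from disk (or the packaged study panel) and write the
    table analogs, Newick trees and conservation calls to the output
    directory."""
    ploidy = PloidyModel()
    if config.vcf is not None:
        config.require("vcf", "panel")
        panel = BreedPanel.read_tsv(config.panel)
        matrix = read_genotypes(config.vcf, panel, ploidy)
    else:
        panel, matrix, _ = fixtures.study_panel()
    result = decode_panel(matrix, panel, rounding=config.rounding,
                          frequency_tiebreak=config.frequency_tiebreak)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tables(
        {"table1_sites": result.site_table,
         "table3_variants": result.variant_table,
         "table4_by_breed": result.breed_table,
         "consistency": result.consistency,
         "conservation": result.conservation},
        outdir,
        decimals={"table1_sites": 3, "table3_variants": 3,
                  "table4_by_breed": 2})
    for gene, tree in result.trees.items():
        (outdir / f"{gene}_tree.nwk").write_text(tree.to_newick() + "\n")
        tree.node_table().to_csv(outdir / f"{gene}_tree_nodes.tsv",
                                 sep="\t", index=False)
    excl = pd.DataFrame(result.exclusions,
                        columns=["animal", "gene", "reason"])
    excl.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    return result


def run_qc(config: RunConfig):
    """QC a WGS genotype set against reference/array genotypes."""
    from .genotype_io import read_reference_genotypes

    config.require("vcf", "panel", "truth")
    panel = BreedPanel.read_tsv(config.panel)
    matrix = read_genotypes(config.vcf, panel)
    wgs = {}
    for animal in matrix.animals:
        for sid in matrix.site_ids:
            cell = matrix.get(animal, sid)
            if cell is not None:
                wgs[(animal, sid)] = cell
    truth = dict(read_reference_genotypes(config.truth).items())
    array = None
    if config.array is not None:
        array = dict(read_reference_genotypes(config.array).items())
    report = build_report(wgs, truth, array=array, depths=matrix.depths,
                          min_depth=config.min_depth)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tables({"qc_report": report.per_animal}, outdir,
                 decimals={"qc_report": 3})
    pd.Series(report.panel).to_csv(outdir / "qc_panel.tsv", sep="\t",
                                   header=False)
    return report


def run_simulate(config: RunConfig):
    """Generate a synthetic panel on disk (VCF + panel TSV + manifest)."""
    from .synthetic_data import (
        default_panel_spec,
        generate_panel,
        simulate_depth_and_calls,
    )

    spec = default_panel_spec(n_per_breed=config.n_per_breed,
                              seed=config.seed)
    panel, truth_matrix, truth = generate_panel(spec)
    observed = simulate_depth_and_calls(truth_matrix, spec.depth,
                                        min_depth=config.min_depth,
                                        seed=config.seed + 1)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel.write_tsv(outdir / "panel.tsv")
    write_vcf(observed, outdir / "genotypes.vcf")
    rows = []
    for gene, by_animal in truth.items():
        for animal, haps in by_animal.items():
            for h in haps:
                rows.append((animal, gene, ",".join(h)))
    pd.DataFrame(rows, columns=["animal_id", "gene", "haplotype"]) \
        .to_csv(outdir / "truth_haplotypes.tsv", sep="\t", index=False)
    manifest = {
        "seed": config.seed,
        "min_depth": config.min_depth,
        "n_animals": len(panel),
        "depth_location": spec.depth.location,
        "depth_spread": spec.depth.spread,
    }
    import yaml

    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return panel, observed
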