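"""Synthetic panels with the statistical structure of the study data.

The generator emulates a breed-structured diversity panel genotyped by WGS:

* haplotypes are drawn independently within breed (Hardy–Weinberg within
  breed, no inbreeding — the panel's rams were chosen to minimise their
  relationships, making independence the natural null);
* autosomal genes receive two haplotypes per animal, X-linked genes one per
  male;
* per-cell read depth follows a rounded normal truncated at 1 (location
  16.8, spread 3.5 by default — the coverage regime of a ~40 GB short-read
  genome);
* genotype errors arise by *allele dropout*: at a heterozygous cell with
  depth d each read carries either allele with probability 1/2, the call is
  heterozygous only if both alleles were seen, and cells with depth below
  the scoring threshold (3 reads) are missing.  Reads carry no base-call
  error by default (a miscall rate parameter exists but defaults to 0).

Everything is reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import BreedPanel, GenotypeMatrix, PloidyModel

__all__ = [
    "DepthModel",
    "GeneSpec",
    "PanelSpec",
    "default_panel_spec",
    "generate_panel",
    "simulate_depth_and_calls",
    "analytic_het_dropout",
    "generate_reference_truth",
    "generate_ortholog_set",
]


@dataclass(frozen=True)
class DepthModel:
    """Read-depth distribution: rounded normal truncated at ``minimum``."""

    location: float = 16.8
    spread: float = 3.5
    minimum: int = 1

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        x = rng.normal(self.location, self.spread, size=size)
        out = np.floor(x + 0.5)
        bad = out < self.minimum
        while bad.any():
            x = rng.normal(self.location, self.spread, size=int(bad.sum()))
            out[bad] = np.floor(x + 0.5)
            bad = out < self.minimum
        return out.astype(int)

    def pmf(self, max_depth: int = 200) -> tuple[np.ndarray, np.ndarray]:
        """Probability mass of each integer depth (normalised over >= minimum)."""
        from scipy.stats import norm

        d = np.arange(self.minimum, max_depth + 1)
        p = (norm.cdf(d + 0.5, self.location, self.spread)
             - norm.cdf(d - 0.5, self.location, self.spread))
        return d, p / p.sum()


@dataclass(frozen=True)
class GeneSpec:
    """One gene's variant structure for the generator."""

    gene: str
    chrom: str
    site_ids: tuple[str, ...]
    vectors: Mapping[str, tuple[str, ...]]  # variant code -> residue vector
    allele_map: Mapping[tuple[int, str], str]  # (position index, residue) -> allele
    breed_freqs: Mapping[str, Mapping[str, float]]  # breed -> code -> freq


@dataclass(frozen=True)
class PanelSpec:
    """Full specification of a synthetic panel."""

    breeds: tuple[tuple[str, int, str], ...]  # (breed, size, sex)
    genes: Mapping[str, GeneSpec]
    depth: DepthModel = DepthModel()
    miscall_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for breed, size, _ in self.breeds:
            if size < 0:
                raise ValueError(f"negative size for breed {breed}")
        for gs in self.genes.values():
            for breed, freqs in gs.breed_freqs.items():
                total = sum(freqs.values())
                if freqs and abs(total - 1.0) > 1e-6:
                    raise ValueError(
                        f"{gs.gene}/{breed}: frequencies sum to {total}")


def default_panel_spec(n_per_breed: Optional[int] = None,
                       seed: int = 0) -> PanelSpec:
    """The study conditions: 11 breed groups with the published per-breed
    protein-variant frequencies; ``n_per_breed`` overrides every group size
    (for large-sample recovery experiments)."""
    from . import fixtures

    bt = fixtures.breed_table()
    breeds = tuple(
        (r.breed, n_per_breed if n_per_breed is not None else r.n, r.sex)
        for r in bt.itertuples(index=False))
    bf = fixtures.breed_frequencies()
    st = fixtures.sites_table()
    genes = {}
    for gene in fixtures.GENES:
        rows = st[st["gene"] == gene]
        positions = fixtures.gene_positions(gene)
        allele_raw = fixtures.residue_to_allele(gene)
        allele_map = {(positions.index(p), res): a
                      for (p, res), a in allele_raw.items()}
        freqs: dict[str, dict[str, float]] = {}
        for r in bf[bf["gene"] == gene].itertuples(index=False):
            freqs.setdefault(r.breed, {})[r.variant] = r.freq
        genes[gene] = GeneSpec(
            gene=gene,
            chrom=rows["chrom"].iloc[0],
            site_ids=tuple(f"{gene}:{r.label}" for r in rows.itertuples(index=False)),
            vectors=fixtures.haplotype_vectors(gene),
            allele_map=allele_map,
            breed_freqs=freqs)
    return PanelSpec(breeds=breeds, genes=genes, seed=seed)


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------


def _breed_code(breed: str) -> str:
    return breed.replace(" ", "").replace("-", "")


def generate_panel(spec: PanelSpec):
    """Draw a panel: (panel, truth matrix, truth phased haplotypes).

    Each autosomal chromosome is drawn independently from the breed's
    haplotype distribution; X-linked genes in males are drawn once.
    ``truth`` maps gene -> animal -> tuple of residue vectors (the simulated
    phase).  Fully reproducible from ``spec.seed``.
    """
    from . import fixtures
    from .gene_models import VariantSite

    rng = np.random.default_rng(spec.seed)
    ploidy_model = PloidyModel()

    rows = []
    for breed, size, sex in spec.breeds:
        code = _breed_code(breed)
        for i in range(1, size + 1):
            rows.append((f"{code}{i:05d}", breed, sex))
    panel = BreedPanel(pd.DataFrame(rows, columns=["animal_id", "breed", "sex"]))
    animals = panel.animals

    # sites (reuse packaged site definitions when ids match; otherwise make
    # generic biallelic sites from the allele maps)
    site_lookup = {s.site_id: s for s in fixtures.variant_sites()}
    sites = []
    for gs in spec.genes.values():
        for k, sid in enumerate(gs.site_ids):
            if sid in site_lookup:
                sites.append(site_lookup[sid])
            else:
                alleles = sorted({a for (i, _), a in gs.allele_map.items()
                                  if i == k})
                sites.append(VariantSite(gs.chrom, k + 1, alleles[0],
                                         tuple(alleles[1:]), site_id=sid))
    matrix = GenotypeMatrix(sites, animals, panel=panel, ploidy=ploidy_model)

    truth: dict[str, dict[str, tuple]] = {}
    columns: dict[str, list] = {sid: [None] * len(animals)
                                for sid in matrix.site_ids}
    animal_breed = [panel.table["breed"].iloc[i] for i in range(len(animals))]
    animal_sex = [panel.table["sex"].iloc[i] for i in range(len(animals))]

    for gene, gs in spec.genes.items():
        truth[gene] = {}
        codes = sorted(gs.vectors)
        n_pos = len(next(iter(gs.vectors.values())))
        # precompute per-code allele rows
        allele_rows = {c: tuple(gs.allele_map[(i, gs.vectors[c][i])]
                                for i in range(n_pos)) for c in codes}
        by_breed: dict[str, list[int]] = {}
        for idx, b in enumerate(animal_breed):
            by_breed.setdefault(b, []).append(idx)
        is_x = ploidy_model.is_x(gs.chrom)
        for breed, indices in by_breed.items():
            freqs = gs.breed_freqs.get(breed, {})
            if not freqs:
                raise ValueError(f"no {gene} frequencies for breed {breed}")
            bc = sorted(freqs)
            p = np.array([freqs[c] for c in bc], dtype=float)
            p = p / p.sum()
            ploidies = [1 if is_x and animal_sex[i] == "M" else 2
                        for i in indices]
            flat = rng.choice(len(bc), size=sum(ploidies), p=p)
            offsets = np.concatenate([[0], np.cumsum(ploidies)])
            for row, idx in enumerate(indices):
                chosen = tuple(bc[d]
                               for d in flat[offsets[row]:offsets[row + 1]])
                haps = tuple(gs.vectors[c] for c in chosen)
                truth[gene][animals[idx]] = haps
                for k, sid in enumerate(gs.site_ids):
                    cell = tuple(sorted(allele_rows[c][k] for c in chosen))
                    columns[sid][idx] = cell
    for sid, col in columns.items():
        matrix.calls[sid] = col
    return panel, matrix, truth


# ---------------------------------------------------------------------------
# Depth and allele-dropout error model
# ---------------------------------------------------------------------------


def simulate_depth_and_calls(
    truth: GenotypeMatrix,
    depth: DepthModel = DepthModel(),
    min_depth: int = 3,
    miscall_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Apply the read-depth and allele-dropout error model to true genotypes.

    Per cell, a depth d is drawn from the truncated rounded normal; cells
    with d below ``min_depth`` become missing.  A heterozygous cell with d
    reads is called heterozygous only if both alleles are observed among the
    d coin-flip reads; otherwise the (erroneous) homozygous call is made.
    Homozygous and hemizygous cells are called correctly unless a nonzero
    ``miscall_rate`` flips individual alleles.
    """
    rng = np.random.default_rng(seed)
    observed = truth.copy()
    n_animals = len(truth.animals)
    observed.depths = pd.DataFrame(np.nan, index=truth.animals,
                                   columns=truth.site_ids)
    for sid in truth.site_ids:
        col = list(truth.calls[sid])
        d = depth.draw(rng, n_animals)
        ref_reads = rng.binomial(d, 0.5)
        miscall = (rng.random(n_animals) < miscall_rate
                   if miscall_rate > 0 else np.zeros(n_animals, dtype=bool))
        out = []
        for i, cell in enumerate(col):
            if cell is None or d[i] < min_depth:
                out.append(None)
                continue
            if len(cell) == 2 and cell[0] != cell[1]:
                k = ref_reads[i]
                if k == 0:
                    cell = (cell[1], cell[1])
                elif k == d[i]:
                    cell = (cell[0], cell[0])
            if miscall[i]:
                site = truth.site(sid)
                others = [a.lower() for a in site.alleles
                          if a.lower() != cell[0]]
                if others:
                    cell = tuple(sorted((others[0],) + cell[1:]))
            out.append(cell)
        observed.calls[sid] = out
        observed.depths[sid] = d.astype(float)
    return observed


def analytic_het_dropout(depth: DepthModel = DepthModel(),
                         min_depth: int = 3) -> float:
    """Expected allele-dropout rate among scored heterozygous cells.

    A het cell with depth d is called (erroneously) homozygous with
    probability 2^(1-d); the rate is averaged over the depth distribution
    conditional on d >= min_depth.
    """
    d, p = depth.pmf()
    keep = d >= min_depth
    p = p[keep] / p[keep].sum()
    return float(np.sum(p * 2.0 ** (1 - d[keep])))


# ---------------------------------------------------------------------------
# Reference-truth tables for QC testing
# ---------------------------------------------------------------------------


def generate_reference_truth(
    n_animals: int,
    n_sites: int,
    n_errors: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A truth genotype table and a copy with exactly ``n_errors`` injected.

    Errors turn heterozygous cells homozygous (or swap a homozygote's
    allele), the error mode seen in low-coverage WGS genotypes, and are
    exactly recoverable by genotype accuracy comparison.
    """
    if n_sites <= 0 or n_animals <= 0:
        raise ValueError("n_animals and n_sites must be positive")
    if n_errors > n_animals * n_sites:
        raise ValueError("more errors than cells")
    rng = np.random.default_rng(seed)
    bases = np.array(list("acgt"))
    rows = []
    for s in range(n_sites):
        ref, alt = rng.choice(4, size=2, replace=False)
        for a in range(n_animals):
            g = rng.integers(0, 3)  # 0 hom-ref, 1 het, 2 hom-alt
            alleles = [bases[ref], bases[alt]]
            gt = sorted([alleles[0], alleles[0]] if g == 0
                        else [alleles[0], alleles[1]] if g == 1
                        else [alleles[1], alleles[1]])
            rows.append((f"an{a + 1:04d}", f"site{s + 1:04d}", "/".join(gt),
                         alleles[0], alleles[1]))
    truth = pd.DataFrame(rows, columns=["animal_id", "site_id", "genotype",
                                        "ref", "alt"])
    corrupted = truth.copy()
    cells = rng.choice(len(truth), size=n_errors, replace=False)
    for idx in cells:
        ref, alt = truth.loc[idx, "ref"], truth.loc[idx, "alt"]
        g = truth.loc[idx, "genotype"]
        het = "/".join(sorted([ref, alt]))
        corrupted.loc[idx, "genotype"] = (
            "/".join([ref, ref]) if g == het else het)
    return (truth[["animal_id", "site_id", "genotype"]],
            corrupted[["animal_id", "site_id", "genotype"]])


# ---------------------------------------------------------------------------
# Synthetic ortholog sets
# ---------------------------------------------------------------------------

_RESIDUE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def generate_ortholog_set(
    species_clades: Mapping[str, str],
    ladder: Sequence[str],
    columns: Mapping[str, Mapping],
    seed: int = 0,
):
    """Build an :class:`~ramdecode.conservation.OrthologSet` to order.

    ``species_clades`` maps species -> narrowest ladder clade;
    ``columns`` maps column name -> spec with keys ``reference_residue``,
    ``conserved_through`` (ladder clade), optional ``exceptions`` (species ->
    residue inside the conserved clade), ``variant_residue`` and
    ``variant_carriers`` (species outside the conserved clade given the
    sheep variant residue).  Columns are constructed so strict conservation
    depth recovers the spec exactly: every species inside the conserved
    clade matches the reference (bar listed exceptions) and every species
    outside mismatches.
    """
    from .conservation import OrthologSet

    if not ladder or not species_clades:
        raise ValueError("taxonomy ladder and species map must be non-empty")
    ladder = tuple(ladder)
    index = {c: i for i, c in enumerate(ladder)}
    unknown = set(species_clades.values()) - set(ladder)
    if unknown:
        raise ValueError(f"clades not in ladder: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    paths = {sp: ladder[index[c]:] for sp, c in species_clades.items()}
    data: dict[str, dict[str, str]] = {}
    for name, spec in columns.items():
        ref = spec["reference_residue"]
        depth = spec["conserved_through"]
        exceptions = dict(spec.get("exceptions", {}))
        variant = spec.get("variant_residue", "")
        carriers = set(spec.get("variant_carriers", ()))
        if depth not in index:
            raise ValueError(f"{name}: clade {depth} not in ladder")
        col = {}
        others = [r for r in _RESIDUE_ALPHABET if r != ref and r != variant]
        for sp in species_clades:
            inside = index[species_clades[sp]] <= index[depth]
            if sp in exceptions:
                col[sp] = exceptions[sp]
            elif sp in carriers:
                col[sp] = variant if len(variant) == 1 else "Δ"
            elif inside:
                col[sp] = ref
            else:
                col[sp] = str(rng.choice(list(others)))
        data[name] = col
    residues = pd.DataFrame(data)

    from .fixtures import CLADE_TMRCA

    tmrca = {sp: CLADE_TMRCA.get(species_clades[sp], float("nan"))
             for sp in species_clades}
    return OrthologSet(residues, paths, tmrca)
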