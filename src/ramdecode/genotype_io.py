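"""Genotype data model and file IO.

Holds the animals × sites genotype matrix with sex-aware ploidy (autosomes
diploid; X hemizygous in males), the breed/sex panel table, and readers and
writers for the formats the pipeline consumes and emits: VCF 4.2 for
genotypes (GT and DP only), TSV for panels, reference genotypes and result
tables.  Missing genotypes stay missing — nothing is imputed — and all text
inputs are read gzip-transparently.
"""

from __future__ import annotations

import gzip
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .gene_models import VariantSite

__all__ = [
    "BreedPanel",
    "PloidyModel",
    "GenotypeMatrix",
    "read_genotypes",
    "write_vcf",
    "read_reference_genotypes",
    "write_tables",
    "round_half_up",
]

X_CHROM_NAMES = frozenset({"X", "chrX", "chrx", "x", "OARX", "OAR_X"})


def open_text(path):
    """Open a text file, transparently decompressing ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def round_half_up(x: float, decimals: int) -> float:
    """Round half away from zero to a fixed number of decimals.

    Printed tables in this domain round 0.5 up (e.g. 0.1875 -> 0.19), which
    differs from banker's rounding.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Panel and ploidy
# ---------------------------------------------------------------------------


@dataclass
class BreedPanel:
    """Assignment of animals to breed groups and sexes."""

    table: pd.DataFrame  # columns: animal_id, breed, sex

    def __post_init__(self) -> None:
        required = {"animal_id", "breed", "sex"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"panel table needs columns {sorted(required)}")
        if self.table["animal_id"].duplicated().any():
            dups = self.table.loc[self.table["animal_id"].duplicated(), "animal_id"]
            raise ValueError(f"duplicate animal ids: {sorted(set(dups))}")
        self.table = self.table.reset_index(drop=True)

    @property
    def animals(self) -> list[str]:
        return list(self.table["animal_id"])

    def sex_of(self, animal: str) -> str:
        row = self.table.loc[self.table["animal_id"] == animal]
        if row.empty:
            raise KeyError(f"unknown animal {animal!r}")
        return row["sex"].iloc[0]

    def breed_of(self, animal: str) -> str:
        row = self.table.loc[self.table["animal_id"] == animal]
        if row.empty:
            raise KeyError(f"unknown animal {animal!r}")
        return row["breed"].iloc[0]

    def breed_counts(self) -> dict[str, int]:
        counts = self.table.groupby("breed", sort=False)["animal_id"].count()
        return dict(counts)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def read_tsv(cls, path) -> "BreedPanel":
        with open_text(path) as fh:
            return cls(pd.read_csv(fh, sep="\t", dtype=str))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PloidyModel:
    """Chromosome-aware ploidy: autosomes 2; X is 1 in males, 2 in females."""

    x_chroms: frozenset[str] = X_CHROM_NAMES

    def is_x(self, chrom: str) -> bool:
        return chrom in self.x_chroms

    def ploidy(self, chrom: str, sex: str) -> int:
        if self.is_x(chrom):
            return 1 if sex.upper() in ("M", "MALE") else 2
        return 2


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------


class GenotypeMatrix:
    """Animals × variant sites with unordered allele multisets.

    Each cell is a sorted tuple of allele strings whose length equals the
    animal's ploidy at that site, or None for a missing call.  Optional
    per-cell read depths ride alongside.
    """

    def __init__(
        self,
        sites: Sequence[VariantSite],
        animals: Sequence[str],
        panel: Optional[BreedPanel] = None,
        ploidy: Optional[PloidyModel] = None,
    ) -> None:
        ids = [s.site_id for s in sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids")
        self.sites: list[VariantSite] = list(sites)
        self.site_ids: list[str] = ids
        self._site_by_id = {s.site_id: s for s in sites}
        self.animals: list[str] = list(animals)
        self.calls = pd.DataFrame(index=self.animals, columns=ids, dtype=object)
        self.depths: Optional[pd.DataFrame] = None
        self.panel = panel
        self.ploidy = ploidy or PloidyModel()
        self.warnings: list[str] = []

    # -- cell access --------------------------------------------------------

    def site(self, site_id: str) -> VariantSite:
        return self._site_by_id[site_id]

    def get(self, animal: str, site_id: str) -> Optional[tuple[str, ...]]:
        v = self.calls.at[animal, site_id]
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

    def set(self, animal: str, site_id: str,
            alleles: Optional[Iterable[str]], depth: Optional[float] = None) -> None:
        site = self._site_by_id[site_id]
        if alleles is not None:
            cell = tuple(sorted(a.lower() for a in alleles))
            valid = {a.lower() for a in site.alleles}
            if not set(cell).issubset(valid):
                raise ValueError(
                    f"alleles {cell} not in site {site_id} alphabet {sorted(valid)}")
            self.calls.at[animal, site_id] = cell
        else:
            self.calls.at[animal, site_id] = None
        if depth is not None:
            if self.depths is None:
                self.depths = pd.DataFrame(
                    np.nan, index=self.animals, columns=self.site_ids)
            self.depths.at[animal, site_id] = depth

    def expected_ploidy(self, animal: str, site_id: str) -> int:
        sex = self.panel.sex_of(animal) if self.panel is not None else "F"
        return self.ploidy.ploidy(self._site_by_id[site_id].chrom, sex)

    # -- aggregates ---------------------------------------------------------

    def allele_counts(self, site_id: str) -> Counter:
        counts: Counter = Counter()
        for animal in self.animals:
            cell = self.get(animal, site_id)
            if cell is not None:
                counts.update(cell)
        return counts

    def scored_animals(self, site_id: str) -> list[str]:
        return [a for a in self.animals if self.get(a, site_id) is not None]

    def n_missing(self) -> int:
        return int(sum(self.get(a, s) is None
                       for a in self.animals for s in self.site_ids))

    def copy(self) -> "GenotypeMatrix":
        out = GenotypeMatrix(self.sites, self.animals, self.panel, self.ploidy)
        out.calls = self.calls.copy()
        out.depths = None if self.depths is None else self.depths.copy()
        out.warnings = list(self.warnings)
        return out


# ---------------------------------------------------------------------------
# VCF IO (pysam; GT and DP only)
# ---------------------------------------------------------------------------


def read_genotypes(vcf_path, panel: BreedPanel,
                   ploidy: Optional[PloidyModel] = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Diploid GT fields become unordered allele multisets; haploid calls (or
    homozygous diploid-coded calls) on X in males collapse to one allele.  A
    true heterozygote on male X is recorded as a warning and the cell set
    missing.  ``./.`` is missing.  DP is retained when present.
    """
    import pysam

    ploidy = ploidy or PloidyModel()
    with pysam.VariantFile(str(vcf_path)) as vf:
        vcf_samples = list(vf.header.samples)
        unknown = set(vcf_samples) - set(panel.animals)
        if unknown:
            raise ValueError(f"VCF samples not in panel: {sorted(unknown)}")
        sites: list[VariantSite] = []
        records = []
        for rec in vf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            sites.append(VariantSite(rec.chrom, rec.pos, rec.ref, alts,
                                     site_id=rec.id or ""))
            records.append(rec)

    matrix = GenotypeMatrix(sites, vcf_samples, panel=panel, ploidy=ploidy)
    for site, rec in zip(sites, records):
        allele_seq = (rec.ref,) + tuple(rec.alts or ())
        for sample in vcf_samples:
            call = rec.samples[sample]
            gt = call.get("GT")
            dp = call.get("DP")
            depth = float(dp) if dp is not None else None
            idx = [i for i in (gt or ()) if i is not None]
            expected = ploidy.ploidy(site.chrom, panel.sex_of(sample))
            if not idx:
                matrix.set(sample, site.site_id, None, depth)
                continue
            alleles = [allele_seq[i] for i in idx]
            if expected == 1:
                if len(set(alleles)) == 1:
                    matrix.set(sample, site.site_id, alleles[:1], depth)
                else:
                    matrix.warnings.append(
                        f"{sample} {site.site_id}: heterozygous call on "
                        f"hemizygous X; cell set missing")
                    matrix.set(sample, site.site_id, None, depth)
            else:
                if len(alleles) == 1:
                    matrix.warnings.append(
                        f"{sample} {site.site_id}: haploid call at diploid "
                        f"site; cell set missing")
                    matrix.set(sample, site.site_id, None, depth)
                else:
                    matrix.set(sample, site.site_id, alleles, depth)
    return matrix


def write_vcf(matrix: GenotypeMatrix, vcf_path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with GT (and DP) fields."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##source=ramdecode")
    for chrom in dict.fromkeys(s.chrom for s in matrix.sites):
        max_pos = max(s.pos + len(s.ref_allele) for s in matrix.sites
                      if s.chrom == chrom)
        header.contigs.add(chrom, length=max_pos + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for animal in matrix.animals:
        header.add_sample(animal)

    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for site in matrix.sites:
            rec = out.new_record(
                contig=site.chrom, start=site.pos - 1,
                alleles=tuple(a.upper() for a in site.alleles), id=site.site_id)
            allele_index = {a.lower(): i for i, a in enumerate(site.alleles)}
            for animal in matrix.animals:
                cell = matrix.get(animal, site.site_id)
                expected = matrix.expected_ploidy(animal, site.site_id)
                if cell is None:
                    rec.samples[animal]["GT"] = (None,) * expected
                else:
                    rec.samples[animal]["GT"] = tuple(
                        allele_index[a] for a in cell)
                if matrix.depths is not None:
                    d = matrix.depths.at[animal, site.site_id]
                    if not np.isnan(d):
                        rec.samples[animal]["DP"] = int(d)
            out.write(rec)


# ---------------------------------------------------------------------------
# Reference genotype tables and result writing
# ---------------------------------------------------------------------------


def parse_genotype_string(g: str) -> tuple[str, ...]:
    """Parse 'A/G' (unordered) or hemizygous 'A' into a sorted allele tuple."""
    g = g.strip()
    if not g or g in (".", "./.", "-"):
        raise ValueError(f"malformed genotype string {g!r}")
    parts = g.split("/") if "/" in g else [g]
    if any(not p or not p.replace("*", "").isalpha() for p in parts):
        raise ValueError(f"malformed genotype string {g!r}")
    return tuple(sorted(p.lower() for p in parts))


def read_reference_genotypes(path) -> pd.Series:
    """Read a reference genotype TSV (animal_id, site_id, genotype).

    Returns a Series of sorted allele tuples indexed by (animal_id, site_id);
    duplicate keys or malformed genotype strings raise.
    """
    with open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    required = {"animal_id", "site_id", "genotype"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference genotype table needs columns {sorted(required)}")
    if df.empty:
        return pd.Series(dtype=object,
                         index=pd.MultiIndex.from_arrays([[], []],
                                                         names=["animal_id", "site_id"]))
    dup = df.duplicated(subset=["animal_id", "site_id"])
    if dup.any():
        raise ValueError(
            f"duplicate (animal, site) rows: "
            f"{df.loc[dup, ['animal_id', 'site_id']].values.tolist()}")
    values = [parse_genotype_string(g) for g in df["genotype"]]
    idx = pd.MultiIndex.from_frame(df[["animal_id", "site_id"]])
    return pd.Series(values, index=idx)


def write_tables(results: Mapping[str, pd.DataFrame], destination,
                 decimals: Optional[Mapping[str, int]] = None) -> dict[str, Path]:
    """Write result tables as TSVs with stable column order.

    ``decimals`` maps table name -> decimal places for float columns
    (half-up, 3 by default).  Empty frames yield header-only files; output is
    byte-identical across runs on the same input.
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    decimals = decimals or {}
    written = {}
    for name in sorted(results):
        df = results[name].copy()
        nd = decimals.get(name, 3)
        for col in df.columns:
            if pd.api.types.is_float_dtype(df[col]):
                df[col] = df[col].map(
                    lambda x, nd=nd: "" if pd.isna(x)
                    else f"{round_half_up(x, nd):.{nd}f}")
        path = destination / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written[name] = path
    return written
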