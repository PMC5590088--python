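"""Allele and protein-variant frequency estimation.

Frequencies are estimated with chromosome-aware denominators: an autosomal
site contributes two allele copies per scored animal, an X-linked site one
copy per scored male.  Site-level minor allele frequencies (MAF) need no
phase; protein-variant (haplotype) frequencies count each phased chromosome
once, panel-wide and per breed group, with unresolved-phase individuals
excluded from both numerator and denominator.  MAF is defined against the
panel-minor allele, not the reference allele.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genotype_io import BreedPanel, GenotypeMatrix, round_half_up
from .haplotyping import PhasedIndividual, Residues

__all__ = [
    "FrequencyTable",
    "site_maf",
    "haplotype_frequencies",
    "maf_consistency_check",
]


class UndefinedFrequencyError(ValueError):
    """Frequency requested over an empty denominator."""


@dataclass
class FrequencyTable:
    """Counts and frequencies keyed by (gene, variant or site)."""

    table: pd.DataFrame  # columns: gene, variant, count, denominator, frequency, [breed columns]
    excluded: int = 0  # unresolved-phase individuals left out

    def rounded(self, decimals: int = 3) -> pd.DataFrame:
        df = self.table.copy()
        for col in df.columns:
            if pd.api.types.is_float_dtype(df[col]):
                df[col] = df[col].map(lambda x: round_half_up(x, decimals))
        return df


def site_maf(matrix: GenotypeMatrix, site_id: str,
             allele: Optional[str] = None) -> dict:
    """Minor allele frequency at one site.

    The minor allele is the least frequent allele in the panel (reference or
    not); with a single observed allele the MAF is 0.  The denominator is
    the total allele count over scored animals (2 per diploid animal, 1 per
    hemizygous male), so no phase information is needed.  Passing ``allele``
    pins the counted allele instead of taking the panel-minor one — used
    when reporting a known variant allele's frequency within a subgroup
    where it may be the majority (or fixed).
    """
    counts = matrix.allele_counts(site_id)
    denom = sum(counts.values())
    if denom == 0:
        raise UndefinedFrequencyError(f"all calls missing at {site_id}")
    site = matrix.site(site_id)
    by_allele = {a.lower(): counts.get(a.lower(), 0) for a in site.alleles}
    if allele is not None:
        major = max((a for a in by_allele if a != allele.lower()),
                    key=lambda a: by_allele[a])
        minor_count = by_allele[allele.lower()]
        return {
            "site_id": site_id,
            "major_allele": major,
            "minor_count": minor_count,
            "denominator": denom,
            "maf": minor_count / denom,
            "allele_counts": dict(by_allele),
        }
    major = max(by_allele, key=lambda a: (by_allele[a], a == site.ref_allele.lower()))
    minor_count = denom - by_allele[major]
    return {
        "site_id": site_id,
        "major_allele": major,
        "minor_count": minor_count,
        "denominator": denom,
        "maf": minor_count / denom,
        "allele_counts": dict(by_allele),
    }


def _hap_counts(phased: Iterable[PhasedIndividual]) -> tuple[Counter, int]:
    counts: Counter = Counter()
    excluded = 0
    for ind in phased:
        if ind.status == "unresolved" or not ind.haplotypes:
            excluded += 1
            continue
        counts.update(ind.haplotypes)
    return counts, excluded


def haplotype_frequencies(
    phased: Sequence[PhasedIndividual],
    panel: Optional[BreedPanel] = None,
    by_breed: bool = False,
) -> FrequencyTable:
    """Protein-variant frequencies from phased individuals.

    Each haplotype copy counts once per chromosome (two per diploid
    individual, one per hemizygous male).  Unresolved individuals are
    excluded from numerator and denominator; their number is reported on the
    returned table.  With ``by_breed`` the per-breed frequency columns are
    added (breed membership from ``panel``).
    """
    if not phased:
        return FrequencyTable(pd.DataFrame(
            columns=["gene", "variant", "residues", "count", "denominator",
                     "frequency"]))
    gene = phased[0].gene
    counts, excluded = _hap_counts(phased)
    denom = sum(counts.values())
    if denom == 0:
        raise UndefinedFrequencyError("no resolved haplotypes")

    order = sorted(counts, key=lambda h: (-counts[h], h))
    rows = []
    for k, hap in enumerate(order):
        rows.append({
            "gene": gene,
            "variant": k + 1,
            "residues": ",".join(hap),
            "count": counts[hap],
            "denominator": denom,
            "frequency": counts[hap] / denom,
        })
    df = pd.DataFrame(rows)

    if by_breed:
        if panel is None:
            raise ValueError("by_breed requires a panel")
        breed_of = dict(zip(panel.table["animal_id"], panel.table["breed"]))
        breeds = list(dict.fromkeys(panel.table["breed"]))
        per_breed: dict[str, Counter] = {b: Counter() for b in breeds}
        for ind in phased:
            if ind.status == "unresolved" or not ind.haplotypes:
                continue
            per_breed[breed_of[ind.animal]].update(ind.haplotypes)
        for b in breeds:
            total = sum(per_breed[b].values())
            df[b] = [per_breed[b].get(h, 0) / total if total else float("nan")
                     for h in order]
            df[f"{b}_count"] = [per_breed[b].get(h, 0) for h in order]
    return FrequencyTable(df, excluded=excluded)


def maf_consistency_check(
    site_mafs: Mapping[str, float],
    hap_table: FrequencyTable,
    carriers: Mapping[str, Sequence[int]],
    tolerance: float = 0.002,
) -> pd.DataFrame:
    """Cross-check site MAFs against summed carrier-haplotype frequencies.

    ``carriers`` maps site_id -> the variant codes (1-based rows of the
    haplotype table) whose isoforms carry that site's variant residue.  The
    discrepancy |MAF − Σ carrier frequencies| should not exceed printed
    rounding; larger values are flagged (default tolerance 0.002).
    """
    df = hap_table.table.set_index("variant")
    rows = []
    for site_id, maf in site_mafs.items():
        total = sum(float(df.loc[v, "frequency"]) for v in carriers.get(site_id, ()))
        disc = abs(maf - total)
        rows.append({
            "site_id": site_id,
            "maf": maf,
            "haplotype_sum": total,
            "discrepancy": disc,
            "flagged": disc > tolerance,
        })
    return pd.DataFrame(rows)
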