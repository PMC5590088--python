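"""Cross-species residue conservation classification.

Given an alignment column of ortholog residues and a nested-clade taxonomy
(e.g. species ⊂ Artiodactyla ⊂ Laurasiatheria ⊂ Eutheria ⊂ Theria ⊂
Mammalia ⊂ Tetrapoda ⊂ Vertebrata), classify how deeply a sheep reference
residue is conserved: the largest clade in which every species with a known
residue matches the reference ("strict" mode), plus an exceptions-tolerant
mode that lists the outlier species per clade — needed to express statements
like "conserved throughout Theria except humans, manatees and armadillos".
Also reports whether the sheep *variant* residue occurs in any other
species, and pairwise percent identity of aligned sequences.

Sheep itself is excluded from the profile when its own variant is assessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "OrthologSet",
    "ConservationCall",
    "conservation_depth",
    "conservation_exceptions",
    "variant_seen_elsewhere",
    "percent_identity",
    "classify_column",
]

UNKNOWN_TOKENS = frozenset({"?", "-", "", "nr", "nm", "ni", "X"})


@dataclass
class OrthologSet:
    """Per-species residues at variant columns plus clade membership.

    ``residues`` is a species × column frame of one-letter residues (or
    deletion/unknown tokens); ``clade_paths`` maps species to its nested
    clade path ordered narrowest first; clade paths must be suffix-nested,
    i.e. every path is a suffix of the full ladder.
    """

    residues: pd.DataFrame
    clade_paths: Mapping[str, tuple[str, ...]]
    tmrca: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        paths = list(self.clade_paths.values())
        if not paths:
            raise ValueError("empty taxonomy")
        ladder = max(paths, key=len)
        for sp, p in self.clade_paths.items():
            if tuple(p) != tuple(ladder[len(ladder) - len(p):]):
                raise ValueError(
                    f"clade path of {sp} is not nested within the ladder")
        missing = set(self.residues.index) - set(self.clade_paths)
        if missing:
            raise ValueError(f"species without clade path: {sorted(missing)}")
        self.ladder = tuple(ladder)

    def column(self, name: str) -> dict[str, str]:
        return {sp: r for sp, r in self.residues[name].items()}


@dataclass(frozen=True)
class ConservationCall:
    """Conservation classification of one variant residue column."""

    gene: str
    aa_pos: int
    ref_residue: str
    deepest_clade: Optional[str]  # strict mode; None if not even the
    # narrowest clade is uniform
    deepest_clade_tolerant: Optional[str] = None
    exceptions: tuple[str, ...] = ()
    variant_residue: str = ""
    variant_seen_elsewhere: Optional[bool] = None
    variant_species: tuple[str, ...] = ()


def _known(residue: str) -> bool:
    return residue not in UNKNOWN_TOKENS


def conservation_depth(
    column: Mapping[str, str],
    clade_paths: Mapping[str, tuple[str, ...]],
    ref_residue: str,
    ladder: Optional[Sequence[str]] = None,
    exclude: Iterable[str] = (),
) -> Optional[str]:
    """Deepest (largest) clade in which the column is strictly conserved.

    Species with unknown residues are ignored.  Returns None when even the
    narrowest ladder clade contains a mismatching species.  Adding a
    conforming species can never shrink the returned clade, and adding a
    mismatching one can never grow it.
    """
    known = {sp: r for sp, r in column.items()
             if _known(r) and sp not in set(exclude)}
    if not known:
        raise ValueError("no species with a known residue")
    if ladder is None:
        ladder = max((clade_paths[sp] for sp in known), key=len)
    deepest = None
    for clade in ladder:
        members = [sp for sp in known if clade in clade_paths[sp]]
        if any(known[sp] != ref_residue for sp in members):
            break
        deepest = clade
    return deepest


def conservation_exceptions(
    column: Mapping[str, str],
    clade_paths: Mapping[str, tuple[str, ...]],
    ref_residue: str,
    ladder: Sequence[str],
    exclude: Iterable[str] = (),
    max_exceptions: int = 3,
) -> tuple[Optional[str], tuple[str, ...]]:
    """Exceptions-tolerant conservation depth.

    Returns the largest clade in which at most ``max_exceptions`` species
    deviate from the reference residue, together with the sorted deviating
    species.  This expresses "conserved throughout clade X with the notable
    exception of ...".
    """
    known = {sp: r for sp, r in column.items()
             if _known(r) and sp not in set(exclude)}
    if not known:
        raise ValueError("no species with a known residue")
    deepest, outliers = None, ()
    for clade in ladder:
        members = [sp for sp in known if clade in clade_paths[sp]]
        mism = sorted(sp for sp in members if known[sp] != ref_residue)
        if len(mism) > max_exceptions:
            break
        deepest, outliers = clade, tuple(mism)
    return deepest, outliers


def variant_seen_elsewhere(
    column: Mapping[str, str],
    variant_residue: str,
    exclude: Iterable[str] = (),
) -> tuple[Optional[bool], tuple[str, ...]]:
    """Whether any non-sheep species carries the sheep variant residue.

    Returns (flag, species); the flag is None (unknown) when every residue
    in the column is unknown.
    """
    if not column:
        raise ValueError("empty column profile")
    known = {sp: r for sp, r in column.items()
             if _known(r) and sp not in set(exclude)}
    if not known:
        return None, ()
    hits = tuple(sorted(sp for sp, r in known.items() if r == variant_residue))
    return bool(hits), hits


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of two aligned sequences, gap columns excluded."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences differ in length")
    pairs = [(a, b) for a, b in zip(seq_a.upper(), seq_b.upper())
             if a != "-" and b != "-"]
    if not pairs:
        raise ValueError("no aligned (gap-free) columns")
    matches = sum(a == b for a, b in pairs)
    return 100.0 * matches / len(pairs)


def classify_column(
    orthologs: OrthologSet,
    gene: str,
    aa_pos: int,
    ref_residue: str,
    variant_residue: str,
    exclude: Iterable[str] = ("sheep",),
) -> ConservationCall:
    """Full conservation call for one variant column."""
    name = f"{gene}:{aa_pos}"
    column = orthologs.column(name)
    strict = conservation_depth(column, orthologs.clade_paths, ref_residue,
                                orthologs.ladder, exclude=exclude)
    tolerant, exceptions = conservation_exceptions(
        column, orthologs.clade_paths, ref_residue, orthologs.ladder,
        exclude=exclude)
    seen, species = variant_seen_elsewhere(column, variant_residue,
                                           exclude=exclude)
    return ConservationCall(
        gene=gene, aa_pos=aa_pos, ref_residue=ref_residue,
        deepest_clade=strict, deepest_clade_tolerant=tolerant,
        exceptions=exceptions, variant_residue=variant_residue,
        variant_seen_elsewhere=seen, variant_species=species)


# ---------------------------------------------------------------------------
# IO: aligned FASTA + clade TSV
# ---------------------------------------------------------------------------


def read_ortholog_set(fasta_path, clades_path) -> OrthologSet:
    """Read residue columns from aligned FASTA plus a clade-path TSV.

    FASTA records are per species; each sequence position corresponds to one
    variant column (column names come from the TSV header line
    ``#columns=...`` or are numbered).  The clades TSV has columns species,
    clade_path (semicolon-joined, narrowest first) and optional tmrca.
    """
    from Bio import SeqIO

    clades = pd.read_csv(clades_path, sep="\t", dtype=str)
    paths = {r.species: tuple(r.clade_path.split(";"))
             for r in clades.itertuples(index=False)}
    tmrca = {}
    if "tmrca" in clades.columns:
        tmrca = {r.species: float(r.tmrca) for r in clades.itertuples(index=False)
                 if r.tmrca not in ("", None)}
    import io

    col_names = None
    with open(fasta_path) as fh:
        lines = fh.readlines()
    if lines and lines[0].startswith("#columns="):
        col_names = lines[0].strip().split("=", 1)[1].split(",")
        lines = lines[1:]
    records = {rec.id: str(rec.seq)
               for rec in SeqIO.parse(io.StringIO("".join(lines)), "fasta")}
    length = len(next(iter(records.values())))
    if col_names is None:
        col_names = [str(i + 1) for i in range(length)]
    rows = {sp: list(seq) for sp, seq in records.items()}
    residues = pd.DataFrame.from_dict(rows, orient="index", columns=col_names)
    return OrthologSet(residues, paths, tmrca)


def write_ortholog_set(orthologs: OrthologSet, fasta_path, clades_path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write("#columns=" + ",".join(orthologs.residues.columns) + "\n")
        for sp in orthologs.residues.index:
            fh.write(f">{sp}\n{''.join(orthologs.residues.loc[sp])}\n")
    rows = [(sp, ";".join(path), orthologs.tmrca.get(sp, ""))
            for sp, path in orthologs.clade_paths.items()]
    pd.DataFrame(rows, columns=["species", "clade_path", "tmrca"]) \
        .to_csv(clades_path, sep="\t", index=False)
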