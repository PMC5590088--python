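"""Parsimony haplotype phasing and protein-variant trees.

Protein haplotypes are residue vectors over a gene's variant amino-acid
positions.  Phase is assigned without pedigree information using two rules:

1. *Unambiguous rule*: an individual homozygous at every variant site, or
   heterozygous at exactly one, has only one possible pair of haplotypes
   (hemizygous X genotypes carry a single haplotype and are never ambiguous).
2. *Maximum parsimony*: an individual heterozygous at two or more sites is
   phased by enumerating every genotype-consistent haplotype pair and
   choosing the pair that requires the fewest haplotypes not already known
   in the panel, breaking ties toward the larger summed frequency of known
   members.  A residual tie is surfaced as unresolved rather than guessed.

Observed haplotypes are arranged in a single-substitution tree (nodes are
protein isoforms, edges are single amino-acid changes) of minimum size:
the fewest inferred intermediate isoforms — restricted to combinations of
residues observed at each position — are added to connect the observed
nodes, found by exhaustive search over candidate subsets in deterministic
(lexicographic) order.  The tree is rooted at the node closest to an
outgroup residue profile taken from related species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ProteinHaplotype",
    "PhasedIndividual",
    "ParsimonyTree",
    "TreeNode",
    "IncompleteDataError",
    "phase_unambiguous",
    "enumerate_pairings",
    "infer_ambiguous_phase",
    "build_parsimony_tree",
    "root_tree",
    "hamming",
]

Residues = tuple[str, ...]
#: A residue genotype: one sorted residue multiset per variant position,
#: each of length equal to the individual's ploidy at the gene.
ResidueGenotype = Sequence[tuple[str, ...]]

UNKNOWN_RESIDUE = "?"


class IncompleteDataError(ValueError):
    """Genotype has a missing call at one of the gene's variant sites."""


@dataclass(frozen=True)
class ProteinHaplotype:
    """A residue vector over a gene's variant amino-acid positions."""

    gene: str
    residues: Residues
    observed: bool = True

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PhasedIndividual:
    """Phase assignment for one individual at one gene.

    ``haplotypes`` holds two vectors for diploid individuals, one for
    hemizygous ones, and none when the phase is unresolved.
    """

    animal: str
    gene: str
    haplotypes: tuple[Residues, ...]
    status: str  # unambiguous | inferred | unresolved

    def genotype(self) -> tuple[tuple[str, ...], ...]:
        """Recombine the haplotype pair back into the residue genotype."""
        if not self.haplotypes:
            return ()
        return tuple(
            tuple(sorted(h[i] for h in self.haplotypes))
            for i in range(len(self.haplotypes[0])))


def hamming(a: Residues, b: Residues) -> int:
    if len(a) != len(b):
        raise ValueError("vectors differ in length")
    return sum(x != y for x, y in zip(a, b))


def _check_genotype(genotype: ResidueGenotype) -> int:
    """Validate completeness and constant ploidy; returns the ploidy."""
    if not genotype:
        raise ValueError("empty genotype")
    ploidies = set()
    for cell in genotype:
        if cell is None or len(cell) == 0 or any(
                r is None or r == "" for r in cell):
            raise IncompleteDataError("missing genotype at a variant site")
        ploidies.add(len(cell))
    if len(ploidies) != 1 or ploidies.pop() not in (1, 2):
        raise ValueError("genotype cells must all have ploidy 1 or 2")
    return len(genotype[0])


def phase_unambiguous(animal: str, gene: str,
                      genotype: ResidueGenotype) -> Optional[PhasedIndividual]:
    """Apply the unambiguous phasing rule.

    Returns a :class:`PhasedIndividual` when the individual is hemizygous,
    fully homozygous, or heterozygous at exactly one site; None when two or
    more heterozygous sites make the phase ambiguous.  Missing genotypes
    raise :class:`IncompleteDataError`.
    """
    ploidy = _check_genotype(genotype)
    if ploidy == 1:
        hap = tuple(cell[0] for cell in genotype)
        return PhasedIndividual(animal, gene, (hap,), "unambiguous")
    het = [i for i, cell in enumerate(genotype) if cell[0] != cell[1]]
    if len(het) >= 2:
        return None
    a = tuple(cell[0] for cell in genotype)
    b = tuple(cell[1] for cell in genotype)
    pair = tuple(sorted((a, b)))
    return PhasedIndividual(animal, gene, pair, "unambiguous")


def enumerate_pairings(genotype: ResidueGenotype) -> list[tuple[Residues, Residues]]:
    """All genotype-consistent haplotype pairs for a diploid genotype.

    With h heterozygous sites there are 2**(h-1) distinct unordered pairs
    (the first heterozygous site's assignment is fixed to break symmetry).
    """
    ploidy = _check_genotype(genotype)
    if ploidy != 1 and any(len(set(c)) > 2 for c in genotype):
        raise ValueError("more than two residues in one cell")
    if ploidy == 1:
        return [(tuple(c[0] for c in genotype),) * 1]  # degenerate
    het = [i for i, cell in enumerate(genotype) if cell[0] != cell[1]]
    if not het:
        hap = tuple(cell[0] for cell in genotype)
        return [(hap, hap)]
    pairs = []
    for flips in itertools.product((0, 1), repeat=len(het) - 1):
        a, b = [], []
        assignment = dict(zip(het[1:], flips))
        for i, cell in enumerate(genotype):
            if i not in het:
                a.append(cell[0])
                b.append(cell[0])
            elif i == het[0]:
                a.append(cell[0])
                b.append(cell[1])
            else:
                k = assignment[i]
                a.append(cell[k])
                b.append(cell[1 - k])
        pairs.append(tuple(sorted((tuple(a), tuple(b)))))
    # dedupe while preserving deterministic order
    return list(dict.fromkeys(pairs))


def infer_ambiguous_phase(
    animal: str,
    gene: str,
    genotype: ResidueGenotype,
    known: Mapping[Residues, float],
    frequency_tiebreak: bool = True,
) -> PhasedIndividual:
    """Phase a multi-heterozygous individual by maximum parsimony.

    Candidate pairs are scored by the number of member haplotypes absent
    from the ``known`` set (fewer is more parsimonious); ties prefer the
    pair whose known members have the larger summed panel frequency; a
    remaining tie is returned as unresolved.  Individuals with fewer than
    two heterozygous sites are delegated to :func:`phase_unambiguous`.
    """
    if not known:
        raise ValueError("known haplotype set must be non-empty")
    simple = phase_unambiguous(animal, gene, genotype)
    if simple is not None:
        return simple
    best: list[tuple[Residues, Residues]] = []
    best_score: Optional[tuple[int, float]] = None
    for pair in enumerate_pairings(genotype):
        novel = sum(1 for h in pair if h not in known)
        freq = sum(known.get(h, 0.0) for h in pair) if frequency_tiebreak else 0.0
        score = (novel, -freq)
        if best_score is None or score < best_score:
            best_score, best = score, [pair]
        elif score == best_score:
            best.append(pair)
    if len(best) > 1:
        return PhasedIndividual(animal, gene, (), "unresolved")
    return PhasedIndividual(animal, gene, best[0], "inferred")


# ---------------------------------------------------------------------------
# Parsimony trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeNode:
    residues: Residues
    observed: bool
    weight: float = 0.0  # panel frequency (or count) attached to the isoform
    label: str = ""


@dataclass
class ParsimonyTree:
    """Single-substitution tree over protein isoforms.

    Nodes are observed or inferred haplotypes; every edge joins vectors at
    Hamming distance exactly 1; the tree is connected with node count − 1
    edges.  ``root`` indexes into ``nodes`` once the tree has been rooted.
    """

    gene: str
    nodes: list[TreeNode]
    edges: list[tuple[int, int]]
    root: Optional[int] = None

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if len(self.edges) != n - 1:
            raise ValueError("edge count must be node count - 1")
        adj = {i: set() for i in range(n)}
        for i, j in self.edges:
            if hamming(self.nodes[i].residues, self.nodes[j].residues) != 1:
                raise ValueError("edge joins nodes at Hamming distance != 1")
            adj[i].add(j)
            adj[j].add(i)
        seen, stack = set(), [0] if n else []
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(adj[u] - seen)
        if len(seen) != n:
            raise ValueError("tree is not connected")
        self._adjacency = adj

    @property
    def n_inferred(self) -> int:
        return sum(1 for nd in self.nodes if not nd.observed)

    def node_index(self, residues: Residues) -> int:
        for i, nd in enumerate(self.nodes):
            if nd.residues == residues:
                return i
        raise KeyError(residues)

    def neighbors(self, i: int) -> set[int]:
        return set(self._adjacency[i])

    def node_table(self):
        import pandas as pd

        return pd.DataFrame(
            [(nd.label, ",".join(nd.residues), nd.observed, nd.weight,
              i == self.root)
             for i, nd in enumerate(self.nodes)],
            columns=["label", "residues", "observed", "frequency", "is_root"])

    def to_newick(self) -> str:
        """Newick export, rooted at ``root`` (or node 0 when unrooted)."""
        import dendropy

        tree = dendropy.Tree()
        start = self.root if self.root is not None else 0
        dnodes = {start: tree.seed_node}
        tree.seed_node.label = self.nodes[start].label
        stack = [start]
        visited = {start}
        while stack:
            u = stack.pop()
            for v in sorted(self._adjacency[u] - visited):
                visited.add(v)
                child = dnodes[u].new_child(label=self.nodes[v].label,
                                            edge_length=1)
                dnodes[v] = child
                stack.append(v)
        return tree.as_string(
            schema="newick", suppress_rooting=True,
            suppress_leaf_node_labels=False).strip()


def _connected(nodes: Sequence[Residues]) -> bool:
    """Connectivity of the Hamming-distance-1 graph over ``nodes``."""
    if not nodes:
        return False
    n = len(nodes)
    seen = {0}
    frontier = [0]
    while frontier:
        u = frontier.pop()
        for v in range(n):
            if v not in seen and hamming(nodes[u], nodes[v]) == 1:
                seen.add(v)
                frontier.append(v)
    return len(seen) == n


def build_parsimony_tree(
    counts: Mapping[Residues, float],
    gene: str = "",
) -> ParsimonyTree:
    """Build the minimum single-substitution tree over observed haplotypes.

    ``counts`` maps observed residue vectors to their panel count or
    frequency.  Candidate intermediates are all combinations of residues
    observed at each position; subsets are tried in order of increasing size
    (lexicographically within a size), so the minimal tree is found and the
    construction is deterministic.  Node labels follow the convention that
    the most frequent isoform is "variant1".
    """
    observed = sorted(counts)
    if not observed:
        raise ValueError("at least one observed haplotype required")
    length = len(observed[0])
    if any(len(h) != length for h in observed):
        raise ValueError("haplotype vectors differ in length")

    alphabet = [sorted({h[i] for h in observed}) for i in range(length)]
    candidates = [v for v in itertools.product(*alphabet)
                  if v not in set(observed)]

    chosen: tuple[Residues, ...] = ()
    if not _connected(observed):
        # precompute Hamming-1 adjacency over the whole candidate universe so
        # each subset test is a plain BFS
        universe = list(observed) + list(candidates)
        n_obs = len(observed)
        adj: list[list[int]] = [[] for _ in universe]
        for i, j in itertools.combinations(range(len(universe)), 2):
            if hamming(universe[i], universe[j]) == 1:
                adj[i].append(j)
                adj[j].append(i)

        def subset_connects(extra: tuple[int, ...]) -> bool:
            allowed = set(range(n_obs)) | set(extra)
            seen = {0}
            frontier = [0]
            while frontier:
                u = frontier.pop()
                for v in adj[u]:
                    if v in allowed and v not in seen:
                        seen.add(v)
                        frontier.append(v)
            return len(seen & set(range(n_obs))) == n_obs and \
                seen >= set(extra)

        found = False
        cand_idx = range(n_obs, len(universe))
        for k in range(1, len(candidates) + 1):
            for subset in itertools.combinations(cand_idx, k):
                if subset_connects(subset):
                    chosen = tuple(universe[i] for i in subset)
                    found = True
                    break
            if found:
                break
        if not found:  # cannot happen: the full product graph is connected
            raise RuntimeError("no connecting intermediate set found")

    vectors = list(observed) + list(chosen)
    order = sorted(range(len(vectors)), key=lambda i: vectors[i])
    vectors = [vectors[i] for i in order]
    observed_set = set(observed)

    # deterministic spanning tree (Kruskal over lexicographically sorted edges)
    parent = list(range(len(vectors)))

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    edges = []
    for i, j in itertools.combinations(range(len(vectors)), 2):
        if hamming(vectors[i], vectors[j]) == 1:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                edges.append((i, j))

    # labels: observed nodes by descending weight ("variant1" most frequent),
    # inferred nodes in lexicographic order
    obs_sorted = sorted((v for v in vectors if v in observed_set),
                        key=lambda v: (-counts[v], v))
    labels = {v: f"variant{k + 1}" for k, v in enumerate(obs_sorted)}
    inf_sorted = [v for v in vectors if v not in observed_set]
    labels.update({v: f"inferred{k + 1}" for k, v in enumerate(inf_sorted)})

    nodes = [TreeNode(v, v in observed_set, float(counts.get(v, 0.0)), labels[v])
             for v in vectors]
    return ParsimonyTree(gene, nodes, edges)


def root_tree(tree: ParsimonyTree, outgroup: Residues) -> ParsimonyTree:
    """Root the tree at the node closest to an outgroup residue profile.

    Positions where the outgroup residue is unknown (``'?'``) are ignored in
    the distance; ties are broken toward observed nodes, then
    lexicographically.
    """
    if len(outgroup) != len(tree.nodes[0].residues):
        raise ValueError("outgroup profile length mismatch")

    def distance(v: Residues) -> int:
        return sum(o != UNKNOWN_RESIDUE and o != r
                   for o, r in zip(outgroup, v))

    best = min(range(len(tree.nodes)),
               key=lambda i: (distance(tree.nodes[i].residues),
                              not tree.nodes[i].observed,
                              tree.nodes[i].residues))
    return ParsimonyTree(tree.gene, tree.nodes, tree.edges, root=best)
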