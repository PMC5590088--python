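"""Phasing rules, parsimony inference, and single-substitution trees."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramdecode import fixtures
from ramdecode.haplotyping import (
    IncompleteDataError,
    PhasedIndividual,
    build_parsimony_tree,
    enumerate_pairings,
    hamming,
    infer_ambiguous_phase,
    phase_unambiguous,
    root_tree,
)

GDF9 = fixtures.haplotype_vectors("GDF9")
BMP15 = fixtures.haplotype_vectors("BMP15")
BMPR1B = fixtures.haplotype_vectors("BMPR1B")
GDF9_FREQ = {GDF9[c]: f for c, f in
             zip("1234", (0.693, 0.245, 0.036, 0.026))}


def genotype_of(*haps):
    return [tuple(sorted(h[i] for h in haps)) for i in range(len(haps[0]))]


class TestPhaseUnambiguous:
    def test_all_homozygous(self):
        ph = phase_unambiguous("a", "GDF9", genotype_of(GDF9["1"], GDF9["1"]))
        assert ph.status == "unambiguous"
        assert ph.haplotypes == (GDF9["1"], GDF9["1"])

    def test_single_het_site(self):
        ph = phase_unambiguous("a", "GDF9", genotype_of(GDF9["1"], GDF9["2"]))
        assert ph.status == "unambiguous"
        assert set(ph.haplotypes) == {GDF9["1"], GDF9["2"]}

    def test_two_het_sites_ambiguous(self):
        # v1/v3 differ at positions 87 and 241
        assert phase_unambiguous(
            "a", "GDF9", genotype_of(GDF9["1"], GDF9["3"])) is None

    def test_hemizygous_never_ambiguous(self):
        ph = phase_unambiguous("a", "BMP15", [(r,) for r in BMP15["4"]])
        assert ph.status == "unambiguous"
        assert ph.haplotypes == (BMP15["4"],)

    def test_missing_site_raises(self):
        geno = genotype_of(GDF9["1"], GDF9["1"])
        geno[2] = None
        with pytest.raises(IncompleteDataError):
            phase_unambiguous("a", "GDF9", geno)


class TestEnumeratePairings:
    @given(st.integers(1, 4), st.integers(0, 2 ** 10))
    @settings(max_examples=60, deadline=None)
    def test_count_and_round_trip(self, n_het, hom_mask):
        """2**(h-1) pairs, each recombining to the input genotype."""
        n_pos = 5
        het_sites = list(range(n_het))
        geno = []
        for i in range(n_pos):
            if i in het_sites:
                geno.append(("A", "B"))
            else:
                geno.append(("C", "C") if (hom_mask >> i) & 1 else ("D", "D"))
        pairs = enumerate_pairings(geno)
        assert len(pairs) == 2 ** (n_het - 1)
        for pair in pairs:
            assert genotype_of(*pair) == geno


class TestInferAmbiguousPhase:
    def test_cis_configuration_preferred(self):
        """Het at 87 and 241: the cis pairing (v1, v3) uses 0 novel
        haplotypes vs 2 for trans."""
        geno = genotype_of(GDF9["1"], GDF9["3"])
        ph = infer_ambiguous_phase("a", "GDF9", geno, GDF9_FREQ)
        assert ph.status == "inferred"
        assert set(ph.haplotypes) == {GDF9["1"], GDF9["3"]}

    def test_frequency_tiebreak(self):
        """Het at 241 and 332: both pairings need one novel haplotype; the
        tie-break selects the pair containing v1 (0.693 > 0.245)."""
        geno = [("R", "R"), ("E", "K"), ("I", "V"), ("V", "V")]
        ph = infer_ambiguous_phase("a", "GDF9", geno, GDF9_FREQ)
        assert ph.status == "inferred"
        assert GDF9["1"] in ph.haplotypes
        assert ("R", "K", "I", "V") in ph.haplotypes

    def test_without_tiebreak_unresolved(self):
        geno = [("R", "R"), ("E", "K"), ("I", "V"), ("V", "V")]
        ph = infer_ambiguous_phase("a", "GDF9", geno, GDF9_FREQ,
                                   frequency_tiebreak=False)
        assert ph.status == "unresolved"
        assert ph.haplotypes == ()

    def test_delegates_when_unambiguous(self):
        geno = genotype_of(GDF9["1"], GDF9["2"])
        ph = infer_ambiguous_phase("a", "GDF9", geno, GDF9_FREQ)
        assert ph.status == "unambiguous"

    @given(st.integers(2, 4), st.integers(0, 10 ** 6))
    @settings(max_examples=80, deadline=None)
    def test_oracle_equivalence(self, n_het, case_seed):
        """The chosen pair equals the argmin of the same score computed by
        independent brute-force enumeration over residue assignments."""
        import numpy as np

        rng = np.random.default_rng(case_seed)
        n_pos = n_het + int(rng.integers(0, 2))
        geno = []
        for i in range(n_pos):
            if i < n_het:
                geno.append(tuple(sorted(rng.choice(list("ACDEF"), 2,
                                                    replace=False))))
            else:
                r = str(rng.choice(list("ACDEF")))
                geno.append((r, r))
        known = set()
        for _ in range(int(rng.integers(1, 5))):
            known.add(tuple(str(rng.choice(cell)) for cell in geno))
        known_freq = {h: float(f) for h, f in
                      zip(sorted(known),
                          rng.dirichlet(np.ones(len(known))))}

        # oracle: brute force over all per-site orderings (2**h, not 2**(h-1))
        best_score, best_pairs = None, set()
        for choice in itertools.product((0, 1), repeat=n_pos):
            a = tuple(cell[c] for cell, c in zip(geno, choice))
            b = tuple(cell[1 - c] for cell, c in zip(geno, choice))
            pair = tuple(sorted((a, b)))
            novel = (a not in known_freq) + (b not in known_freq)
            freq = known_freq.get(a, 0.0) + known_freq.get(b, 0.0)
            score = (novel, -round(freq, 12))
            if best_score is None or score < best_score:
                best_score, best_pairs = score, {pair}
            elif score == best_score:
                best_pairs.add(pair)

        ph = infer_ambiguous_phase("a", "G", geno, known_freq)
        if len(best_pairs) > 1:
            assert ph.status == "unresolved"
        else:
            assert ph.status == "inferred"
            assert tuple(sorted(ph.haplotypes)) == next(iter(best_pairs))

    def test_round_trip_always(self, study):
        """Recombining any returned pair reproduces the input genotype,
        for every individual in the study panel."""
        from ramdecode.pipeline import residue_maps, phase_gene

        panel, matrix, _ = study
        rmaps = residue_maps(sites=matrix.sites)
        for gene in fixtures.GENES:
            phased, _ = phase_gene(matrix, gene, rmaps[gene])
            rmap = rmaps[gene]
            for ind in phased:
                observed = []
                for sid in rmap["site_ids"]:
                    cell = matrix.get(ind.animal, sid)
                    observed.append(tuple(sorted(
                        rmap["allele_res"][sid][a] for a in cell)))
                assert ind.genotype() == tuple(observed)


class TestParsimonyTree:
    def test_gdf9_one_inferred_intermediate(self):
        """Variant 3 is Hamming-2 from every observed node, so exactly one
        intermediate is added; the intermediate is interior."""
        counts = {GDF9[c]: n for c, n in zip("1234", (133, 47, 7, 5))}
        tree = build_parsimony_tree(counts, "GDF9")
        assert tree.n_inferred == 1
        inferred = [n for n in tree.nodes if not n.observed][0]
        assert inferred.residues in {("H", "E", "V", "V"), ("R", "K", "V", "V")}

    def test_bmp15_chain(self):
        """No inferred nodes; chain 1-2 with 3 and 4 attached to 2."""
        counts = {BMP15[c]: n for c, n in zip("1234", (63, 24, 8, 1))}
        tree = build_parsimony_tree(counts, "BMP15")
        assert tree.n_inferred == 0
        v = {c: tree.node_index(BMP15[c]) for c in "1234"}
        edges = {frozenset(e) for e in tree.edges}
        assert edges == {frozenset((v["1"], v["2"])),
                         frozenset((v["2"], v["3"])),
                         frozenset((v["2"], v["4"]))}

    def test_bmpr1b_star(self):
        counts = {BMPR1B[c]: n for c, n in zip("123", (182, 5, 5))}
        tree = build_parsimony_tree(counts, "BMPR1B")
        assert tree.n_inferred == 0
        v1 = tree.node_index(BMPR1B["1"])
        assert all(v1 in e for e in tree.edges)

    def test_singleton(self):
        tree = build_parsimony_tree({("A", "B"): 10}, "G")
        assert len(tree.nodes) == 1 and tree.edges == []

    def test_labels_by_frequency(self):
        counts = {BMPR1B[c]: n for c, n in zip("123", (182, 5, 5))}
        tree = build_parsimony_tree(counts, "BMPR1B")
        labels = {n.residues: n.label for n in tree.nodes}
        assert labels[BMPR1B["1"]] == "variant1"
        # tie between I64 and N345 resolved lexicographically
        assert labels[BMPR1B["2"]] == "variant2"

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=40, deadline=None)
    def test_minimality_matches_exhaustive_search(self, case_seed):
        """For <=6 observed haplotypes over <=4 positions, the number of
        inferred nodes equals the minimum found by exhaustive search over
        candidate subsets (independent connectivity check via networkx)."""
        import numpy as np
        import networkx as nx

        rng = np.random.default_rng(case_seed)
        n_pos = int(rng.integers(2, 5))
        n_hap = int(rng.integers(2, min(7, 2 ** n_pos)))
        observed = set()
        while len(observed) < n_hap:
            observed.add(tuple(str(rng.choice(list("AB"))) for _ in range(n_pos)))
        observed = sorted(observed)
        counts = {h: float(rng.integers(1, 50)) for h in observed}
        tree = build_parsimony_tree(counts, "G")

        alphabet = [sorted({h[i] for h in observed}) for i in range(n_pos)]
        candidates = [v for v in itertools.product(*alphabet)
                      if v not in set(observed)]

        def connected(nodes):
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from((a, b) for a, b in
                             itertools.combinations(nodes, 2)
                             if hamming(a, b) == 1)
            return nx.is_connected(g)

        minimum = None
        for k in range(len(candidates) + 1):
            if any(connected(observed + list(s))
                   for s in itertools.combinations(candidates, k)):
                minimum = k
                break
        assert tree.n_inferred == minimum

    def test_determinism(self):
        counts = {GDF9[c]: n for c, n in zip("1234", (133, 47, 7, 5))}
        t1 = build_parsimony_tree(counts, "GDF9")
        t2 = build_parsimony_tree(dict(reversed(list(counts.items()))), "GDF9")
        assert [n.residues for n in t1.nodes] == [n.residues for n in t2.nodes]
        assert t1.edges == t2.edges


class TestRootTree:
    def test_bmpr1b_roots_at_variant1(self):
        counts = {BMPR1B[c]: n for c, n in zip("123", (182, 5, 5))}
        tree = root_tree(build_parsimony_tree(counts, "BMPR1B"), ("M", "T"))
        assert tree.nodes[tree.root].residues == BMPR1B["1"]

    def test_gdf9_roots_at_unobserved_intermediate(self):
        counts = {GDF9[c]: n for c, n in zip("1234", (133, 47, 7, 5))}
        tree = build_parsimony_tree(counts, "GDF9")
        inferred = [n.residues for n in tree.nodes if not n.observed][0]
        rooted = root_tree(tree, inferred)
        assert rooted.nodes[rooted.root].residues == inferred
        assert not rooted.nodes[rooted.root].observed

    def test_unknown_positions_ignored(self):
        counts = {BMPR1B[c]: n for c, n in zip("123", (182, 5, 5))}
        tree = root_tree(build_parsimony_tree(counts, "BMPR1B"), ("?", "N"))
        assert tree.nodes[tree.root].residues == BMPR1B["3"]

    def test_single_node(self):
        tree = root_tree(build_parsimony_tree({("A",): 1}, "G"), ("A",))
        assert tree.root == 0

    def test_newick_contains_all_labels(self):
        counts = {BMP15[c]: n for c, n in zip("1234", (63, 24, 8, 1))}
        tree = root_tree(build_parsimony_tree(counts, "BMP15"), ("L", "R", "L"))
        nwk = tree.to_newick()
        for n in tree.nodes:
            assert n.label in nwk
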