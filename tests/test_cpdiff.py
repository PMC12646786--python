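import numpy as np
import pytest

import cytocline as cc
from cytocline.cpdiff import SaturationError, _splits
from cytocline.io_tables import GeneAnnotation


def _aln(cols_a, cols_b, n=4):
    """Alignment with n identical sequences per group from column strings."""
    return {
        **{f"A{i}": cols_a for i in range(n)},
        **{f"B{i}": cols_b for i in range(n)},
    }


class TestFindFixedDifferences:
    def test_planted_columns_found_exactly(self):
        a = "ACGTACGTAC"
        b = "ACCTACGAAG"  # differs at 1-based 3, 8, 10
        diffs = cc.find_fixed_differences(_aln(a, b), ["A0", "A1"], ["B0", "B1"])
        assert [d.position for d in diffs] == [3, 8, 10]
        assert [(d.allele_A, d.allele_B) for d in diffs] == [
            ("G", "C"), ("T", "A"), ("C", "G")
        ]

    def test_within_group_polymorphism_excludes_column(self):
        aln = _aln("AAAA", "CAAA", n=2)
        aln["A1"] = "GAAA"  # polymorphic inside group A at column 1
        diffs = cc.find_fixed_differences(aln, ["A0", "A1"], ["B0", "B1"])
        assert diffs == []

    def test_gap_in_either_group_excludes_column(self):
        aln = _aln("AAAA", "CAAA", n=2)
        aln["B1"] = "-AAA"
        assert cc.find_fixed_differences(aln, ["A0", "A1"], ["B0", "B1"]) == []

    def test_group_label_swap_symmetry(self):
        a, b = "ACGTACGTAC", "ACCTACGAAG"
        fwd = cc.find_fixed_differences(_aln(a, b), ["A0", "A1"], ["B0", "B1"])
        rev = cc.find_fixed_differences(_aln(a, b), ["B0", "B1"], ["A0", "A1"])
        assert [(d.position, d.allele_A, d.allele_B) for d in fwd] == [
            (d.position, d.allele_B, d.allele_A) for d in rev
        ]

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            cc.find_fixed_differences(_aln("AA", "CC"), ["A0", "A1"], ["A1", "B0"])

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            cc.find_fixed_differences(_aln("AA", "CC"), ["A0", "ZZ"], ["B0", "B1"])


class TestClassifyEffect:
    REF = "AAAGATCCC"  # codons at 4..6: GAT (Asp) on the plus strand
    CDS = [GeneAnnotation("g", "cp", 4, 6, "+")]

    def test_third_position_gat_to_gac_synonymous(self):
        d = cc.FixedDifference(position=6, allele_A="T", allele_B="C")
        out = cc.classify_effect(d, self.CDS, self.REF)
        assert out.effect == "synonymous"
        assert (out.aa_A, out.aa_B) == ("D", "D")
        assert out.codon_index == 1

    def test_first_position_aaa_to_gaa_nonsynonymous(self):
        ref = "AAAAAACCC"
        cds = [GeneAnnotation("g", "cp", 4, 6, "+")]
        d = cc.FixedDifference(position=4, allele_A="A", allele_B="G")
        out = cc.classify_effect(d, cds, ref)
        assert out.effect == "nonsynonymous"
        assert (out.aa_A, out.aa_B) == ("K", "E")  # Lys -> Glu

    def test_minus_strand_reverse_complemented(self):
        # genomic TTT on minus strand reads AAA (Lys); T->C at genomic pos 6
        # is coding first position A->G: Lys -> Glu
        ref = "AAATTTCCC"
        cds = [GeneAnnotation("g", "cp", 4, 6, "-")]
        d = cc.FixedDifference(position=6, allele_A="T", allele_B="C")
        out = cc.classify_effect(d, cds, ref)
        assert out.effect == "nonsynonymous"
        assert (out.aa_A, out.aa_B) == ("K", "E")

    def test_outside_cds_is_noncoding(self):
        d = cc.FixedDifference(position=1, allele_A="A", allele_B="C")
        out = cc.classify_effect(d, self.CDS, self.REF)
        assert out.effect == "noncoding" and out.gene_id is None

    def test_cds_length_not_multiple_of_three_errors(self):
        bad = [GeneAnnotation("g", "cp", 4, 7, "+")]
        d = cc.FixedDifference(position=5, allele_A="A", allele_B="C")
        with pytest.raises(cc.cpdiff.AnnotationError):
            cc.classify_effect(d, bad, self.REF)

    def test_two_differences_in_one_codon_classified_jointly(self):
        # GAT with both first and third position changed: joint codon CAC (His)
        diffs = [
            cc.FixedDifference(position=4, allele_A="G", allele_B="C"),
            cc.FixedDifference(position=6, allele_A="T", allele_B="C"),
        ]
        out = cc.classify_effects(diffs, self.CDS, self.REF)
        assert all(d.multi_site for d in out)
        assert all(d.aa_B == "H" for d in out)
        assert all(d.effect == "nonsynonymous" for d in out)

    def test_planted_alignment_scale_62_and_9(self):
        aln, cds, truth = cc.generate_cp_alignment(cc.AlignmentConfig(), 5)
        a_ids = sorted(k for k in aln if k.startswith("A"))
        b_ids = sorted(k for k in aln if k.startswith("B"))
        diffs = cc.find_fixed_differences(aln, a_ids, b_ids)
        diffs = cc.classify_effects(diffs, cds, aln[a_ids[0]])
        assert len(diffs) == 62
        assert sum(d.effect == "nonsynonymous" for d in diffs) == 9
        planted = {d["position"]: d["effect"] for d in truth.planted_fixed_diffs}
        assert {d.position: d.effect for d in diffs} == planted


class TestJukesCantor:
    def test_identical_zero(self):
        assert cc.jc_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_closed_form_at_p_01(self):
        s1 = "A" * 90 + "C" * 10
        s2 = "A" * 100
        assert cc.jc_distance(s1, s2) == pytest.approx(0.107326, abs=1e-6)

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            cc.jc_distance("A" * 4, "C" * 3 + "A")

    def test_gap_columns_dropped_pairwise(self):
        assert cc.jc_distance("AC-T", "ACGT") == 0.0

    def test_symmetry(self, rng):
        a = "".join(rng.choice(list("ACGT"), 60))
        b = "".join(rng.choice(list("ACGT"), 60))
        try:
            assert cc.jc_distance(a, b) == cc.jc_distance(b, a)
        except SaturationError:
            pass


def random_additive_matrix(rng, n):
    """Distances from a random weighted binary tree: NJ must recover them."""
    import networkx as nx

    G = nx.Graph()
    labels = [f"T{chr(65 + i)}" for i in range(n)]
    for lbl in labels[:3]:
        G.add_edge("int0", lbl, weight=float(rng.uniform(0.1, 2)))
    nxt = 1
    for lbl in labels[3:]:
        u, v, dat = list(G.edges(data=True))[rng.integers(G.number_of_edges())]
        w = dat["weight"]
        G.remove_edge(u, v)
        mid = f"int{nxt}"
        nxt += 1
        s = float(rng.uniform(0.2, 0.8))
        G.add_edge(u, mid, weight=w * s)
        G.add_edge(mid, v, weight=w * (1 - s))
        G.add_edge(mid, lbl, weight=float(rng.uniform(0.1, 2)))
    dist = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
    D = np.array([[dist[a][b] for b in labels] for a in labels])
    return D, labels


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        import dendropy

        # tree ((A:1,B:2):1,(C:3,D:4))
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        nwk = cc.nj_tree(D, ["A", "B", "C", "D"])
        t = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        tax = {x.label: x for x in t.taxon_namespace}
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert pdm.distance(tax[a], tax[b]) == pytest.approx(D[i, j])
        # AB|CD split present
        assert frozenset("AB") in _splits(nwk, set("ABCD"))

    def test_additive_matrices_recovered(self, rng):
        import dendropy

        for _ in range(20):
            n = int(rng.integers(4, 9))
            D, labels = random_additive_matrix(rng, n)
            t = dendropy.Tree.get(data=cc.nj_tree(D, labels), schema="newick")
            pdm = t.phylogenetic_distance_matrix()
            tax = {x.label: x for x in t.taxon_namespace}
            for i in range(n):
                for j in range(i + 1, n):
                    assert pdm.distance(tax[labels[i]], tax[labels[j]]) == pytest.approx(
                        D[i, j], abs=1e-6
                    )

    def test_three_taxa_three_point_formulas(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        nwk = cc.nj_tree(D, ["a", "b", "c"])
        # a = (2+3-4)/2 = 0.5, b = 1.5, c = 2.5
        assert nwk == "(a:0.5,b:1.5,c:2.5);"

    def test_taxon_order_invariance(self, rng):
        D, labels = random_additive_matrix(rng, 6)
        nwk1 = cc.nj_tree(D, labels)
        perm = rng.permutation(6)
        nwk2 = cc.nj_tree(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert set(_splits(nwk1, set(labels))) == set(_splits(nwk2, set(labels)))

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.1, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="asymmetric"):
            cc.nj_tree(D, ["a", "b", "c"])


class TestPolarize:
    def test_group_a_matches_outgroups(self):
        aln = {"A1": "GAT", "A2": "GAT", "B1": "CAT", "B2": "CAT",
               "O1": "GAT", "O2": "GAT"}
        call = cc.polarize(aln, {"A": ["A1", "A2"], "B": ["B1", "B2"]},
                           ["O1", "O2"], "g", 1)
        assert call.ancestral_group == "A"

    def test_split_outgroups_unresolved(self):
        aln = {"A1": "GAT", "A2": "GAT", "B1": "CAT", "B2": "CAT",
               "O1": "GAT", "O2": "CAT"}
        call = cc.polarize(aln, {"A": ["A1", "A2"], "B": ["B1", "B2"]},
                           ["O1", "O2"], "g", 1)
        assert call.ancestral_group == "unresolved"

    def test_missing_outgroups_rejected(self):
        with pytest.raises(ValueError):
            cc.polarize({"A1": "GAT"}, {"A": ["A1"], "B": []}, [], "g", 1)

    def test_simulated_divergence_calls_derived_group(self, rng):
        correct = 0
        for s in range(50):
            r = np.random.default_rng(4000 + s)
            L = 60
            anc = "".join(r.choice(list("ACGT"), L))
            derived = list(anc)
            for pos in r.choice(L, 6, replace=False):
                derived[pos] = r.choice([c for c in "ACGT" if c != derived[pos]])
            derived = "".join(derived)

            def mutate(seq, k):
                s2 = list(seq)
                for pos in r.choice(L, k, replace=False):
                    s2[pos] = r.choice([c for c in "ACGT" if c != s2[pos]])
                return "".join(s2)

            aln = {
                "A1": mutate(anc, 1), "A2": mutate(anc, 1),
                "B1": mutate(derived, 1), "B2": mutate(derived, 1),
                "O1": mutate(anc, 2), "O2": mutate(anc, 2),
            }
            call = cc.polarize(aln, {"A": ["A1", "A2"], "B": ["B1", "B2"]},
                               ["O1", "O2"], "g", s)
            correct += call.ancestral_group == "A"
        assert correct >= 48  # >= 95% of replicates
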