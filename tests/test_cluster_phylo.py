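import random

import dendropy
import numpy as np
import pytest

from ltrkit.cluster_phylo import (
    DistanceMatrix,
    cluster_by_identity,
    concat_domains,
    nj_tree,
    observed_distance_matrix,
    select_representative,
)
from ltrkit.core_io import ElementRecord, GenomicSequence
from ltrkit.domain_scan import DomainArchitecture, DomainCall
from ltrkit.synth_fixtures import mutate_protein, random_protein

AA = "ACDEFGHIKLMNPQRSTVWY"


def _record(lengths: dict):
    calls = []
    pos = 0
    rng = random.Random(0)
    for dtype, L in lengths.items():
        calls.append(
            DomainCall(dtype, (pos, pos + 3 * L), "+", f"Ty3-{dtype}__X", "L", 100.0, 100.0, 1,
                       protein=random_protein(rng, L))
        )
        pos += 3 * L
    rec = ElementRecord(GenomicSequence("e", "A" * (pos + 10)))
    rec.architecture = DomainArchitecture(calls, "Ty3/gypsy", None)
    return rec


class TestConcatDomains:
    def test_length_additivity_and_fixed_order(self):
        rec = _record({"GAG": 400, "PROT": 100, "RT": 250, "RH": 130, "INT": 280})
        prot = concat_domains(rec)
        assert len(prot) == 100 + 250 + 130 + 280
        calls = {c.domain_type: c.protein for c in rec.architecture.calls}
        assert prot == calls["PROT"] + calls["RT"] + calls["RH"] + calls["INT"]

    def test_missing_domain_skips_element(self):
        rec = _record({"PROT": 100, "RT": 250, "INT": 280})  # no RH
        assert concat_domains(rec) is None

    def test_order_is_superfamily_independent(self, annotated_small):
        records, _ = annotated_small
        for rec in records:
            prot = concat_domains(rec)
            calls = {c.domain_type: c.protein for c in rec.architecture.calls}
            assert prot == calls["PROT"] + calls["RT"] + calls["RH"] + calls["INT"]


def _spread_mutant(rng, base, k):
    """k substitutions spread across the interior so local trimming cannot
    shift the nominal identity across a threshold."""
    out = list(base)
    positions = [round(1 + i * (len(base) - 3) / (k - 1)) for i in range(k)]
    for i in sorted(set(positions)):
        out[i] = rng.choice([a for a in AA if a != out[i]])
    return "".join(out)


class TestClusterByIdentity:
    def test_identical_pair_clusters_together(self):
        p = random_protein(random.Random(1), 200)
        clusters = cluster_by_identity({"a": p, "b": p})
        assert len(clusters) == 1
        assert clusters[0].members == ["a", "b"]

    def test_79_percent_identity_separates(self):
        rng = random.Random(2)
        base = random_protein(rng, 200)
        other = _spread_mutant(rng, base, 42)  # 79% nominal identity
        assert len(cluster_by_identity({"a": base, "b": other})) == 2

    def test_80_percent_identity_joins(self):
        rng = random.Random(3)
        base = random_protein(rng, 200)
        other = _spread_mutant(rng, base, 40)  # 80% nominal identity
        assert len(cluster_by_identity({"a": base, "b": other})) == 1

    def test_transitive_linkage(self):
        rng = random.Random(4)
        a = random_protein(rng, 200)
        b = _spread_mutant(rng, a, 30)  # a~b at 85%
        c = _spread_mutant(rng, b, 30)  # b~c at 85%, a~c ~72%
        clusters = cluster_by_identity({"a": a, "b": b, "c": c})
        assert len(clusters) == 1 and clusters[0].members == ["a", "b", "c"]

    def test_order_invariance(self):
        rng = random.Random(5)
        prots = {f"p{i}": random_protein(rng, 150) for i in range(4)}
        prots["p4"] = _spread_mutant(rng, prots["p0"], 10)
        forward = cluster_by_identity(prots)
        backward = cluster_by_identity(dict(reversed(list(prots.items()))))
        assert [c.members for c in forward] == [c.members for c in backward]
        assert [c.representative for c in forward] == [c.representative for c in backward]


class TestSelectRepresentative:
    def test_singleton_is_its_own_representative(self):
        assert select_representative(["x"], {"x": "MKLV" * 30}) == "x"

    def test_near_identical_members_pick_longest(self):
        rng = random.Random(6)
        base = random_protein(rng, 200)
        prots = {"a": base, "b": base[:195], "c": base[:190]}
        assert select_representative(["a", "b", "c"], prots) == "a"

    def test_larger_subgroup_wins(self):
        rng = random.Random(7)
        base_x = random_protein(rng, 220)
        base_y = random_protein(rng, 200)
        prots = {
            "x1": base_x, "x2": mutate_protein(rng, base_x, 8), "x3": mutate_protein(rng, base_x, 8),
            "y1": base_y, "y2": mutate_protein(rng, base_y, 8),
        }
        rep = select_representative(sorted(prots), prots)
        assert rep == "x1"  # seed of the size-3 sub-group


class TestObservedDistance:
    def test_identical_rows_zero(self):
        dm = observed_distance_matrix([("a", "ACDEF"), ("b", "ACDEF")])
        assert dm.matrix[0, 1] == 0.0

    def test_gap_columns_excluded_pairwise(self):
        dm = observed_distance_matrix([("a", "AC-T"), ("b", "ACGT")])
        assert dm.matrix[0, 1] == 0.0  # 3 comparable columns, all identical

    def test_two_of_ten_differences(self):
        a = "AAAAAAAAAA"
        b = "AACCAAAAAA"
        dm = observed_distance_matrix([("a", a), ("b", b)])
        assert dm.matrix[0, 1] == pytest.approx(0.2)

    def test_ragged_alignment_is_error(self):
        with pytest.raises(ValueError, match="ragged"):
            observed_distance_matrix([("a", "ACGT"), ("b", "ACG")])


def _patristic(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])


FOUR_TAXON = DistanceMatrix(
    ["A", "B", "C", "D"],
    # additive distances of tree ((A:1,B:2):1,(C:3,D:1))
    np.array([[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float),
)


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        dist = _patristic(nj_tree(FOUR_TAXON))
        labels = FOUR_TAXON.labels
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                want = FOUR_TAXON.matrix[labels.index(a), labels.index(b)]
                assert dist(a, b) == pytest.approx(want, abs=1e-9)

    def test_equal_distances_give_star_like_tree(self):
        n = 4
        m = np.full((n, n), 2.0)
        np.fill_diagonal(m, 0.0)
        newick = nj_tree(DistanceMatrix(list("ABCD"), m))
        dist = _patristic(newick)
        for a in "ABC":
            assert dist(a, "D") == pytest.approx(2.0, abs=1e-9)

    def test_label_permutation_preserves_topology(self):
        perm = [2, 0, 3, 1]
        labels = [FOUR_TAXON.labels[i] for i in perm]
        m = FOUR_TAXON.matrix[np.ix_(perm, perm)]
        t1 = nj_tree(FOUR_TAXON)
        t2 = nj_tree(DistanceMatrix(labels, m))
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1, schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2, schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(d1, d2) == 0

    def test_matches_skbio_on_additive_input(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        ours = dendropy.Tree.get(data=nj_tree(FOUR_TAXON), schema="newick")
        theirs = dendropy.Tree.get(
            data=str(sk_nj(SkDM(FOUR_TAXON.matrix, FOUR_TAXON.labels))),
            schema="newick",
            taxon_namespace=ours.taxon_namespace,
        )
        ours.encode_bipartitions()
        theirs.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(ours, theirs) == 0

    def test_fewer_than_three_taxa_is_error(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestBimodality:
    def test_two_divergent_families_separate_into_two_modes(self):
        """Within-family vs between-family distances form two modes with an
        empty band between them when families sit at ~90%/~40% identity."""
        rng = random.Random(8)
        base1 = random_protein(rng, 150)
        base2 = mutate_protein(rng, base1, 90)  # ~40% identity to base1
        fam1 = [mutate_protein(rng, base1, 8) for _ in range(5)]
        fam2 = [mutate_protein(rng, base2, 8) for _ in range(5)]
        rows = [(f"a{i}", s) for i, s in enumerate(fam1)]
        rows += [(f"b{i}", s) for i, s in enumerate(fam2)]
        dm = observed_distance_matrix(rows)
        intra, inter = [], []
        for i in range(10):
            for j in range(i + 1, 10):
                (intra if (i < 5) == (j < 5) else inter).append(dm.matrix[i, j])
        assert max(intra) < min(inter)  # empty band between the modes
        assert min(inter) - max(intra) > 0.2
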