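import itertools

import numpy as np
import pytest

from c1comp import (
    HitFilter,
    MarkerIdentity,
    Proteome,
    SimConfig,
    aai_matrix,
    best_hits,
    compute_aai,
    fig1_table,
    marker_identity,
    protein_scheme,
    reciprocal_best_hits,
    simulate,
)
from c1comp.aai import AAIError, RBHSet
from c1comp.seqio import GenomeBundle, FeatureTable, Feature

from conftest import random_protein


def _proteome(rng, n, length=120):
    return Proteome({f"g{i:03d}": random_protein(rng, length) for i in range(n)})


class TestBestHits:
    def test_self_best_hit_is_self(self):
        rng = np.random.default_rng(0)
        p = _proteome(rng, 10)
        hits = best_hits(p, p)
        assert set(hits) == set(p)
        assert all(h.subject_tag == q for q, h in hits.items())
        assert all(h.identity_pct == 100.0 for h in hits.values())

    def test_tie_broken_by_smallest_subject_tag(self):
        rng = np.random.default_rng(1)
        seq = random_protein(rng, 100)
        query = Proteome({"q": seq})
        subjects = Proteome({"s2": seq, "s1": seq})
        hits = best_hits(query, subjects)
        assert hits["q"].subject_tag == "s1"

    def test_mutated_ortholog_identity_near_70(self, small_pair):
        bundles, _, truth = small_pair
        a, b = bundles
        hits = best_hits(a.proteome, b.proteome)
        tags = truth.orthologs
        ids = [hits[m["A"]].identity_pct for m in tags.values()
               if m["A"] in hits]
        assert abs(np.mean(ids) - 70.0) <= 2.0

    def test_short_proteins_excluded(self):
        rng = np.random.default_rng(2)
        p = Proteome({"long": random_protein(rng, 100),
                      "short": random_protein(rng, 30)})
        hits = best_hits(p, p)
        assert "short" not in hits


class TestRBH:
    def test_identical_proteomes_all_pairs_at_100(self):
        rng = np.random.default_rng(3)
        p = _proteome(rng, 8)
        rbh = reciprocal_best_hits(p, p)
        assert len(rbh) == 8
        assert all(pair.identity_pct == 100.0 for pair in rbh.pairs)

    def test_duplicated_gene_pairs_at_most_once(self):
        rng = np.random.default_rng(4)
        seq = random_protein(rng, 150)
        a = Proteome({"a1": seq, "a2": seq, "x": random_protein(rng, 150)})
        b = Proteome({"b": seq, "y": random_protein(rng, 150)})
        rbh = reciprocal_best_hits(a, b)
        hits_to_b = [p for p in rbh.pairs if p.subject_tag == "b"]
        assert len(hits_to_b) == 1
        assert hits_to_b[0].query_tag in ("a1", "a2")

    def test_symmetric_pair_sets(self, small_pair):
        bundles, _, _ = small_pair
        a, b = bundles
        fwd = reciprocal_best_hits(a.proteome, b.proteome)
        rev = reciprocal_best_hits(b.proteome, a.proteome)
        fwd_pairs = {frozenset((p.query_tag, p.subject_tag)) for p in fwd.pairs}
        rev_pairs = {frozenset((p.query_tag, p.subject_tag)) for p in rev.pairs}
        assert fwd_pairs == rev_pairs

    def test_most_orthologs_recovered(self, small_pair):
        bundles, _, truth = small_pair
        a, b = bundles
        rbh = reciprocal_best_hits(a.proteome, b.proteome)
        true_pairs = {frozenset((m["A"], m["B"])) for m in truth.orthologs.values()}
        found = {frozenset((p.query_tag, p.subject_tag)) for p in rbh.pairs}
        assert len(found & true_pairs) >= 0.95 * len(true_pairs)


class TestAAI:
    def test_self_aai_is_exactly_100(self):
        rng = np.random.default_rng(5)
        p = _proteome(rng, 6)
        res = compute_aai(reciprocal_best_hits(p, p))
        assert res.aai_pct == 100.0

    def test_unweighted_mean(self):
        pairs = RBHSet("A", "B", [])
        from c1comp.aai import HitPair
        pairs.pairs = [HitPair("a", "b", 60.0, 1, 1, 100),
                       HitPair("c", "d", 80.0, 1, 1, 100)]
        assert compute_aai(pairs).aai_pct == 70.0

    def test_empty_rbh_raises(self):
        with pytest.raises(AAIError, match="no orthologs"):
            compute_aai(RBHSet("A", "B", []))

    def test_aai_unchanged_by_unpaired_genes(self, small_pair):
        bundles, _, _ = small_pair
        a, b = bundles
        rbh = reciprocal_best_hits(a.proteome, b.proteome)
        base = compute_aai(rbh).aai_pct
        paired = {p.query_tag for p in rbh.pairs}
        rng = np.random.default_rng(6)
        extra = Proteome(dict(a.proteome.items()) | {
            "noise1": random_protein(rng, 200),
            "noise2": random_protein(rng, 200)})
        res = compute_aai(reciprocal_best_hits(extra, b.proteome))
        assert res.aai_pct == pytest.approx(base, abs=1e-6)
        assert paired <= {p.query_tag for p in
                          reciprocal_best_hits(extra, b.proteome).pairs}


class TestAAIMatrix:
    def test_identical_genomes_matrix_of_100(self):
        rng = np.random.default_rng(7)
        p = _proteome(rng, 6)
        ft = FeatureTable([Feature(t, "c1", 1 + 400 * i, 360 + 400 * i, "+")
                           for i, t in enumerate(p)])
        g1 = GenomeBundle("G1", p, ft)
        g2 = GenomeBundle("G2", p, ft)
        mat = aai_matrix([g1, g2])
        assert np.allclose(mat.values.values, 100.0)

    def test_three_genome_targets_recovered(self):
        cfg = SimConfig(
            seed=13, labels=("A", "B", "C"), genes_per_genome=50,
            target_identity_pct={("A", "B"): 90.0, ("A", "C"): 70.0,
                                 ("B", "C"): 70.0},
        )
        bundles, _, _ = simulate(cfg)
        mat = aai_matrix(bundles)
        assert abs(mat.values.loc["A", "B"] - 90.0) <= 2.0
        assert abs(mat.values.loc["A", "C"] - 70.0) <= 2.0
        assert abs(mat.values.loc["B", "C"] - 70.0) <= 2.0
        assert np.allclose(mat.values.values, mat.values.values.T)


class TestMarkerIdentity:
    def test_identical_markers(self):
        seqs = {"A": "ACGT" * 100, "B": "ACGT" * 100}
        res = marker_identity("A", "B", seqs)
        assert res.identity_pct == 100.0

    def test_one_mutation_in_1500(self):
        rng = np.random.default_rng(8)
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, 1500))
        mutated = list(s)
        mutated[700] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[700]]
        res = marker_identity("A", "B", {"A": s, "B": "".join(mutated)})
        assert res.identity_pct == pytest.approx(100 * 1499 / 1500, abs=1e-6)

    def test_simulated_3pct_divergence(self, small_pair):
        bundles, _, truth = small_pair
        res = marker_identity(bundles[0], bundles[1])
        assert abs(res.identity_pct - 97.0) <= 0.5

    def test_missing_marker_names_genome(self):
        with pytest.raises(AAIError, match="Zed"):
            marker_identity("Zed", "B", {"B": "ACGT"})


class TestFig1Table:
    def test_pair_count_combinatorics(self):
        cfg = SimConfig(seed=21, labels=("A", "B", "C"), genes_per_genome=30,
                        target_identity_pct=80.0)
        bundles, _, _ = simulate(cfg)
        mat = aai_matrix(bundles)
        markers = [marker_identity(x, y)
                   for x, y in itertools.combinations(bundles, 2)]
        table = fig1_table(mat, markers)
        assert len(table) == 3  # n(n-1)/2 for n=3
        assert set(table.columns) >= {"aai_pct", "marker_identity_pct"}

    def test_divergence_ranks_agree(self):
        # deeper protein divergence should come with deeper 16S divergence;
        # pairwise targets are built from per-genome branch loads so the
        # matrix is exactly star-decomposable
        from c1comp import expected_identity_pct
        labels = ("A", "B", "C", "D")
        prot_load = {"A": 0.02, "B": 0.06, "C": 0.20, "D": 0.45}
        nt_load = {"A": 0.002, "B": 0.006, "C": 0.02, "D": 0.045}
        targets = {
            (x, y): expected_identity_pct(prot_load[x] + prot_load[y])
            for x, y in itertools.combinations(labels, 2)}
        divergence = {
            (x, y): 100.0 - expected_identity_pct(nt_load[x] + nt_load[y], 4)
            for x, y in itertools.combinations(labels, 2)}
        cfg = SimConfig(
            seed=22, labels=labels, genes_per_genome=40,
            target_identity_pct=targets,
            marker_divergence_pct=divergence,
        )
        bundles, _, _ = simulate(cfg)
        mat = aai_matrix(bundles)
        markers = [marker_identity(x, y)
                   for x, y in itertools.combinations(bundles, 2)]
        table = fig1_table(mat, markers).sort_values("aai_pct")
        corr = table["aai_pct"].corr(table["marker_identity_pct"],
                                     method="spearman")
        assert corr > 0.8
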