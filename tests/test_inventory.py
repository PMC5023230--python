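import numpy as np
import pytest

from c1comp import (
    DuplicationEvent,
    InventoryThresholds,
    SimConfig,
    SingletonSpec,
    TruncationEvent,
    assign_types,
    build_inventory,
    find_fragments,
    find_homologs,
    simulate,
)
from c1comp.inventory import InventoryError, InventoryHit
from c1comp.seqio import (
    Feature,
    FeatureTable,
    GenomeBundle,
    PanelEntry,
    Proteome,
    ReferencePanel,
)

from conftest import random_protein


def _bundle(label, proteins):
    ft = FeatureTable([
        Feature(t, "c1", 1 + 1000 * i, 3 * len(s) + 1000 * i, "+")
        for i, (t, s) in enumerate(proteins.items())])
    return GenomeBundle(label, Proteome(proteins), ft)


@pytest.fixture(scope="module")
def panel():
    rng = np.random.default_rng(50)
    return ReferencePanel([
        PanelEntry("REF_Mao", "Mao", random_protein(rng, 400)),
        PanelEntry("REF_Hps", "Hps", random_protein(rng, 200)),
    ])


class TestFindHomologs:
    def test_exact_copy_is_one_full_hit(self, panel):
        rng = np.random.default_rng(51)
        mao = panel.by_function("Mao")[0].sequence
        g = _bundle("G", {"g1": mao, "g2": random_protein(rng, 300)})
        hits = find_homologs(g, panel)
        assert len(hits) == 1
        h = hits[0]
        assert (h.locus_tag, h.function_label, h.status) == ("g1", "Mao", "full")
        assert h.identity_pct == 100.0

    def test_no_similarity_gives_empty_list(self, panel):
        rng = np.random.default_rng(52)
        g = _bundle("G", {f"g{i}": random_protein(rng, 250) for i in range(5)})
        assert find_homologs(g, panel) == []

    def test_three_paralogs_all_recovered_full(self):
        # mirrors a genome encoding three nearly-identical oxidase copies
        cfg = SimConfig(seed=53, labels=("G",), genes_per_genome=30,
                        singletons=(SingletonSpec("Mao", ("G",)),),
                        duplications=(DuplicationEvent("Mao", 3, 95.0),))
        bundles, panel, truth = simulate(cfg)
        hits = find_homologs(bundles[0], panel)
        mao_hits = [h for h in hits if h.function_label == "Mao"]
        assert len(mao_hits) == 3
        assert all(h.status == "full" for h in mao_hits)
        assert {h.locus_tag for h in mao_hits} == set(truth.functions["G"])

    def test_planted_copies_recovered_exactly(self):
        # sensitivity 1.0 and no spurious hits at planted identity >= 60
        cfg = SimConfig(seed=54, labels=("A", "B"), genes_per_genome=40,
                        target_identity_pct=75.0,
                        singletons=(SingletonSpec("Mao", ("A", "B")),
                                    SingletonSpec("Hps", ("A", "B"))))
        bundles, panel, truth = simulate(cfg)
        for b in bundles:
            hits = find_homologs(b, panel)
            assert ({h.locus_tag for h in hits}
                    == set(truth.functions[b.label]))

    def test_raising_identity_threshold_monotone(self, small_pair):
        cfg = SimConfig(seed=55, labels=("G",), genes_per_genome=20,
                        singletons=(SingletonSpec("Mao", ("G",)),
                                    SingletonSpec("Hps", ("G",))))
        bundles, panel, _ = simulate(cfg)
        counts = []
        for min_id in (30.0, 60.0, 90.0, 99.5):
            th = InventoryThresholds(min_identity_pct=min_id)
            counts.append(len(find_homologs(bundles[0], panel, th)))
        assert counts == sorted(counts, reverse=True)


@pytest.fixture(scope="module")
def truncated_genome():
    cfg = SimConfig(seed=56, labels=("M",), genes_per_genome=20,
                    singletons=(SingletonSpec("Mao", ("M",)),
                                SingletonSpec("Hps", ("M",))),
                    truncations=(TruncationEvent("Mao", "M", 129),))
    return simulate(cfg)


class TestFindFragments:
    def test_129nt_fragment_reported_with_span_129(self, truncated_genome):
        bundles, panel, truth = truncated_genome
        mao = panel.by_function("Mao")[0]
        hits = find_fragments(bundles[0], mao)
        # the permissive remnant thresholds (>=25 aa at >=40%) may also
        # admit marginal chance windows; the true remnant is the best hit
        best = max(hits, key=lambda h: h.score)
        assert best.status == "partial"
        assert best.span_bp == 129
        rec = truth.truncations[0]
        assert best.nt_span == (rec["start"], rec["end"])
        strong = [h for h in hits if h.identity_pct >= 60.0]
        assert strong == [best]

    def test_unrelated_reference_finds_nothing(self, truncated_genome):
        bundles, panel, _ = truncated_genome
        rng = np.random.default_rng(57)
        decoy = PanelEntry("REF_Tmo", "Tmo", random_protein(rng, 500))
        assert find_fragments(bundles[0], decoy) == []

    def test_full_length_gene_not_reported_as_fragment(self, truncated_genome):
        bundles, panel, _ = truncated_genome
        hps = panel.by_function("Hps")[0]
        # Hps is intact in the genome: its six-frame hit covers the whole
        # reference and is therefore left to the homolog search
        assert find_fragments(bundles[0], hps) == []

    def test_spans_are_codon_multiples_within_contig(self, truncated_genome):
        bundles, panel, _ = truncated_genome
        mao = panel.by_function("Mao")[0]
        contig_len = len(bundles[0].contigs["contig1"])
        for h in find_fragments(bundles[0], mao):
            assert h.span_bp % 3 == 0
            s, e = h.nt_span
            assert 1 <= s <= e <= contig_len


class TestAssignTypes:
    def _hits(self, tags):
        return [InventoryHit("G", "Fdh", t, 100.0, 1.0, "full") for t in tags]

    def test_threshold_separates_families(self):
        rng = np.random.default_rng(58)
        base = random_protein(rng, 200)
        near = base[:20] + base[20:]  # identical
        far = random_protein(rng, 200)
        seqs = {"a": base, "b": near, "c": far}
        typed = assign_types(self._hits(["a", "b", "c"]), seqs)
        by_tag = {h.locus_tag: h.type_id for h in typed}
        assert by_tag["a"] == by_tag["b"] == 1
        assert by_tag["c"] == 2

    def test_single_hit_is_type_1(self):
        rng = np.random.default_rng(59)
        typed = assign_types(self._hits(["solo"]),
                             {"solo": random_protein(rng, 100)})
        assert typed[0].type_id == 1

    def test_three_simulated_families_recovered(self):
        # three divergent types, near-identical within, unrelated between
        rng = np.random.default_rng(60)
        families = [random_protein(rng, 250) for _ in range(3)]
        seqs = {}
        for fi, fam in enumerate(families):
            for ci in range(2):
                s = list(fam)
                for p in rng.choice(len(s), size=25, replace=False):
                    s[p] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
                seqs[f"f{fi}c{ci}"] = "".join(s)
        typed = assign_types(self._hits(sorted(seqs)), seqs)
        groups = {}
        for h in typed:
            groups.setdefault(h.type_id, set()).add(h.locus_tag[:2])
        assert len(groups) == 3
        assert all(len(v) == 1 for v in groups.values())

    def test_type_ids_invariant_to_input_order(self):
        rng = np.random.default_rng(61)
        base = random_protein(rng, 150)
        seqs = {"a": base, "b": base, "c": random_protein(rng, 150)}
        fwd = assign_types(self._hits(["a", "b", "c"]), seqs)
        rev = assign_types(self._hits(["c", "b", "a"]), seqs)
        assert ({h.locus_tag: h.type_id for h in fwd}
                == {h.locus_tag: h.type_id for h in rev})


class TestBuildInventory:
    def test_absent_function_rendered_as_dash(self):
        rng = np.random.default_rng(62)
        panel = ReferencePanel([
            PanelEntry("REF_Tmo", "Tmo", random_protein(rng, 300)),
            PanelEntry("REF_Hps", "Hps", random_protein(rng, 200)),
        ])
        hps = panel.by_function("Hps")[0].sequence
        g = _bundle("G", {"g1": hps, "g2": random_protein(rng, 200)})
        matrix = build_inventory([g], panel)
        frame = matrix.to_frame()
        assert frame.loc["Tmo", "G"] == "-"
        assert frame.loc["Hps", "G"] == "g1"

    def test_empty_panel_raises(self):
        rng = np.random.default_rng(63)
        g = _bundle("G", {"g1": random_protein(rng, 100)})
        with pytest.raises(InventoryError):
            build_inventory([g], ReferencePanel([]))

    def test_island_functions_fill_rows(self, hgt_pair):
        bundles, panel, truth = hgt_pair
        matrix = build_inventory(bundles, panel)
        for fn in ("Mao", "Tmo", "Gma", "MgsA"):
            assert matrix.cell(fn, "D") and matrix.cell(fn, "R")
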