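"""C1 gene-cluster (genomic island) detection and inheritance calls.

Methylotrophy genes are frequently organized in chromosomal islands —
dense runs of functionally related genes with the occasional
hypothetical or transposase insertion — and such islands move between
lineages.  This module (1) chains inventory hits along each contig into
clusters, (2) matches clusters across genomes by their function-set
overlap, and (3) classifies each shared gene (or cluster) as laterally
transferred or vertically inherited by contrasting its per-gene amino
acid identity (AI) with the genome-pair AAI: an AI far above AAI is the
signature of a recent transfer, an AI tracking AAI is ordinary vertical
descent.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .aai import AAIMatrix, AAIResult, RBHSet
from .align import ScoringScheme, align_global, protein_scheme
from .inventory import InventoryHit
from .seqio import GenomeBundle


class IslandError(ValueError):
    pass


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class GeneCluster:
    genome: str
    contig_id: str
    members: list[str]              # locus tags, sorted by start coordinate
    functions: list[str]            # parallel to members
    span_bp: int
    cluster_id: str = ""

    def function_set(self) -> frozenset:
        return frozenset(self.functions)


@dataclass(frozen=True)
class TransferCall:
    locus_a: str
    locus_b: str
    genome_a: str
    genome_b: str
    ai_pct: float
    genome_aai_pct: float
    verdict: str                    # lateral | vertical | ambiguous

    @property
    def delta(self) -> float:
        return self.ai_pct - self.genome_aai_pct


@dataclass
class ClusterComparison:
    cluster_a: GeneCluster
    cluster_b: GeneCluster
    shared_functions: list[str]
    jaccard: float
    mean_member_ai: float
    classification: str = ""        # common | unique | ""


@dataclass(frozen=True)
class TransferMargins:
    """Decision bands for lateral-vs-vertical calls, in identity points.

    ``lateral`` when AI - AAI >= lateral_margin; ``vertical`` when
    |AI - AAI| <= vertical_band; otherwise ``ambiguous``.  The deltas
    are always reported so calls can be re-thresholded without
    recomputation.
    """

    lateral_margin: float = 15.0
    vertical_band: float = 10.0

    def verdict(self, delta: float) -> str:
        if delta >= self.lateral_margin:
            return "lateral"
        if abs(delta) <= self.vertical_band:
            return "vertical"
        return "ambiguous"


# ---------------------------------------------------------------------------
# cluster detection
# ---------------------------------------------------------------------------


def detect_clusters(
    genome: GenomeBundle,
    hits: list[InventoryHit],
    max_gap: int = 3,
    min_size: int = 3,
) -> list[GeneCluster]:
    """Chain inventory hits on each contig into gene clusters.

    Greedy left-to-right: consecutive member genes may be separated by
    at most ``max_gap`` intervening non-member genes on the same contig;
    runs with >= ``min_size`` members are emitted.  Fragment hits
    (no annotated locus) are ignored.
    """
    located = []
    for h in hits:
        if h.nt_span is not None:       # unannotated fragment, no gene index
            continue
        if h.locus_tag not in genome.features:
            raise IslandError(
                f"hit {h.locus_tag} not in feature table of {genome.label}")
        located.append(h)
    by_contig: dict[str, list[InventoryHit]] = {}
    for h in located:
        by_contig.setdefault(genome.features.get(h.locus_tag).contig_id, []).append(h)
    clusters: list[GeneCluster] = []
    for contig_id in sorted(by_contig):
        chits = sorted(by_contig[contig_id],
                       key=lambda h: genome.features.gene_index(h.locus_tag))
        run: list[InventoryHit] = []
        def flush(run: list[InventoryHit]) -> None:
            if len(run) >= min_size:
                members = [h.locus_tag for h in run]
                feats = [genome.features.get(t) for t in members]
                clusters.append(GeneCluster(
                    genome=genome.label,
                    contig_id=contig_id,
                    members=members,
                    functions=[h.function_label for h in run],
                    span_bp=max(f.end for f in feats) - min(f.start for f in feats) + 1,
                ))
        for h in chits:
            if not run:
                run = [h]
                continue
            prev_idx = genome.features.gene_index(run[-1].locus_tag)
            idx = genome.features.gene_index(h.locus_tag)
            if idx - prev_idx - 1 <= max_gap:
                run.append(h)
            else:
                flush(run)
                run = [h]
        flush(run)
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"{genome.label}:c{i}"
    return clusters


# ---------------------------------------------------------------------------
# cluster comparison
# ---------------------------------------------------------------------------


def _greedy_function_pairing(
    ca: GeneCluster, cb: GeneCluster,
    proteome_a, proteome_b, scheme: ScoringScheme,
) -> list[tuple[str, str, float]]:
    """Best-identity pairing of members with matching functions, each
    member used at most once."""
    candidates: list[tuple[float, str, str]] = []
    for ta, fa in zip(ca.members, ca.functions):
        for tb, fb in zip(cb.members, cb.functions):
            if fa != fb:
                continue
            ident = align_global(proteome_a[ta], proteome_b[tb], scheme).identity_pct
            candidates.append((ident, ta, tb))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for ident, ta, tb in candidates:
        if ta in used_a or tb in used_b:
            continue
        used_a.add(ta)
        used_b.add(tb)
        pairs.append((ta, tb, ident))
    return pairs


def compare_clusters(
    clusters_a: list[GeneCluster],
    clusters_b: list[GeneCluster],
    proteome_a,
    proteome_b,
    scheme: ScoringScheme | None = None,
    min_jaccard: float = 0.5,
) -> list[ClusterComparison]:
    """All cross-genome cluster pairs with function-set Jaccard >= 0.5,
    scored by the mean AI of their matched members."""
    scheme = scheme or protein_scheme()
    out: list[ClusterComparison] = []
    for ca, cb in itertools.product(clusters_a, clusters_b):
        fa, fb = ca.function_set(), cb.function_set()
        union = fa | fb
        if not union:
            continue
        jaccard = len(fa & fb) / len(union)
        if jaccard < min_jaccard:
            continue
        pairs = _greedy_function_pairing(ca, cb, proteome_a, proteome_b, scheme)
        mean_ai = (sum(p[2] for p in pairs) / len(pairs)) if pairs else 0.0
        out.append(ClusterComparison(
            cluster_a=ca, cluster_b=cb,
            shared_functions=sorted(fa & fb),
            jaccard=jaccard,
            mean_member_ai=mean_ai,
        ))
    return out


def classify_common_unique(
    comparisons_by_pair: dict[frozenset, list[ClusterComparison]],
    clusters_by_genome: dict[str, list[GeneCluster]],
    groups: dict[str, str],
    min_jaccard: float = 0.5,
) -> dict[str, str]:
    """Label each cluster 'common' or 'unique' within its genus group.

    A cluster is common when a counterpart (Jaccard >= threshold)
    exists in every other genome of the same declared group; groups are
    user-supplied (genome label -> group name), not inferred.
    """
    labels: dict[str, str] = {}
    for genome, clusters in clusters_by_genome.items():
        group = groups.get(genome)
        others = [g for g, grp in groups.items() if grp == group and g != genome]
        for c in clusters:
            if not others:
                labels[c.cluster_id] = "unique"
                continue
            ok = True
            for other in others:
                comps = comparisons_by_pair.get(frozenset((genome, other)), [])
                found = any(
                    (cmp.cluster_a.cluster_id == c.cluster_id
                     or cmp.cluster_b.cluster_id == c.cluster_id)
                    and cmp.jaccard >= min_jaccard
                    for cmp in comps)
                if not found:
                    ok = False
                    break
            labels[c.cluster_id] = "common" if ok else "unique"
    return labels


# ---------------------------------------------------------------------------
# lateral vs vertical calls
# ---------------------------------------------------------------------------


def call_transfers(
    pairs: RBHSet | list[tuple[str, str, float]],
    genome_aai: AAIResult,
    margins: TransferMargins | None = None,
) -> list[TransferCall]:
    """Lateral / vertical / ambiguous verdict per ortholog pair.

    ``pairs`` is either an RBH set or explicit (locus_a, locus_b,
    ai_pct) triples; the verdict compares each pair's AI with the
    genome-pair AAI using the configured margins.
    """
    margins = margins or TransferMargins()
    if isinstance(pairs, RBHSet):
        triples = [(p.query_tag, p.subject_tag, p.identity_pct) for p in pairs.pairs]
    else:
        triples = list(pairs)
    out = []
    for la, lb, ai in triples:
        delta = ai - genome_aai.aai_pct
        out.append(TransferCall(
            locus_a=la, locus_b=lb,
            genome_a=genome_aai.genome_a, genome_b=genome_aai.genome_b,
            ai_pct=ai, genome_aai_pct=genome_aai.aai_pct,
            verdict=margins.verdict(delta),
        ))
    return out


def aggregate_verdict(calls: list[TransferCall]) -> str:
    """Majority verdict of a cluster's member calls (ties -> ambiguous)."""
    if not calls:
        return "ambiguous"
    counts = Counter(c.verdict for c in calls)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return "ambiguous"
    return top[0][0]


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

_CATEGORY_KEYWORDS = [
    ("transposase", "transposase"),
    ("regulat", "regulatory"),
    ("transport", "transport"),
    ("hypothetical", "hypothetical"),
]


def _product_category(product: str) -> str:
    text = product.lower()
    for needle, cat in _CATEGORY_KEYWORDS:
        if needle in text:
            return cat
    return "methylotrophy" if product else "other"


@dataclass
class IslandReport:
    clusters: pd.DataFrame          # one row per cluster member
    transfer_calls: pd.DataFrame    # one row per compared gene pair
    cluster_verdicts: pd.DataFrame  # aggregated per compared cluster pair


def island_report(
    genomes: list[GenomeBundle],
    hits_by_genome: dict[str, list[InventoryHit]],
    matrix: AAIMatrix | None,
    max_gap: int = 3,
    min_size: int = 3,
    margins: TransferMargins | None = None,
    scheme: ScoringScheme | None = None,
    groups: dict[str, str] | None = None,
) -> IslandReport:
    """Cluster map plus lateral/vertical calls for a genome set.

    With a single genome (or no AAI matrix) only the cluster table is
    produced.  Per compared cluster pair, member genes are paired by
    function and identity, each member call is made against the
    genome-pair AAI, and the cluster verdict is the majority call.
    """
    margins = margins or TransferMargins()
    scheme = scheme or protein_scheme()
    bundles = {g.label: g for g in genomes}
    clusters_by_genome = {
        g.label: detect_clusters(g, hits_by_genome.get(g.label, []),
                                 max_gap, min_size)
        for g in genomes
    }

    cluster_rows = []
    for label, clusters in clusters_by_genome.items():
        feats = bundles[label].features
        for c in clusters:
            for tag, fn in zip(c.members, c.functions):
                f = feats.get(tag)
                cluster_rows.append({
                    "genome": label, "cluster_id": c.cluster_id,
                    "contig_id": c.contig_id, "locus_tag": tag,
                    "function": fn, "start": f.start, "end": f.end,
                    "strand": f.strand,
                    "category": _product_category(f.product),
                })
    cluster_df = pd.DataFrame(
        cluster_rows,
        columns=["genome", "cluster_id", "contig_id", "locus_tag", "function",
                 "start", "end", "strand", "category"])

    call_rows: list[dict] = []
    verdict_rows: list[dict] = []
    comparisons_by_pair: dict[frozenset, list[ClusterComparison]] = {}
    if matrix is not None and len(genomes) > 1:
        for ga, gb in itertools.combinations(genomes, 2):
            aai_res = matrix.get(ga.label, gb.label)
            if aai_res is None:
                continue
            comps = compare_clusters(
                clusters_by_genome[ga.label], clusters_by_genome[gb.label],
                ga.proteome, gb.proteome, scheme)
            comparisons_by_pair[frozenset((ga.label, gb.label))] = comps
            for cmp in comps:
                pairs = _greedy_function_pairing(
                    cmp.cluster_a, cmp.cluster_b, ga.proteome, gb.proteome, scheme)
                calls = call_transfers(
                    [(ta, tb, ident) for ta, tb, ident in pairs], aai_res, margins)
                for call in calls:
                    call_rows.append({
                        "genome_a": call.genome_a, "genome_b": call.genome_b,
                        "cluster_a": cmp.cluster_a.cluster_id,
                        "cluster_b": cmp.cluster_b.cluster_id,
                        "locus_a": call.locus_a, "locus_b": call.locus_b,
                        "ai_pct": call.ai_pct,
                        "genome_aai_pct": call.genome_aai_pct,
                        "delta": call.delta, "verdict": call.verdict,
                    })
                verdict_rows.append({
                    "genome_a": ga.label, "genome_b": gb.label,
                    "cluster_a": cmp.cluster_a.cluster_id,
                    "cluster_b": cmp.cluster_b.cluster_id,
                    "jaccard": cmp.jaccard,
                    "mean_member_ai": cmp.mean_member_ai,
                    "verdict": aggregate_verdict(calls),
                })
    call_df = pd.DataFrame(
        call_rows,
        columns=["genome_a", "genome_b", "cluster_a", "cluster_b", "locus_a",
                 "locus_b", "ai_pct", "genome_aai_pct", "delta", "verdict"])
    verdict_df = pd.DataFrame(
        verdict_rows,
        columns=["genome_a", "genome_b", "cluster_a", "cluster_b", "jaccard",
                 "mean_member_ai", "verdict"])
    if groups:
        labels = classify_common_unique(comparisons_by_pair, clusters_by_genome,
                                        groups)
        if len(cluster_df):
            cluster_df["cluster_class"] = cluster_df["cluster_id"].map(
                lambda cid: labels.get(cid, "unique"))
    return IslandReport(clusters=cluster_df, transfer_calls=call_df,
                        cluster_verdicts=verdict_df)
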