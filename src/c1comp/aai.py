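"""Reciprocal-best-hit orthology and average amino acid identity (AAI).

AAI between two genomes is the unweighted mean percent identity over
their reciprocal-best-hit (RBH) protein pairs — the standard genome-wide
relatedness statistic for comparing proteomes across large evolutionary
distances, where nucleotide-level measures saturate.  Per-gene amino
acid identity (AI) of a single pair is the same quantity for one
protein, and the contrast between AI and AAI is what the island module
uses to flag lateral transfer.

Hits are filtered with the classic AAI criterion: local identity >= 30%
and an alignment covering >= 70% of the shorter protein; proteins under
50 aa are excluded as fragment noise.  All thresholds are configurable
via :class:`HitFilter`.

Searching every query against every subject with exact Smith-Waterman
is quadratic and dominated by the alignment kernel, so candidate
subjects are preselected per query by edit distance (edlib), and exact
local alignment is run on the top ``prescreen_k`` candidates only.  The
prescreen is deterministic; set ``prescreen_k=None`` to search
exhaustively.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .align import ScoringScheme, align_global, align_local, nucleotide_scheme, protein_scheme
from .seqio import GenomeBundle, Proteome


class AAIError(ValueError):
    pass


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HitFilter:
    """Acceptance thresholds for a local hit to count as homologous."""

    min_identity_pct: float = 30.0
    min_short_coverage: float = 0.7  # fraction of the shorter protein aligned
    min_length: int = 50             # proteins below this are skipped entirely

    def passes(self, identity_pct: float, coverage_query: float,
               coverage_subject: float, len_query: int, len_subject: int) -> bool:
        short_cov = coverage_query if len_query <= len_subject else coverage_subject
        return (identity_pct >= self.min_identity_pct
                and short_cov >= self.min_short_coverage)


@dataclass(frozen=True)
class HitPair:
    query_tag: str
    subject_tag: str
    identity_pct: float
    coverage_query: float
    coverage_subject: float
    score: float


@dataclass
class RBHSet:
    """Mutual best hits between two proteomes; each locus in <=1 pair."""

    genome_a: str
    genome_b: str
    pairs: list[HitPair]

    def __len__(self) -> int:
        return len(self.pairs)

    def identities(self) -> np.ndarray:
        return np.array([p.identity_pct for p in self.pairs], dtype=float)


@dataclass(frozen=True)
class AAIResult:
    genome_a: str
    genome_b: str
    aai_pct: float
    n_pairs: int
    identity_sd: float


@dataclass(frozen=True)
class MarkerIdentity:
    genome_a: str
    genome_b: str
    marker: str
    identity_pct: float


# ---------------------------------------------------------------------------
# best hits / RBH
# ---------------------------------------------------------------------------


def _candidate_order(query: str, subjects: list[tuple[str, str]]) -> list[int]:
    """Subject indices ranked by normalized edit distance (stable)."""
    dist = np.empty(len(subjects), dtype=float)
    for i, (_, s) in enumerate(subjects):
        d = edlib.align(query, s, task="distance")["editDistance"]
        dist[i] = d / max(len(query), len(s))
    return list(np.argsort(dist, kind="stable"))


def best_hits(
    proteome_a: Proteome,
    proteome_b: Proteome,
    scheme: ScoringScheme | None = None,
    filter: HitFilter | None = None,
    prescreen_k: int | None = 8,
) -> dict[str, HitPair]:
    """Best filtered hit in ``proteome_b`` for each query of ``proteome_a``.

    The best hit maximizes local alignment score; ties are broken by
    higher identity, then lexicographically smallest subject tag.
    Queries with no hit passing the filter are absent from the result.
    """
    if len(proteome_a) == 0 or len(proteome_b) == 0:
        raise AAIError("proteomes must be nonempty")
    scheme = scheme or protein_scheme()
    filter = filter or HitFilter()
    subjects = [(t, s) for t, s in proteome_b.items() if len(s) >= filter.min_length]
    out: dict[str, HitPair] = {}
    for qtag, qseq in proteome_a.items():
        if len(qseq) < filter.min_length or not subjects:
            continue
        if prescreen_k is None or len(subjects) <= prescreen_k:
            order = range(len(subjects))
        else:
            order = _candidate_order(qseq, subjects)[:prescreen_k]
        best: tuple[float, float, str] | None = None  # (score, identity, subject)
        best_hit: HitPair | None = None
        for i in order:
            stag, sseq = subjects[i]
            res = align_local(qseq, sseq, scheme)
            if res.is_empty:
                continue
            if not filter.passes(res.identity_pct, res.coverage_a, res.coverage_b,
                                 len(qseq), len(sseq)):
                continue
            key = (res.score, res.identity_pct, stag)
            if best is None or key[0] > best[0] or (
                key[0] == best[0] and (key[1] > best[1] or
                                       (key[1] == best[1] and stag < best[2]))):
                best = key
                best_hit = HitPair(qtag, stag, res.identity_pct,
                                   res.coverage_a, res.coverage_b, res.score)
        if best_hit is not None:
            out[qtag] = best_hit
    return out


def reciprocal_best_hits(
    proteome_a: Proteome,
    proteome_b: Proteome,
    scheme: ScoringScheme | None = None,
    filter: HitFilter | None = None,
    genome_a: str = "A",
    genome_b: str = "B",
    prescreen_k: int | None = 8,
) -> RBHSet:
    """Pairs (a, b) where each protein is the other's best hit."""
    fwd = best_hits(proteome_a, proteome_b, scheme, filter, prescreen_k)
    rev = best_hits(proteome_b, proteome_a, scheme, filter, prescreen_k)
    pairs = []
    for qtag, hit in fwd.items():
        back = rev.get(hit.subject_tag)
        if back is not None and back.subject_tag == qtag:
            pairs.append(hit)
    pairs.sort(key=lambda p: p.query_tag)
    return RBHSet(genome_a=genome_a, genome_b=genome_b, pairs=pairs)


def compute_aai(rbh: RBHSet) -> AAIResult:
    """Unweighted mean identity over RBH pairs."""
    if len(rbh) == 0:
        raise AAIError(
            f"no orthologs between {rbh.genome_a} and {rbh.genome_b}"
        )
    ids = rbh.identities()
    return AAIResult(
        genome_a=rbh.genome_a,
        genome_b=rbh.genome_b,
        aai_pct=float(ids.mean()),
        n_pairs=len(ids),
        identity_sd=float(ids.std(ddof=1)) if len(ids) > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# genome-set level
# ---------------------------------------------------------------------------


@dataclass
class AAIMatrix:
    labels: list[str]
    values: pd.DataFrame                       # labels x labels, percent
    results: dict[frozenset, AAIResult]        # per unordered pair
    rbh: dict[frozenset, RBHSet] = field(default_factory=dict)

    def get(self, a: str, b: str) -> AAIResult | None:
        if a == b:
            return AAIResult(a, b, 100.0, 0, 0.0)
        return self.results.get(frozenset((a, b)))


def aai_matrix(
    genomes: list[GenomeBundle],
    scheme: ScoringScheme | None = None,
    filter: HitFilter | None = None,
    prescreen_k: int | None = 8,
) -> AAIMatrix:
    """Symmetric AAI matrix over a genome set (diagonal fixed at 100).

    The identity of an RBH pair is direction-independent under the exact
    symmetric kernel, so one reciprocal search per unordered pair
    suffices and the matrix is symmetric by construction.  Pairs with no
    orthologs are left missing (NaN) with a warning.
    """
    if len(genomes) < 2:
        raise AAIError("need at least two genomes")
    labels = [g.label for g in genomes]
    values = pd.DataFrame(np.full((len(labels), len(labels)), np.nan),
                          index=labels, columns=labels)
    np.fill_diagonal(values.values, 100.0)
    results: dict[frozenset, AAIResult] = {}
    rbh_sets: dict[frozenset, RBHSet] = {}
    for ga, gb in itertools.combinations(genomes, 2):
        rbh = reciprocal_best_hits(ga.proteome, gb.proteome, scheme, filter,
                                   ga.label, gb.label, prescreen_k)
        key = frozenset((ga.label, gb.label))
        rbh_sets[key] = rbh
        try:
            res = compute_aai(rbh)
        except AAIError as exc:
            warnings.warn(str(exc))
            continue
        results[key] = res
        values.loc[ga.label, gb.label] = res.aai_pct
        values.loc[gb.label, ga.label] = res.aai_pct
    return AAIMatrix(labels=labels, values=values, results=results, rbh=rbh_sets)


# ---------------------------------------------------------------------------
# 16S / marker identity
# ---------------------------------------------------------------------------

_MARKER_PRODUCT_HINT = "16S"


def extract_marker(bundle: GenomeBundle, marker: str = "16S") -> str | None:
    """Pull a marker gene sequence from the genome's rRNA features.

    Looks for a feature whose product mentions the marker name and cuts
    the (strand-corrected) subsequence out of its contig.
    """
    from Bio.Seq import Seq

    for f in bundle.features:
        if marker in f.product and f.contig_id in bundle.contigs:
            sub = bundle.contigs[f.contig_id][f.start - 1 : f.end]
            return sub if f.strand == "+" else str(Seq(sub).reverse_complement())
    return None


def marker_identity(
    genome_a: GenomeBundle | str,
    genome_b: GenomeBundle | str,
    marker_seqs: dict[str, str] | None = None,
    marker: str = "16S",
) -> MarkerIdentity:
    """Global nucleotide identity of a marker gene (terminal gaps excluded).

    The marker sequence for each genome is taken from ``marker_seqs``
    (label -> sequence) when given, else extracted from rRNA features.
    """
    def resolve(g) -> tuple[str, str]:
        label = g if isinstance(g, str) else g.label
        if marker_seqs and label in marker_seqs:
            return label, marker_seqs[label]
        if not isinstance(g, str):
            seq = extract_marker(g, marker)
            if seq:
                return label, seq
        raise AAIError(f"no {marker} sequence for genome {label}")

    label_a, seq_a = resolve(genome_a)
    label_b, seq_b = resolve(genome_b)
    res = align_global(seq_a, seq_b, nucleotide_scheme())
    return MarkerIdentity(label_a, label_b, marker, res.identity_pct)


def fig1_table(matrix: AAIMatrix,
               marker_identities: list[MarkerIdentity]) -> pd.DataFrame:
    """One row per unordered genome pair: AAI vs marker identity.

    This is the data behind the classic relatedness landscape scatter
    (marker identity on y, AAI on x).
    """
    marker_map = {frozenset((m.genome_a, m.genome_b)): m for m in marker_identities}
    rows = []
    for a, b in itertools.combinations(matrix.labels, 2):
        res = matrix.get(a, b)
        m = marker_map.get(frozenset((a, b)))
        rows.append({
            "genome_a": a,
            "genome_b": b,
            "aai_pct": res.aai_pct if res else np.nan,
            "n_orthologs": res.n_pairs if res else 0,
            "marker_identity_pct": m.identity_pct if m else np.nan,
        })
    return pd.DataFrame(rows)
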