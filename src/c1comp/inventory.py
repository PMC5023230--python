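"""Methylotrophy gene inventory: homolog search, typing, fragment detection.

Builds the genomes x functions inventory matrix: for each genome, every
protein is searched against a reference panel of methylotrophy proteins
(methylamine oxidase Mao, trimethylamine monooxygenase Tmo, the
N-methylglutamate pathway Gma/MgsA-C/MgdA-D, RuMP-cycle and
H4F-pathway enzymes, ...), each hit is assigned to its best-scoring
function, homologs of one function are grouped into "types" by
single-linkage clustering on global identity, and contigs are scanned in
six frames for short truncated-gene remnants that no longer encode a
predicted protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import edlib
import pandas as pd

from .align import ScoringScheme, align_global, align_local, protein_scheme, six_frame_translate
from .seqio import GenomeBundle, PanelEntry, ReferencePanel


class InventoryError(ValueError):
    pass


@dataclass(frozen=True)
class InventoryThresholds:
    """Search and status thresholds for the inventory.

    A protein counts as a homolog of a function when its best local
    alignment to a panel member reaches ``min_identity_pct`` and covers
    ``min_ref_coverage`` of the reference; it is flagged partial when
    reference coverage falls below ``partial_threshold``.  Six-frame
    fragment scanning accepts shorter remnants (>= ``fragment_min_aa``
    aligned residues at >= ``fragment_min_identity_pct``).
    """

    min_identity_pct: float = 30.0
    min_ref_coverage: float = 0.4
    partial_threshold: float = 0.5
    fragment_min_identity_pct: float = 40.0
    fragment_min_aa: int = 25
    type_linkage_pct: float = 50.0
    prescreen_max_norm_dist: float = 0.85


@dataclass(frozen=True)
class InventoryHit:
    genome: str
    function_label: str
    locus_tag: str
    identity_pct: float
    coverage_of_reference: float
    status: str                      # "full" | "partial"
    type_id: int | None = None
    score: float = 0.0
    panel_id: str = ""
    nt_span: tuple[int, int] | None = None   # fragments: 1-based inclusive
    contig_id: str | None = None
    span_bp: int = 0


# ---------------------------------------------------------------------------
# homolog search
# ---------------------------------------------------------------------------


def find_homologs(
    genome: GenomeBundle,
    panel: ReferencePanel,
    thresholds: InventoryThresholds | None = None,
    scheme: ScoringScheme | None = None,
) -> list[InventoryHit]:
    """All panel homologs among a genome's predicted proteins.

    Each protein is reported under at most one function — the one whose
    panel member it hits with the best score; candidate panel members
    are prescreened by normalized edit distance before exact local
    alignment.
    """
    if len(genome.proteome) == 0:
        raise InventoryError(f"genome {genome.label}: empty proteome")
    if len(panel) == 0:
        raise InventoryError("empty reference panel")
    th = thresholds or InventoryThresholds()
    scheme = scheme or protein_scheme()
    hits: list[InventoryHit] = []
    entries = list(panel)
    for tag, seq in genome.proteome.items():
        best: InventoryHit | None = None
        for e in entries:
            nd = edlib.align(seq, e.sequence, task="distance")["editDistance"]
            if nd / max(len(seq), len(e.sequence)) > th.prescreen_max_norm_dist:
                continue
            res = align_local(seq, e.sequence, scheme)
            if res.is_empty:
                continue
            if (res.identity_pct < th.min_identity_pct
                    or res.coverage_b < th.min_ref_coverage):
                continue
            status = "partial" if res.coverage_b < th.partial_threshold else "full"
            cand = InventoryHit(
                genome=genome.label,
                function_label=e.function_label,
                locus_tag=tag,
                identity_pct=res.identity_pct,
                coverage_of_reference=res.coverage_b,
                status=status,
                score=res.score,
                panel_id=e.panel_id,
            )
            if best is None or (cand.score, cand.identity_pct) > (
                    best.score, best.identity_pct):
                best = cand
        if best is not None:
            hits.append(best)
    hits.sort(key=lambda h: h.locus_tag)
    return hits


# ---------------------------------------------------------------------------
# truncated-gene remnants
# ---------------------------------------------------------------------------


def find_fragments(
    genome: GenomeBundle,
    panel_entry: PanelEntry,
    thresholds: InventoryThresholds | None = None,
    scheme: ScoringScheme | None = None,
) -> list[InventoryHit]:
    """Six-frame scan of the contigs for short remnants of one reference.

    Reports local hits of the panel protein against every translation
    frame of every contig that cover < ``partial_threshold`` of the
    reference (full-length genes are the business of
    :func:`find_homologs`) but reach the fragment identity/length
    thresholds.  The reported span is ``3 x aligned residues`` in
    nucleotides, with forward-strand genomic coordinates.
    """
    if not genome.contigs:
        raise InventoryError(f"genome {genome.label}: no contigs to scan")
    th = thresholds or InventoryThresholds()
    scheme = scheme or protein_scheme()
    out: list[InventoryHit] = []
    counter = 0
    for contig_id in sorted(genome.contigs):
        for frame in six_frame_translate(genome.contigs[contig_id]):
            if len(frame.aa_seq) < th.fragment_min_aa:
                continue
            res = align_local(panel_entry.sequence, frame.aa_seq, scheme)
            if res.is_empty:
                continue
            # a remnant is an ORF-like run: the aligned window is split at
            # in-frame stops and only the best stop-free segment counts
            segments: list[list[tuple[int | None, int | None]]] = [[]]
            for col in res.aligned_pairs:
                j = col[1]
                if j is not None and frame.aa_seq[j] == "*":
                    segments.append([])
                else:
                    segments[-1].append(col)
            best_cols = max(
                segments,
                key=lambda seg: sum(1 for i, j in seg
                                    if i is not None and j is not None
                                    and panel_entry.sequence[i] == frame.aa_seq[j]))
            frag_positions = [j for _, j in best_cols if j is not None]
            ref_positions = [i for i, _ in best_cols if i is not None]
            n_res = len(frag_positions)
            if n_res < th.fragment_min_aa or not ref_positions:
                continue
            matches = sum(1 for i, j in best_cols
                          if i is not None and j is not None
                          and panel_entry.sequence[i] == frame.aa_seq[j])
            identity = 100.0 * matches / len(best_cols)
            ref_cov = ((ref_positions[-1] - ref_positions[0] + 1)
                       / len(panel_entry.sequence))
            if (identity < th.fragment_min_identity_pct
                    or ref_cov >= th.partial_threshold):
                continue
            span = frame.nt_span(frag_positions[0], frag_positions[-1] + 1)
            counter += 1
            out.append(InventoryHit(
                genome=genome.label,
                function_label=panel_entry.function_label,
                locus_tag=f"{genome.label}|{panel_entry.function_label}"
                          f"|frag{counter}",
                identity_pct=identity,
                coverage_of_reference=ref_cov,
                status="partial",
                score=res.score,
                panel_id=panel_entry.panel_id,
                nt_span=span,
                contig_id=contig_id,
                span_bp=3 * n_res,
            ))
    out.sort(key=lambda h: (h.contig_id, h.nt_span))
    return out


# ---------------------------------------------------------------------------
# typing
# ---------------------------------------------------------------------------


def assign_types(
    hits: list[InventoryHit],
    sequences: dict[str, str],
    scheme: ScoringScheme | None = None,
    linkage_pct: float = 50.0,
) -> list[InventoryHit]:
    """Cluster one function's homologs into types.

    Single-linkage clustering on pairwise global identity at the given
    threshold; clusters are numbered 1.. by decreasing size, ties broken
    by smallest member locus tag, so the labeling is invariant to input
    order.  Partial hits (fragments) carry no type.
    """
    if not hits:
        raise InventoryError("no hits to type")
    scheme = scheme or protein_scheme()
    full = sorted((h for h in hits if h.status == "full"),
                  key=lambda h: (h.genome, h.locus_tag))
    parent = list(range(len(full)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(full)):
        for j in range(i + 1, len(full)):
            a = sequences[full[i].locus_tag]
            b = sequences[full[j].locus_tag]
            if align_global(a, b, scheme).identity_pct >= linkage_pct:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[int]] = {}
    for i in range(len(full)):
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(
        clusters.values(),
        key=lambda idx: (-len(idx), min(full[i].locus_tag for i in idx)),
    )
    type_of: dict[int, int] = {}
    for type_id, members in enumerate(ordered, start=1):
        for i in members:
            type_of[i] = type_id
    out = []
    for h in hits:
        if h.status == "full":
            i = next(k for k, fh in enumerate(full) if fh is h)
            out.append(replace(h, type_id=type_of[i]))
        else:
            out.append(h)
    return out


# ---------------------------------------------------------------------------
# inventory matrix
# ---------------------------------------------------------------------------


@dataclass
class InventoryMatrix:
    """Functions x genomes matrix; each cell a list of hits."""

    functions: list[str]
    genomes: list[str]
    cells: dict[tuple[str, str], list[InventoryHit]]
    hits: list[InventoryHit]

    def cell(self, function_label: str, genome: str) -> list[InventoryHit]:
        return self.cells.get((function_label, genome), [])

    def to_frame(self) -> pd.DataFrame:
        """Render with comma-joined locus tags, '(partial)' suffix and '-'
        for absent functions, mirroring a printed inventory table."""
        data = {}
        for g in self.genomes:
            col = []
            for fn in self.functions:
                hits = sorted(self.cell(fn, g), key=lambda h: h.locus_tag)
                if not hits:
                    col.append("-")
                else:
                    col.append(", ".join(
                        h.locus_tag + (" (partial)" if h.status == "partial" else "")
                        for h in hits))
            data[g] = col
        return pd.DataFrame(data, index=pd.Index(self.functions, name="function"))


def build_inventory(
    genomes: list[GenomeBundle],
    panel: ReferencePanel,
    thresholds: InventoryThresholds | None = None,
    scheme: ScoringScheme | None = None,
    fragment_functions: list[str] | None = None,
) -> InventoryMatrix:
    """Homolog search + typing + optional fragment scan over a genome set.

    ``fragment_functions`` selects the panel functions whose references
    are additionally searched in six frames against the contigs (the
    scan is proportional to contig length, so it is opt-in).
    """
    if not genomes:
        raise InventoryError("no genomes")
    if len(panel) == 0:
        raise InventoryError("empty reference panel")
    th = thresholds or InventoryThresholds()
    all_hits: list[InventoryHit] = []
    seqs: dict[str, str] = {}
    for g in genomes:
        hits = find_homologs(g, panel, th, scheme)
        for h in hits:
            seqs[h.locus_tag] = g.proteome[h.locus_tag]
        all_hits.extend(hits)
        for fn in fragment_functions or []:
            for e in panel.by_function(fn):
                if g.contigs:
                    all_hits.extend(find_fragments(g, e, th, scheme))

    # warn if a locus would plausibly fit several functions (overlap check)
    by_tag: dict[str, set[str]] = {}
    for h in all_hits:
        by_tag.setdefault(h.locus_tag, set()).add(h.function_label)
    for tag, fns in by_tag.items():
        if len(fns) > 1:
            warnings.warn(f"locus {tag} matches multiple functions: {sorted(fns)}")

    typed: list[InventoryHit] = []
    functions = panel.functions()
    for fn in functions:
        fn_hits = [h for h in all_hits if h.function_label == fn]
        if fn_hits:
            typed.extend(assign_types(fn_hits, seqs, scheme, th.type_linkage_pct))
    cells: dict[tuple[str, str], list[InventoryHit]] = {}
    for h in typed:
        cells.setdefault((h.function_label, h.genome), []).append(h)
    for key in cells:
        cells[key].sort(key=lambda h: h.locus_tag)
    return InventoryMatrix(
        functions=functions,
        genomes=[g.label for g in genomes],
        cells=cells,
        hits=typed,
    )
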