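"""Pairwise alignment with identity and coverage statistics.

This is the computational kernel under reciprocal-best-hit / AAI
computation, the gene-inventory search and 16S identity.  Alignment
itself is delegated to :class:`Bio.Align.PairwiseAligner` (exact affine
Needleman-Wunsch / Smith-Waterman); this module owns the scoring
conventions and the identity / coverage definitions, which the
downstream statistics depend on:

* a gap of length ``k`` costs ``gap_open + k * gap_extend``;
* percent identity is ``100 * matches / aligned_columns``, where gap
  columns count for global alignments (terminal gap columns excluded)
  and only the local window counts for local alignments;
* coverage of a sequence is the fraction of its length inside the
  aligned span.

Defaults follow BLAST conventions: BLOSUM62 with gap open 11 / extend 1
for proteins, +2/-3 with gap 5/2 for nucleotides.  'X' residues score 0
against everything (draft genomes contain ambiguous translations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq


class AlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scoring schemes
# ---------------------------------------------------------------------------


def _protein_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.load("BLOSUM62").copy()
    for a in m.alphabet:
        m["X", a] = 0.0
        m[a, "X"] = 0.0
    return m


def _nucleotide_matrix(match: float, mismatch: float) -> substitution_matrices.Array:
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == "N" or b == "N":
                m[a, b] = 0.0
            else:
                m[a, b] = match if a == b else mismatch
    return m


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both positive)."""

    name: str
    gap_open: float
    gap_extend: float
    matrix: substitution_matrices.Array = field(repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise AlignmentError("gap penalties must be positive")

    @property
    def alphabet(self) -> str:
        return str(self.matrix.alphabet)

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.substitution_matrix = self.matrix
        # Biopython charges open_gap_score on the first gap position, so a
        # k-gap costs open + k*extend under this parameterization.
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        al.mode = mode
        return al


@lru_cache(maxsize=None)
def protein_scheme(gap_open: float = 11.0, gap_extend: float = 1.0) -> ScoringScheme:
    """BLAST-protein defaults: BLOSUM62, gap open 11, extend 1."""
    return ScoringScheme("BLOSUM62", gap_open, gap_extend, _protein_matrix())


@lru_cache(maxsize=None)
def nucleotide_scheme(
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
) -> ScoringScheme:
    """BLASTN-like defaults: +2/-3, gap open 5, extend 2."""
    return ScoringScheme("NUC.2.-3", gap_open, gap_extend,
                         _nucleotide_matrix(match, mismatch))


# ---------------------------------------------------------------------------
# alignment results
# ---------------------------------------------------------------------------


@dataclass
class AlignmentResult:
    """One pairwise alignment with its summary statistics.

    ``aligned_pairs`` lists per-column 0-based positions, with ``None``
    as the gap marker; terminal gap columns are not included.
    """

    score: float
    aligned_pairs: list[tuple[int | None, int | None]]
    identity_pct: float
    coverage_a: float
    coverage_b: float
    mode: str
    n_matches: int = 0
    n_columns: int = 0

    @property
    def is_empty(self) -> bool:
        return not self.aligned_pairs


_EMPTY = dict(score=0.0, aligned_pairs=[], identity_pct=0.0,
              coverage_a=0.0, coverage_b=0.0)


def _validate(seq_a: str, seq_b: str, scheme: ScoringScheme) -> None:
    if not seq_a or not seq_b:
        raise AlignmentError("sequences must be nonempty")
    allowed = set(scheme.alphabet)
    for label, seq in (("a", seq_a), ("b", seq_b)):
        bad = set(seq) - allowed
        if bad:
            raise AlignmentError(
                f"sequence {label} has characters {sorted(bad)} outside the "
                f"{scheme.name} alphabet"
            )


def _summarize(alignment, seq_a: str, seq_b: str, mode: str) -> AlignmentResult:
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        return AlignmentResult(mode=mode, **_EMPTY)
    pairs: list[tuple[int | None, int | None]] = []
    matches = 0
    prev_a = prev_b = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            # internal gap columns between aligned blocks
            for i in range(prev_a, a0):
                pairs.append((i, None))
            for j in range(prev_b, b0):
                pairs.append((None, j))
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
            if seq_a[i] == seq_b[j]:
                matches += 1
        prev_a, prev_b = a1, b1
    n_columns = len(pairs)
    identity = 100.0 * matches / n_columns
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    return AlignmentResult(
        score=float(alignment.score),
        aligned_pairs=pairs,
        identity_pct=identity,
        coverage_a=span_a / len(seq_a),
        coverage_b=span_b / len(seq_b),
        mode=mode,
        n_matches=matches,
        n_columns=n_columns,
    )


def align_global(seq_a: str, seq_b: str, scheme: ScoringScheme) -> AlignmentResult:
    """Optimal affine-gap global alignment.

    The first optimal traceback reported by the kernel is used, which is
    deterministic for fixed inputs.  Terminal gap columns are excluded
    from the identity denominator but are penalized in the score.
    """
    _validate(seq_a, seq_b, scheme)
    alignment = scheme.aligner("global").align(seq_a, seq_b)[0]
    return _summarize(alignment, seq_a, seq_b, "global")


def align_local(seq_a: str, seq_b: str, scheme: ScoringScheme) -> AlignmentResult:
    """Optimal Smith-Waterman affine-gap local alignment.

    If no positive-scoring alignment exists the empty alignment (score
    0, coverage 0) is returned.
    """
    _validate(seq_a, seq_b, scheme)
    aligner = scheme.aligner("local")
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return AlignmentResult(mode="local", **_EMPTY)
    alignment = aligner.align(seq_a, seq_b)[0]
    return _summarize(alignment, seq_a, seq_b, "local")


# ---------------------------------------------------------------------------
# six-frame translation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameTranslation:
    """Translation of one reading frame of a nucleotide sequence.

    ``frame`` is +1/+2/+3 (forward, codons starting at offset frame-1)
    or -1/-2/-3 (reverse complement, codons starting at offset
    ``|frame|-1`` of the reverse-complemented sequence).  Stop codons
    are rendered '*'; codons containing N translate to 'X'.
    """

    frame: int
    aa_seq: str
    nt_length: int  # length of the source nucleotide sequence

    def nt_span(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Forward-strand nucleotide span (1-based inclusive) of residues
        ``aa_start..aa_end`` (0-based, end exclusive)."""
        off = abs(self.frame) - 1
        first = off + 3 * aa_start          # 0-based first nt in frame coords
        last = off + 3 * aa_end - 1         # 0-based last nt in frame coords
        if self.frame > 0:
            return first + 1, last + 1
        # reverse frames: frame coords run along the reverse complement
        return self.nt_length - last, self.nt_length - first


def six_frame_translate(nucleotide_seq: str) -> list[FrameTranslation]:
    """Translate all six reading frames with the standard genetic code."""
    seq = nucleotide_seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise AlignmentError(f"nucleotide sequence has invalid characters {sorted(bad)}")
    n = len(seq)
    rc = str(Seq(seq).reverse_complement())
    frames: list[FrameTranslation] = []
    for strand_seq, sign in ((seq, 1), (rc, -1)):
        for off in (0, 1, 2):
            sub = strand_seq[off : off + 3 * ((n - off) // 3)]
            aa = str(Seq(sub).translate()) if sub else ""
            frames.append(FrameTranslation(frame=sign * (off + 1), aa_seq=aa,
                                           nt_length=n))
    return frames
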