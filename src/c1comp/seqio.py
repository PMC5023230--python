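"""Sequence, feature and report I/O.

All genomic coordinates in this package are 1-based inclusive (GFF3
convention), on the forward strand of the containing contig.  Locus tags
are opaque strings.

The on-disk formats are deliberately plain: FASTA (wrapped at 60 columns
on write), GFF3 or 6-column TSV feature tables, and TSV/JSON reports, so
that every pipeline stage can be rerun from its predecessor's output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")

# feature-table TSV columns, in order
FEATURE_COLUMNS = ["locus_tag", "contig_id", "start", "end", "strand", "product"]


class SeqIOError(ValueError):
    """Malformed input data (duplicate ids, bad coordinates, bad alphabet)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Feature:
    """One gene row: coordinates are 1-based inclusive, strand '+' or '-'."""

    locus_tag: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise SeqIOError(
                f"feature {self.locus_tag}: invalid coordinates "
                f"{self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise SeqIOError(f"feature {self.locus_tag}: strand must be + or -")


class FeatureTable:
    """Gene features sorted by (contig_id, start).

    The gene index of a locus within its contig is its rank after this
    sort; adjacency reasoning for cluster detection is defined on that
    index.  Sorting is idempotent: the constructor always re-sorts.
    """

    def __init__(self, rows: Iterable[Feature]):
        self.rows: list[Feature] = sorted(rows, key=lambda f: (f.contig_id, f.start))
        seen: set[str] = set()
        for f in self.rows:
            if f.locus_tag in seen:
                raise SeqIOError(f"duplicate locus tag {f.locus_tag}")
            seen.add(f.locus_tag)
        self._by_tag = {f.locus_tag: f for f in self.rows}
        # index of each gene within its contig after sorting
        self._index: dict[str, int] = {}
        counts: dict[str, int] = {}
        for f in self.rows:
            i = counts.get(f.contig_id, 0)
            self._index[f.locus_tag] = i
            counts[f.contig_id] = i + 1

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag in self._by_tag

    def get(self, locus_tag: str) -> Feature:
        return self._by_tag[locus_tag]

    def gene_index(self, locus_tag: str) -> int:
        """Rank of the gene within its contig (0-based, by start)."""
        return self._index[locus_tag]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (f.locus_tag, f.contig_id, f.start, f.end, f.strand, f.product)
                for f in self.rows
            ],
            columns=FEATURE_COLUMNS,
        )


class Proteome:
    """Ordered map locus_tag -> amino-acid sequence for one genome.

    Sequences are uppercase over ACDEFGHIKLMNPQRSTVWY plus X; empty
    sequences and duplicate tags are rejected.
    """

    def __init__(self, entries: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = entries.items() if isinstance(entries, Mapping) else entries
        self.entries: dict[str, str] = {}
        for tag, seq in items:
            if tag in self.entries:
                raise SeqIOError(f"duplicate locus tag {tag}")
            if not seq:
                raise SeqIOError(f"empty sequence for {tag}")
            bad = set(seq) - PROTEIN_ALPHABET
            if bad:
                raise SeqIOError(
                    f"protein {tag}: invalid residues {sorted(bad)}"
                )
            self.entries[tag] = seq

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, tag: str) -> bool:
        return tag in self.entries

    def __getitem__(self, tag: str) -> str:
        return self.entries[tag]

    def items(self):
        return self.entries.items()

    def subset(self, tags: Iterable[str]) -> "Proteome":
        keep = set(tags)
        return Proteome({t: s for t, s in self.entries.items() if t in keep})


@dataclass
class GenomeBundle:
    """Everything known about one genome: contigs, proteins, features."""

    label: str
    proteome: Proteome
    features: FeatureTable
    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tag in self.proteome:
            if tag not in self.features:
                raise SeqIOError(
                    f"genome {self.label}: protein {tag} missing from feature table"
                )
        if self.contigs:
            for f in self.features:
                if f.contig_id not in self.contigs:
                    raise SeqIOError(
                        f"genome {self.label}: feature {f.locus_tag} references "
                        f"unknown contig {f.contig_id}"
                    )
                if f.end > len(self.contigs[f.contig_id]):
                    raise SeqIOError(
                        f"genome {self.label}: feature {f.locus_tag} extends past "
                        f"end of contig {f.contig_id}"
                    )


@dataclass(frozen=True)
class PanelEntry:
    panel_id: str
    function_label: str
    sequence: str
    source: str = ""
    notes: str = ""


class ReferencePanel:
    """Reference proteins for the methylotrophy functions under study.

    ``function_label`` uses the field vocabulary (Mao, Tmo, Tmd, EutQ,
    Gma, MgsA-C, MgdA-D, FolD, Mch, PurU, Fhs, FaDH, Fdh*, Pgi, Zwf,
    OpcA, Pgl, Gnd, Hps, Hpi, Pfk, Fba, Tkt, Tal, GlpX, Rpe, Rpi, Tpi,
    Gap, Pgk, Eda, plus Mdh and Tmd-candidate).  A function may have
    several entries (e.g. divergent reference types).
    """

    def __init__(self, entries: Iterable[PanelEntry]):
        self.entries: list[PanelEntry] = list(entries)
        seen: set[str] = set()
        for e in self.entries:
            if not e.function_label:
                raise SeqIOError(f"panel entry {e.panel_id}: empty function label")
            if e.panel_id in seen:
                raise SeqIOError(f"duplicate panel id {e.panel_id}")
            seen.add(e.panel_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def functions(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.function_label not in out:
                out.append(e.function_label)
        return out

    def by_function(self, label: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.function_label == label]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, alphabet: str = "protein") -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence map.

    Sequences are uppercased; a single terminal '*' (stop) is stripped
    from protein records.  Duplicate ids and, for proteins, residues
    outside ACDEFGHIKLMNPQRSTVWYX raise :class:`SeqIOError`.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise SeqIOError(f"duplicate id {rec.id}")
        seq = str(rec.seq).upper()
        if alphabet == "protein" and seq.endswith("*"):
            seq = seq[:-1]
        allowed = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
        bad = set(seq) - allowed
        if bad:
            raise SeqIOError(
                f"record {rec.id}: characters {sorted(bad)} outside "
                f"{alphabet} alphabet"
            )
        if not seq:
            raise SeqIOError(f"record {rec.id}: empty sequence")
        out[rec.id] = seq
    if not out:
        raise SeqIOError(f"no FASTA records in {path}")
    return out


def write_fasta(entries: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_features(path: str | Path, dialect: str = "tsv") -> FeatureTable:
    """Read a gene feature table from TSV or GFF3.

    TSV dialect: 6 tab-separated columns (locus_tag, contig_id, start,
    end, strand, product), optional header.  GFF3 dialect: only CDS and
    rRNA rows are consumed; the locus tag comes from the ``locus_tag``
    or ``ID`` attribute.  Coordinates stay 1-based inclusive.
    """
    path = Path(path)
    rows: list[Feature] = []
    if dialect == "tsv":
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "locus_tag":  # header row
                    continue
                if len(parts) < 5:
                    raise SeqIOError(f"feature row with <5 columns: {line!r}")
                tag, contig, start, end, strand = parts[:5]
                product = parts[5] if len(parts) > 5 else ""
                if not tag:
                    raise SeqIOError(f"missing locus tag in row {line!r}")
                rows.append(
                    Feature(tag, contig, int(start), int(end), strand, product)
                )
    elif dialect == "gff3":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    continue
                contig, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
                if ftype not in ("CDS", "rRNA"):
                    continue
                a = _parse_gff3_attributes(attrs)
                tag = a.get("locus_tag") or a.get("ID")
                if not tag:
                    raise SeqIOError(f"GFF3 {ftype} row without locus_tag/ID: {line!r}")
                rows.append(
                    Feature(tag, contig, int(start), int(end), strand,
                            a.get("product", ""))
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return FeatureTable(rows)


def write_features(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_panel(fasta_path: str | Path, meta_path: str | Path) -> ReferencePanel:
    """Load a reference panel from FASTA plus a metadata TSV.

    The TSV needs columns panel_id, function_label and optionally
    source, notes; every panel_id must have a FASTA record.
    """
    seqs = read_fasta(fasta_path, "protein")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    entries = []
    for _, row in meta.iterrows():
        pid = row["panel_id"]
        if pid not in seqs:
            raise SeqIOError(f"panel id {pid} has no FASTA record")
        entries.append(
            PanelEntry(
                panel_id=pid,
                function_label=row["function_label"],
                sequence=seqs[pid],
                source=row.get("source", ""),
                notes=row.get("notes", ""),
            )
        )
    return ReferencePanel(entries)


def load_genome_dir(path: str | Path, label: str | None = None) -> GenomeBundle:
    """Load one genome from a directory holding proteins.faa, contigs.fna
    (optional) and features.tsv / features.gff3."""
    path = Path(path)
    label = label or path.name
    proteome = Proteome(read_fasta(path / "proteins.faa", "protein"))
    if (path / "features.tsv").exists():
        features = read_features(path / "features.tsv", "tsv")
    elif (path / "features.gff3").exists():
        features = read_features(path / "features.gff3", "gff3")
    else:
        raise SeqIOError(f"no feature table in {path}")
    contigs: dict[str, str] = {}
    if (path / "contigs.fna").exists():
        contigs = read_fasta(path / "contigs.fna", "nucleotide")
    return GenomeBundle(label=label, proteome=proteome, features=features,
                        contigs=contigs)


def write_genome_dir(bundle: GenomeBundle, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.proteome.entries, path / "proteins.faa")
    write_features(bundle.features, path / "features.tsv")
    if bundle.contigs:
        write_fasta(bundle.contigs, path / "contigs.fna")


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------


def _format_value(v) -> str:
    if isinstance(v, float):
        return f"{v:.1f}"
    return str(v)


def write_report(table: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a result table deterministically.

    Column order is preserved; rows are sorted by all columns in order
    (genome label first by pipeline convention); identity-like floats
    are rendered with one decimal.  Writing the same table twice yields
    byte-identical files.
    """
    path = Path(path)
    df = table.copy()
    if len(df) and len(df.columns):
        df = df.sort_values(by=list(df.columns[: min(2, len(df.columns))]),
                            kind="mergesort")
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(map(str, df.columns)) + "\n")
            for _, row in df.iterrows():
                fh.write("\t".join(_format_value(v) for v in row) + "\n")
    elif format == "json":
        records = [
            {col: (round(v, 1) if isinstance(v, float) else v)
             for col, v in zip(df.columns, row)}
            for row in df.itertuples(index=False)
        ]
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
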