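"""Synthetic proteome evolution with known ground truth.

Generates genome bundles that emulate the observations the pipeline is
built to recover: proteomes diverged vertically to target pairwise
identity levels, near-identical duplicated key genes, shared HGT islands
at identity far above the genome background, truncated gene remnants
embedded in contigs, and 16S sequences diverged in parallel.

Substitution model
------------------
Site-uniform replacement over a uniform alphabet: each substitution
event hits a uniformly chosen site and replaces its residue with a
uniformly chosen *different* residue.  For this chain the expected
identity between two sequences separated by ``lam`` substitutions per
site is

    E[identity] = 1/k + (1 - 1/k) * exp(-(k/(k-1)) * lam)

with alphabet size ``k`` (20 for proteins, 4 for nucleotides); the
``1/k`` floor is back-coincidence.  :func:`substitutions_for_identity`
inverts this curve.  Pairwise targets are realized by assigning each
genome a branch load ``d_i`` (substitutions per site from the common
ancestor) with ``d_i + d_j = lam(target_ij)``; a target matrix that
admits no non-negative, consistent branch decomposition is rejected.
Realized mean identities are checked against the targets and the
divergence is re-tuned (deterministically) until they agree within one
point.

No indels are simulated by default and back-translation uses uniform
synonymous codons; gene order is a random permutation except for
configured islands, which stay contiguous.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .seqio import (
    Feature,
    FeatureTable,
    GenomeBundle,
    PanelEntry,
    Proteome,
    ReferencePanel,
    write_genome_dir,
    write_fasta,
)

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
NT_LETTERS = "ACGT"

_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
        for aa in _CODONS:
            _CODONS[aa].sort()
        _CODONS["*"] = sorted(standard_dna_table.stop_codons)
    return _CODONS


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IslandSpec:
    """A contiguous run of methylotrophy genes carried by some genomes."""

    name: str
    functions: tuple[str, ...]
    genomes: tuple[str, ...]


@dataclass(frozen=True)
class SingletonSpec:
    """A scattered (non-island) methylotrophy gene."""

    function: str
    genomes: tuple[str, ...]


@dataclass(frozen=True)
class DuplicationEvent:
    function_label: str
    copies: int
    within_identity_pct: float
    genomes: tuple[str, ...] | None = None  # default: every carrier


@dataclass(frozen=True)
class HgtEvent:
    donor: str
    recipient: str
    functions: tuple[str, ...]
    island_identity_pct: float


@dataclass(frozen=True)
class TruncationEvent:
    function_label: str
    genome: str
    fragment_length_nt: int


@dataclass
class SimConfig:
    """Study conditions for one simulated genome set.

    ``genes_per_genome`` counts the shared vertical core; methylotrophy
    genes declared through islands/singletons are added on top of it.
    ``target_identity_pct`` is a single value applied to all pairs or a
    ``{(a, b): pct}`` map; ``marker_divergence_pct`` likewise (percent
    divergence, i.e. identity = 100 - divergence).
    """

    seed: int
    labels: tuple[str, ...] = ("G1", "G2")
    genes_per_genome: int = 500
    gene_length_mean: float = 300.0
    gene_length_sd: float = 75.0
    gene_length_min: int = 50
    target_identity_pct: float | dict = 70.0
    marker_divergence_pct: float | dict = 3.0
    marker_length: int = 1500
    islands: tuple[IslandSpec, ...] = ()
    singletons: tuple[SingletonSpec, ...] = ()
    duplications: tuple[DuplicationEvent, ...] = ()
    hgt: tuple[HgtEvent, ...] = ()
    truncations: tuple[TruncationEvent, ...] = ()
    panel_lengths: dict = field(default_factory=lambda: {"Mao": 700})
    panel_default_length: int = 300
    spacer_len: int = 200

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if len(set(self.labels)) != len(self.labels):
            raise SimulationError("duplicate genome labels")
        for t in self._pair_values(self.target_identity_pct):
            if not (30.0 <= t <= 100.0):
                raise SimulationError(f"target identity {t} outside [30, 100]")
        for ev in self.truncations:
            if ev.fragment_length_nt <= 0 or ev.fragment_length_nt % 3:
                raise SimulationError(
                    "fragment length must be a positive multiple of 3")
        for ev in self.hgt:
            if ev.donor not in self.labels or ev.recipient not in self.labels:
                raise SimulationError(f"HGT event references unknown genome: {ev}")

    def _pair_values(self, spec) -> list[float]:
        if isinstance(spec, dict):
            return [float(v) for v in spec.values()]
        return [float(spec)]

    def pair_target(self, a: str, b: str) -> float:
        return _pair_lookup(self.target_identity_pct, a, b)

    def pair_marker_identity(self, a: str, b: str) -> float:
        return 100.0 - _pair_lookup(self.marker_divergence_pct, a, b)


def _pair_lookup(spec, a: str, b: str) -> float:
    if isinstance(spec, dict):
        for key in ((a, b), (b, a), frozenset((a, b))):
            if key in spec:
                return float(spec[key])
        raise SimulationError(f"no value configured for pair ({a}, {b})")
    return float(spec)


# ---------------------------------------------------------------------------
# substitution model
# ---------------------------------------------------------------------------


def expected_identity_pct(lam: float, alphabet_size: int = 20) -> float:
    """Expected percent identity after ``lam`` substitutions per site."""
    k = alphabet_size
    return 100.0 * (1.0 / k + (1.0 - 1.0 / k) * math.exp(-(k / (k - 1.0)) * lam))


def substitutions_for_identity(
    target_identity_pct: float, length: int, alphabet_size: int = 20
) -> float:
    """Expected substitution count that decays identity to the target.

    Inverts the expected-identity curve of the site-uniform replacement
    model (back-coincidence accounted); monotone decreasing in the
    target.  Targets at or below the ``100/k`` saturation floor are
    unreachable and raise.
    """
    if target_identity_pct <= 0:
        raise SimulationError("target identity must be positive")
    if target_identity_pct > 100:
        raise SimulationError("target identity cannot exceed 100")
    k = alphabet_size
    t = target_identity_pct / 100.0
    floor = 1.0 / k
    if t <= floor:
        raise SimulationError(
            f"target identity {target_identity_pct}% is at or below the "
            f"{100.0 / k:.1f}% saturation floor of a {k}-letter alphabet")
    lam = -((k - 1.0) / k) * math.log((t - floor) / (1.0 - floor))
    return lam * length


def _lam_for(target_pct: float, alphabet_size: int = 20) -> float:
    """Per-site substitution load for a pairwise identity target."""
    return substitutions_for_identity(target_pct, 1, alphabet_size)


def _apply_hits(arr: np.ndarray, n_hits: int, rng: np.random.Generator,
                k: int) -> None:
    """Apply ``n_hits`` substitution events in place (sequential, so
    repeated hits on one site can back-mutate)."""
    if n_hits <= 0:
        return
    pos = rng.integers(0, arr.size, n_hits)
    off = rng.integers(1, k, n_hits)
    for p, o in zip(pos, off):
        arr[p] = (arr[p] + o) % k


def _solve_branch_loads(labels: list[str], lam: dict[frozenset, float]) -> np.ndarray:
    """Non-negative per-genome branch loads with d_i + d_j = lam_ij.

    Solved by least squares; an inconsistent (non-star-decomposable) or
    negative solution raises with the worst-fitting pair.
    """
    n = len(labels)
    if n == 1:
        return np.zeros(1)
    pairs = list(itertools.combinations(range(n), 2))
    if n == 2:
        d = lam[frozenset(labels)] / 2.0
        return np.array([d, d])
    A = np.zeros((len(pairs), n))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        A[row, i] = A[row, j] = 1.0
        y[row] = lam[frozenset((labels[i], labels[j]))]
    d, *_ = np.linalg.lstsq(A, y, rcond=None)
    worst = None
    for (i, j), target in zip(pairs, y):
        got = expected_identity_pct(d[i] + d[j])
        want = expected_identity_pct(target)
        err = abs(got - want)
        if worst is None or err > worst[0]:
            worst = (err, labels[i], labels[j])
    if worst[0] > 1.0:
        raise SimulationError(
            f"pairwise identity matrix is not consistent with a shared "
            f"ancestry decomposition; worst pair ({worst[1]}, {worst[2]}) "
            f"off by {worst[0]:.2f} points")
    if d.min() < -1e-9:
        i = int(np.argmin(d))
        raise SimulationError(
            f"pairwise identity matrix requires negative divergence for "
            f"{labels[i]}")
    return np.clip(d, 0.0, None)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """What the simulator actually emitted, keyed for verification."""

    orthologs: dict[str, dict[str, str]]            # ancestral id -> genome -> tag
    origins: dict[str, dict[str, str]]              # genome -> tag -> origin
    functions: dict[str, dict[str, str]]            # genome -> tag -> function
    islands: dict[str, dict[str, list[str]]]        # island -> genome -> tags
    realized_identity_pct: dict[str, float]         # "a|b" -> mean core identity
    realized_marker_identity_pct: dict[str, float]  # "a|b" -> 16S identity
    truncations: list[dict]                         # genome/function/span records

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------


@dataclass
class _Gene:
    anc_id: str
    function: str | None            # None for core genes
    island: str | None
    carriers: tuple[str, ...]
    seq: np.ndarray                 # ancestral residues as ints


def _decode(arr: np.ndarray, letters: str = AA_LETTERS) -> str:
    return "".join(letters[i] for i in arr)


def _back_translate(aa: str, rng: np.random.Generator) -> str:
    table = _codon_table()
    out = []
    for ch in aa:
        codons = table[ch]
        out.append(codons[rng.integers(0, len(codons))])
    return "".join(out)


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return _decode(rng.integers(0, 4, n), NT_LETTERS)


def simulate(config: SimConfig) -> tuple[list[GenomeBundle], ReferencePanel, GroundTruth]:
    """Run the generator; fully reproducible from ``config.seed``."""
    labels = list(config.labels)
    master = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["ancestor", "panel", "diverge", "events", "layout", "marker"],
            master.spawn(6),
        )
    }

    # --- reference panel and ancestral methylotrophy genes ----------------
    functions_needed: list[str] = []
    for isl in config.islands:
        functions_needed.extend(isl.functions)
    for s in config.singletons:
        functions_needed.append(s.function)
    seen: set[str] = set()
    functions_needed = [f for f in functions_needed
                        if not (f in seen or seen.add(f))]
    panel_rng = streams["panel"]
    panel_entries = []
    panel_seq: dict[str, np.ndarray] = {}
    for fn in functions_needed:
        length = int(config.panel_lengths.get(fn, config.panel_default_length))
        arr = panel_rng.integers(0, 20, length)
        panel_seq[fn] = arr
        panel_entries.append(PanelEntry(
            panel_id=f"REF_{fn}", function_label=fn, sequence=_decode(arr),
            source="synthetic", notes="simulator reference"))
    panel = ReferencePanel(panel_entries)

    # --- ancestral gene roster --------------------------------------------
    anc_rng = streams["ancestor"]
    genes: list[_Gene] = []
    lengths = np.maximum(
        config.gene_length_min,
        np.rint(anc_rng.normal(config.gene_length_mean, config.gene_length_sd,
                               config.genes_per_genome)).astype(int))
    for i in range(config.genes_per_genome):
        genes.append(_Gene(
            anc_id=f"anc{i + 1:04d}", function=None, island=None,
            carriers=tuple(labels),
            seq=anc_rng.integers(0, 20, lengths[i])))
    for isl in config.islands:
        for j, fn in enumerate(isl.functions):
            genes.append(_Gene(
                anc_id=f"anc_{isl.name}_{fn}", function=fn, island=isl.name,
                carriers=tuple(isl.genomes), seq=panel_seq[fn].copy()))
    for s in config.singletons:
        genes.append(_Gene(
            anc_id=f"anc_single_{s.function}", function=s.function, island=None,
            carriers=tuple(s.genomes), seq=panel_seq[s.function].copy()))

    # --- vertical divergence with re-tuning -------------------------------
    lam = {
        frozenset((a, b)): _lam_for(config.pair_target(a, b))
        for a, b in itertools.combinations(labels, 2)
    }
    lam_adjusted = dict(lam)
    core = [g for g in genes if g.function is None]
    diverge_seed = master.spawn(1)[0]

    def run_divergence(loads: np.ndarray, attempt: int):
        rng = np.random.default_rng(diverge_seed)  # same stream every attempt
        per_genome: dict[str, dict[str, np.ndarray]] = {lb: {} for lb in labels}
        for gi, lb in enumerate(labels):
            d = loads[gi]
            for g in genes:
                if lb not in g.carriers:
                    continue
                arr = g.seq.copy()
                _apply_hits(arr, int(round(d * arr.size)), rng, 20)
                per_genome[lb][g.anc_id] = arr
        return per_genome

    def realized(per_genome) -> dict[frozenset, float]:
        out = {}
        for a, b in itertools.combinations(labels, 2):
            num = den = 0
            for g in core:
                sa, sb = per_genome[a][g.anc_id], per_genome[b][g.anc_id]
                num += int((sa == sb).sum())
                den += sa.size
            out[frozenset((a, b))] = 100.0 * num / den if den else 100.0
        return out

    loads = _solve_branch_loads(labels, lam_adjusted)
    per_genome = run_divergence(loads, 0)
    if len(labels) > 1:
        for attempt in range(1, 5):
            real = realized(per_genome)
            targets_err = max(
                abs(real[frozenset((a, b))] - config.pair_target(a, b))
                for a, b in itertools.combinations(labels, 2))
            if targets_err <= 1.0:
                break
            for key in lam_adjusted:
                lam_real = _lam_for(max(real[key], 5.5))
                lam_adjusted[key] = max(0.0, lam_adjusted[key] + (lam[key] - lam_real))
            loads = _solve_branch_loads(labels, lam_adjusted)
            per_genome = run_divergence(loads, attempt)
        real = realized(per_genome)
    else:
        real = {}

    # --- per-genome gene instances ----------------------------------------
    ev_rng = streams["events"]

    @dataclass
    class _Instance:
        anc_id: str
        genome: str
        aa: np.ndarray
        origin: str                 # vertical | hgt | duplicate
        function: str | None
        island: str | None
        block: str | None           # layout block key for contiguity

    instances: dict[str, list[_Instance]] = {lb: [] for lb in labels}
    for lb in labels:
        for g in genes:
            if lb not in g.carriers:
                continue
            instances[lb].append(_Instance(
                anc_id=g.anc_id, genome=lb, aa=per_genome[lb][g.anc_id],
                origin="vertical", function=g.function, island=g.island,
                block=g.island))

    # duplications: copies diverge from the genome's own current copy
    for ev in config.duplications:
        targets = ev.genomes if ev.genomes is not None else tuple(labels)
        lam_dup = _lam_for(ev.within_identity_pct)
        for lb in targets:
            sources = [inst for inst in instances[lb]
                       if inst.function == ev.function_label
                       and inst.origin == "vertical"]
            for src in sources:
                for c in range(ev.copies - 1):
                    arr = src.aa.copy()
                    _apply_hits(arr, int(round(lam_dup * arr.size)), ev_rng, 20)
                    instances[lb].append(_Instance(
                        anc_id=f"{src.anc_id}.dup{c + 1}", genome=lb, aa=arr,
                        origin="duplicate", function=src.function,
                        island=src.island, block=src.block))

    # HGT: donor island genes copied into the recipient as a contiguous run
    for hi, ev in enumerate(config.hgt):
        donor_insts = [inst for inst in instances[ev.donor]
                       if inst.function in ev.functions
                       and inst.origin in ("vertical", "hgt")]
        missing = set(ev.functions) - {inst.function for inst in donor_insts}
        if missing:
            raise SimulationError(
                f"HGT donor {ev.donor} lacks functions {sorted(missing)}")
        lam_hgt = _lam_for(ev.island_identity_pct)
        block = f"hgt{hi + 1}"
        for fn in ev.functions:           # preserve configured island order
            src = next(inst for inst in donor_insts if inst.function == fn)
            arr = src.aa.copy()
            _apply_hits(arr, int(round(lam_hgt * arr.size)), ev_rng, 20)
            instances[ev.recipient].append(_Instance(
                anc_id=f"{src.anc_id}.hgt", genome=ev.recipient, aa=arr,
                origin="hgt", function=fn, island=block, block=block))

    # truncations: drop the protein, keep an internal in-frame fragment
    truncation_by_genome: dict[str, list[tuple[TruncationEvent, _Instance]]] = {}
    for ev in config.truncations:
        pool = [inst for inst in instances[ev.genome]
                if inst.function == ev.function_label]
        if not pool:
            raise SimulationError(
                f"truncation target {ev.function_label} absent from {ev.genome}")
        victim = pool[0]
        instances[ev.genome].remove(victim)
        truncation_by_genome.setdefault(ev.genome, []).append((ev, victim))

    # --- 16S markers -------------------------------------------------------
    marker_rng = streams["marker"]
    marker_anc = marker_rng.integers(0, 4, config.marker_length)
    if len(labels) > 1:
        lam_m = {
            frozenset((a, b)): _lam_for(config.pair_marker_identity(a, b), 4)
            for a, b in itertools.combinations(labels, 2)}
        loads_m = _solve_branch_loads(labels, lam_m)
    else:
        loads_m = np.zeros(1)
    markers: dict[str, np.ndarray] = {}
    for gi, lb in enumerate(labels):
        arr = marker_anc.copy()
        _apply_hits(arr, int(round(loads_m[gi] * arr.size)), marker_rng, 4)
        markers[lb] = arr
    realized_marker = {
        f"{a}|{b}": 100.0 * float((markers[a] == markers[b]).mean())
        for a, b in itertools.combinations(labels, 2)}

    # --- layout and contig assembly ----------------------------------------
    layout_rng = streams["layout"]
    bundles: list[GenomeBundle] = []
    truth_orthologs: dict[str, dict[str, str]] = {}
    truth_origins: dict[str, dict[str, str]] = {lb: {} for lb in labels}
    truth_functions: dict[str, dict[str, str]] = {lb: {} for lb in labels}
    truth_islands: dict[str, dict[str, list[str]]] = {}
    truth_truncations: list[dict] = []

    for lb in labels:
        insts = instances[lb]
        # group into layout units: island blocks stay contiguous
        blocks: dict[str, list[_Instance]] = {}
        units: list[list[_Instance]] = []
        for inst in insts:
            if inst.block:
                if inst.block not in blocks:
                    blocks[inst.block] = []
                    units.append(blocks[inst.block])
                blocks[inst.block].append(inst)
            else:
                units.append([inst])
        # truncated remnants ride along as their own unit
        frag_units: list[tuple[TruncationEvent, _Instance]] = \
            truncation_by_genome.get(lb, [])
        order = layout_rng.permutation(len(units))
        slot_draws = layout_rng.integers(0, len(units) + 1, len(frag_units))
        frag_queue = sorted(
            zip(slot_draws.tolist(), range(len(frag_units))))  # (slot, idx)

        contig_parts: list[str] = []
        features: list[Feature] = []
        proteins: dict[str, str] = {}
        pos = 0
        counter = 0

        def add_spacer() -> None:
            nonlocal pos
            spacer = _random_nt(config.spacer_len, layout_rng)
            contig_parts.append(spacer)
            pos += len(spacer)

        def add_fragment(ev: TruncationEvent, victim: _Instance) -> None:
            nonlocal pos
            n_res = ev.fragment_length_nt // 3
            aa = _decode(victim.aa)
            start_res = max(0, (len(aa) - n_res) // 2)
            window = aa[start_res : start_res + n_res]
            frag_nt = "TAA" + _back_translate(window, layout_rng) + "TAA"
            start = pos + 3 + 1
            contig_parts.append(frag_nt)
            pos += len(frag_nt)
            truth_truncations.append({
                "genome": lb, "function": ev.function_label,
                "fragment_length_nt": ev.fragment_length_nt,
                "contig_id": "contig1",
                "start": start, "end": start + ev.fragment_length_nt - 1,
            })

        add_spacer()
        # 16S gene first
        rrs = _decode(markers[lb], NT_LETTERS)
        features.append(Feature(f"{lb}_rrs", "contig1", pos + 1, pos + len(rrs),
                                "+", "16S ribosomal RNA"))
        contig_parts.append(rrs)
        pos += len(rrs)

        frag_iter = iter(frag_queue)
        next_frag = next(frag_iter, None)
        for unit_rank, ui in enumerate(order):
            while next_frag is not None and next_frag[0] <= unit_rank:
                add_spacer()
                ev, victim = frag_units[next_frag[1]]
                add_fragment(ev, victim)
                next_frag = next(frag_iter, None)
            for inst in units[ui]:
                add_spacer()
                counter += 1
                tag = f"{lb}_{counter:04d}"
                aa = _decode(inst.aa)
                stop = _codon_table()["*"][layout_rng.integers(0, 3)]
                nt = _back_translate(aa, layout_rng) + stop
                strand = "+" if layout_rng.integers(0, 2) else "-"
                if strand == "-":
                    nt = str(Seq(nt).reverse_complement())
                start = pos + 1
                contig_parts.append(nt)
                pos += len(nt)
                product = (f"{inst.function} methylotrophy protein"
                           if inst.function else "hypothetical protein")
                features.append(Feature(tag, "contig1", start, pos, strand,
                                        product))
                proteins[tag] = aa
                truth_orthologs.setdefault(inst.anc_id, {})[lb] = tag
                truth_origins[lb][tag] = inst.origin
                if inst.function:
                    truth_functions[lb][tag] = inst.function
                if inst.island:
                    truth_islands.setdefault(inst.island, {}) \
                        .setdefault(lb, []).append(tag)
        while next_frag is not None:
            add_spacer()
            ev, victim = frag_units[next_frag[1]]
            add_fragment(ev, victim)
            next_frag = next(frag_iter, None)
        add_spacer()

        bundles.append(GenomeBundle(
            label=lb,
            proteome=Proteome(proteins),
            features=FeatureTable(features),
            contigs={"contig1": "".join(contig_parts)},
        ))

    truth = GroundTruth(
        orthologs=truth_orthologs,
        origins=truth_origins,
        functions=truth_functions,
        islands=truth_islands,
        realized_identity_pct={
            f"{a}|{b}": real[frozenset((a, b))]
            for a, b in itertools.combinations(labels, 2)},
        realized_marker_identity_pct=realized_marker,
        truncations=truth_truncations,
    )
    return bundles, panel, truth


def write_simulation(
    bundles: list[GenomeBundle],
    panel: ReferencePanel,
    truth: GroundTruth,
    outdir: str | Path,
) -> None:
    """Emit per-genome directories, the panel FASTA+TSV and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for b in bundles:
        write_genome_dir(b, outdir / b.label)
    write_fasta({e.panel_id: e.sequence for e in panel}, outdir / "panel.faa")
    with open(outdir / "panel.tsv", "w") as fh:
        fh.write("panel_id\tfunction_label\tsource\tnotes\n")
        for e in panel:
            fh.write(f"{e.panel_id}\t{e.function_label}\t{e.source}\t{e.notes}\n")
    with open(outdir / "truth.json", "w") as fh:
        fh.write(truth.to_json() + "\n")
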