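"""Synthetic genomes with planted amplification loci and ground truth.

The generator emulates the structures the screen targets and the
structures it must reject:

* planted loci ``SRS*c1 + unit + SRS*c2 + ... + SRS*c(k+1)`` with
  per-junction SRS copy numbers, one master unit per locus mutated
  independently per copy (post-amplification divergence), and optional
  partial head/tail units outside the outer blocks;
* confounders — uniform-copy arrays (every junction has the same SRS
  copy number; the screen's explicit exclusion) and SRS-free tandem
  arrays (plain long-period tandem repeats without SRS junctions);
* i.i.d. background of configurable GC content (a "hard mode" plants
  random microsatellites to stress precision).

Everything is a pure function of ``(spec, spec.seed)`` at byte level.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .detect import HSRLocus
from .repeat_finder import canonical_motif, find_tandem_repeats

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimSpecError(ValueError):
    """Raised when a simulation spec cannot be realised."""


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. DNA with P(G or C) = ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently (to a uniformly chosen different
    base) with probability ``rate``; length preserved, no indels."""
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.zeros(arr.shape, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        code[arr == b] = i
    mask = rng.random(len(seq)) < rate
    shift = rng.integers(1, 4, size=len(seq))
    newcode = (code + shift) % 4
    arr[mask] = _BASES[newcode[mask]]
    return arr.tobytes().decode()


_UNIT_CLEAN_SCORE = 16  # matches the default scan-level detector floor


def _clean_random_unit(length: int, gc: float, rng: np.random.Generator) -> str:
    """A random unit free of internal tandem runs at the detector floor.

    An incidental microsatellite inside a master unit would recur in every
    unit copy, planting junction-like repeat runs the spec did not ask
    for; breaking each found run (one redrawn base in its middle) keeps
    every planted structure unambiguously of its declared kind.  (Real
    amplified units can of course contain such repeats; see the methods
    note on what the generator does not emulate.)
    """
    arr = np.frombuffer(random_dna(length, gc, rng).encode(), dtype=np.uint8).copy()
    for _ in range(100):
        found = find_tandem_repeats(
            arr.tobytes().decode(),
            min_period=2,
            max_period=min(200, length - 1),
            min_score=_UNIT_CLEAN_SCORE,
        )
        if not found:
            return arr.tobytes().decode()
        for rec in found:
            mid = (rec.start + rec.end) // 2
            old = arr[mid]
            while arr[mid] == old:
                arr[mid] = _BASES[rng.integers(0, 4)]
    raise SimSpecError("could not draw a repeat-free unit sequence")


def _break_unit_edges(master: str, motif: str, rng: np.random.Generator) -> str:
    """Redraw the master unit's first/last base when it would continue the
    flanking SRS run's periodicity: block boundaries then sit exactly at
    the planted junctions instead of jittering into the units (which can
    shift rounded copy counts, e.g. turning a uniform array non-uniform)."""
    others_first = [b for b in "ACGT" if b != motif[0]]
    others_last = [b for b in "ACGT" if b != motif[-1]]
    out = list(master)
    if out[0] == motif[0]:
        out[0] = others_first[int(rng.integers(0, 3))]
    if out[-1] == motif[-1]:
        out[-1] = others_last[int(rng.integers(0, 3))]
    return "".join(out)


def _no_subperiod_structure(motif: str) -> bool:
    """True when a tandem array of ``motif`` contains no detectable runs of
    a shorter period.  A near-periodic motif (e.g. GAGGGAGGG, whose array
    is full of perfect AGGG runs) yields two equally valid structural
    descriptions of one planted locus — the study conditions avoid that
    ambiguity rather than arbitrate it."""
    return not find_tandem_repeats(
        motif * 3, min_period=1, max_period=len(motif) - 1,
        min_score=_UNIT_CLEAN_SCORE,
    )


def _is_primitive(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


@dataclass
class PlantedLocus:
    """Description of one planted ``SRS*N + unit + SRS*N`` structure.

    ``insert_at`` is the genomic offset of the construct (including any
    partial head unit), or None for random placement.  Fractions give the
    portion of one unit planted outside the outer blocks.
    """

    srs_motif: str
    copy_counts: List[int]
    unit_length: int = 200
    n_units: int = 3
    substitution_rate: float = 0.0
    head_fraction: float = 0.0
    tail_fraction: float = 0.0
    insert_at: Optional[int] = None

    def validate(self) -> None:
        if not (2 <= len(self.srs_motif) <= 200):
            raise SimSpecError("SRS motif length must be in [2, 200]")
        if not set(self.srs_motif.upper()) <= set("ACGT"):
            raise SimSpecError("SRS motif must be A/C/G/T")
        if not _is_primitive(self.srs_motif.upper()):
            raise SimSpecError(
                f"SRS motif {self.srs_motif!r} is a repetition of a shorter motif; "
                "use the primitive motif"
            )
        if not (50 <= self.unit_length <= 30000):
            raise SimSpecError("unit_length must be in [50, 30000]")
        if self.n_units < 1:
            raise SimSpecError("n_units must be >= 1")
        if len(self.copy_counts) != self.n_units + 1:
            raise SimSpecError("need n_units + 1 copy counts (one per junction)")
        if any(c < 1 for c in self.copy_counts):
            raise SimSpecError("copy counts must be >= 1")
        if len(self.copy_counts) > 1 and len(set(self.copy_counts)) < 2:
            raise SimSpecError(
                "planted locus has uniform SRS copy numbers; the screen excludes "
                "such arrays by design — plant a Confounder(kind='uniform') instead"
            )
        if not (0 <= self.head_fraction <= 1 and 0 <= self.tail_fraction <= 1):
            raise SimSpecError("head/tail fractions must be in [0, 1]")
        if not (0 <= self.substitution_rate < 1):
            raise SimSpecError("substitution_rate must be in [0, 1)")

    @property
    def total_length(self) -> int:
        m = len(self.srs_motif)
        return (
            round(self.head_fraction * self.unit_length)
            + sum(self.copy_counts) * m
            + self.n_units * self.unit_length
            + round(self.tail_fraction * self.unit_length)
        )


@dataclass
class Confounder:
    """A structure the screen must reject.

    ``kind="uniform"``: an SRS-junction array whose copy numbers are all
    equal (``copy_count`` at every junction).  ``kind="srs_free"``: the
    unit repeated back-to-back with no SRS junctions at all.
    """

    kind: str = "uniform"
    srs_motif: str = "GATC"
    copy_count: int = 3
    unit_length: int = 200
    n_units: int = 3
    insert_at: Optional[int] = None

    def validate(self) -> None:
        if self.kind not in ("uniform", "srs_free"):
            raise SimSpecError(f"unknown confounder kind {self.kind!r}")
        if self.kind == "uniform":
            if not _is_primitive(self.srs_motif.upper()):
                raise SimSpecError("confounder SRS motif must be primitive")
        if not (50 <= self.unit_length <= 30000):
            raise SimSpecError("unit_length must be in [50, 30000]")
        if self.n_units < 1 or self.copy_count < 1:
            raise SimSpecError("n_units and copy_count must be >= 1")

    @property
    def total_length(self) -> int:
        if self.kind == "uniform":
            return (
                (self.n_units + 1) * self.copy_count * len(self.srs_motif)
                + self.n_units * self.unit_length
            )
        return self.n_units * self.unit_length


@dataclass
class SimSpec:
    """Full description of one synthetic genome (seed mandatory)."""

    genome_length: int
    seed: int
    gc_background: float = 0.41
    seq_id: str = "chr1"
    loci: List[PlantedLocus] = field(default_factory=list)
    confounders: List[Confounder] = field(default_factory=list)
    n_background_microsatellites: int = 0   # "hard mode"

    def validate(self) -> None:
        if self.genome_length < 1:
            raise SimSpecError("genome_length must be positive")
        if not (0 < self.gc_background < 1):
            raise SimSpecError("gc_background must be in (0, 1)")
        for loc in self.loci:
            loc.validate()
        for c in self.confounders:
            c.validate()
        total = sum(l.total_length for l in self.loci) + sum(
            c.total_length for c in self.confounders
        )
        n_inserts = len(self.loci) + len(self.confounders)
        if total + (n_inserts + 1) * _MARGIN > self.genome_length:
            raise SimSpecError(
                f"genome_length {self.genome_length} too short for "
                f"{total} bp of inserts plus spacing"
            )


@dataclass
class TruthRecord:
    """Ground truth for one planted structure.

    ``start``/``end`` delimit the SRS-block span (what the scanner reports
    as the locus); partial head/tail units lie outside it.
    """

    seq_id: str
    start: int
    end: int
    kind: str                      # "hsr", "confounder_uniform", "confounder_srs_free"
    srs_motif: str
    family: str                    # canonical, strand-merged
    n_units: int
    copy_counts: List[int]
    block_intervals: List[Tuple[int, int]]
    unit_intervals: List[Tuple[int, int]]
    head_fraction: float = 0.0
    tail_fraction: float = 0.0

    @property
    def span(self) -> int:
        return self.end - self.start


_MARGIN = 300  # bp kept between inserts and from the sequence ends


def _build_locus(
    locus: PlantedLocus, gc: float, rng: np.random.Generator
) -> Tuple[str, dict]:
    """Sequence of the full construct plus a relative layout."""
    m = len(locus.srs_motif)
    master = _break_unit_edges(
        _clean_random_unit(locus.unit_length, gc, rng), locus.srs_motif, rng
    )
    units = [mutate(master, locus.substitution_rate, rng) for _ in range(locus.n_units)]
    h_len = round(locus.head_fraction * locus.unit_length)
    t_len = round(locus.tail_fraction * locus.unit_length)
    head = mutate(master, locus.substitution_rate, rng)[locus.unit_length - h_len :] if h_len else ""
    tail = mutate(master, locus.substitution_rate, rng)[:t_len] if t_len else ""

    parts = [head]
    block_rel: List[Tuple[int, int]] = []
    unit_rel: List[Tuple[int, int]] = []
    pos = len(head)
    for i, c in enumerate(locus.copy_counts):
        block = locus.srs_motif * c
        parts.append(block)
        block_rel.append((pos, pos + len(block)))
        pos += len(block)
        if i < locus.n_units:
            parts.append(units[i])
            unit_rel.append((pos, pos + locus.unit_length))
            pos += locus.unit_length
    parts.append(tail)
    seq = "".join(parts)

    if locus.substitution_rate == 0:
        # construction validity: copies must be byte-identical at zero noise
        assert all(u == master for u in units)
    return seq, {"blocks": block_rel, "units": unit_rel, "head_len": h_len, "tail_len": t_len}


def _build_confounder(conf: Confounder, gc: float, rng: np.random.Generator) -> Tuple[str, dict]:
    master = _clean_random_unit(conf.unit_length, gc, rng)
    if conf.kind == "uniform":
        master = _break_unit_edges(master, conf.srs_motif, rng)
        m_block = conf.srs_motif * conf.copy_count
        parts, block_rel, unit_rel, pos = [], [], [], 0
        for i in range(conf.n_units + 1):
            parts.append(m_block)
            block_rel.append((pos, pos + len(m_block)))
            pos += len(m_block)
            if i < conf.n_units:
                parts.append(master)
                unit_rel.append((pos, pos + conf.unit_length))
                pos += conf.unit_length
        return "".join(parts), {"blocks": block_rel, "units": unit_rel, "head_len": 0, "tail_len": 0}
    # srs_free: plain long-period tandem array
    seq = master * conf.n_units
    unit_rel = [(i * conf.unit_length, (i + 1) * conf.unit_length) for i in range(conf.n_units)]
    return seq, {"blocks": [], "units": unit_rel, "head_len": 0, "tail_len": 0}


def _place(
    lengths: Sequence[int],
    fixed: Sequence[Optional[int]],
    genome_length: int,
    rng: np.random.Generator,
) -> List[int]:
    """Non-overlapping insert offsets with ``_MARGIN`` bp separation."""
    placed: List[Tuple[int, int]] = []
    offsets: List[Optional[int]] = [None] * len(lengths)
    for i, (length, at) in enumerate(zip(lengths, fixed)):
        if at is None:
            continue
        iv = (at - _MARGIN, at + length + _MARGIN)
        if at < _MARGIN or at + length + _MARGIN > genome_length:
            raise SimSpecError(f"fixed insert at {at} does not fit")
        if any(iv[0] < e and s < iv[1] for s, e in placed):
            raise SimSpecError(f"fixed insert at {at} overlaps another insert")
        placed.append(iv)
        offsets[i] = at
    for i, (length, at) in enumerate(zip(lengths, fixed)):
        if at is not None:
            continue
        for _ in range(1000):
            start = int(rng.integers(_MARGIN, genome_length - length - _MARGIN + 1))
            iv = (start - _MARGIN, start + length + _MARGIN)
            if not any(iv[0] < e and s < iv[1] for s, e in placed):
                placed.append(iv)
                offsets[i] = start
                break
        else:
            raise SimSpecError("could not place all inserts; genome too crowded")
    return offsets  # type: ignore[return-value]


def generate(spec: SimSpec) -> Tuple[Dict[str, str], List[TruthRecord]]:
    """Realise a spec: returns ``({seq_id: sequence}, truth records)``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    background = np.frombuffer(
        random_dna(spec.genome_length, spec.gc_background, rng).encode(), dtype=np.uint8
    ).copy()

    builds: List[Tuple[str, dict, object]] = []
    for locus in spec.loci:
        seq, layout = _build_locus(locus, spec.gc_background, rng)
        builds.append((seq, layout, locus))
    for conf in spec.confounders:
        seq, layout = _build_confounder(conf, spec.gc_background, rng)
        builds.append((seq, layout, conf))
    if spec.n_background_microsatellites:
        for _ in range(spec.n_background_microsatellites):
            mlen = int(rng.integers(2, 7))
            motif = random_dna(mlen, 0.5, rng)
            copies = int(rng.integers(10, 30))
            builds.append((motif * copies, {"blocks": [], "units": [], "head_len": 0,
                                            "tail_len": 0}, None))

    lengths = [len(b[0]) for b in builds]
    fixed = [getattr(b[2], "insert_at", None) for b in builds]
    offsets = _place(lengths, fixed, spec.genome_length, rng)

    truths: List[TruthRecord] = []
    for (seq, layout, obj), off in zip(builds, offsets):
        ins = np.frombuffer(seq.encode(), dtype=np.uint8)
        background[off : off + len(ins)] = ins
        if obj is None:
            continue  # background microsatellite: no truth record
        blocks = [(off + s, off + e) for s, e in layout["blocks"]]
        units = [(off + s, off + e) for s, e in layout["units"]]
        if isinstance(obj, PlantedLocus):
            kind = "hsr"
            motif = obj.srs_motif
            copies = list(obj.copy_counts)
            hf, tf = obj.head_fraction, obj.tail_fraction
        else:
            kind = f"confounder_{obj.kind}"
            motif = obj.srs_motif if obj.kind == "uniform" else ""
            copies = [obj.copy_count] * (obj.n_units + 1) if obj.kind == "uniform" else []
            hf = tf = 0.0
        if blocks:
            span = (blocks[0][0], blocks[-1][1])
        else:
            span = (units[0][0], units[-1][1])
        truths.append(
            TruthRecord(
                seq_id=spec.seq_id,
                start=span[0],
                end=span[1],
                kind=kind,
                srs_motif=motif,
                family=canonical_motif(motif).canonical if motif else "",
                n_units=len(units),
                copy_counts=copies,
                block_intervals=blocks,
                unit_intervals=units,
                head_fraction=hf,
                tail_fraction=tf,
            )
        )

    _break_boundary_extensions(background, truths, rng)
    return {spec.seq_id: background.tobytes().decode()}, truths


_EDGE_MERGE_GAP = 8  # matches the scanner's default same-family merge window


def _strip_family_runs_near_edge(
    genome: np.ndarray,
    family: str,
    period: int,
    edge: int,
    side: str,
    rng: np.random.Generator,
) -> None:
    """Break chance same-family tandem runs the scanner would merge into a
    planted array's outer junction block.

    Offending runs end within the merge window of the edge or cross it —
    a background suffix plus the block's first bases can form a perfect
    phase-shifted run of the same family.  Only period-``period`` runs can
    share the family (canonical keys preserve motif length).  Redraws touch
    background bases only, never the planted array."""
    from .repeat_finder import canonical_motif as _canon

    w = _EDGE_MERGE_GAP + max(4 * period, 40)
    for _ in range(30):
        if side == "left":
            # window reaches into the block so boundary-crossing runs show
            w_start = max(0, edge - w)
            w_end = min(len(genome), edge + 2 * period + _EDGE_MERGE_GAP)
        else:
            w_start = max(0, edge - 2 * period - _EDGE_MERGE_GAP)
            w_end = min(len(genome), edge + w)
        seg = genome[w_start:w_end].tobytes().decode()
        if len(seg) <= 2 * period:
            return
        rel_edge = edge - w_start
        bad = []
        for rec in find_tandem_repeats(
            seg, min_period=period, max_period=period, min_score=_UNIT_CLEAN_SCORE
        ):
            if _canon(rec.consensus).canonical != family:
                continue
            if side == "left" and rec.start < rel_edge and rec.end >= rel_edge - _EDGE_MERGE_GAP:
                bad.append(rec)
            elif side == "right" and rec.end > rel_edge and rec.start <= rel_edge + _EDGE_MERGE_GAP:
                bad.append(rec)
        if not bad:
            return
        for rec in bad:
            # redraw the outermost background base of the run, breaking the
            # recurrence that supports it (s[pos] == s[pos +/- period])
            if side == "left":
                pos = w_start + rec.start          # < edge by construction
                partner = min(pos + period, len(genome) - 1)
            else:
                pos = w_start + rec.end - 1        # >= edge by construction
                partner = max(pos - period, 0)
            while genome[pos] == genome[partner]:
                genome[pos] = _BASES[rng.integers(0, 4)]


def _break_boundary_extensions(
    genome: np.ndarray, truths: List[TruthRecord], rng: np.random.Generator
) -> None:
    """Keep truth block spans exactly the maximal runs a detector sees:
    redraw the single background base flanking each planted SRS array when
    it would extend the perfect tandem run by chance, and break chance
    same-family background runs close enough to be merged into the outer
    block.  Bases belonging to partial head/tail units are never touched."""
    from .repeat_finder import canonical_motif as _canon

    n = len(genome)
    for t in truths:
        if not t.block_intervals or not t.srs_motif:
            continue
        d = len(t.srs_motif)
        fam = _canon(t.srs_motif).canonical
        # left edge: run extends iff genome[start-1] == genome[start-1+d]
        p = t.start
        if t.head_fraction == 0 and p - 1 >= 0 and p - 1 + d < n:
            while genome[p - 1] == genome[p - 1 + d]:
                genome[p - 1] = _BASES[rng.integers(0, 4)]
            _strip_family_runs_near_edge(genome, fam, d, p, "left", rng)
            while genome[p - 1] == genome[p - 1 + d]:
                genome[p - 1] = _BASES[rng.integers(0, 4)]
        # right edge: run extends iff genome[end] == genome[end-d]
        q = t.end
        if t.tail_fraction == 0 and q < n and q - d >= 0:
            while genome[q] == genome[q - d]:
                genome[q] = _BASES[rng.integers(0, 4)]
            _strip_family_runs_near_edge(genome, fam, d, q, "right", rng)
            while genome[q] == genome[q - d]:
                genome[q] = _BASES[rng.integers(0, 4)]


# ---------------------------------------------------------------------------
# file round trip

def simulate_genome(spec: SimSpec, prefix: str | os.PathLike) -> Tuple[str, str]:
    """Write ``<prefix>.fasta`` and ``<prefix>.truth.gff3``; byte-identical
    for identical ``(spec, seed)``.  Returns the two paths."""
    genome, truths = generate(spec)
    prefix = os.fspath(prefix)
    fasta_path, gff_path = f"{prefix}.fasta", f"{prefix}.truth.gff3"
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()],
        fasta_path,
        "fasta",
    )
    write_truth_gff3(truths, gff_path)
    return fasta_path, gff_path


def write_truth_gff3(truths: Sequence[TruthRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as gff:
        gff.write("##gff-version 3\n")
        for i, t in enumerate(truths, start=1):
            tid = f"truth{i:05d}"
            attrs = (
                f"ID={tid};kind={t.kind};srs_motif={t.srs_motif};family={t.family};"
                f"n_units={t.n_units};"
                f"copy_numbers={','.join(str(c) for c in t.copy_counts)};"
                f"head_fraction={t.head_fraction:.4f};tail_fraction={t.tail_fraction:.4f}"
            )
            gff.write(
                f"{t.seq_id}\thsrscan_sim\ttandem_amplification_locus\t"
                f"{t.start + 1}\t{t.end}\t{t.n_units}\t.\t.\t{attrs}\n"
            )
            for j, (s, e) in enumerate(t.block_intervals, start=1):
                copies = t.copy_counts[j - 1] if t.copy_counts else 0
                gff.write(
                    f"{t.seq_id}\thsrscan_sim\tsrs_block\t{s + 1}\t{e}\t.\t.\t.\t"
                    f"ID={tid}.b{j};Parent={tid};copies={copies};motif={t.srs_motif}\n"
                )
            for j, (s, e) in enumerate(t.unit_intervals, start=1):
                gff.write(
                    f"{t.seq_id}\thsrscan_sim\tamplified_unit\t{s + 1}\t{e}\t.\t.\t.\t"
                    f"ID={tid}.u{j};Parent={tid}\n"
                )


def read_truth_gff3(path: str | os.PathLike) -> List[TruthRecord]:
    from .trf_io import _parse_gff_attrs

    truths: Dict[str, TruthRecord] = {}
    order: List[str] = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            seq_id, ftype = cols[0], cols[2]
            start, end = int(cols[3]) - 1, int(cols[4])
            attrs = _parse_gff_attrs(cols[8])
            if ftype == "tandem_amplification_locus":
                tid = attrs["ID"]
                order.append(tid)
                copies = attrs.get("copy_numbers", "")
                truths[tid] = TruthRecord(
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    kind=attrs["kind"],
                    srs_motif=attrs.get("srs_motif", ""),
                    family=attrs.get("family", ""),
                    n_units=int(attrs["n_units"]),
                    copy_counts=[int(c) for c in copies.split(",")] if copies else [],
                    block_intervals=[],
                    unit_intervals=[],
                    head_fraction=float(attrs.get("head_fraction", 0)),
                    tail_fraction=float(attrs.get("tail_fraction", 0)),
                )
            elif ftype == "srs_block":
                truths[attrs["Parent"]].block_intervals.append((start, end))
            elif ftype == "amplified_unit":
                truths[attrs["Parent"]].unit_intervals.append((start, end))
    return [truths[t] for t in order]


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    mean_boundary_error: float     # bp, over matched loci; NaN when none matched
    unit_count_agreement: float    # fraction of matched loci with exact unit count
    boundary_within_slack: float   # fraction of matched loci within +/- slack bp
    n_true: int
    n_detected: int
    n_matched: int

    def to_row(self) -> Dict[str, object]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "mean_boundary_error": self.mean_boundary_error,
            "unit_count_agreement": self.unit_count_agreement,
            "boundary_within_slack": self.boundary_within_slack,
            "n_true": self.n_true,
            "n_detected": self.n_detected,
            "n_matched": self.n_matched,
        }


def _reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def evaluate_detection(
    detected: Sequence[HSRLocus],
    truth: Sequence[TruthRecord],
    slack: int = 0,
) -> DetectionMetrics:
    """Score detections against planted truth.

    A detection matches a planted locus when their spans overlap
    reciprocally >= 50 % and the strand-merged SRS families agree
    (one-to-one, best overlap first).  Confounders can never be matched,
    so any detection over one counts as a false positive.
    """
    planted = [t for t in truth if t.kind == "hsr"]
    pairs = []
    for i, d in enumerate(detected):
        for j, t in enumerate(planted):
            if d.seq_id != t.seq_id:
                continue
            if d.family.canonical != t.family:
                continue
            ro = _reciprocal_overlap((d.start, d.end), (t.start, t.end))
            if ro >= 0.5:
                pairs.append((ro, i, j))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_d: set = set()
    used_t: set = set()
    matches: List[Tuple[int, int]] = []
    for _ro, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matches.append((i, j))

    n_d, n_t, n_m = len(detected), len(planted), len(matches)
    if matches:
        errs = []
        unit_ok = 0
        within = 0
        for i, j in matches:
            d, t = detected[i], planted[j]
            ds, de = abs(d.start - t.start), abs(d.end - t.end)
            errs.append((ds + de) / 2.0)
            if d.n_units == t.n_units:
                unit_ok += 1
            if ds <= slack and de <= slack:
                within += 1
        mean_err = float(np.mean(errs))
        unit_agree = unit_ok / n_m
        within_frac = within / n_m
    else:
        mean_err = float("nan")
        unit_agree = float("nan")
        within_frac = float("nan")
    return DetectionMetrics(
        precision=n_m / n_d if n_d else 1.0,
        recall=n_m / n_t if n_t else 1.0,
        mean_boundary_error=mean_err,
        unit_count_agreement=unit_agree,
        boundary_within_slack=within_frac,
        n_true=n_t,
        n_detected=n_d,
        n_matched=n_m,
    )


def truth_from_loci(loci: Sequence[HSRLocus]) -> List[TruthRecord]:
    """Recast detected loci as truth records (self-evaluation helper)."""
    return [
        TruthRecord(
            seq_id=l.seq_id,
            start=l.start,
            end=l.end,
            kind="hsr",
            srs_motif=l.blocks[0].observed_motif,
            family=l.family.canonical,
            n_units=l.n_units,
            copy_counts=list(l.copy_numbers),
            block_intervals=[(b.start, b.end) for b in l.blocks],
            unit_intervals=[(u.start, u.end) for u in l.units],
        )
        for l in loci
    ]


# ---------------------------------------------------------------------------
# YAML spec round trip

def load_simspec(path: str | os.PathLike) -> SimSpec:
    """Read a flat YAML simulation spec."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    loci = [PlantedLocus(**d) for d in data.pop("loci", [])]
    confs = [Confounder(**d) for d in data.pop("confounders", [])]
    spec = SimSpec(loci=loci, confounders=confs, **data)
    spec.validate()
    return spec


def save_simspec(spec: SimSpec, path: str | os.PathLike) -> None:
    data = {
        "genome_length": spec.genome_length,
        "seed": spec.seed,
        "gc_background": spec.gc_background,
        "seq_id": spec.seq_id,
        "n_background_microsatellites": spec.n_background_microsatellites,
        "loci": [
            {
                "srs_motif": l.srs_motif,
                "copy_counts": list(l.copy_counts),
                "unit_length": l.unit_length,
                "n_units": l.n_units,
                "substitution_rate": l.substitution_rate,
                "head_fraction": l.head_fraction,
                "tail_fraction": l.tail_fraction,
                "insert_at": l.insert_at,
            }
            for l in spec.loci
        ],
        "confounders": [
            {
                "kind": c.kind,
                "srs_motif": c.srs_motif,
                "copy_count": c.copy_count,
                "unit_length": c.unit_length,
                "n_units": c.n_units,
                "insert_at": c.insert_at,
            }
            for c in spec.confounders
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def random_spec(
    seed: int,
    genome_length: int = 100_000,
    n_loci: Optional[int] = None,
    substitution_rate: float = 0.0,
    with_confounders: bool = True,
    head_fraction: float = 0.0,
    tail_fraction: float = 0.0,
) -> SimSpec:
    """A randomized study-condition spec: 1-3 planted loci with variable
    copy counts, plus a uniform-copy and an SRS-free confounder."""
    rng = np.random.default_rng(seed)
    if n_loci is None:
        n_loci = int(rng.integers(1, 4))
    loci = []
    used_families: set = set()
    for _ in range(n_loci):
        # distinct SRS families: same-family structures within chaining
        # distance would bridge into one rejected chain
        while True:
            mlen = int(rng.integers(2, 13))
            motif = random_dna(mlen, 0.5, rng)
            fam = canonical_motif(motif).canonical
            if (
                _is_primitive(motif)
                and _no_subperiod_structure(motif)
                and fam not in used_families
            ):
                used_families.add(fam)
                break
        n_units = int(rng.integers(3, 6))
        # junction blocks must be long enough to reach the detector's
        # minimum alignment score (10 bp at the default 2/3/5 weights);
        # shorter runs are invisible to a TRF-style screen by definition
        low = max(2, -(-10 // mlen))
        while True:
            copies = [int(c) for c in rng.integers(low, low + 5, size=n_units + 1)]
            if len(set(copies)) >= 2:
                break
        loci.append(
            PlantedLocus(
                srs_motif=motif,
                copy_counts=copies,
                unit_length=int(rng.integers(100, 500)),
                n_units=n_units,
                substitution_rate=substitution_rate,
                head_fraction=head_fraction,
                tail_fraction=tail_fraction,
            )
        )
    confs = []
    if with_confounders:
        while True:
            cm = random_dna(4, 0.5, rng)
            if (
                _is_primitive(cm)
                and _no_subperiod_structure(cm)
                and canonical_motif(cm).canonical not in used_families
            ):
                break
        confs = [
            Confounder(kind="uniform", srs_motif=cm, copy_count=4,
                       unit_length=int(rng.integers(100, 400)), n_units=3),
            Confounder(kind="srs_free", unit_length=int(rng.integers(300, 600)), n_units=4),
        ]
    return SimSpec(
        genome_length=genome_length,
        seed=int(rng.integers(0, 2**31 - 1)),
        loci=loci,
        confounders=confs,
    )
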