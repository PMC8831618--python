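"""Core screen for SRS-junction tandem-amplification ("high-speed rail") loci.

A locus is an alternating chain ``SRS*N1 + unit + SRS*N2 + ... + SRS*Nk``:
tandem runs (blocks) of one short repeated sequence (SRS) family delimit
near-identical amplified units, and the SRS copy numbers N vary between
junctions.  The screen applies five conditions to candidate chains built
from a tandem-repeat annotation matrix:

1. SRS motif length within [srs_min_len, srs_max_len] (default 2-200 bp);
2. SRS match above srs_min_match (default >70 %), checked both per tandem
   record and between the observed motifs of chained blocks;
3. unit (inter-block gap) length within [unit_min_len, unit_max_len]
   (default 50-30,000 bp);
4. adjacent amplified units globally align at >= unit_min_identity
   (default 90 %);
5. SRS copy numbers across the chain's blocks are not all equal
   (uniform-copy arrays are excluded as non-diagnostic).

Accepted loci additionally carry a head and a tail ratio: the fraction of
one amplified unit present immediately outside the outermost SRS block
(0 = the locus ends on SRS, 1 = a full extra unit flanks the array).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import edlib
import numpy as np

from .repeat_finder import (
    AlignWeights,
    MotifFamilyKey,
    _rotations,
    canonical_motif,
    find_tandem_repeats,
    reverse_complement,
)
from .trf_io import TandemRepeatRecord


@dataclass
class ScanConfig:
    """All screening thresholds.

    Defaults implement the published conditions; ``srs_class_split`` puts
    2-3 bp motifs in the "short" class and 4-200 bp motifs in "long".
    """

    srs_min_len: int = 2
    srs_max_len: int = 200
    srs_class_split: int = 3          # short: len <= split
    srs_min_match: float = 70.0       # condition 2, per tandem record (strict >)
    srs_cross_match: float = 70.0     # condition 2, between chained block motifs
    unit_min_len: int = 50
    unit_max_len: int = 30000
    unit_min_identity: float = 90.0   # condition 4
    min_units: int = 3
    require_variable_copies: bool = True   # condition 5
    merge_strands: bool = True
    merge_max_gap: int = 8   # bp between same-family fragments of one junction run
    all_pairs_identity: bool = False  # condition 4 over all unit pairs, not adjacent
    overlap_policy: str = "greedy_by_units"
    # head/tail statistic
    head_tail_min_anchor: int = 20    # bp of flank required for a nonzero ratio
    head_tail_window: Optional[int] = None  # defaults to unit_max_len
    # internal repeat finder (used when no TRF annotation is supplied);
    # 16 = two copies of a 4 bp motif at match reward 2 — the screen must
    # see junction blocks down to N=2 of short motifs
    finder_min_score: int = 16
    finder_weights: AlignWeights = field(default_factory=AlignWeights)

    def validate(self) -> None:
        if not (2 <= self.srs_min_len <= self.srs_max_len):
            raise ValueError("require 2 <= srs_min_len <= srs_max_len")
        if self.unit_min_len >= self.unit_max_len:
            raise ValueError("require unit_min_len < unit_max_len")
        if not (0 < self.unit_min_identity <= 100):
            raise ValueError("unit_min_identity must be in (0, 100]")
        if not (0 <= self.srs_min_match <= 100):
            raise ValueError("srs_min_match must be in [0, 100]")
        if self.min_units < 1:
            raise ValueError("min_units must be >= 1")
        if self.overlap_policy != "greedy_by_units":
            raise ValueError(f"unknown overlap_policy {self.overlap_policy!r}")

    @property
    def window(self) -> int:
        return self.head_tail_window if self.head_tail_window is not None else self.unit_max_len


@dataclass
class SRSBlock:
    """One tandem run of an SRS motif at a junction; N = ``copy_count``."""

    seq_id: str
    start: int
    end: int
    family: MotifFamilyKey
    observed_motif: str
    copy_count: int
    percent_matches: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Unit:
    """An amplified unit: the sequence between two consecutive SRS blocks."""

    seq_id: str
    start: int
    end: int
    sequence: Optional[str]
    identity_to_prev: Optional[float] = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HSRLocus:
    """A detected ``SRS*N + unit + ... + SRS*N`` locus.

    Blocks and units strictly alternate (``len(blocks) == len(units) + 1``)
    and tile ``[start, end)`` without overlap.
    """

    seq_id: str
    start: int
    end: int
    family: MotifFamilyKey
    srs_class: str                 # "short" (2-3 bp) or "long" (4-200 bp)
    blocks: List[SRSBlock]
    units: List[Unit]
    copy_numbers: List[int]
    head_ratio: float
    tail_ratio: float

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def span(self) -> int:
        return self.end - self.start

    def check_invariants(self, config: Optional[ScanConfig] = None) -> None:
        """Assert structural and (optionally) threshold invariants."""
        assert len(self.blocks) == len(self.units) + 1, "alternation violated"
        parts = []
        for b, u in zip(self.blocks, self.units + [None]):
            parts.append((b.start, b.end))
            if u is not None:
                parts.append((u.start, u.end))
        assert parts[0][0] == self.start and parts[-1][1] == self.end
        for (s1, e1), (s2, e2) in zip(parts, parts[1:]):
            assert e1 == s2, "blocks/units do not tile the span"
        assert len(self.copy_numbers) == len(self.blocks)
        if config is not None:
            for b in self.blocks:
                assert config.srs_min_len <= len(b.observed_motif) <= config.srs_max_len
            for u in self.units:
                assert config.unit_min_len <= u.length <= config.unit_max_len
                if u.identity_to_prev is not None:
                    assert u.identity_to_prev >= config.unit_min_identity
            if config.require_variable_copies:
                assert len(set(self.copy_numbers)) >= 2, "uniform copy numbers"
            assert len(self.units) >= config.min_units


# ---------------------------------------------------------------------------
# stage 1: records -> blocks

def build_blocks(
    records: Iterable[TandemRepeatRecord], config: ScanConfig
) -> List[SRSBlock]:
    """Apply conditions (1)-(2) to tandem-repeat records and key survivors
    by motif family.  Flagged (non-ACGT-consensus) records are dropped."""
    blocks = []
    for rec in records:
        if rec.flagged:
            continue
        if not (config.srs_min_len <= rec.period_size <= config.srs_max_len):
            continue
        if not rec.percent_matches > config.srs_min_match:
            continue
        blocks.append(
            SRSBlock(
                seq_id=rec.seq_id,
                start=rec.start,
                end=rec.end,
                family=canonical_motif(rec.consensus, config.merge_strands),
                observed_motif=rec.consensus,
                copy_count=int(np.floor(rec.copy_number + 0.5)),
                percent_matches=rec.percent_matches,
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# stage 2: blocks -> chains

def merge_adjacent_blocks(blocks: List[SRSBlock], config: ScanConfig) -> List[SRSBlock]:
    """Fuse same-family blocks within ``merge_max_gap`` bp of each other:
    detector fragmentation (a substitution splitting one junction run, or
    overlapping records at different phases) must not split one junction
    into two.  The window is a few base pairs on purpose — an unrelated
    same-family run further away is a separate structure, and absorbing
    it would corrupt the junction's copy count.  Merged copy counts are
    recomputed from the fused span."""
    if not blocks:
        return []
    blocks = sorted(blocks, key=lambda b: b.start)
    merged = [replace(blocks[0])]
    for b in blocks[1:]:
        prev = merged[-1]
        if b.start - prev.end <= config.merge_max_gap:
            prev.end = max(prev.end, b.end)
            prev.copy_count = int(np.floor((prev.end - prev.start) / len(prev.observed_motif) + 0.5))
            prev.percent_matches = min(prev.percent_matches, b.percent_matches)
        else:
            merged.append(replace(b))
    return merged


def chain_blocks(blocks: List[SRSBlock], config: ScanConfig) -> List[List[SRSBlock]]:
    """Emit maximal runs of consecutive same-family blocks whose inter-block
    gaps all lie in [unit_min_len, unit_max_len]; a gap outside the range
    splits the chain.  Chains with fewer than ``min_units`` gaps are dropped.
    """
    chains: List[List[SRSBlock]] = []
    cur: List[SRSBlock] = []
    for b in sorted(blocks, key=lambda x: x.start):
        if not cur:
            cur = [b]
            continue
        gap = b.start - cur[-1].end
        if config.unit_min_len <= gap <= config.unit_max_len:
            cur.append(b)
        else:
            chains.append(cur)
            cur = [b]
    if cur:
        chains.append(cur)
    return [c for c in chains if len(c) - 1 >= config.min_units]


# ---------------------------------------------------------------------------
# pairwise identity

def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of the edit-distance-optimal global alignment of
    ``a`` and ``b``: matching columns / alignment columns x 100."""
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    total = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            k = int(num)
            num = ""
            total += k
            if ch == "=":
                matches += k
    return 100.0 * matches / total


def _identity_at_least(a: str, b: str, threshold: float) -> Optional[float]:
    """``pairwise_identity(a, b)`` when it can reach ``threshold``, else None.

    Identity = 1 - distance/columns with unit costs, and columns <= |a|+|b|,
    so a bounded-distance alignment (cheap for dissimilar pairs) rules out
    most failing pairs without a full traceback.
    """
    k = int((1.0 - threshold / 100.0) * (len(a) + len(b)))
    res = edlib.align(a, b, mode="NW", task="distance", k=k)
    if res["editDistance"] == -1:
        return None
    ident = pairwise_identity(a, b)
    return ident if ident >= threshold else None


def _family_motif_identity(a: str, b: str, merge_strands: bool) -> float:
    """Best identity of ``a`` against any rotation of ``b`` (and of its
    reverse complement when strands are merged)."""
    candidates = _rotations(b)
    if merge_strands:
        candidates += _rotations(reverse_complement(b))
    return max(pairwise_identity(a, c) for c in set(candidates))


# ---------------------------------------------------------------------------
# stage 3: chain -> locus

def _extract_units(chain: List[SRSBlock], seq: str) -> List[Unit]:
    return [
        Unit(seq_id=chain[0].seq_id, start=b1.end, end=b2.start, sequence=seq[b1.end : b2.start])
        for b1, b2 in zip(chain, chain[1:])
    ]


def _finish_locus(
    chain: List[SRSBlock],
    units: List[Unit],
    genome: Mapping[str, str],
    config: ScanConfig,
) -> Optional[HSRLocus]:
    """Condition (5) plus head/tail scoring for a fully screened chain."""
    copy_numbers = [b.copy_count for b in chain]
    if config.require_variable_copies and len(set(copy_numbers)) < 2:
        return None
    if config.all_pairs_identity:
        for i in range(len(units)):
            for j in range(i + 2, len(units)):
                if _identity_at_least(
                    units[i].sequence, units[j].sequence, config.unit_min_identity
                ) is None:
                    return None
    motif_len = len(chain[0].observed_motif)
    locus = HSRLocus(
        seq_id=chain[0].seq_id,
        start=chain[0].start,
        end=chain[-1].end,
        family=chain[0].family,
        srs_class="short" if motif_len <= config.srs_class_split else "long",
        blocks=chain,
        units=units,
        copy_numbers=copy_numbers,
        head_ratio=0.0,
        tail_ratio=0.0,
    )
    locus.head_ratio, locus.tail_ratio = head_tail_ratio(locus, genome, config)
    return locus


def validate_chain(
    chain: List[SRSBlock], genome: Mapping[str, str], config: ScanConfig
) -> Optional[HSRLocus]:
    """Apply conditions (2, cross-block), (4) and (5) to a candidate chain;
    return the accepted locus (with head/tail ratios) or ``None``."""
    seq_id = chain[0].seq_id
    if seq_id not in genome:
        raise KeyError(f"sequence {seq_id!r} not in genome store")
    seq = genome[seq_id]

    # condition 2, second reading: chained motifs agree within the family
    for b1, b2 in zip(chain, chain[1:]):
        if (
            _family_motif_identity(b1.observed_motif, b2.observed_motif, config.merge_strands)
            < config.srs_cross_match
        ):
            return None

    units = _extract_units(chain, seq)

    # condition 4
    for u_prev, u in zip(units, units[1:]):
        ident = _identity_at_least(u_prev.sequence, u.sequence, config.unit_min_identity)
        if ident is None:
            return None
        u.identity_to_prev = ident

    return _finish_locus(chain, units, genome, config)


def validate_chain_fragments(
    chain: List[SRSBlock], genome: Mapping[str, str], config: ScanConfig
) -> List[HSRLocus]:
    """Screen a chain, treating identity failures as locus boundaries.

    A failing adjacent-unit identity (or an inconsistent junction motif
    pair) does not reject the chain outright: it marks the end of one
    candidate array, since the sequence beyond it is no longer the same
    amplified unit.  The chain is split there — adjacent fragments share
    the junction block — and each fragment with at least ``min_units``
    units is screened on its own.  This keeps a genuine locus detectable
    when a stray same-family repeat lies within chaining distance.
    """
    seq_id = chain[0].seq_id
    if seq_id not in genome:
        raise KeyError(f"sequence {seq_id!r} not in genome store")
    seq = genome[seq_id]
    units = _extract_units(chain, seq)
    k = len(units)

    # a unit is usable only if its two flanking junction motifs agree
    usable = [
        _family_motif_identity(
            chain[i].observed_motif, chain[i + 1].observed_motif, config.merge_strands
        )
        >= config.srs_cross_match
        for i in range(k)
    ]
    ident: List[Optional[float]] = [None] * max(0, k - 1)
    for i in range(k - 1):
        if usable[i] and usable[i + 1]:
            ident[i] = _identity_at_least(
                units[i].sequence, units[i + 1].sequence, config.unit_min_identity
            )

    loci: List[HSRLocus] = []
    p = 0
    while p < k:
        if not usable[p]:
            p += 1
            continue
        q = p
        while q + 1 < k and usable[q + 1] and ident[q] is not None:
            q += 1
        if q - p + 1 >= config.min_units:
            frag_units = []
            for i in range(p, q + 1):
                u = replace(units[i])
                u.identity_to_prev = ident[i - 1] if i > p else None
                frag_units.append(u)
            locus = _finish_locus(chain[p : q + 2], frag_units, genome, config)
            if locus is not None:
                loci.append(locus)
        p = q + 1
    return loci


# ---------------------------------------------------------------------------
# head/tail statistic

def medoid_unit(locus: HSRLocus) -> str:
    """The unit with maximum mean identity to the others (ties: first)."""
    seqs = [u.sequence for u in locus.units]
    if any(s is None for s in seqs):
        raise ValueError("units lack sequences; re-extract from the genome")
    if len(seqs) == 1:
        return seqs[0]
    best_i, best_mean = 0, -1.0
    for i, s in enumerate(seqs):
        mean = float(
            np.mean([pairwise_identity(s, t) for j, t in enumerate(seqs) if j != i])
        )
        if mean > best_mean:
            best_i, best_mean = i, mean
    return seqs[best_i]


def _flank_unit_coverage(
    flank: str, consensus: str, config: ScanConfig, side: str
) -> float:
    """Fraction of ``consensus`` present in ``flank`` abutting the locus.

    ``side == "head"``: the flank's suffix is compared with the consensus
    suffix; ``"tail"``: prefix against prefix.  The breakpoint is the
    length k maximising a cumulative +1 match / -1 mismatch score (a
    no-indel alignment scan; random sequence drifts the score down, true
    unit sequence drifts it up).  A nonzero ratio requires the matched
    stretch to reach ``head_tail_min_anchor`` bp and the unit identity
    threshold; otherwise the end is scored 0 (SRS-terminal).
    """
    L = len(consensus)
    if L == 0 or not flank:
        return 0.0
    k_max = min(len(flank), L)
    if side == "head":
        f = flank[::-1][:k_max]
        c = consensus[::-1][:k_max]
    else:
        f = flank[:k_max]
        c = consensus[:k_max]
    fa = np.frombuffer(f.encode(), dtype=np.uint8)
    ca = np.frombuffer(c.encode(), dtype=np.uint8)
    match = (fa == ca).astype(np.int64)
    # +1/-3 scoring: climbs over true unit sequence even at a few percent
    # divergence, falls steeply (-2/bp expected) over 25 %-identity
    # background, so the argmax sits at the partial unit's breakpoint
    score = np.cumsum(4 * match - 3)
    k = int(np.argmax(score)) + 1
    if score[k - 1] <= 0:
        return 0.0
    if k < config.head_tail_min_anchor:
        return 0.0
    identity = 100.0 * match[:k].sum() / k
    if identity < config.unit_min_identity:
        return 0.0
    return min(1.0, k / L)


def head_tail_ratio(
    locus: HSRLocus, genome: Mapping[str, str], config: ScanConfig
) -> Tuple[float, float]:
    """Score each locus end by the fraction of one amplified unit present
    outside the outermost SRS block (0 = ends on SRS, 1 = full unit)."""
    seq = genome[locus.seq_id]
    consensus = medoid_unit(locus)
    w = config.window
    head_flank = seq[max(0, locus.start - w) : locus.start]
    tail_flank = seq[locus.end : locus.end + w]
    head = _flank_unit_coverage(head_flank, consensus, config, side="head")
    tail = _flank_unit_coverage(tail_flank, consensus, config, side="tail")
    return head, tail


# ---------------------------------------------------------------------------
# stage 4: overlap resolution and the full scan

def resolve_overlaps(loci: Sequence[HSRLocus]) -> List[HSRLocus]:
    """Greedy non-overlapping selection: more units, then longer span,
    then smaller start.  Deterministic for a fixed input set."""
    ranked = sorted(loci, key=lambda l: (-l.n_units, -l.span, l.start, l.seq_id))
    kept: List[HSRLocus] = []
    by_seq: Dict[str, List[Tuple[int, int]]] = {}
    for loc in ranked:
        ivs = by_seq.setdefault(loc.seq_id, [])
        if any(loc.start < e and s < loc.end for s, e in ivs):
            continue
        ivs.append((loc.start, loc.end))
        kept.append(loc)
    return sorted(kept, key=lambda l: (l.seq_id, l.start))


def scan_genome(
    genome: Mapping[str, str],
    records: Optional[Iterable[TandemRepeatRecord]] = None,
    config: Optional[ScanConfig] = None,
):
    """Run the full screen over a genome.

    ``genome`` maps sequence id to uppercase DNA.  When ``records`` is
    None the built-in finder supplies the tandem-repeat matrix.  Returns
    ``(loci, report)`` where the report is a
    :class:`~hsrscan.stats.ScanReport`.
    """
    from .stats import ScanReport

    config = config or ScanConfig()
    config.validate()

    if records is None:
        records = []
        for seq_id in genome:
            records.extend(
                find_tandem_repeats(
                    genome[seq_id],
                    weights=config.finder_weights,
                    min_period=1,
                    max_period=config.srs_max_len,
                    min_score=config.finder_min_score,
                    seq_id=seq_id,
                )
            )

    blocks = build_blocks(records, config)
    grouped: Dict[Tuple[str, str], List[SRSBlock]] = {}
    for b in blocks:
        grouped.setdefault((b.seq_id, b.family.canonical), []).append(b)

    candidates: List[HSRLocus] = []
    for (_seq_id, _fam), group in sorted(grouped.items()):
        merged = merge_adjacent_blocks(group, config)
        for chain in chain_blocks(merged, config):
            candidates.extend(validate_chain_fragments(chain, genome, config))

    loci = resolve_overlaps(candidates)
    for loc in loci:
        loc.check_invariants(config)
    report = ScanReport.from_scan(loci, genome)
    return loci, report
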