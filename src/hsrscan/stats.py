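"""Genome-level summaries of detected amplification loci.

Covers the descriptive panels a screen of many genomes reports: locus
counts per SRS length class, genome density (Mb per locus), GC of SRS
versus host genome, recombination-motif presence (the TG/AC dinucleotide
family and friends), the pooled head/tail ratio histogram, and structural
comparison of matched loci across genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detect import HSRLocus, _identity_at_least, medoid_unit, pairwise_identity
from .repeat_finder import canonical_motif

DEFAULT_RECOMBINATION_MOTIFS: Tuple[str, ...] = ("AC", "CA", "TG", "GT")


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T) of ``seq``, ignoring N."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("GC content undefined: no A/C/G/T bases")
    return (counts["G"] + counts["C"]) / total


def genome_density(n_loci: int, genome_length: int) -> float:
    """Mb of genome per detected locus."""
    if n_loci < 1:
        raise ValueError("density undefined for zero loci")
    return genome_length / 1e6 / n_loci


def motif_presence(
    loci: Sequence[HSRLocus],
    motifs: Sequence[str] = DEFAULT_RECOMBINATION_MOTIFS,
    count_occurrences: bool = False,
) -> Dict[str, int]:
    """Count loci whose SRS motif contains a member of each motif family.

    Motifs are grouped into complement/rotation families (TG, GT, AC and
    CA form the single "AC" family); a locus counts once per family.  With
    ``count_occurrences`` the number of substring occurrences is summed
    instead of presence/absence.
    """
    families: Dict[str, List[str]] = {}
    for m in motifs:
        fam = canonical_motif(m, merge_strands=True).canonical
        families.setdefault(fam, [])
        if m not in families[fam]:
            families[fam].append(m)
    counts = {fam: 0 for fam in families}
    for loc in loci:
        motif = loc.blocks[0].observed_motif if loc.blocks else loc.family.canonical
        for fam, members in families.items():
            if count_occurrences:
                counts[fam] += sum(motif.count(m) for m in members)
            elif any(m in motif for m in members):
                counts[fam] += 1
    return counts


RATIO_BIN_LABELS: Tuple[str, ...] = ("0",) + tuple(
    f"({i / 10:.1f},{(i + 1) / 10:.1f})" for i in range(10)
) + ("1",)


def ratio_histogram(loci: Sequence[HSRLocus], n_bins: int = 10) -> "pd.Series":
    """Pooled head+tail ratio histogram: an exact-0 bin, ``n_bins`` equal
    bins over (0,1), and an exact-1 bin.  Counts sum to 2 x len(loci)."""
    labels = ["0"] + [
        f"({i / n_bins:.1f},{(i + 1) / n_bins:.1f})" for i in range(n_bins)
    ] + ["1"]
    counts = dict.fromkeys(labels, 0)
    for loc in loci:
        for r in (loc.head_ratio, loc.tail_ratio):
            if r == 0.0:
                counts["0"] += 1
            elif r == 1.0:
                counts["1"] += 1
            else:
                idx = min(int(r * n_bins), n_bins - 1)
                counts[labels[1 + idx]] += 1
    return pd.Series(counts, name="count")


@dataclass
class ScanReport:
    """Per-genome summary of a scan."""

    n_loci_short: int
    n_loci_long: int
    genome_length: int
    mb_per_locus: Optional[float]
    median_srs_len: Optional[float]
    median_unit_count: Optional[float]
    median_unit_len: Optional[float]
    gc_genome: float
    gc_srs: Optional[float]
    motif_counts: Dict[str, int] = field(default_factory=dict)
    ratio_histogram: Optional[pd.Series] = None

    @classmethod
    def from_scan(cls, loci: Sequence[HSRLocus], genome: Mapping[str, str]) -> "ScanReport":
        genome_length = sum(len(s) for s in genome.values())
        n_short = sum(1 for l in loci if l.srs_class == "short")
        n_long = sum(1 for l in loci if l.srs_class == "long")
        n_total = len(loci)
        srs_seq = "".join(
            genome[l.seq_id][b.start : b.end] for l in loci for b in l.blocks
        )
        all_seq = "".join(genome.values())
        return cls(
            n_loci_short=n_short,
            n_loci_long=n_long,
            genome_length=genome_length,
            mb_per_locus=genome_density(n_total, genome_length) if n_total else None,
            median_srs_len=(
                float(np.median([len(l.blocks[0].observed_motif) for l in loci]))
                if loci else None
            ),
            median_unit_count=float(np.median([l.n_units for l in loci])) if loci else None,
            median_unit_len=(
                float(np.median([u.length for l in loci for u in l.units])) if loci else None
            ),
            gc_genome=gc_content(all_seq),
            gc_srs=gc_content(srs_seq) if srs_seq else None,
            motif_counts=motif_presence(loci),
            ratio_histogram=ratio_histogram(loci),
        )

    def to_row(self, genome_name: str = "genome") -> Dict[str, object]:
        row: Dict[str, object] = {
            "genome": genome_name,
            "n_loci_short": self.n_loci_short,
            "n_loci_long": self.n_loci_long,
            "genome_length": self.genome_length,
            "mb_per_locus": "NA" if self.mb_per_locus is None else f"{self.mb_per_locus:.4f}",
            "median_srs_len": "NA" if self.median_srs_len is None else self.median_srs_len,
            "median_unit_count": "NA" if self.median_unit_count is None else self.median_unit_count,
            "median_unit_len": "NA" if self.median_unit_len is None else self.median_unit_len,
            "gc_genome": f"{self.gc_genome:.4f}",
            "gc_srs": "NA" if self.gc_srs is None else f"{self.gc_srs:.4f}",
        }
        for fam, c in sorted(self.motif_counts.items()):
            row[f"motif_{fam}"] = c
        return row


def write_report_tsv(
    reports: Mapping[str, ScanReport], path: str
) -> None:
    """One TSV row per genome."""
    rows = [rep.to_row(name) for name, rep in reports.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def compare_across_genomes(
    loci_sets: Mapping[str, Tuple[Sequence[HSRLocus], Mapping[str, str]]],
    min_identity: float = 90.0,
    flank_window: int = 30000,
) -> pd.DataFrame:
    """Match loci across genomes and tabulate their structural dynamics.

    ``loci_sets`` maps genome name to ``(loci, genome sequences)``; unit
    sequences are re-extracted when absent.  Two loci from different
    genomes match when they share an SRS family and their medoid units
    align at >= ``min_identity`` percent.  Matched groups (connected
    components) are reported one row per member locus with per-genome unit
    counts, copy-number vectors and span lengths; unmatched loci follow
    with an empty group id.
    """
    if len(loci_sets) < 2:
        raise ValueError("compare_across_genomes needs at least two genomes")

    entries = []  # (genome, locus, medoid sequence)
    for name, (loci, genome) in loci_sets.items():
        for loc in loci:
            for u in loc.units:
                if u.sequence is None:
                    u.sequence = genome[loc.seq_id][u.start : u.end]
            entries.append((name, loc, medoid_unit(loc)))

    n = len(entries)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            gi, li, mi = entries[i]
            gj, lj, mj = entries[j]
            if gi == gj:
                continue
            if li.family.canonical != lj.family.canonical:
                continue
            if _identity_at_least(mi, mj, min_identity) is not None:
                union(i, j)

    comp: Dict[int, List[int]] = {}
    for i in range(n):
        comp.setdefault(find(i), []).append(i)
    groups = sorted(
        (sorted(members) for members in comp.values()), key=lambda g: g[0]
    )

    rows = []
    gid = 0
    for members in groups:
        genomes_in = {entries[i][0] for i in members}
        matched = len(genomes_in) >= 2
        label = ""
        if matched:
            gid += 1
            label = f"group{gid}"
        for i in members:
            name, loc, _ = entries[i]
            rows.append(
                {
                    "group": label if matched else "",
                    "matched": matched,
                    "genome": name,
                    "seq_id": loc.seq_id,
                    "start": loc.start,
                    "end": loc.end,
                    "srs_family": loc.family.canonical,
                    "n_units": loc.n_units,
                    "copy_numbers": ",".join(str(c) for c in loc.copy_numbers),
                    "span": loc.span,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "group", "matched", "genome", "seq_id", "start", "end",
            "srs_family", "n_units", "copy_numbers", "span",
        ],
    )
    return df.sort_values(
        ["matched", "group", "genome", "seq_id", "start"],
        ascending=[False, True, True, True, True],
    ).reset_index(drop=True)
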