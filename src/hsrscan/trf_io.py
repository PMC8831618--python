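"""Reading Tandem Repeats Finder ``.dat`` output and writing locus reports.

Tandem Repeats Finder (TRF) writes one ``.dat`` record per detected tandem
repeat: 15 whitespace-separated fields in 1-based inclusive coordinates,
grouped under ``Sequence:`` headers.  This module parses that dialect into
:class:`TandemRepeatRecord` (0-based half-open internally) and serialises
detected amplification loci as BED6, GFF3 and a TSV report.

Coordinate conventions: everything in memory is 0-based half-open; TRF and
GFF3 are 1-based inclusive and are converted exactly at the file boundary,
BED is already 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, List, Optional, Sequence, Tuple

if TYPE_CHECKING:  # pragma: no cover
    from .detect import HSRLocus

_DNA = set("ACGTN")

#: number of whitespace-separated fields on a TRF ``.dat`` data line
N_DAT_FIELDS = 15


class TRFFormatError(ValueError):
    """Raised when a ``.dat`` file violates the TRF data-line dialect."""


@dataclass
class TandemRepeatRecord:
    """One tandem-repeat annotation, the scanner's atomic input.

    Attributes mirror the TRF record matrix (interval, period, fractional
    copy number, percent matches/indels, alignment score, consensus motif).
    ``flagged`` marks records whose consensus contains characters outside
    {A,C,G,T}; they are kept on read but skipped by downstream screening.
    """

    seq_id: str
    start: int            # 0-based inclusive
    end: int              # 0-based exclusive
    period_size: int
    copy_number: float
    consensus_size: int
    percent_matches: float
    percent_indels: float
    score: float
    consensus: str
    region_seq: Optional[str] = None
    flagged: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start},{self.end})")
        if self.period_size < 1:
            raise ValueError("period_size must be >= 1")
        if self.copy_number <= 0:
            raise ValueError("copy_number must be > 0")
        if not (0 <= self.percent_matches <= 100):
            raise ValueError("percent_matches out of [0,100]")
        if not (0 <= self.percent_indels <= 100):
            raise ValueError("percent_indels out of [0,100]")
        if not self.consensus:
            raise ValueError("empty consensus")
        self.consensus = self.consensus.upper()
        if not set(self.consensus) <= _DNA:
            self.flagged = True
        elif "N" in self.consensus:
            self.flagged = True

    @property
    def length(self) -> int:
        return self.end - self.start


def read_trf_dat(path: str | os.PathLike) -> List[TandemRepeatRecord]:
    """Parse a TRF ``.dat`` file into records, input order preserved.

    Data lines are attributed to the most recent ``Sequence:`` header.
    ``Parameters:`` lines, blank lines and TRF preamble text are tolerated
    and skipped.  Malformed data lines raise :class:`TRFFormatError` naming
    the offending line number.
    """
    records: List[TandemRepeatRecord] = []
    seq_id: Optional[str] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                seq_id = line.split(":", 1)[1].strip().split()[0]
                continue
            if not line[0].isdigit():
                # "Parameters:" line or TRF preamble — skipped
                continue
            fields = line.split()
            if len(fields) != N_DAT_FIELDS:
                raise TRFFormatError(
                    f"{path}:{lineno}: expected {N_DAT_FIELDS} fields, got {len(fields)}"
                )
            if seq_id is None:
                raise TRFFormatError(
                    f"{path}:{lineno}: data line before any 'Sequence:' header"
                )
            try:
                start_1 = int(fields[0])
                end_1 = int(fields[1])
                period = int(fields[2])
                copies = float(fields[3])
                cons_size = int(fields[4])
                pct_match = float(fields[5])
                pct_indel = float(fields[6])
                score = float(fields[7])
            except ValueError as exc:
                raise TRFFormatError(
                    f"{path}:{lineno}: non-numeric numeric field ({exc})"
                ) from None
            records.append(
                TandemRepeatRecord(
                    seq_id=seq_id,
                    start=start_1 - 1,  # TRF is 1-based inclusive
                    end=end_1,
                    period_size=period,
                    copy_number=copies,
                    consensus_size=cons_size,
                    percent_matches=pct_match,
                    percent_indels=pct_indel,
                    score=score,
                    consensus=fields[13],
                    region_seq=fields[14],
                )
            )
    return records


def write_trf_dat(records: Iterable[TandemRepeatRecord], path: str | os.PathLike) -> None:
    """Write records in the TRF ``.dat`` dialect accepted by :func:`read_trf_dat`.

    Composition percentages and entropy are recomputed from the region
    sequence when available, else written as zeros (pass-through fields).
    """
    import math

    by_seq: dict = {}
    for rec in records:
        by_seq.setdefault(rec.seq_id, []).append(rec)
    with open(path, "w") as fh:
        for seq_id, recs in by_seq.items():
            fh.write(f"Sequence: {seq_id}\n")
            for r in recs:
                region = r.region_seq or ""
                comp = []
                for base in "ACGT":
                    comp.append(
                        round(100.0 * region.count(base) / len(region)) if region else 0
                    )
                if region:
                    ent = -sum(
                        (c / 100.0) * math.log2(c / 100.0) for c in comp if c > 0
                    )
                else:
                    ent = 0.0
                fh.write(
                    f"{r.start + 1} {r.end} {r.period_size} "
                    f"{r.copy_number:.1f} {r.consensus_size} "
                    f"{r.percent_matches:.0f} {r.percent_indels:.0f} "
                    f"{r.score:.0f} {comp[0]} {comp[1]} {comp[2]} {comp[3]} "
                    f"{ent:.2f} {r.consensus} {region or r.consensus}\n"
                )


# ---------------------------------------------------------------------------
# locus writers

_TSV_COLUMNS = (
    "seq_id\tstart\tend\tsrs_motif\tsrs_class\tn_units\tcopy_numbers\t"
    "min_adjacent_unit_identity\thead_ratio\ttail_ratio\n"
)


def _fmt_ratio(x: float) -> str:
    return f"{x:.4f}"


def write_loci(loci: Sequence["HSRLocus"], prefix: str | os.PathLike) -> Tuple[str, str, str]:
    """Write loci as ``<prefix>.bed`` (BED6), ``<prefix>.gff3`` and ``<prefix>.tsv``.

    BED score carries the unit count; the GFF3 parent feature has type
    ``tandem_amplification_locus`` with ``srs_block`` / ``amplified_unit``
    children.  Returns the three paths written.
    """
    prefix = os.fspath(prefix)
    bed_path, gff_path, tsv_path = f"{prefix}.bed", f"{prefix}.gff3", f"{prefix}.tsv"

    with open(bed_path, "w") as bed:
        for loc in loci:
            bed.write(
                f"{loc.seq_id}\t{loc.start}\t{loc.end}\t{loc.family.canonical}\t"
                f"{len(loc.units)}\t.\n"
            )

    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for i, loc in enumerate(loci, start=1):
            lid = f"hsr{i:05d}"
            copies = ",".join(str(c) for c in loc.copy_numbers)
            attrs = (
                f"ID={lid};srs_motif={loc.family.canonical};srs_class={loc.srs_class};"
                f"n_units={len(loc.units)};copy_numbers={copies};"
                f"head_ratio={_fmt_ratio(loc.head_ratio)};"
                f"tail_ratio={_fmt_ratio(loc.tail_ratio)}"
            )
            gff.write(
                f"{loc.seq_id}\thsrscan\ttandem_amplification_locus\t"
                f"{loc.start + 1}\t{loc.end}\t{len(loc.units)}\t.\t.\t{attrs}\n"
            )
            for j, blk in enumerate(loc.blocks, start=1):
                gff.write(
                    f"{loc.seq_id}\thsrscan\tsrs_block\t{blk.start + 1}\t{blk.end}\t"
                    f".\t.\t.\tID={lid}.b{j};Parent={lid};copies={blk.copy_count};"
                    f"motif={blk.observed_motif}\n"
                )
            for j, unit in enumerate(loc.units, start=1):
                ident = (
                    ""
                    if unit.identity_to_prev is None
                    else f";identity_to_prev={unit.identity_to_prev:.2f}"
                )
                gff.write(
                    f"{loc.seq_id}\thsrscan\tamplified_unit\t{unit.start + 1}\t"
                    f"{unit.end}\t.\t.\t.\tID={lid}.u{j};Parent={lid}{ident}\n"
                )

    with open(tsv_path, "w") as tsv:
        tsv.write(_TSV_COLUMNS)
        for loc in loci:
            idents = [u.identity_to_prev for u in loc.units if u.identity_to_prev is not None]
            min_ident = f"{min(idents):.2f}" if idents else "NA"
            tsv.write(
                f"{loc.seq_id}\t{loc.start}\t{loc.end}\t{loc.family.canonical}\t"
                f"{loc.srs_class}\t{len(loc.units)}\t"
                f"{','.join(str(c) for c in loc.copy_numbers)}\t{min_ident}\t"
                f"{_fmt_ratio(loc.head_ratio)}\t{_fmt_ratio(loc.tail_ratio)}\n"
            )
    return bed_path, gff_path, tsv_path


def _parse_gff_attrs(col: str) -> dict:
    out = {}
    for part in col.rstrip(";").split(";"):
        if part:
            k, _, v = part.partition("=")
            out[k] = v
    return out


def read_loci_gff3(path: str | os.PathLike) -> List["HSRLocus"]:
    """Rebuild :class:`~hsrscan.detect.HSRLocus` objects from a GFF3 written
    by :func:`write_loci`.

    Unit sequences are not stored in GFF3 and come back as ``None``;
    intervals, copy numbers, motifs, classes and ratios round-trip exactly.
    """
    from .detect import HSRLocus, SRSBlock, Unit
    from .repeat_finder import MotifFamilyKey

    parents: dict = {}
    order: List[str] = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            seq_id, _src, ftype, start_1, end_1 = cols[0], cols[1], cols[2], cols[3], cols[4]
            start, end = int(start_1) - 1, int(end_1)
            attrs = _parse_gff_attrs(cols[8])
            if ftype == "tandem_amplification_locus":
                lid = attrs["ID"]
                order.append(lid)
                parents[lid] = {
                    "seq_id": seq_id,
                    "start": start,
                    "end": end,
                    "motif": attrs["srs_motif"],
                    "srs_class": attrs["srs_class"],
                    "copy_numbers": [int(c) for c in attrs["copy_numbers"].split(",")],
                    "head_ratio": float(attrs["head_ratio"]),
                    "tail_ratio": float(attrs["tail_ratio"]),
                    "blocks": [],
                    "units": [],
                }
            elif ftype == "srs_block":
                p = parents[attrs["Parent"]]
                p["blocks"].append(
                    SRSBlock(
                        seq_id=seq_id,
                        start=start,
                        end=end,
                        family=MotifFamilyKey(canonical=attrs.get("motif", ""), strand_merged=False),
                        observed_motif=attrs.get("motif", ""),
                        copy_count=int(attrs["copies"]),
                        percent_matches=100.0,
                    )
                )
            elif ftype == "amplified_unit":
                p = parents[attrs["Parent"]]
                ident = attrs.get("identity_to_prev")
                p["units"].append(
                    Unit(
                        seq_id=seq_id,
                        start=start,
                        end=end,
                        sequence=None,
                        identity_to_prev=None if ident is None else float(ident),
                    )
                )

    loci = []
    for lid in order:
        p = parents[lid]
        fam = MotifFamilyKey(canonical=p["motif"], strand_merged=False)
        for blk in p["blocks"]:
            blk.family = fam
        loci.append(
            HSRLocus(
                seq_id=p["seq_id"],
                start=p["start"],
                end=p["end"],
                family=fam,
                srs_class=p["srs_class"],
                blocks=p["blocks"],
                units=p["units"],
                copy_numbers=p["copy_numbers"],
                head_ratio=p["head_ratio"],
                tail_ratio=p["tail_ratio"],
            )
        )
    return loci
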