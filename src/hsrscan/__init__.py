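"""hsrscan: screen genomes for SRS-junction tandem-amplification loci.

Detects "high-speed rail" structures — amplified units linked head-to-tail
by tandem runs of a short repeated sequence (SRS) whose copy numbers vary
between junctions — and ships a planted-locus simulator for benchmarking.
"""

from .detect import (
    HSRLocus,
    ScanConfig,
    SRSBlock,
    Unit,
    build_blocks,
    chain_blocks,
    head_tail_ratio,
    medoid_unit,
    pairwise_identity,
    resolve_overlaps,
    scan_genome,
    validate_chain,
    validate_chain_fragments,
)
from .repeat_finder import (
    AlignWeights,
    MotifFamilyKey,
    canonical_motif,
    find_tandem_repeats,
    wraparound_align,
)
from .stats import (
    ScanReport,
    compare_across_genomes,
    gc_content,
    genome_density,
    motif_presence,
    ratio_histogram,
)
from .stats import write_report_tsv
from .synth import (
    Confounder,
    DetectionMetrics,
    PlantedLocus,
    SimSpec,
    TruthRecord,
    evaluate_detection,
    generate,
    load_simspec,
    mutate,
    random_spec,
    read_truth_gff3,
    save_simspec,
    simulate_genome,
    truth_from_loci,
    write_truth_gff3,
)
from .trf_io import TandemRepeatRecord, read_loci_gff3, read_trf_dat, write_loci

__version__ = "0.1.0"


def load_fasta(path) -> dict:
    """Read a FASTA file into ``{seq_id: uppercase sequence}``."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


__all__ = [
    "AlignWeights",
    "Confounder",
    "DetectionMetrics",
    "HSRLocus",
    "MotifFamilyKey",
    "PlantedLocus",
    "ScanConfig",
    "ScanReport",
    "SimSpec",
    "SRSBlock",
    "TandemRepeatRecord",
    "TruthRecord",
    "Unit",
    "build_blocks",
    "canonical_motif",
    "chain_blocks",
    "compare_across_genomes",
    "evaluate_detection",
    "find_tandem_repeats",
    "gc_content",
    "generate",
    "genome_density",
    "head_tail_ratio",
    "load_fasta",
    "load_simspec",
    "medoid_unit",
    "motif_presence",
    "mutate",
    "pairwise_identity",
    "random_spec",
    "ratio_histogram",
    "read_loci_gff3",
    "read_trf_dat",
    "read_truth_gff3",
    "resolve_overlaps",
    "save_simspec",
    "scan_genome",
    "simulate_genome",
    "truth_from_loci",
    "validate_chain",
    "validate_chain_fragments",
    "wraparound_align",
    "write_loci",
    "write_report_tsv",
    "write_truth_gff3",
]
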