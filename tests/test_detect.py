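"""The five screening conditions, head/tail statistic and overlap rules."""

import numpy as np
import pytest

from hsrscan.detect import (
    ScanConfig,
    build_blocks,
    chain_blocks,
    head_tail_ratio,
    merge_adjacent_blocks,
    pairwise_identity,
    resolve_overlaps,
    scan_genome,
    validate_chain,
)
from hsrscan.synth import Confounder, PlantedLocus, SimSpec, generate, random_dna
from hsrscan.trf_io import TandemRepeatRecord
from conftest import make_locus
from oracles import oracle_edit_distance


def _record(period=4, pct=100.0, consensus="CCTT", start=0, copies=3.0, seq_id="chr1"):
    return TandemRepeatRecord(
        seq_id=seq_id,
        start=start,
        end=start + int(period * copies),
        period_size=period,
        copy_number=copies,
        consensus_size=period,
        percent_matches=pct,
        percent_indels=0.0,
        score=2 * period * copies,
        consensus=consensus,
    )


class TestBuildBlocks:
    def test_admits_valid_record_with_family(self, config):
        (blk,) = build_blocks([_record()], config)
        assert blk.family.canonical == canonical("CCTT")
        assert blk.copy_count == 3

    def test_condition1_srs_length_bounds(self, config):
        long_rec = _record(period=250, consensus="ACGTACGTAG" * 25, copies=2.0)
        assert build_blocks([long_rec], config) == []
        assert build_blocks([_record(period=1, consensus="A", copies=12.0)], config) == []

    def test_condition2_match_strictly_above_threshold(self, config):
        assert build_blocks([_record(pct=65.0)], config) == []
        assert build_blocks([_record(pct=70.0)], config) == []  # "larger than 70%"
        assert len(build_blocks([_record(pct=70.1)], config)) == 1

    def test_flagged_records_dropped(self, config):
        rec = _record(consensus="CCNT")
        assert rec.flagged
        assert build_blocks([rec], config) == []

    def test_copy_count_rounding(self, config):
        (blk,) = build_blocks([_record(copies=3.5)], config)
        assert blk.copy_count == 4


def canonical(m):
    from hsrscan.repeat_finder import canonical_motif

    return canonical_motif(m).canonical


def _blocks_at(starts, block_len=12, motif="CCTT", seq_id="chr1", copies=3):
    from hsrscan.detect import SRSBlock
    from hsrscan.repeat_finder import canonical_motif

    fam = canonical_motif(motif)
    return [
        SRSBlock(seq_id=seq_id, start=s, end=s + block_len, family=fam,
                 observed_motif=motif, copy_count=c, percent_matches=100.0)
        for s, c in zip(starts, copies if isinstance(copies, list) else [copies] * len(starts))
    ]


class TestChainBlocks:
    def test_uniform_gaps_one_chain(self, config):
        blocks = _blocks_at([0, 212, 424, 636])  # gaps of 200
        (chain,) = chain_blocks(blocks, config)
        assert len(chain) == 4

    def test_short_gap_splits_and_drops(self, config):
        blocks = _blocks_at([0, 212, 264, 476])  # gaps 200, 40, 200
        assert chain_blocks(blocks, config) == []

    def test_oversized_gap_splits(self, config):
        blocks = _blocks_at([0, 212, 31224, 31436])  # middle gap 31000
        assert chain_blocks(blocks, config) == []
        config.min_units = 1
        chains = chain_blocks(blocks, config)
        assert [len(c) for c in chains] == [2, 2]

    def test_fragmented_same_family_blocks_merge(self, config):
        # two detector fragments 4 bp apart fuse into one junction block;
        # the merged copy count comes from the fused span
        blocks = _blocks_at([0, 16, 228], copies=[3, 3, 4])
        merged = merge_adjacent_blocks(blocks, config)
        assert len(merged) == 2
        assert (merged[0].start, merged[0].end) == (0, 28)
        assert merged[0].copy_count == 7  # 28 bp / 4 bp motif

    def test_distant_same_family_run_not_absorbed(self, config):
        # an unrelated same-family run 20 bp away stays a separate block
        blocks = _blocks_at([0, 32], copies=[3, 2])
        assert len(merge_adjacent_blocks(blocks, config)) == 2


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("A" * 100, "A" * 100) == 100.0

    def test_five_substitutions_in_hundred(self, rng):
        a = random_dna(100, 0.5, rng)
        b = list(a)
        for i in (3, 20, 50, 77, 99):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        assert pairwise_identity(a, "".join(b)) == 95.0

    def test_one_matching_column(self):
        assert pairwise_identity("ACGT", "TTTT") == 25.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_consistent_with_edit_distance_oracle(self, rng):
        """matches = alignment columns - optimal edit distance, against an
        independent textbook DP."""
        for _ in range(25):
            la, lb = rng.integers(1, 40, size=2)
            a = random_dna(int(la), 0.5, rng)
            b = random_dna(int(lb), 0.5, rng)
            import edlib

            res = edlib.align(a, b, mode="NW", task="path")
            cols = matches = 0
            num = ""
            for ch in res["cigar"]:
                if ch.isdigit():
                    num += ch
                else:
                    cols += int(num)
                    if ch == "=":
                        matches += int(num)
                    num = ""
            assert cols - matches >= res["editDistance"]
            assert res["editDistance"] == oracle_edit_distance(a, b)
            assert pairwise_identity(a, b) == pytest.approx(100 * matches / cols)


def _planted_genome(copy_counts, unit_length=200, motif="CCTT", seed=11, rate=0.0,
                    confounder=False, **locus_kw):
    loci, confs = [], []
    if len(set(copy_counts)) >= 2:
        loci = [PlantedLocus(srs_motif=motif, copy_counts=list(copy_counts),
                             unit_length=unit_length, n_units=len(copy_counts) - 1,
                             substitution_rate=rate, **locus_kw)]
    else:
        confs = [Confounder(kind="uniform", srs_motif=motif, copy_count=copy_counts[0],
                            unit_length=unit_length, n_units=len(copy_counts) - 1)]
    if confounder:
        confs.append(Confounder(kind="uniform", srs_motif="GGAAT", copy_count=4,
                                unit_length=180, n_units=3))
    spec = SimSpec(genome_length=max(20000, (len(copy_counts) * (unit_length + 400)) + 5000),
                   seed=seed, loci=loci, confounders=confs)
    return generate(spec)


class TestValidateChain:
    def test_variable_copies_accepted(self, config):
        genome, truth = _planted_genome([3, 5, 2, 4])
        loci, _ = scan_genome(genome)
        assert len(loci) == 1
        assert loci[0].copy_numbers == [3, 5, 2, 4]

    def test_condition5_uniform_copies_rejected(self, config):
        genome, truth = _planted_genome([3, 3, 3, 3])
        loci, _ = scan_genome(genome)
        assert loci == []

    def test_condition4_low_identity_rejected(self, config, rng):
        # hand-built chain whose middle unit is unrelated sequence
        motif, c = "CCTTG", [3, 5, 2, 4]
        units = [random_dna(200, 0.5, rng) for _ in range(2)]
        parts, pos = [], 0
        seq = (motif * c[0] + units[0] + motif * c[1] + units[1] + motif * c[2]
               + random_dna(200, 0.5, rng) + motif * c[3])
        genome = {"chr1": "T" * 100 + seq + "T" * 100}
        blocks, start = [], 100
        from hsrscan.detect import SRSBlock
        from hsrscan.repeat_finder import canonical_motif

        for i, copies in enumerate(c):
            end = start + len(motif) * copies
            blocks.append(SRSBlock(seq_id="chr1", start=start, end=end,
                                   family=canonical_motif(motif), observed_motif=motif,
                                   copy_count=copies, percent_matches=100.0))
            if i < 3:
                start = end + 200
        assert validate_chain(blocks, genome, config) is None

    def test_alternation_and_tiling_invariants(self, config):
        genome, _ = _planted_genome([2, 4, 3, 5, 2])
        loci, _ = scan_genome(genome)
        for loc in loci:
            loc.check_invariants(config)  # |blocks| = |units| + 1 and tiling


class TestHeadTailRatio:
    def test_srs_terminal_locus_scores_exactly_zero(self, config):
        genome, _ = _planted_genome([3, 5, 2, 4], seed=5)
        loci, _ = scan_genome(genome)
        assert (loci[0].head_ratio, loci[0].tail_ratio) == (0.0, 0.0)

    def test_full_extra_unit_scores_one(self, config):
        genome, _ = _planted_genome([3, 5, 2, 4], unit_length=400, seed=6,
                                    head_fraction=1.0, tail_fraction=1.0)
        loci, _ = scan_genome(genome)
        assert (loci[0].head_ratio, loci[0].tail_ratio) == (1.0, 1.0)

    def test_half_unit_recovered_within_tolerance(self, config):
        genome, _ = _planted_genome([3, 5, 2, 4], unit_length=400, seed=7,
                                    head_fraction=0.5)
        loci, _ = scan_genome(genome)
        assert loci[0].head_ratio == pytest.approx(0.5, abs=0.02)
        assert loci[0].tail_ratio == 0.0


class TestResolveOverlaps:
    def test_disjoint_kept(self):
        a = make_locus(start=100)
        b = make_locus(start=10000)
        assert len(resolve_overlaps([a, b])) == 2

    def test_nested_more_units_wins(self):
        big = make_locus(start=100, copy_numbers=(3, 5, 2, 4, 3, 5))  # 5 units
        small = make_locus(start=300, copy_numbers=(3, 5, 2, 4))      # 3 units
        kept = resolve_overlaps([small, big])
        assert kept == [big]

    def test_unit_tie_longer_span_wins(self):
        short = make_locus(start=100, unit_length=100)
        long_ = make_locus(start=150, unit_length=400)
        kept = resolve_overlaps([short, long_])
        assert kept == [long_]


class TestScanGenome:
    def test_planted_locus_recovered_exactly(self):
        genome, truth = _planted_genome([3, 5, 2, 4], confounder=True)
        loci, report = scan_genome(genome)
        t = [t for t in truth if t.kind == "hsr"][0]
        assert len(loci) == 1
        loc = loci[0]
        assert (loc.start, loc.end) == (t.start, t.end)
        assert loc.family.canonical == t.family
        assert loc.n_units == 3

    def test_long_srs_class(self):
        # the 23 bp junction motif of the antifreeze-protein locus
        genome, truth = _planted_genome(
            [3, 5, 2, 4], motif="ATGTGGCCCGGACCGCCTCCAGG", unit_length=1000, seed=13
        )
        loci, _ = scan_genome(genome)
        assert len(loci) == 1
        assert loci[0].srs_class == "long"

    def test_uniform_copy_confounders_only_yields_nothing(self):
        spec = SimSpec(
            genome_length=30000, seed=21,
            confounders=[
                Confounder(kind="uniform", srs_motif="GATC", copy_count=3,
                           unit_length=200, n_units=3),
                Confounder(kind="uniform", srs_motif="CGAAT", copy_count=5,
                           unit_length=350, n_units=4),
            ],
        )
        genome, _ = generate(spec)
        loci, _ = scan_genome(genome)
        assert loci == []

    def test_trf_records_path_equivalent_to_internal_finder(self):
        from hsrscan.repeat_finder import find_tandem_repeats

        genome, _ = _planted_genome([3, 5, 2, 4], seed=17)
        cfg = ScanConfig()
        records = []
        for sid, seq in genome.items():
            records.extend(find_tandem_repeats(
                seq, min_period=1, max_period=cfg.srs_max_len,
                min_score=cfg.finder_min_score, seq_id=sid))
        via_records, _ = scan_genome(genome, records=records)
        direct, _ = scan_genome(genome)
        assert [(l.start, l.end) for l in via_records] == [(l.start, l.end) for l in direct]

    def test_raising_thresholds_never_adds_loci(self):
        genome, _ = _planted_genome([3, 5, 2, 4], rate=0.01, seed=19)
        base = len(scan_genome(genome)[0])
        for cfg in (
            ScanConfig(unit_min_identity=99.9),
            ScanConfig(min_units=4),
            ScanConfig(min_units=10),
        ):
            assert len(scan_genome(genome, config=cfg)[0]) <= base

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScanConfig(unit_min_identity=150).validate()
        with pytest.raises(ValueError):
            ScanConfig(unit_min_len=500, unit_max_len=100).validate()
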