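"""Simulator determinism, construction validity and the detection evaluator."""

import numpy as np
import pytest

from hsrscan.detect import scan_genome
from hsrscan.synth import (
    Confounder,
    PlantedLocus,
    SimSpec,
    SimSpecError,
    evaluate_detection,
    generate,
    load_simspec,
    mutate,
    random_spec,
    read_truth_gff3,
    save_simspec,
    simulate_genome,
    truth_from_loci,
)


def _one_locus_spec(seed=42, **kw):
    defaults = dict(srs_motif="CCTT", copy_counts=[3, 5, 2, 4],
                    unit_length=200, n_units=3)
    defaults.update(kw)
    return SimSpec(genome_length=20000, seed=seed, loci=[PlantedLocus(**defaults)])


class TestGenerate:
    def test_byte_determinism(self):
        g1, t1 = generate(_one_locus_spec())
        g2, t2 = generate(_one_locus_spec())
        assert g1 == g2
        assert [(t.start, t.end, t.copy_counts) for t in t1] == [
            (t.start, t.end, t.copy_counts) for t in t2
        ]

    def test_planted_region_matches_declared_layout(self):
        genome, (t,) = generate(_one_locus_spec())
        seq = genome["chr1"]
        for (s, e), copies in zip(t.block_intervals, t.copy_counts):
            assert seq[s:e] == "CCTT" * copies
        units = [seq[s:e] for s, e in t.unit_intervals]
        assert len(set(units)) == 1  # rate 0: all copies identical
        assert len(units[0]) == 200

    def test_genome_length_preserved(self):
        genome, _ = generate(_one_locus_spec())
        assert len(genome["chr1"]) == 20000

    def test_head_fraction_layout_arithmetic(self):
        genome, (t,) = generate(_one_locus_spec(head_fraction=0.5))
        seq = genome["chr1"]
        # a 100 bp partial unit sits immediately before block 1 and equals
        # the master unit's suffix
        master = seq[t.unit_intervals[0][0]: t.unit_intervals[0][1]]
        assert seq[t.start - 100: t.start] == master[-100:]

    def test_too_small_genome_rejected_before_output(self):
        with pytest.raises(SimSpecError):
            SimSpec(genome_length=1000, seed=1,
                    loci=[PlantedLocus(srs_motif="CCTT", copy_counts=[3, 5, 2, 4],
                                       unit_length=400, n_units=3)]).validate()

    def test_uniform_planted_copies_rejected(self):
        with pytest.raises(SimSpecError, match="uniform"):
            PlantedLocus(srs_motif="CCTT", copy_counts=[3, 3, 3, 3],
                         unit_length=200, n_units=3).validate()

    def test_non_primitive_motif_rejected(self):
        with pytest.raises(SimSpecError, match="primitive"):
            PlantedLocus(srs_motif="ACAC", copy_counts=[3, 5, 2, 4],
                         unit_length=200, n_units=3).validate()

    def test_confounder_truth_marked_and_unscreened(self):
        spec = SimSpec(genome_length=20000, seed=9,
                       confounders=[Confounder(kind="uniform", srs_motif="GATC",
                                               copy_count=3, unit_length=200, n_units=3)])
        genome, (t,) = generate(spec)
        assert t.kind == "confounder_uniform"
        assert scan_genome(genome)[0] == []


class TestMutate:
    def test_rate_zero_identity(self, rng):
        seq = "ACGT" * 50
        assert mutate(seq, 0.0, rng) == seq

    def test_substitution_fraction_binomial(self):
        rng = np.random.default_rng(5)
        seq = "ACGT" * 25000
        rate = 0.05
        out = mutate(seq, rate, rng)
        assert len(out) == len(seq)
        observed = sum(a != b for a, b in zip(seq, out)) / len(seq)
        se = (rate * (1 - rate) / len(seq)) ** 0.5
        assert abs(observed - rate) < 3 * se

    def test_seed_reproducibility(self):
        seq = "ACGTTGCA" * 100
        a = mutate(seq, 0.1, np.random.default_rng(77))
        b = mutate(seq, 0.1, np.random.default_rng(77))
        assert a == b

    def test_invalid_rate(self, rng):
        with pytest.raises(ValueError):
            mutate("ACGT", 1.0, rng)


class TestSimulateGenomeFiles:
    def test_files_byte_identical_across_runs(self, tmp_path):
        spec = _one_locus_spec()
        fa1, gff1 = simulate_genome(spec, tmp_path / "a")
        fa2, gff2 = simulate_genome(_one_locus_spec(), tmp_path / "b")
        assert open(fa1, "rb").read() == open(fa2, "rb").read()
        assert open(gff1, "rb").read() == open(gff2, "rb").read()

    def test_truth_gff_round_trip(self, tmp_path):
        spec = _one_locus_spec(head_fraction=0.25)
        _, gff = simulate_genome(spec, tmp_path / "t")
        _, truths = generate(spec)
        back = read_truth_gff3(gff)
        assert len(back) == len(truths)
        for a, b in zip(truths, back):
            assert (a.start, a.end, a.kind, a.srs_motif, a.family) == (
                b.start, b.end, b.kind, b.srs_motif, b.family
            )
            assert a.block_intervals == b.block_intervals
            assert a.unit_intervals == b.unit_intervals
            assert a.head_fraction == pytest.approx(b.head_fraction)

    def test_yaml_spec_round_trip(self, tmp_path):
        spec = _one_locus_spec(substitution_rate=0.01, head_fraction=0.25)
        spec.confounders = [Confounder(kind="srs_free", unit_length=300, n_units=4)]
        path = tmp_path / "spec.yaml"
        save_simspec(spec, path)
        back = load_simspec(path)
        assert back.genome_length == spec.genome_length
        assert back.seed == spec.seed
        assert back.loci[0].copy_counts == spec.loci[0].copy_counts
        assert back.loci[0].head_fraction == spec.loci[0].head_fraction
        assert back.confounders[0].kind == "srs_free"
        # and the round-tripped spec realises the same genome
        assert generate(spec)[0] == generate(back)[0]


class TestEvaluateDetection:
    def test_self_evaluation_is_perfect(self):
        genome, truth = generate(random_spec(seed=4))
        loci, _ = scan_genome(genome)
        assert loci
        m = evaluate_detection(loci, truth_from_loci(loci))
        assert (m.precision, m.recall, m.mean_boundary_error) == (1.0, 1.0, 0.0)
        assert m.unit_count_agreement == 1.0

    def test_partial_recall(self):
        genome, truth = generate(
            SimSpec(genome_length=30000, seed=15,
                    loci=[PlantedLocus(srs_motif="CCTTG", copy_counts=[3, 5, 2, 4],
                                       unit_length=200, n_units=3),
                          PlantedLocus(srs_motif="GGATA", copy_counts=[4, 2, 5, 3],
                                       unit_length=250, n_units=3)])
        )
        loci, _ = scan_genome(genome)
        assert len(loci) == 2
        m = evaluate_detection(loci[:1], truth)
        assert m.recall == 0.5 and m.precision == 1.0

    def test_confounder_detection_counts_as_false_positive(self):
        from conftest import make_locus

        spec = SimSpec(genome_length=20000, seed=16,
                       confounders=[Confounder(kind="uniform", srs_motif="GATC",
                                               copy_count=3, unit_length=200, n_units=3)])
        genome, truth = generate(spec)
        t = truth[0]
        fake = make_locus(motif="GATC", copy_numbers=(3, 3, 3, 3),
                          unit_length=200, start=t.start)
        fake.end = t.end
        m = evaluate_detection([fake], truth)
        assert m.precision == 0.0
        assert m.recall == 1.0  # no planted loci to find

    def test_family_mismatch_not_matched(self):
        genome, truth = generate(_one_locus_spec(seed=18))
        loci, _ = scan_genome(genome)
        t = truth[0]
        wrong = [l for l in loci]
        from hsrscan.repeat_finder import MotifFamilyKey

        wrong[0].family = MotifFamilyKey(canonical="GGGTA", strand_merged=True)
        m = evaluate_detection(wrong, truth)
        assert m.recall == 0.0 and m.precision == 0.0
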