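import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hsrscan.detect import HSRLocus, ScanConfig, SRSBlock, Unit
from hsrscan.repeat_finder import MotifFamilyKey

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def config() -> ScanConfig:
    return ScanConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_locus(
    seq_id: str = "chr1",
    motif: str = "CCTT",
    copy_numbers=(3, 5, 2, 4),
    unit_length: int = 200,
    start: int = 1000,
    head_ratio: float = 0.0,
    tail_ratio: float = 0.0,
    unit_seqs=None,
) -> HSRLocus:
    """Assemble a structurally valid locus object without running a scan."""
    m = len(motif)
    blocks, units = [], []
    pos = start
    fam = MotifFamilyKey(canonical=motif, strand_merged=True)
    for i, c in enumerate(copy_numbers):
        blocks.append(
            SRSBlock(seq_id=seq_id, start=pos, end=pos + c * m, family=fam,
                     observed_motif=motif, copy_count=c, percent_matches=100.0)
        )
        pos += c * m
        if i < len(copy_numbers) - 1:
            seq = None if unit_seqs is None else unit_seqs[i]
            units.append(
                Unit(seq_id=seq_id, start=pos, end=pos + unit_length, sequence=seq,
                     identity_to_prev=None if i == 0 else 100.0)
            )
            pos += unit_length
    return HSRLocus(
        seq_id=seq_id, start=start, end=pos, family=fam,
        srs_class="short" if m <= 3 else "long",
        blocks=blocks, units=units, copy_numbers=list(copy_numbers),
        head_ratio=head_ratio, tail_ratio=tail_ratio,
    )
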