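"""Shared fixtures: randomized CNV records, profiles, cohorts, and a
chromosome-8 cytogenetic band table (hg19 coordinates, 40 bands)."""

import numpy as np
import pytest

from smckat import AMPLIFICATION, DELETION, CNVProfile, CNVRecord

# hg19 chromosome 8 cytogenetic bands: (band, start, end), 1-based inclusive
CHR8_BANDS = [
    ("p23.3", 1, 2_300_000),
    ("p23.2", 2_300_001, 6_300_000),
    ("p23.1", 6_300_001, 12_800_000),
    ("p22", 12_800_001, 19_200_000),
    ("p21.3", 19_200_001, 23_500_000),
    ("p21.2", 23_500_001, 27_500_000),
    ("p21.1", 27_500_001, 29_000_000),
    ("p12", 29_000_001, 36_700_000),
    ("p11.23", 36_700_001, 38_500_000),
    ("p11.22", 38_500_001, 39_900_000),
    ("p11.21", 39_900_001, 43_200_000),
    ("p11.1", 43_200_001, 45_200_000),
    ("q11.1", 45_200_001, 47_200_000),
    ("q11.21", 47_200_001, 51_300_000),
    ("q11.22", 51_300_001, 51_700_000),
    ("q11.23", 51_700_001, 54_600_000),
    ("q12.1", 54_600_001, 60_600_000),
    ("q12.2", 60_600_001, 61_300_000),
    ("q12.3", 61_300_001, 65_100_000),
    ("q13.1", 65_100_001, 67_100_000),
    ("q13.2", 67_100_001, 69_600_000),
    ("q13.3", 69_600_001, 72_000_000),
    ("q21.11", 72_000_001, 74_600_000),
    ("q21.12", 74_600_001, 74_700_000),
    ("q21.13", 74_700_001, 83_500_000),
    ("q21.2", 83_500_001, 85_900_000),
    ("q21.3", 85_900_001, 92_300_000),
    ("q22.1", 92_300_001, 97_900_000),
    ("q22.2", 97_900_001, 100_500_000),
    ("q22.3", 100_500_001, 105_100_000),
    ("q23.1", 105_100_001, 109_500_000),
    ("q23.2", 109_500_001, 111_100_000),
    ("q23.3", 111_100_001, 116_700_000),
    ("q24.11", 116_700_001, 118_300_000),
    ("q24.12", 118_300_001, 121_500_000),
    ("q24.13", 121_500_001, 126_300_000),
    ("q24.21", 126_300_001, 130_400_000),
    ("q24.22", 130_400_001, 135_400_000),
    ("q24.23", 135_400_001, 138_900_000),
    ("q24.3", 138_900_001, 145_138_636),
]


@pytest.fixture
def rng():
    return np.random.default_rng(20211126)


@pytest.fixture
def record_factory():
    """Callable producing a random valid CNVRecord from a Generator."""

    def make(rng, chrom="1", max_pos=20_000, max_len=5_000):
        start = int(rng.integers(1, max_pos))
        end = start + int(rng.integers(0, max_len))
        if rng.random() < 0.5:
            cnv_type, dosage = DELETION, int(rng.integers(0, 2))
        else:
            cnv_type, dosage = AMPLIFICATION, int(rng.integers(3, 8))
        return CNVRecord(chrom, start, end, cnv_type, dosage)

    return make


@pytest.fixture
def profile_factory(record_factory):
    def make(rng, sample_id, length, chroms=("1",), **kwargs):
        records = tuple(
            record_factory(rng, chrom=str(rng.choice(chroms)), **kwargs)
            for _ in range(length)
        )
        return CNVProfile(sample_id=sample_id, records=records)

    return make


@pytest.fixture
def cohort_factory(profile_factory):
    def make(rng, d, min_len=0, max_len=6, **kwargs):
        return [
            profile_factory(
                rng, f"s{i}", int(rng.integers(min_len, max_len + 1)), **kwargs
            )
            for i in range(d)
        ]

    return make


@pytest.fixture
def chr8_cytoband_file(tmp_path):
    """UCSC-format cytoBand.txt for chromosome 8 (0-based half-open)."""
    path = tmp_path / "cytoBand.txt"
    with open(path, "w") as fh:
        for band, start, end in CHR8_BANDS:
            fh.write(f"chr8\t{start - 1}\t{end}\t{band}\tgneg\n")
    return path
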