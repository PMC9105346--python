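import numpy as np
import pytest

from duplexffpe import (
    AlignedPairRecord,
    PopulationAFTable,
    ReadAlignment,
    SimulationParams,
    simulate_library,
    simulate_reference,
)


def af_table_from(snps, ref_name: str) -> PopulationAFTable:
    return PopulationAFTable.from_dataframe(snps, ref_name)


def make_pair(
    start: int,
    seq1: str,
    seq2: str | None = None,
    *,
    ref_name: str = "chrT",
    end: int | None = None,
    qname: str = "q",
    mapq: int = 60,
    proper: bool = True,
    cigar1=None,
    cigar2=None,
    reverse_r1: bool = False,
    qual: int = 30,
) -> AlignedPairRecord:
    """Hand-build a read pair; by default both mates cover [start, start+len)."""
    seq2 = seq1 if seq2 is None else seq2
    c1 = cigar1 or (("M", len(seq1)),)
    c2 = cigar2 or (("M", len(seq2)),)
    r1 = ReadAlignment(start, reverse_r1, seq1, c1, mapq, qual)
    r2_start = start if end is None else end - sum(n for op, n in c2 if op in "MDN=X")
    r2 = ReadAlignment(r2_start, not reverse_r1, seq2, c2, mapq, qual)
    return AlignedPairRecord(qname, ref_name, r1, r2, proper=proper)


@pytest.fixture(scope="session")
def small_reference():
    rng = np.random.default_rng(42)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = lut[rng.integers(0, 4, 2000)].tobytes().decode()
    return seq


@pytest.fixture(scope="session")
def clean_library():
    """A noise-free simulated library shared by several test modules."""
    params = SimulationParams(
        reference_length=60_000,
        n_templates=400,
        seed=11,
        somatic_rate_snv=100,
        somatic_rate_indel=40,
        lesion_rate=0.0,
        pcr_error_rate=0.0,
        seq_error_rate=0.0,
        strand_dropout_prob=0.0,
        pcr_copies_mean=8,
        snp_density_per_mb=400,
    )
    reference, snps = simulate_reference(params)
    library = simulate_library(reference, snps, params)
    return params, reference, snps, library
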