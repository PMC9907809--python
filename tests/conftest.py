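import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from satscreen import (
    AACountTable,
    EnrichmentRecord,
    ResidueVariant,
    build_library,
    default_library,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# 12-codon toy CDS: M K A C D P E F G H I L
TOY_CDS = "ATGAAAGCTTGTGATCCGGAATTTGGTCATATTCTG"


@pytest.fixture
def toy_library():
    """Small saturated library over residues 2-11 of the toy CDS."""
    return build_library(TOY_CDS, residue_start=2, residue_end=11)


@pytest.fixture(scope="session")
def full_library():
    """The default synthetic library (residues 50-134, all codons)."""
    return default_library()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_aa_table(
    counts: dict[ResidueVariant, int],
    condition: str,
    replicate: int = 1,
    total_reads: int | None = None,
    wt_count: int = 0,
) -> AACountTable:
    total = total_reads if total_reads is not None else sum(counts.values()) + wt_count
    return AACountTable(
        sample_id=f"{condition}_r{replicate}",
        condition=condition,
        replicate=replicate,
        aa_counts=dict(counts),
        wt_count=wt_count,
        total_reads=total,
    )


def make_record(
    position: int,
    ref_aa: str,
    alt_aa: str,
    mean: float | None,
    dropout: bool = False,
) -> EnrichmentRecord:
    """Minimal scored record for hit-calling and statistics tests."""
    return EnrichmentRecord(
        variant=ResidueVariant(position, ref_aa, alt_aa),
        frac_ctrl=(1e-4,),
        frac_sel=(1e-4,),
        log2fc_reps=(mean if mean is not None else float("nan"),),
        floored=(False,),
        log2fc_mean=mean,
        control_dropout=dropout,
        n_replicates=1,
    )
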