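import numpy as np
import pandas as pd
import pytest

from cnvscreen import CnvCall, MarkerMap, generate_marker_map


@pytest.fixture(scope="session")
def small_map() -> MarkerMap:
    """~500 markers on one 2 Mb chromosome at 4 kb mean spacing."""
    return generate_marker_map({"1": 2_000_000}, 4000, seed=11)


@pytest.fixture()
def tiny_map() -> MarkerMap:
    """Hand-built 8-marker map on two chromosomes."""
    rows = [
        ("rsA1", "1", 1_000, 0.3, 0.40),
        ("rsA2", "1", 5_000, 0.5, 0.45),
        ("rsA3", "1", 9_000, 0.7, 0.50),
        ("rsA4", "1", 13_000, 0.2, 0.55),
        ("rsA5", "1", 17_000, 0.8, 0.60),
        ("rsB1", "2", 2_000, 0.4, 0.42),
        ("rsB2", "2", 6_000, 0.6, 0.48),
        ("rsB3", "2", 10_000, 0.5, 0.52),
    ]
    return MarkerMap(pd.DataFrame(rows, columns=["name", "chrom", "pos", "pfb", "gc"]))


def make_call(
    sample_id="S1",
    chrom="1",
    start=1_000,
    end=20_000,
    copy_number=1,
    num_snps=5,
    start_snp="rs1",
    end_snp="rs5",
    confidence=15.0,
) -> CnvCall:
    return CnvCall(
        sample_id=sample_id,
        chrom=chrom,
        start=start,
        end=end,
        copy_number=copy_number,
        num_snps=num_snps,
        start_snp=start_snp,
        end_snp=end_snp,
        confidence=confidence,
    )


@pytest.fixture()
def call_factory():
    return make_call
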