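import pytest

from vgenepop.datasets import study_config, synthetic_reference
from vgenepop.reference_db import Allele, AlleleDatabase, group_operational_segments


@pytest.fixture(scope="session")
def ighv_db():
    db = synthetic_reference("IGHV", seed=0)
    group_operational_segments(db)
    return db


@pytest.fixture(scope="session")
def trbv_db():
    db = synthetic_reference("TRBV", seed=0)
    group_operational_segments(db)
    return db


@pytest.fixture(scope="session")
def ighv_config(ighv_db):
    return study_config("IGHV", ighv_db, seed=0)


@pytest.fixture()
def toy_db():
    """Two segments, three alleles, plus a pseudogene."""
    a01 = "ATGGATAAACCCGGGTTTACA"
    db = AlleleDatabase(alleles=[
        Allele("IGHV1-18", "01", a01),
        Allele("IGHV1-18", "02", a01[:6] + "C" + a01[7:]),
        Allele("IGHV6-1", "01", "ATGTTTCCCAAAGGGACATCA"),
        Allele("IGHV7-40", "01", "ATGCCCCCCCCCCCCCCCTAA", functional=False),
    ], locus="IGHV")
    group_operational_segments(db, 0.95)
    return db
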