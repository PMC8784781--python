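"""Shared fixtures: the published reference oligo set and random-target makers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

from asq.aspdesign import SnpTarget
from asq.universal import build_universal_set

# the validated reference assay (barley HvSAP16 promoter SNP, A/T)
TAG = "ccagctgaacggt"
UNIQ = "accgttcagctgg"
BARCODES4 = ("TCGACC", "ACCTGC", "TGCAGG", "AGGTCG")
UP_SEQS = {
    "UP-1": TAG + "TCGACC",
    "UP-2": TAG + "ACCTGC",
    "UP-3": TAG + "TGCAGG",
    "UP-4": TAG + "AGGTCG",
}
F1 = "ccagctgaacggtTCGACCAGACGATGTTGGACAAGCTTCTC"
F2 = "ccagctgaacggtACCTGCAGACGATGTTGGACAAGCTTCAC"
R = "GCACATTTGTACTGAGGATGGTAG"


@pytest.fixture(scope="session")
def universal_set():
    return build_universal_set()


@pytest.fixture(scope="session")
def hvsap16():
    from asq.hvsap16_synthetic import hvsap16_target

    return hvsap16_target()


def make_random_target(rng: np.random.Generator, length: int = 220) -> SnpTarget:
    """A random bi-allelic SNP target with a realistic base composition."""
    bases = np.array(list("ACGT"))
    template = "".join(rng.choice(bases, size=length, p=[0.27, 0.23, 0.23, 0.27]))
    snp = length // 2
    ref = template[snp]
    alt = rng.choice([b for b in "ACGT" if b != ref])
    return SnpTarget(template=template, snp_position=snp, alleles=(ref, str(alt)))
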