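"""Shared fixtures and independent oracle tables.

The genetic code below is frozen as a literal so consequence-classification
tests do not depend on the same library routine the implementation uses.
Stops are written as '*'; the bacterial code (table 11) translates all 64
codons identically to the standard code (they differ only in start codons,
which consequence classification never consults).
"""

import numpy as np
import pytest

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_consequence(ref_codon: str, alt_codon: str) -> str:
    """Brute-force substitution class from the frozen code table."""
    ref_aa, alt_aa = GENETIC_CODE[ref_codon], GENETIC_CODE[alt_codon]
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stop_loss"
    return "nonsynonymous"


@pytest.fixture
def genetic_code():
    return GENETIC_CODE


@pytest.fixture
def rng():
    return np.random.default_rng(20250919)


@pytest.fixture
def random_sequence(rng):
    def make(length: int, gc: float = 0.5) -> str:
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(rng.choice(list("ACGT"), size=length, p=p))

    return make
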