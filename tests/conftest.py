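import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pepscreen.pssm import PositionMatrix, POSITIONS, ROW_ORDER
from pepscreen.seqio import CodingRegion
from pepscreen.simulate import MOST_FREQUENT_CODON
from pepscreen.translation import translate_coding_region

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: single-codon encoding including a TAG stand-in for the stop symbol,
#: used to build PeptideRecords straight from peptide strings in tests
CODON_OF = {**MOST_FREQUENT_CODON, "*": "TAG"}


def record_from_peptide(peptide, read_id="r"):
    dna = "".join(CODON_OF[aa] for aa in peptide)
    rec = translate_coding_region(CodingRegion(read_id, dna))
    assert rec.peptide == peptide
    return rec


def records_from_peptides(peptides):
    return [record_from_peptide(p, f"r{i}") for i, p in enumerate(peptides)]


def random_peptides(rng, n, with_center_y=True, alphabet="ACDEFGHIKLMNPQRSTVW"):
    """Random 11-mers over the 20 AAs (central Y fixed when requested)."""
    letters = rng.choice(list(alphabet + "Y"), size=(n, 11))
    peps = []
    for row in letters:
        if with_center_y:
            row[5] = "Y"
        peps.append("".join(row))
    return peps


@pytest.fixture
def toy_matrix():
    """log2 matrix with A=+1 and C=-1 at every variable position, else 0."""
    values = pd.DataFrame(0.0, index=ROW_ORDER, columns=POSITIONS)
    var = [p for p in POSITIONS if p != 0]
    values.loc["A", var] = 1.0
    values.loc["C", var] = -1.0
    values.loc["*", :] = np.nan
    return PositionMatrix(values, layer="log2_enrichment", mode="nostop", sample_id="toy")
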