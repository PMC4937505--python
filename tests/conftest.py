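import numpy as np
import pandas as pd
import pytest

from caspkit import synthetic
from caspkit.design import DEFAULT_DESIGN


@pytest.fixture(scope="session")
def design():
    return DEFAULT_DESIGN


@pytest.fixture(scope="session")
def small_db():
    return synthetic.gen_protein_db(60, (60, 300), seed=101)


@pytest.fixture(scope="session")
def psm_bundle(small_db, design):
    """A modest PSM table with planted archetypes, decoys and truth."""
    psms, truth = synthetic.gen_cleavage_psms(
        small_db, design, n_psms=600, n_peptides=120, noise_sd=0.2,
        decoy_fraction=0.3, seed=202,
    )
    return psms, truth


def make_psm_frame(target_scores, decoy_scores):
    """Minimal scored PSM table from raw score lists."""
    rows = []
    for i, s in enumerate(target_scores):
        rows.append((f"t{i}", f"PEPT{i}D", f"ACC{i}", 0, s))
    for i, s in enumerate(decoy_scores):
        rows.append((f"d{i}", f"DECT{i}D", f"DECOY_ACC{i}", 1, s))
    return pd.DataFrame(
        rows, columns=["spectrum_id", "peptide", "proteins", "decoy", "discriminant_score"]
    )
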