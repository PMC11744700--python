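import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pofp.data import wavelength_to_energy
from pofp.features import fingerprint_table
from pofp.models import build_fcnn, fit
from pofp.synthetic import generate_dataset

TPE = "C(=C(c1ccccc1)c1ccccc1)(c1ccccc1)c1ccccc1"

#: Small (<= 20 heavy atoms) molecules spanning the feature chemistry:
#: plain aromatics, donors, acceptors, ESIPT motifs, breakers, charges.
PANEL = [
    "c1ccccc1",                  # benzene
    "c1ccc2ccccc2c1",            # naphthalene
    "c1ccncc1",                  # pyridine
    "c1cnccn1",                  # pyrazine
    "c1ccsc1",                   # thiophene
    "c1ccoc1",                   # furan
    "C=Cc1ccccc1",               # styrene
    "c1ccc(C=Cc2ccccc2)cc1",     # stilbene
    "-".join(["c1ccccc1", "c1ccccc1"]),  # biphenyl
    "N#Cc1ccccc1",               # benzonitrile
    "CN(C)c1ccccc1",             # N,N-dimethylaniline
    "COc1ccccc1",                # anisole
    "O=Cc1ccccc1",               # benzaldehyde
    "O=Cc1ccccc1O",              # salicylaldehyde
    "N=Cc1ccccc1O",              # salicylaldimine
    "CC(C)(C)c1ccccc1",          # tert-butylbenzene
    "FC(F)(F)c1ccccc1",          # (trifluoromethyl)benzene
    "Cc1nc2ccccc2s1",            # 2-methylbenzothiazole
    "c1cc[nH+]cc1",              # pyridinium
    "CC(C)=C(C)C",               # tetramethylethylene
]


@pytest.fixture(scope="session")
def synth_ds():
    """The default study-scale synthetic dataset (700 records, seed 42)."""
    return generate_dataset(700, seed=42)


@pytest.fixture(scope="session")
def synth_xy(synth_ds):
    frame = synth_ds.to_frame()
    X, kept, rejections = fingerprint_table(frame["smiles"].tolist(), "num")
    assert not rejections
    y = np.array([wavelength_to_energy(l) for l in frame["lambda_solid_nm"]])
    yc = frame["feature_class"].to_numpy()
    return X.astype(float), y, yc


@pytest.fixture(scope="session")
def fcnn_reg(synth_xy):
    X, y, _ = synth_xy
    return fit(build_fcnn(task="regression", seed=42), X, y)


@pytest.fixture(scope="session")
def fcnn_clf(synth_xy):
    X, _, yc = synth_xy
    return fit(build_fcnn(task="classification", seed=42), X, yc)
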