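import os
from pathlib import Path

import numpy as np
import pytest

from ckdfusion.data_io import SyntheticSpec, generate_synthetic

REPO_ROOT = Path(__file__).resolve().parents[1]

_UCI_CANDIDATES = [
    REPO_ROOT / "data" / "chronic_kidney_disease.arff",
    REPO_ROOT / "data" / "chronic_kidney_disease_full.arff",
    REPO_ROOT / "data" / "ckd.arff",
]


def locate_uci_file():
    """Path to the UCI chronic-kidney-disease ARFF, if supplied."""
    env = os.environ.get("CKD_UCI_PATH")
    if env and Path(env).exists():
        return Path(env)
    for cand in _UCI_CANDIDATES:
        if cand.exists():
            return cand
    return None


UCI_PATH = locate_uci_file()
needs_uci = pytest.mark.skipif(
    UCI_PATH is None,
    reason="UCI chronic-kidney-disease file not available offline; set "
    "CKD_UCI_PATH or place it under data/ to enable")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clinical_ds():
    """Small clinical-style synthetic cohort with some missingness."""
    return generate_synthetic(
        SyntheticSpec(n_per_class=30, missing_rate=0.1, seed=7))


@pytest.fixture
def gaussian_ds():
    """Complete numeric dataset, moderately separated classes."""
    return generate_synthetic(
        SyntheticSpec(n_per_class=40, mode="gaussian", n_features=6,
                      class_shift=1.5, seed=11))


TOY_ARFF = """\
@relation ckd_toy
@attribute 'age' numeric
@attribute 'bp'  numeric
@attribute 'sg' {1.005,1.010,1.015,1.020,1.025}
@attribute 'al' {0,1,2,3,4,5}
@attribute 'su' {0,1,2,3,4,5}
@attribute 'rbc' {normal,abnormal}
@attribute 'pc' {normal,abnormal}
@attribute 'pcc' {present,notpresent}
@attribute 'ba' {present,notpresent}
@attribute 'bgr' numeric
@attribute 'bu' numeric
@attribute 'sc' numeric
@attribute 'sod' numeric
@attribute 'pot' numeric
@attribute 'hemo' numeric
@attribute 'pcv' numeric
@attribute 'wc' numeric
@attribute 'rc' numeric
@attribute 'htn' {yes,no}
@attribute 'dm' {yes,no}
@attribute 'cad' {yes,no}
@attribute 'appet' {good,poor}
@attribute 'pe' {yes,no}
@attribute 'ane' {yes,no}
@attribute 'class' {ckd,notckd}
@data
48,80,1.020,1,0,normal,normal,notpresent,notpresent,121,36,1.2,137,4.4,15.4,44,7800,5.2,yes,yes,no,good,no,no,ckd
7,50,1.020,4,0,?,normal,notpresent,notpresent,\t?,18,0.8,111,2.5,11.3,38,6000,4.7,no,no,no,good,no,no,ckd
80,80,1.025,0,0,normal,normal,notpresent,notpresent,131,18,1.1,141,3.5,15.8,53,6800,6.1,no,no,no,good,no,no,notckd
"""


@pytest.fixture
def toy_arff(tmp_path):
    path = tmp_path / "toy.arff"
    path.write_text(TOY_ARFF, encoding="utf-8")
    return path
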