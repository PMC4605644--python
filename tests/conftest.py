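import warnings

import numpy as np
import pytest

from mirsig import preprocess, synthdata


@pytest.fixture(scope="session")
def marker_dataset():
    """60-sample, 200-feature dataset with 10 deregulated features per case
    group and two injected outlier samples."""
    params = synthdata.SynthParams(
        n_per_group={"CD": 20, "UC": 20, "HC": 20},
        n_features=200,
        frac_deregulated=0.05,
        effect_size=1.5,
        n_outliers=2,
        outlier_scale=6.0,
        seed=7,
    )
    matrix, sheet, truth = synthdata.generate_dataset(params)
    return matrix, sheet, truth


@pytest.fixture(scope="session")
def normalized_dataset(marker_dataset):
    matrix, sheet, truth = marker_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm, kept_sheet, fit, report = preprocess.preprocess_pipeline(matrix, sheet)
    return norm, kept_sheet, truth, report


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
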