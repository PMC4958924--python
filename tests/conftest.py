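import numpy as np
import pandas as pd
import pytest

from weedbayes.core import SurveyDesign
from weedbayes.datasets import FIELDS_COLUMNS, OBS_COLUMNS, WeedSurveyDataset


@pytest.fixture
def tiny_design():
    return SurveyDesign(n_farms=2, fields_per_farm=2, quadrats_per_field=10)


@pytest.fixture
def tiny_dataset(tiny_design):
    """Two farms x two fields, three species, hand-written presences."""
    fields = pd.DataFrame(
        [
            ("farm01", "farm01_f1", 0.0, np.nan, 71.0, 150.0),
            ("farm01", "farm01_f2", 2.0, np.nan, 69.0, 160.0),
            ("farm02", "farm02_f1", 1.0, np.nan, np.nan, 140.0),
            ("farm02", "farm02_f2", 3.5, np.nan, 80.0, 155.0),
        ],
        columns=FIELDS_COLUMNS,
    )
    obs = []
    presences = {
        ("farm01_f1", "sp01"): 4,
        ("farm01_f1", "sp02"): 10,
        ("farm01_f2", "sp01"): 1,
        ("farm02_f1", "sp03"): 5,
        ("farm02_f2", "sp02"): 2,
    }
    for (fid, sp), k in presences.items():
        for q in range(k):
            obs.append((fid, q + 1, sp, 1))
    observations = pd.DataFrame(obs, columns=OBS_COLUMNS)
    return WeedSurveyDataset(
        fields=fields, observations=observations, design=tiny_design
    )
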