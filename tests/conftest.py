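import numpy as np
import pandas as pd
import pytest

from tlsgrade.phenotyping import MARKERS, default_rules
from tlsgrade.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_patients=12,
        tls_per_patient=(2, 4),
        outside_fields_per_patient=(2, 3),
        cells_per_region=(80, 150),
        seed=77,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


def make_cells(marker_rows, region_id="R1", patient_id="P0", section_id="S1"):
    """Cell table from a list of positive-marker tuples."""
    columns = ["patient_id", "section_id", "region_id", "cell_id", *MARKERS]
    rows = []
    for i, positives in enumerate(marker_rows):
        row = {
            "patient_id": patient_id,
            "section_id": section_id,
            "region_id": region_id,
            "cell_id": f"{region_id}_C{i:03d}",
        }
        row.update({m: int(m in positives) for m in MARKERS})
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
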