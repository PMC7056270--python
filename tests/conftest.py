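import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import proteoruler as pr

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def single_sample_design() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1"],
            "genotype": ["WT"],
            "cell_type": ["CD4"],
            "stimulation": ["naive"],
            "replicate": [1],
        }
    )


def make_groups(intensities: dict, design: pd.DataFrame, **overrides) -> pd.DataFrame:
    """Small protein-groups table builder for tests.

    ``intensities``: group_id -> list of per-sample intensities (NaN = not
    detected).  Gene names default to the group id; histones get recognised
    by naming the group e.g. ``H4c1``.
    """
    ids = list(intensities)
    n = len(ids)
    base = {
        "group_id": ids,
        "gene_name": overrides.get("gene_name", ids),
        "mol_weight_da": overrides.get("mol_weight_da", [50000.0] * n),
        "razor_unique_peptides": overrides.get("razor_unique_peptides", [10] * n),
        "unique_peptides": overrides.get("unique_peptides", [9] * n),
        "flag_contaminant": overrides.get("flag_contaminant", [False] * n),
        "flag_reverse": overrides.get("flag_reverse", [False] * n),
        "flag_only_by_site": overrides.get("flag_only_by_site", [False] * n),
    }
    df = pd.DataFrame(base)
    for j, sid in enumerate(design["sample_id"]):
        df[sid] = [float(intensities[g][j]) for g in ids]
    return df


@pytest.fixture(scope="session")
def noise_free_dataset():
    """sigma=0, no missing values: every stage has an exact oracle."""
    params = pr.SimulationParams(
        noise_sigma_log2=0.0, missing_rate=0.0, n_decoys=5, n_contaminants=5
    )
    groups, design, truth = pr.simulate_dataset(n_proteins=250, seed=11, params=params)
    return groups, design, truth


@pytest.fixture(scope="session")
def noise_free_result(noise_free_dataset):
    groups, design, truth = noise_free_dataset
    filtered = pr.detection_filter(pr.filter_groups(groups), design)
    return pr.estimate_copy_numbers(filtered, design), design, truth
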