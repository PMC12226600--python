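import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cortasym.io import ThicknessRecord
from cortasym.regions import N_REGIONS

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_record(
    rng: np.random.Generator | None = None,
    subject_id: str = "S001",
    visit: int = 1,
    group: str = "CTR",
    phenotype: str | None = None,
    rh_offset: float = 0.0,
) -> ThicknessRecord:
    """A valid record with thickness drawn around 2.5 mm; optional rightward offset."""
    if rng is None:
        rng = np.random.default_rng(0)
    lh = 2.5 + 0.25 * rng.standard_normal(N_REGIONS)
    lh = np.clip(lh, 1.0, None)
    rh = lh + 0.02 * rng.standard_normal(N_REGIONS) - rh_offset
    rh = np.clip(rh, 0.5, None)
    if phenotype is None:
        phenotype = "bvFTD" if group == "FTD" else "none"
    return ThicknessRecord(
        subject_id=subject_id,
        visit=visit,
        group=group,
        phenotype=phenotype,
        sex="F" if rng.random() < 0.5 else "M",
        age_at_mri=float(rng.uniform(50, 80)),
        age_of_onset=math.nan if group == "CTR" else float(rng.uniform(45, 70)),
        lh_thickness=lh,
        rh_thickness=rh,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_records(rng) -> list[ThicknessRecord]:
    return [
        make_record(rng, subject_id=f"S{i:03d}", group=g, rh_offset=off)
        for i, (g, off) in enumerate(
            [("CTR", 0.0), ("CTR", 0.0), ("AD", 0.05), ("AD", 0.06), ("FTD", 0.1), ("FTD", 0.12)]
        )
    ]


def bimodal_cai_table(seed: int, delta_sd: float, n: int = 50, sd: float = 0.1):
    """1-D CAI cohort with two planted Gaussian modes separated by delta_sd * sd.

    Returns (table, planted_labels) with the table restricted to one disease.
    """
    rng = np.random.default_rng(seed)
    n1 = n // 2
    low = 0.3 + sd * rng.standard_normal(n1)
    high = 0.3 + delta_sd * sd + sd * rng.standard_normal(n - n1)
    cai = np.abs(np.concatenate([low, high]))
    labels = np.array([0] * n1 + [1] * (n - n1))
    table = pd.DataFrame(
        {
            "subject_id": [f"P{i:03d}" for i in range(n)],
            "visit": 1,
            "group": "FTD",
            "phenotype": "bvFTD",
            "cai": cai,
        }
    )
    return table, labels
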