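import pandas as pd
import pytest

import patnet as pn
from patnet.cohort import META_COLUMNS


@pytest.fixture(scope="session")
def catalog():
    return pn.load_catalog("PAT2.0")


@pytest.fixture(scope="session")
def gen_catalog():
    return pn.load_catalog("PAT2.0_GEN")


@pytest.fixture(scope="session")
def profiles():
    """Calibrated default profiles for the three study diseases."""
    return {d: pn.calibrate_profile(d) for d in ("ALL", "epilepsy", "asthma")}


@pytest.fixture(scope="session")
def all_cohort(profiles):
    """One simulated leukemia cohort at the study size."""
    return pn.generate_cohort(profiles["ALL"], seed=11)


@pytest.fixture(scope="session")
def big_all_cohort(profiles):
    """Large simulated cohort for recovery/consistency checks."""
    return pn.generate_cohort(profiles["ALL"], n=10_000, seed=5)


def make_record(catalog, fill=0, family_id="fam1", disease="ALL",
                sibling_applicable=True, **responses):
    """A family record with every item set to ``fill`` except ``responses``
    (keyed by item id or label)."""
    full = {item.item_id: fill for item in catalog}
    for key, value in responses.items():
        full[catalog.get(key).item_id] = value
    return pn.FamilyRecord(
        family_id=family_id,
        disease=disease,
        responses=full,
        sibling_applicable=sibling_applicable,
    )


def cohort_from_columns(catalog, columns: dict, fill_pattern=(0.0, 1.0)):
    """Build a cohort where ``columns`` fixes specific item columns and all
    remaining items alternate 0/1 (non-zero variance everywhere)."""
    n = len(next(iter(columns.values())))
    frame = pd.DataFrame(
        {
            "family_id": [f"f{i}" for i in range(n)],
            "disease": "ALL",
            "timepoint": "T0",
            "sibling_applicable": True,
        }
    )
    for k, item in enumerate(catalog.item_ids):
        frame[item] = [float(fill_pattern[(i + k) % len(fill_pattern)]) for i in range(n)]
    for key, values in columns.items():
        frame[catalog.get(key).item_id] = [float(v) for v in values]
    return pn.Cohort(frame=frame, catalog=catalog)


__all__ = ["make_record", "cohort_from_columns", "META_COLUMNS"]
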