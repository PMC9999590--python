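import numpy as np
import pandas as pd
import pytest

from neuropathsel import CohortTable, FeatureSpec, LABEL_COLUMN, generate_cohort
from neuropathsel.cohort_prep import filter_missing_labels


def make_table(columns: dict, labels, kinds: dict | None = None) -> CohortTable:
    """Build a small cohort table from plain lists.

    ``kinds`` maps feature name -> kind; unspecified features default to
    ordinal with their observed integer levels.
    """
    kinds = kinds or {}
    data = pd.DataFrame({**columns, LABEL_COLUMN: labels})
    data.index = pd.Index([f"S{i}" for i in range(len(data))], name="subject_id")
    meta = []
    for name, values in columns.items():
        kind = kinds.get(name, "ordinal")
        observed = sorted({v for v in values if v is not None and not pd.isna(v)})
        if kind == "numeric":
            levels = [min(observed), max(observed) + 1]
        else:
            levels = observed if len(observed) > 1 else [0, 1]
        meta.append(FeatureSpec(name, kind, levels))
    meta.append(FeatureSpec(LABEL_COLUMN, "binary_label", [0, 1]))
    return CohortTable(data=data, feature_meta=meta)


@pytest.fixture(scope="session")
def default_cohort() -> CohortTable:
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def labeled_cohort(default_cohort) -> CohortTable:
    return filter_missing_labels(default_cohort)
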