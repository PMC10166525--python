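import numpy as np
import pytest

import stratecho as se


@pytest.fixture(scope="session")
def schema():
    return se.build_schema()


@pytest.fixture(scope="session")
def hand_example():
    """Four samples, two features; feature 0 separates the classes perfectly."""
    X = np.array([[0.0, 0.1], [0.0, 0.9], [1.0, 0.2], [1.0, 0.8]])
    y = np.array(["A", "A", "B", "B"], dtype=object)
    return X, y


@pytest.fixture(scope="session")
def preset_cohort_w20(schema):
    """One progressive-preset cohort at 20 weeks (raw, default sizes)."""
    return se.simulate_cohort(schema, se.progressive_preset(seed=7), timepoint_weeks=20)


@pytest.fixture(scope="session")
def engineered_w20(schema, preset_cohort_w20):
    table, report = se.engineer_table(preset_cohort_w20, schema)
    return table, report


@pytest.fixture(scope="session")
def partitions_w20(schema, engineered_w20):
    table, _ = engineered_w20
    return {p.name: p for p in se.partition_datasets(table, schema)}


def make_table(values, labels, feature_names=None, missing=None, timepoint=20):
    """Small FeatureTable helper for unit tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    if missing is None:
        missing = np.isnan(values)
    return se.FeatureTable(
        animal_ids=[f"a{i}" for i in range(n)],
        class_labels=np.asarray(labels, dtype=object),
        timepoint_weeks=timepoint,
        feature_names=list(feature_names),
        values=values,
        missing_mask=np.asarray(missing, dtype=bool),
    )
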