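import numpy as np
import pytest

import trussmorph as tm


@pytest.fixture(scope="session")
def study_model() -> tm.ShapeModel:
    """Seven-river study design with default deformations and noise."""
    return tm.ShapeModel(seed=7)


@pytest.fixture(scope="session")
def study_dataset(study_model) -> tm.LandmarkDataset:
    return tm.generate_dataset(study_model)


@pytest.fixture(scope="session")
def isometric_model() -> tm.ShapeModel:
    """Pure isometry: identical shape at varying sizes, no noise."""
    base = tm.ShapeModel()
    return tm.ShapeModel(
        group_offsets={g: np.zeros((9, 2)) for g in base.group_sizes},
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def isometric_dataset(isometric_model) -> tm.LandmarkDataset:
    return tm.generate_dataset(isometric_model)


@pytest.fixture(scope="session")
def transformed_table(study_dataset) -> tm.TrussTable:
    """Elliott-adjusted, log10-transformed truss table (35 variables)."""
    raw = tm.truss_distances(study_dataset)
    model = tm.fit_allometry(raw)
    return tm.log_transform(tm.size_adjust(raw, model))


@pytest.fixture(scope="session")
def gpa_result(study_dataset) -> tm.ProcrustesResult:
    return tm.gpa(study_dataset)
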