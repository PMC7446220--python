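import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from synodeconv.io import ExpressionMatrix, SampleRecord, SampleSheet, Scale
from synodeconv.synthetic import generate_cohort, generate_reference_profiles

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = tuple(f"G{i:03d}" for i in range(30))
    samples = ("s1", "s2", "s3", "s4")
    return ExpressionMatrix(genes, samples, rng.normal(7, 1, size=(30, 4)), Scale.log2)


@pytest.fixture
def small_sheet() -> SampleSheet:
    records = []
    for i, (pid, resp) in enumerate(
        [("P1", "good"), ("P2", "moderate"), ("P3", "none"), ("P4", "none")]
    ):
        for tp, suffix in (("week0", "a"), ("week20", "b")):
            records.append(
                SampleRecord(
                    sample_id=f"{pid}{suffix}",
                    patient_id=pid,
                    timepoint=tp,
                    response=resp,
                    batch="b1" if i % 2 == 0 else "b2",
                )
            )
    return SampleSheet(tuple(records))


@pytest.fixture(scope="session")
def reference_profiles():
    return generate_reference_profiles(
        n_genes=600, n_markers_per_type=40, marker_effect=2.0, seed=11
    )


@pytest.fixture(scope="session")
def cohort(reference_profiles):
    return generate_cohort(reference_profiles, seed=11)
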