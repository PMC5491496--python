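import numpy as np
import pandas as pd
import pytest

from lcmirna.data_model import CtMatrix, SampleInfo


def make_ct(
    values: np.ndarray,
    samples=None,
    assays=None,
    plates=None,
    stage: str = "raw",
) -> CtMatrix:
    """Build a CtMatrix from a plain array; NaN cells become undetectable."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    samples = samples or [f"s{i + 1}" for i in range(n)]
    assays = assays or [f"m{j + 1}" for j in range(p)]
    frame = pd.DataFrame(values, index=samples, columns=assays)
    plates = plates or ["A"] * p
    return CtMatrix(
        values=frame,
        detect_mask=frame.notna(),
        plate_of_assay=pd.Series(plates, index=assays),
        stage=stage,
    )


def make_samples(n_case: int, n_control: int, sexes=None) -> list[SampleInfo]:
    out = []
    for i in range(n_case):
        out.append(
            SampleInfo(f"s{i + 1}", "case", 50.0, (sexes or "M" * 99)[i], 5.0, 6.8, 7.0)
        )
    for i in range(n_control):
        out.append(
            SampleInfo(
                f"s{n_case + i + 1}",
                "control",
                60.0,
                (sexes or "M" * 99)[n_case + i],
                5.0,
                6.8,
                7.0,
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
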