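import numpy as np
import pandas as pd
import pytest

import ratioscreen as rs


@pytest.fixture(scope="session")
def default_panel():
    return rs.make_default_panel(1)


@pytest.fixture(scope="session")
def bundle():
    """Canonical synthetic study bundle (seed 1, 69 + 70 subjects)."""
    return rs.simulate_bundle(1)


@pytest.fixture(scope="session")
def qc_matrix(bundle):
    """Analysis-ready matrix: LOD-filtered and mean-imputed."""
    filtered, _ = rs.filter_by_lod(bundle["concentrations"])
    imputed, _ = rs.impute_missing_mean(filtered)
    return imputed


def make_matrix(values: np.ndarray, mask: np.ndarray | None = None,
                batch: list[str] | None = None,
                metabolites: list[str] | None = None) -> rs.ConcentrationMatrix:
    """Build a small ConcentrationMatrix from raw arrays (test helper)."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    subjects = pd.Index([f"S{i+1:03d}" for i in range(n)], name="subject_id")
    cols = metabolites or [f"M{j+1}" for j in range(m)]
    vals = pd.DataFrame(values, index=subjects, columns=cols)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    return rs.ConcentrationMatrix(
        values=vals,
        below_lod=pd.DataFrame(np.asarray(mask, dtype=bool), index=subjects, columns=cols),
        batch=pd.Series(batch or ["B1"] * n, index=subjects, name="batch"),
    )
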