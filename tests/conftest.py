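import numpy as np
import pandas as pd
import pytest

from wearanx.features import cohort_to_table
from wearanx.simulate import CohortConfig, generate_cohort


def ampd_bruteforce(x, seed=0):
    """Literal, loop-based transcription of the multiscale scalogram
    definition; independent oracle for the vectorized detector.

    Entry (k, i) is 0 when x[i] strictly exceeds x[i-k] and x[i+k] (after
    linear detrending), else alpha + U(0,1); the scale minimizing the row
    sum is selected and peaks are columns all-zero up to that scale.
    """
    x = np.asarray(x, float)
    n = len(x)
    tol = 1e-9 * (max(x) - min(x)) if max(x) > min(x) else 0.0
    t = np.arange(n)
    slope, intercept = np.polyfit(t, x, 1)
    x = x - (slope * t + intercept)
    n_scales = int(np.ceil(n / 2)) - 1
    u = np.random.default_rng(seed).random((n_scales, n))
    m = [[0.0] * n for _ in range(n_scales)]
    for k in range(1, n_scales + 1):
        for i in range(n):
            if k <= i < n - k and x[i] > x[i - k] + tol and x[i] > x[i + k] + tol:
                m[k - 1][i] = 0.0
            else:
                m[k - 1][i] = 1.0 + u[k - 1][i]
    gamma = [sum(row) for row in m]
    lam_rows = min(range(n_scales), key=lambda j: gamma[j]) + 1
    peaks = [i for i in range(n)
             if all(m[k][i] == 0.0 for k in range(lam_rows))]
    return np.asarray(peaks, int)


@pytest.fixture(scope="session")
def calib_cohort():
    """Small calibration cohort reused by feature/label tests."""
    cfg = CohortConfig(n_subjects=4, subset="calibration",
                       session_duration_s=600.0, label_noise=0.0, seed=1)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def calib_table(calib_cohort):
    return cohort_to_table(calib_cohort)


@pytest.fixture(scope="session")
def separable_table():
    """Two well-separated Gaussian clusters: any sane classifier should be
    near-perfect."""
    rng = np.random.default_rng(0)
    n = 500
    x0 = rng.normal(0.0, 1.0, (n // 2, 5))
    x1 = rng.normal(3.0, 1.0, (n // 2, 5))
    df = pd.DataFrame(np.vstack([x0, x1]), columns=[f"f{i}" for i in range(5)])
    df["label"] = [0] * (n // 2) + [1] * (n // 2)
    return df


@pytest.fixture(scope="session")
def shuffled_table(separable_table):
    rng = np.random.default_rng(42)
    df = separable_table.copy()
    df["label"] = rng.permutation(df["label"].to_numpy())
    return df
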