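import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def brute_force_dcov2(x, y):
    """Literal triple-sum evaluation of the V-statistic dcov^2 estimator.

    Written with explicit nested loops and no vectorization shortcuts so it
    serves as an independent oracle for the production kernel.
    """
    n = len(x)
    s1 = 0.0
    for i1 in range(n):
        for i2 in range(n):
            s1 += abs(y[i1] - y[i2]) * abs(x[i1] - x[i2])
    s1 /= n**2

    sy = 0.0
    sx = 0.0
    for i1 in range(n):
        for i2 in range(n):
            sy += abs(y[i1] - y[i2])
            sx += abs(x[i1] - x[i2])
    s2 = (sy / n**2) * (sx / n**2)

    s3 = 0.0
    for i1 in range(n):
        for i2 in range(n):
            for i3 in range(n):
                s3 += abs(y[i1] - y[i3]) * abs(x[i2] - x[i3])
    s3 /= n**3
    return s1 + s2 - 2.0 * s3
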