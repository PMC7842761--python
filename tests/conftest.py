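import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent rank-correlation oracle: explicit midrank assignment followed by
# the textbook Pearson sum formula (no numpy/scipy ranking involved)


def midranks(values):
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_sum_formula(x, y):
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return (n * sxy - sx * sy) / den


def spearman_bruteforce(x, y):
    return pearson_sum_formula(midranks(x), midranks(y))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
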