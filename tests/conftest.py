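import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def forward_af(a, b, c, d):
    """Forward-compute (OR, af_total, n_case, n_control) from allele counts.

    a/b are effect/other counts in cases, c/d in controls; sample sizes are
    individuals (allele counts / 2).
    """
    n_case = (a + b) / 2.0
    n_control = (c + d) / 2.0
    or_value = (a * d) / (b * c)
    af_total = (a + c) / (a + b + c + d)
    return or_value, af_total, n_case, n_control


def forward_se(a, b, c, d):
    """Forward-compute (OR, SE, alleles_case, alleles_control)."""
    or_value = (a * d) / (b * c)
    se_value = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_value, se_value, a + b, c + d


def random_tables(rng, n, max_count=5000, minor_concordant=False):
    """Random integer allele-count tables with all cells >= 1."""
    cells = rng.integers(1, max_count, size=(n, 4)).astype(float)
    if minor_concordant:
        a, b, c, d = cells.T
        cells = np.column_stack(
            [np.minimum(a, b), np.maximum(a, b), np.minimum(c, d), np.maximum(c, d)]
        )
    return cells
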