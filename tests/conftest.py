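import numpy as np
import pytest

import facenorms as fn


@pytest.fixture(scope="session")
def normative_cohort():
    return fn.generate_normative_cohort(seed=1)


@pytest.fixture(scope="session")
def fitted_model(normative_cohort):
    return fn.fit_norm_model(normative_cohort)


@pytest.fixture(scope="session")
def norms():
    return fn.published_norms()


@pytest.fixture(scope="session")
def published_thresholds(norms):
    return norms.thresholds()


# All 44 correction-grid cells as printed: {education: (first age, cells)},
# ages advancing in steps of 5 years.
PRINTED_GRID = {
    5: (60, [2.73, 3.09, 3.45, 3.81, 4.17, 4.54]),
    8: (40, [0.30, 0.67, 1.03, 1.39, 1.75, 2.11, 2.47, 2.84, 3.20, 3.56]),
    13: (20, [-2.42, -2.06, -1.70, -1.34, -0.98, -0.62, -0.25, 0.11, 0.47, 0.83, 1.19, 1.55, 1.91, 2.28]),
    17: (20, [-3.28, -2.92, -2.55, -2.19, -1.83, -1.47, -1.11, -0.75, -0.38, -0.02, 0.34, 0.70, 1.06, 1.42]),
}


def printed_grid_cells():
    for edu, (age0, values) in PRINTED_GRID.items():
        for i, v in enumerate(values):
            yield age0 + 5 * i, edu, v
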