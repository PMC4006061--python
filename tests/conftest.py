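import numpy as np
import pytest
from dataclasses import replace

import molarmorph as mm

GROUPS = ("control", "mild", "moderate", "severe")


@pytest.fixture(scope="session")
def template():
    return mm.template_molar()


@pytest.fixture(scope="session")
def small_study():
    """Balanced 6-per-cell study (n = 48), enough for fast statistics."""
    spec = replace(
        mm.default_study_spec(seed=101),
        cell_sizes={(g, s): 6 for g in GROUPS for s in ("F", "M")},
    )
    return mm.generate_study(spec, seed=101)


@pytest.fixture(scope="session")
def small_fit(small_study):
    return mm.gpa(small_study)


@pytest.fixture(scope="session")
def medium_fit():
    """Default-design study (n = 153) and its GPA, shared across tests."""
    ds = mm.generate_study(mm.default_study_spec(seed=202), seed=202)
    return ds, mm.gpa(ds)


def random_rotation(rng):
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
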