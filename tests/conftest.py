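import numpy as np
import pytest

from krpower.design import (
    ObservationPattern,
    StudyDesign,
    UnitGroup,
    compound_symmetry_cov,
)


def oral_cancer_member_design() -> StudyDesign:
    """Worksite cessation trial: 2 arms x (25 clusters of 30 + 15 of 20),
    sd 125 ng/ml, ICC 0.04, 25 ng/ml difference, cell-means coding."""
    sig = compound_symmetry_cov(30, 125.0**2, 0.04)
    pats = (
        ObservationPattern(1, tuple(range(1, 31))),
        ObservationPattern(2, tuple(range(1, 21))),
    )

    def grp(pid, row, count, p_d):
        return UnitGroup(pid, np.tile(np.array(row, float), (p_d, 1)), count)

    groups = (
        grp(1, [1, 0], 25, 30),
        grp(2, [1, 0], 15, 20),
        grp(1, [0, 1], 25, 30),
        grp(2, [0, 1], 15, 20),
    )
    return StudyDesign(
        patterns=pats,
        groups=groups,
        sigma_max=sig,
        beta=[25.0, 0.0],
        C=[[1.0, -1.0]],
        theta0=[0.0],
        alpha=0.05,
        q=2,
        label="oral-cancer",
    )


@pytest.fixture
def oral_design() -> StudyDesign:
    return oral_cancer_member_design()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def random_spd(rng: np.random.Generator, p: int, scale: float = 1.0) -> np.ndarray:
    A = rng.standard_normal((p, p + 2))
    return scale * (A @ A.T / (p + 2) + 0.5 * np.eye(p))
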