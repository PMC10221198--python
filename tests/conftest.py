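import numpy as np
import pytest

from medpatterns import GenerativeTruth, IndicatorMatrix


def make_matrix(values, item_names=None, ids=None) -> IndicatorMatrix:
    values = np.asarray(values)
    if item_names is None:
        item_names = tuple(f"item_{j}" for j in range(values.shape[1]))
    if ids is None:
        ids = np.array([f"S{i}" for i in range(values.shape[0])])
    return IndicatorMatrix(ids, tuple(item_names), values)


@pytest.fixture
def toy_2class():
    """The 4-row, 2-item, 2-class toy: rows 00, 01, 10, 11."""
    data = make_matrix([[0, 0], [0, 1], [1, 0], [1, 1]])
    pi = np.array([0.5, 0.5])
    rho = np.array([[0.1, 0.1], [0.9, 0.9]])
    return data, pi, rho


def small_two_phase_truth(seed: int, shift: float = 0.0, n_subjects: int = 1000):
    """K=2, J=6 two-phase truth; ``shift`` moves phase-2 response
    probabilities by +/-0.3 on the first half of the items (breaking
    measurement invariance when non-zero)."""
    rho1 = np.array([[0.2] * 6, [0.8] * 6])
    rho2 = rho1.copy()
    if shift:
        rho2[0, :3] += shift
        rho2[1, :3] -= shift
    return GenerativeTruth(
        n_subjects=n_subjects,
        class_prevalence=np.array([0.5, 0.5]),
        item_response_p1=rho1,
        item_response_p2=rho2,
        transition_matrix=np.array([[0.8, 0.2], [0.2, 0.8]]),
        seed=seed,
    )


def well_separated_truth(seed: int, n_subjects: int = 3000):
    """Four classes, J=12, each class high (0.9) on its own 3-item block and
    low (0.1) elsewhere: strong separation for selection-consistency checks."""
    rho = np.full((4, 12), 0.1)
    for c in range(4):
        rho[c, 3 * c : 3 * c + 3] = 0.9
    return GenerativeTruth(
        n_subjects=n_subjects,
        class_prevalence=np.array([0.4, 0.3, 0.2, 0.1]),
        item_response_p1=rho,
        item_response_p2=rho,
        transition_matrix=np.full((4, 4), 0.25),
        seed=seed,
    )
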