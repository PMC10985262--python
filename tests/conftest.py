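import numpy as np
import pytest

from danpkit.factor_model import Criterion, Dimension, FactorSystem, bundled_system


@pytest.fixture(scope="session")
def system() -> FactorSystem:
    """The bundled 17-criterion, 3-dimension work-from-home factor system."""
    return bundled_system()


def _make_system(sizes: tuple[int, ...]) -> FactorSystem:
    dims = []
    for o, size in enumerate(sizes, start=1):
        code = f"D{o}"
        crits = tuple(
            Criterion(code=f"D{o}{k}", label=f"criterion {o}.{k}", dimension_code=code)
            for k in range(1, size + 1)
        )
        dims.append(Dimension(code=code, label=f"dimension {o}", criteria=crits))
    return FactorSystem(dimensions=tuple(dims), name="toy")


@pytest.fixture
def small_system() -> FactorSystem:
    """Minimal two-dimension system (2 + 2 criteria)."""
    return _make_system((2, 2))


@pytest.fixture
def make_system():
    """Factory building a toy system with the given per-dimension block sizes."""
    return _make_system


def random_expert_values(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random legal expert matrix: integers 0-4, zero diagonal."""
    values = rng.integers(0, 5, size=(n, n))
    np.fill_diagonal(values, 0)
    return values
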