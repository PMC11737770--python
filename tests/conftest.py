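import numpy as np
import pytest

from cooccur_affinity import TableMargins, Table2x2


@pytest.fixture(scope="session")
def margins_main() -> TableMargins:
    """The running example margins used throughout: mA=50, mB=70, N=150."""
    return TableMargins(50, 70, 150)


@pytest.fixture(scope="session")
def table_main(margins_main) -> Table2x2:
    """The running worked example: X=35 on (50, 70, 150)."""
    return Table2x2(35, margins_main)


@pytest.fixture(scope="session")
def small_margin_sets() -> list[TableMargins]:
    """Assorted margins incl. a boundary-heavy case (mA + mB > N)."""
    return [
        TableMargins(50, 70, 150),
        TableMargins(10, 12, 30),
        TableMargins(5, 5, 12),
        TableMargins(100, 120, 150),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
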