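import numpy as np
import pandas as pd
import pytest

import sobprbe as s


@pytest.fixture(scope="session")
def physics():
    return s.load_fixture_physics("table1")


@pytest.fixture(scope="session")
def sf_table():
    return s.load_fixture_sf()


@pytest.fixture(scope="session")
def lq_fits():
    return s.load_fixture_lq()


@pytest.fixture(scope="session")
def window_sfs(sf_table):
    """Per-column SF means for one cell line / dose label, indexed by column."""

    def _get(cell_line: str, dose_label: str) -> pd.Series:
        sub = sf_table[
            (sf_table["cell_line"] == cell_line) & (sf_table["dose_label"] == dose_label)
        ]
        return sub.set_index("column_index")["sf_mean"]

    return _get


def brute_force_yen(histogram: np.ndarray) -> int:
    """Independent exhaustive evaluation of the entropic-correlation criterion.

    Plain-python scan over all 255 candidate thresholds; deliberately not
    sharing any code with the vectorized implementation.
    """
    h = np.asarray(histogram, dtype=float)
    p = h / h.sum()
    best_t, best = None, -np.inf
    for t in range(255):
        P = p[: t + 1].sum()
        if not 0.0 < P < 1.0:
            continue
        lo = float((p[: t + 1] ** 2).sum())
        hi = float((p[t + 1 :] ** 2).sum())
        if lo <= 0.0 or hi <= 0.0:
            continue
        tc = -np.log(lo * hi) + 2.0 * np.log(P * (1.0 - P))
        if tc > best + 1e-12:
            best, best_t = tc, t
    return best_t


def bisect_isoeffect(sf: float, alpha: float, beta: float, tol: float = 1e-10) -> float:
    """Bisection on D -> alpha*D + beta*D^2 + ln(sf), independent of the closed form."""
    target = -np.log(sf)

    def g(d):
        return alpha * d + beta * d * d - target

    lo, hi = 0.0, 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("no bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
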