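import numpy as np
import pandas as pd
import pytest

from mousebarn.config import SyntheticConfig


def make_stays(rows):
    """Build a stays table from (mouse, sex, box, entry, exit) tuples."""
    return pd.DataFrame(rows, columns=["mouse_id", "sex", "box_id",
                                       "entry", "exit"])


def random_stay_log(rng, n_mice=10, n_boxes=4, n_stays=200, horizon=20000,
                    max_dur=400, integer_times=True):
    """Random valid stay log: per-mouse non-overlapping integer intervals."""
    rows = []
    for m in range(n_mice):
        t = float(rng.integers(0, 50))
        sex = "male" if m % 2 else "female"
        while t < horizon and len(rows) < n_stays * (m + 1) / n_mice:
            dur = float(rng.integers(1, max_dur))
            if not integer_times:
                dur += float(rng.random())
            box = f"B{rng.integers(n_boxes)}"
            rows.append((f"M{m:02d}", sex, box, t, t + dur))
            t = t + dur + float(rng.integers(1, 300))
    return make_stays(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return SyntheticConfig(n_mice=12, n_boxes=4, seed=7)
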