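import datetime

import numpy as np
import pandas as pd
import pytest

from gallwasp.thermal import DailySeries


@pytest.fixture
def make_series():
    """Factory for contiguous daily series: sinusoid + seeded noise."""

    def _make(
        start="2016-01-01",
        days=730,
        base=15.0,
        amplitude=8.0,
        noise_sd=0.0,
        seed=0,
        locality="testloc",
    ):
        idx = pd.date_range(start, periods=days, freq="D")
        doy = idx.dayofyear.to_numpy(dtype=float)
        vals = base + amplitude * np.sin(2 * np.pi * (doy - 105) / 365.0)
        if noise_sd:
            vals = vals + np.random.default_rng(seed).normal(0, noise_sd, days)
        return DailySeries(locality_id=locality, values=pd.Series(vals, index=idx))

    return _make


@pytest.fixture
def dissection_frame():
    """Small hand-written dissection table builder."""

    def _make(rows):
        # rows: list of (bud_id, counts-6-tuple), single locality/cohort/date
        records = []
        for bud, counts in rows:
            rec = {
                "locality": "A",
                "cohort": 2016,
                "date": "2016-07-01",
                "bud_id": bud,
            }
            rec.update(
                dict(zip(("egg", "l1", "l2", "l3", "pupa", "adult"), counts))
            )
            records.append(rec)
        return pd.DataFrame(records)

    return _make
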