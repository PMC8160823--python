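import numpy as np
import pandas as pd
import pytest

from epistab import DesignColumns, RespondentTable


def make_table(df: pd.DataFrame, roles: dict | None = None) -> RespondentTable:
    """Wrap a plain DataFrame, defaulting unlisted columns to 'auxiliary'."""
    base = {c: "auxiliary" for c in df.columns}
    dc = DesignColumns()
    for c in dc.as_tuple():
        if c in df.columns:
            base[c] = "design"
    if roles:
        base.update(roles)
    return RespondentTable(df, base, dc)


@pytest.fixture
def srs_design_frame():
    """Design columns for a simple random sample: one stratum, every record
    its own PSU, unit weights."""

    def _make(n: int) -> dict:
        return {
            "stratum": np.repeat("s0", n),
            "psu": np.array([f"p{i}" for i in range(n)]),
            "weight": np.ones(n),
            "year": np.repeat("2016", n),
        }

    return _make
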