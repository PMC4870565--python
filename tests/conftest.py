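import numpy as np
import pandas as pd
import pytest

from stoolmark import OtuTable, SimSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One default-condition cohort shared by read-only tests."""
    return simulate_cohort(SimSpec(seed=42))


@pytest.fixture
def tiny_table():
    data = pd.DataFrame(
        [[10, 0, 5], [20, 0, 15]],
        index=["S1", "S2"],
        columns=["OTU_A", "OTU_B", "OTU_C"],
    )
    tax = pd.Series(
        [
            "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales",
            "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales",
            "k__Bacteria;p__Bacteroidetes",
        ],
        index=data.columns,
    )
    return OtuTable(data=data, taxonomy=tax, kind="counts")


def brute_force_auc(values, is_case) -> float:
    """Independent pair-counting oracle: (concordant + 0.5*tied) / (n1*n0)."""
    values = np.asarray(values, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    cases = values[is_case]
    ctrls = values[~is_case]
    conc = sum((c > d) + 0.5 * (c == d) for c in cases for d in ctrls)
    return conc / (len(cases) * len(ctrls))
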