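import numpy as np
import pandas as pd
import pytest

from gutshift.tables import CountTable


@pytest.fixture
def toy_table() -> CountTable:
    """Five samples with depths (5k, 12k, 15k, 8k, 30k) over four taxa."""
    rng = np.random.default_rng(7)
    depths = [5_000, 12_000, 15_000, 8_000, 30_000]
    cols = [rng.multinomial(d, [0.4, 0.3, 0.2, 0.1]) for d in depths]
    return CountTable(np.column_stack(cols),
                      [f"t{i}" for i in range(4)],
                      [f"s{i + 1}" for i in range(5)])


@pytest.fixture
def toy_metadata() -> pd.DataFrame:
    rows = []
    for animal, group in [("a1", "CON"), ("a2", "ABX")]:
        for day in (-6, -4, 0, 4, 10):
            rows.append({"sample_id": f"{animal}_d{day}", "animal_id": animal,
                         "group": group, "day": day})
    return pd.DataFrame(rows)
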