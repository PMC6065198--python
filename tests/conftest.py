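import numpy as np
import pandas as pd
import pytest

from devstab.morphometry import LEFT, RIGHT


@pytest.fixture
def hand_anova_values() -> np.ndarray:
    """Worked two-individual example with known mean squares.

    ind1: left (10.0, 10.2), right (10.4, 10.6);
    ind2: left (11.0, 11.2), right (10.8, 11.0).
    MS_side=0.02, MS_individual=0.98, MS_interaction=0.18, MS_error=0.02
    on dfs (1, 1, 1, 4); FA10 = 0.08, interaction F = 9.
    """
    return np.array(
        [[[10.0, 10.2], [10.4, 10.6]],
         [[11.0, 11.2], [10.8, 11.0]]]
    )


def tidy_sizes(values: np.ndarray, genotype: str = "g") -> pd.DataFrame:
    """(n, 2, M) value array -> tidy SizeMeasure table."""
    n, s, m = values.shape
    rows = []
    for i in range(n):
        for j, side in enumerate((LEFT, RIGHT)):
            for k in range(m):
                rows.append(
                    {
                        "genotype": genotype,
                        "individual": f"ind{i + 1}",
                        "side": side,
                        "session": k + 1,
                        "trait": "t",
                        "value": values[i, j, k],
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def hand_anova_table(hand_anova_values) -> pd.DataFrame:
    return tidy_sizes(hand_anova_values)
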