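"""Shared fixtures for the reactionome test suite.

All randomness is pinned; heavy model fits are confined to the
acceptance tests.  Oracles used in the unit tests are implemented inline
from first principles (textbook formulas, brute-force loops, or a
different library) so they stay independent of the package code paths
they check.
"""

import numpy as np
import pandas as pd
import pytest

from reactionome import synthetic


@pytest.fixture(scope="session")
def meta96():
    """Default factorial design (deterministic layout, seeded sex)."""
    return synthetic.generate_design(seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny synthetic panel: 2 genes per category, default design."""
    design = synthetic.generate_design(seed=11)
    truths = synthetic.default_truth_panel(n_genes_per_category=2, seed=11)
    return synthetic.generate_counts(design, truths, seed=11)


def balanced_meta(n):
    """Minimal balanced metadata with population/temperature/sex/family."""
    pops = np.tile(["Finland", "Spain"], (n + 1) // 2)[:n]
    temps = np.tile([25, 25, 34, 34], (n + 3) // 4)[:n]
    sexes = np.tile(["female", "male", "male", "female",
                     "male", "female", "female", "male"], (n + 7) // 8)[:n]
    fams = np.array([f"f{i % 8}" for i in range(n)])
    return pd.DataFrame({"population": pops, "temperature": temps,
                         "sex": sexes, "family": fams})
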