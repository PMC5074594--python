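import numpy as np
import pandas as pd
import pytest

from mirnafeat.features import FEATURE_NAMES, FeatureTable, extract_table
from mirnafeat.synthetic import generate_cohorts


def random_nested_structure(rng: np.random.Generator, max_len: int = 60) -> str:
    """Random nested dot-bracket string (possibly with multiloops)."""
    length = int(rng.integers(1, max_len))
    out = []
    depth = 0
    for _ in range(length):
        r = rng.random()
        if r < 0.35:
            out.append("(")
            depth += 1
        elif r < 0.7 and depth > 0:
            out.append(")")
            depth -= 1
        else:
            out.append(".")
    out.extend(")" * depth)
    return "".join(out)


def brute_force_elements(db: str):
    """Independent element walker used as an oracle for decompose().

    Stacks are counted directly as adjacent pair-steps; helices as
    connected components of the stacking relation between pairs.
    """
    stack, pairs = [], []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.append((stack.pop(), i))
    pairs = sorted(pairs)
    pair_set = set(pairs)
    n_stack = sum(1 for (i, j) in pairs if (i + 1, j - 1) in pair_set)
    # helices = components of the "stacked neighbour" graph over pairs
    parent = {p: p for p in pairs}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for (i, j) in pairs:
        if (i + 1, j - 1) in pair_set:
            parent[find((i, j))] = find((i + 1, j - 1))
    n_helix = len({find(p) for p in pairs})
    return len(pairs), n_helix, n_stack


def make_table(columns: dict, labels, rng: np.random.Generator | None = None) -> FeatureTable:
    """FeatureTable with the given columns planted and all remaining
    catalog columns filled with independent N(0,1) noise."""
    labels = pd.Series(list(labels))
    n = len(labels)
    rng = rng or np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(size=(n, len(FEATURE_NAMES))), columns=list(FEATURE_NAMES)
    )
    for name, col in columns.items():
        values[name] = np.asarray(col, dtype=float)
    values.index = pd.Index([f"r{i}" for i in range(n)], name="id")
    labels.index = values.index
    return FeatureTable(values=values, labels=labels)


@pytest.fixture(scope="session")
def default_cohorts():
    return generate_cohorts(seed=1)


@pytest.fixture(scope="session")
def default_table(default_cohorts):
    return extract_table(default_cohorts)
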