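import numpy as np
import pandas as pd
import pytest

from famscout.matrix import FamilyCountMatrix, PathwayMap


@pytest.fixture
def toy_matrix() -> FamilyCountMatrix:
    counts = pd.DataFrame(
        [[1, 0, 2, 0], [0, 3, 0, 1], [4, 1, 0, 0]],
        index=pd.Index(["spA", "spB", "spC"], name="species"),
        columns=["37M4G", "37R7W", "37Z74", "37MT6"],
    )
    totals = pd.Series([20000, 18000, 25000], index=counts.index, name="total_genes")
    return FamilyCountMatrix(counts, totals)


@pytest.fixture
def toy_pathway() -> PathwayMap:
    return PathwayMap({"K10775": ["37M4G", "37R7W", "37Z74"], "K13232": ["37MT6"]})


def brute_force_inverse(seq_ids, rows):
    """Independent rarity oracle: explicit double loop over sequences.

    For each non-gap cell, count matching residues across all sequences at
    that column (gaps never match), and return N - count; gap cells get 0.
    """
    N = len(rows)
    L = len(rows[0]) if rows else 0
    inverse = np.zeros((N, L), dtype=int)
    for s in range(N):
        for p in range(L):
            res = rows[s][p]
            if res == "-":
                continue
            count = 0
            for t in range(N):
                if rows[t][p] == res:
                    count += 1
            inverse[s, p] = N - count
    return inverse


def random_alignment(rng, max_n=8, max_len=50, gap_prob=0.15, alphabet="ACDEFG"):
    n = int(rng.integers(1, max_n + 1))
    L = int(rng.integers(1, max_len + 1))
    letters = np.array(list(alphabet) + ["-"])
    probs = np.full(len(letters), (1 - gap_prob) / (len(letters) - 1))
    probs[-1] = gap_prob
    rows = [
        "".join(rng.choice(letters, size=L, p=probs)) for _ in range(n)
    ]
    ids = [f"s{i}" for i in range(n)]
    return ids, rows
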