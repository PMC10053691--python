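"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (double loops, straight from
the defining formulas) and independent of the package's vectorized
code paths.
"""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd
import pytest
import skbio

from phyloassembly.io import CommunityMatrix


@pytest.fixture
def four_tip_tree() -> skbio.TreeNode:
    """Smallest balanced tree: d(A,B)=2, d(A,C)=4."""
    return skbio.TreeNode.read(_io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture
def four_tip_ids_d(four_tip_tree):
    from phyloassembly.turnover import cophenetic_distances

    return cophenetic_distances(four_tip_tree)


@pytest.fixture
def toy_counts() -> CommunityMatrix:
    df = pd.DataFrame(
        [[6, 2, 0], [2, 2, 2]],
        index=["S1", "S2"],
        columns=["A", "B", "C"],
    )
    return CommunityMatrix(df)


def beta_mntd_brute(
    a, b, d, weighting: str = "abundance", conspecifics: str = "include"
) -> float:
    """Naive double-loop betaMNTD straight from the definition.

    0.5 * [sum_i f_i * min_j d_ij + sum_j f_j * min_i d_ij], minima over
    the other community's taxa; under conspecifics="exclude" the taxon
    itself is removed from the candidate set and the weights are
    renormalized over taxa that retain a candidate.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)

    def side(src, tgt):
        pres_t = [j for j in range(len(tgt)) if tgt[j] > 0]
        terms = []
        for i in range(len(src)):
            if src[i] <= 0:
                continue
            cands = pres_t if conspecifics == "include" else [
                j for j in pres_t if j != i
            ]
            if not cands:
                continue
            ntd = min(d[i][j] for j in cands)
            w = 1.0 if weighting == "presence" else src[i]
            terms.append((w, ntd))
        tot = sum(w for w, _ in terms)
        return sum(w * ntd for w, ntd in terms) / tot

    return 0.5 * (side(a, b) + side(b, a))


def bray_curtis_brute(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    num = sum(min(x, y) for x, y in zip(a, b))
    return 1.0 - 2.0 * num / (a.sum() + b.sum())


def random_instance(rng, n_taxa_max=16):
    """A random small community pair + ultrametric-free random tree distances."""
    from phyloassembly.simulate import simulate_tree
    from phyloassembly.turnover import cophenetic_distances

    n = int(rng.integers(3, n_taxa_max + 1))
    tree = simulate_tree(n, rng.integers(2**31))
    ids, d = cophenetic_distances(tree)
    a = rng.integers(0, 5, size=n).astype(float)
    b = rng.integers(0, 5, size=n).astype(float)
    if a.sum() == 0:
        a[int(rng.integers(n))] = 1
    if b.sum() == 0:
        b[int(rng.integers(n))] = 1
    return a / a.sum(), b / b.sum(), d
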