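"""Phylogenetic turnover between communities: betaMNTD and betaNTI.

The between-sample mean nearest taxon distance (betaMNTD) is the
abundance-weighted mean, over the taxa of each community, of the
phylogenetic (patristic) distance to the nearest taxon in the other
community.  betaNTI is its z-score against a null distribution obtained
by shuffling the tips of the phylogeny across the regional taxon pool,
which randomizes which taxa carry abundance while preserving the
distribution of phylogenetic distances.  betaNTI < -2 marks
lower-than-random phylogenetic turnover (homogeneous selection),
betaNTI > +2 higher-than-random turnover (variable selection).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import skbio


class UndefinedZScoreError(ValueError):
    """Null distribution has zero spread; the z-score is undefined."""


def cophenetic_distances(tree: skbio.TreeNode) -> tuple[list[str], np.ndarray]:
    """Patristic tip-tip distance matrix.

    Returns the tip identifiers (tree tip order) and the dense symmetric
    matrix of branch-length path sums, zero on the diagonal.
    """
    tips = list(tree.tips())
    if len(tips) == 1:
        return [tips[0].name], np.zeros((1, 1))
    dm = tree.tip_tip_distances()
    return list(dm.ids), np.asarray(dm.data, dtype=float)


def _nearest_taxon_distances(
    sub: np.ndarray, self_mask: np.ndarray | None
) -> np.ndarray:
    """Row minima of a distance block, optionally masking self-matches."""
    if self_mask is not None and self_mask.any():
        sub = np.where(self_mask, np.inf, sub)
    return sub.min(axis=-1)


def beta_mntd(
    a: np.ndarray,
    b: np.ndarray,
    d: np.ndarray,
    weighting: str = "abundance",
    conspecifics: str = "include",
) -> float:
    """Abundance-weighted betaMNTD between two communities.

    ``a`` and ``b`` are abundance vectors over the same taxon pool as
    ``d`` (the cophenetic matrix).  With ``conspecifics="include"`` a
    taxon present in both communities has nearest-taxon distance zero;
    with ``"exclude"`` the minimum is taken over the other community's
    taxa minus itself and weights are renormalized over the taxa that
    retain a defined distance.  ``weighting="presence"`` gives every
    present taxon equal weight.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ia = np.flatnonzero(a > 0)
    ib = np.flatnonzero(b > 0)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty community: betaMNTD undefined")
    if conspecifics not in ("include", "exclude"):
        raise ValueError(f"unknown conspecifics mode {conspecifics!r}")

    def one_side(src, isrc, itgt):
        sub = d[np.ix_(isrc, itgt)]
        mask = None
        if conspecifics == "exclude":
            mask = isrc[:, None] == itgt[None, :]
            valid = ~mask.all(axis=1)
        else:
            valid = np.ones(isrc.size, dtype=bool)
        if not valid.any():
            return np.nan
        ntd = _nearest_taxon_distances(sub[valid], None if mask is None else mask[valid])
        if weighting == "presence":
            w = np.ones(valid.sum())
        else:
            w = src[isrc][valid]
        w = w / w.sum()
        return float(ntd @ w)

    side_a = one_side(a, ia, ib)
    side_b = one_side(b, ib, ia)
    if np.isnan(side_a) or np.isnan(side_b):
        raise ValueError("no taxon with a defined nearest-neighbor distance")
    return 0.5 * (side_a + side_b)


def tip_permutations(n_taxa: int, n_reps: int, seed) -> np.ndarray:
    """Deterministic stream of tip-label permutations, one row per null
    replicate.  ``seed`` may be an int or a numpy SeedSequence/Generator."""
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n_taxa) for _ in range(n_reps)])


@dataclass
class PairTurnover:
    sample_a: str
    sample_b: str
    beta_mntd_obs: float
    null_mean: float
    null_sd: float
    beta_nti: float
    n_reps: int


def _pair_beta_nti(
    fa: np.ndarray,
    fb: np.ndarray,
    d: np.ndarray,
    perms: np.ndarray,
    conspecifics: str,
    weighting: str,
    chunk: int = 200,
) -> tuple[float, float, float]:
    """Observed betaMNTD plus null mean/sd under the tip-shuffle null.

    A permutation relabels the whole pool, so the co-occurrence pattern
    of the pair (which taxa are shared) is preserved; for the exclude
    mode the self-match mask is therefore identical across replicates.
    """
    ia = np.flatnonzero(fa > 0)
    ib = np.flatnonzero(fb > 0)
    obs = beta_mntd(fa, fb, d, weighting=weighting, conspecifics=conspecifics)

    def side_weights(src, isrc, itgt):
        mask = None
        if conspecifics == "exclude":
            mask = isrc[:, None] == itgt[None, :]
            valid = ~mask.all(axis=1)
            isrc = isrc[valid]
            mask = mask[valid]
        if weighting == "presence":
            w = np.ones(isrc.size)
        else:
            w = src[isrc]
        return isrc, itgt, mask, w / w.sum()

    sides = [side_weights(fa, ia, ib), side_weights(fb, ib, ia)]
    nulls = np.zeros(perms.shape[0])
    for start in range(0, perms.shape[0], chunk):
        P = perms[start : start + chunk]
        total = np.zeros(P.shape[0])
        for isrc, itgt, mask, w in sides:
            rows = P[:, isrc]
            cols = P[:, itgt]
            sub = d[rows[:, :, None], cols[:, None, :]]
            if mask is not None and mask.any():
                sub = np.where(mask[None, :, :], np.inf, sub)
            total += sub.min(axis=2) @ w
        nulls[start : start + chunk] = 0.5 * total
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    return obs, mean, sd


def beta_nti(
    a: np.ndarray,
    b: np.ndarray,
    d: np.ndarray,
    n_reps: int = 999,
    seed: int = 0,
    conspecifics: str = "include",
    weighting: str = "abundance",
    permutations: np.ndarray | None = None,
) -> PairTurnover:
    """betaNTI for a single community pair.

    The null shuffles tip labels across the whole taxon pool spanned by
    ``d`` (regional randomization); the z-score uses the sample standard
    deviation (ddof=1) of the null betaMNTD values.
    """
    if permutations is None:
        if n_reps < 99:
            raise ValueError("n_reps must be >= 99")
        permutations = tip_permutations(d.shape[0], n_reps, seed)
    obs, mean, sd = _pair_beta_nti(
        np.asarray(a, float), np.asarray(b, float), d, permutations,
        conspecifics, weighting,
    )
    if sd == 0:
        raise UndefinedZScoreError("null betaMNTD distribution has zero sd")
    return PairTurnover(
        "a", "b", obs, mean, sd, (obs - mean) / sd, permutations.shape[0]
    )


def group_beta_nti(
    rel: pd.DataFrame,
    d: np.ndarray,
    taxon_ids: list[str],
    n_reps: int = 999,
    seed: int = 0,
    conspecifics: str = "include",
    weighting: str = "abundance",
    permutations: np.ndarray | None = None,
) -> pd.DataFrame:
    """betaNTI for every unordered sample pair within one group.

    ``rel`` is the group's sample x ASV relative-abundance table, with
    columns matching ``taxon_ids`` (the order of ``d``).  All pairs share
    the same null permutation stream, so a later phyloscore pass with the
    same stream is internally consistent.  Pairs involving an empty
    sample are skipped.  Pair order is lexicographic by sample id.
    """
    if list(rel.columns) != list(taxon_ids):
        rel = rel.reindex(columns=taxon_ids, fill_value=0.0)
    if permutations is None:
        permutations = tip_permutations(len(taxon_ids), n_reps, seed)
    X = rel.to_numpy(dtype=float)
    names = list(rel.index)
    order = np.argsort(names)
    rows = []
    for i, j in combinations(order, 2):
        fa, fb = X[i], X[j]
        if fa.sum() == 0 or fb.sum() == 0:
            continue
        obs, mean, sd = _pair_beta_nti(
            fa, fb, d, permutations, conspecifics, weighting
        )
        if sd == 0:
            raise UndefinedZScoreError(
                f"zero null sd for pair ({names[i]}, {names[j]})"
            )
        rows.append(
            {
                "sample_a": names[i],
                "sample_b": names[j],
                "beta_mntd_obs": obs,
                "null_mean": mean,
                "null_sd": sd,
                "beta_nti": (obs - mean) / sd,
                "n_reps": permutations.shape[0],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_a", "sample_b", "beta_mntd_obs",
            "null_mean", "null_sd", "beta_nti", "n_reps",
        ],
    )
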