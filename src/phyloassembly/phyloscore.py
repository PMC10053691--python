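"""Per-ASV phyloscores.

For a sample pair, every ASV present in exactly one of the two
communities gets a nearest-taxon distance (NTD): the smallest patristic
distance to any ASV of the other community.  Its phyloscore for that
pair is the z-score of the observed NTD against the same tip-shuffle
null used for betaNTI.  An ASV's total phyloscore is the sum of its
phyloscores over all pairs of the group; consistently negative totals
mark taxa whose close relatives recur across communities more often
than chance — the per-taxon signature of homogeneous selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .turnover import tip_permutations

logger = logging.getLogger(__name__)


@dataclass
class PhyloscoreTable:
    """Phyloscores for one analysis group.

    ``totals``: per-ASV total phyloscore (sum over scored pairs).
    ``n_pairs_scored``: number of pairs contributing to each total.
    ``pair_scores``: long-format (asv, sample_a, sample_b, z) table.
    ``n_degenerate``: cells dropped because the null sd was zero.
    """

    totals: pd.Series
    n_pairs_scored: pd.Series
    pair_scores: pd.DataFrame
    n_degenerate: int = 0
    extras: dict = field(default_factory=dict)


def asv_phyloscores(
    rel: pd.DataFrame,
    d: np.ndarray,
    taxon_ids: list[str],
    n_reps: int = 999,
    seed: int = 0,
    permutations: np.ndarray | None = None,
    keep_pair_scores: bool = True,
    chunk: int = 200,
) -> PhyloscoreTable:
    """Phyloscores for every ASV over every sample pair of a group.

    ``rel`` is the group's sample x ASV abundance table (only presence
    matters here); columns must match ``taxon_ids``, the order of the
    cophenetic matrix ``d``.  Passing the betaNTI ``permutations``
    reuses the same null stream, keeping both statistics internally
    consistent.  Only ASVs present in exactly one community of a pair
    are scored.
    """
    if list(rel.columns) != list(taxon_ids):
        rel = rel.reindex(columns=taxon_ids, fill_value=0.0)
    if permutations is None:
        if n_reps < 99:
            raise ValueError("n_reps must be >= 99")
        permutations = tip_permutations(len(taxon_ids), n_reps, seed)
    X = rel.to_numpy(dtype=float) > 0
    names = list(rel.index)
    order = np.argsort(names)
    n_taxa = len(taxon_ids)
    totals = np.zeros(n_taxa)
    n_scored = np.zeros(n_taxa, dtype=np.int64)
    degenerate = 0
    records = []
    R = permutations.shape[0]
    for i, j in combinations(order, 2):
        pa, pb = X[i], X[j]
        if not pa.any() or not pb.any():
            continue
        for isrc, itgt in (
            (np.flatnonzero(pa & ~pb), np.flatnonzero(pb)),
            (np.flatnonzero(pb & ~pa), np.flatnonzero(pa)),
        ):
            if isrc.size == 0:
                continue
            obs = d[np.ix_(isrc, itgt)].min(axis=1)
            null_sum = np.zeros(isrc.size)
            null_sq = np.zeros(isrc.size)
            for start in range(0, R, chunk):
                P = permutations[start : start + chunk]
                sub = d[P[:, isrc][:, :, None], P[:, itgt][:, None, :]]
                mins = sub.min(axis=2)
                null_sum += mins.sum(axis=0)
                null_sq += (mins**2).sum(axis=0)
            mean = null_sum / R
            var = (null_sq - R * mean**2) / (R - 1)
            sd = np.sqrt(np.maximum(var, 0.0))
            ok = sd > 0
            degenerate += int((~ok).sum())
            z = np.full(isrc.size, np.nan)
            z[ok] = (obs[ok] - mean[ok]) / sd[ok]
            totals[isrc[ok]] += z[ok]
            n_scored[isrc[ok]] += 1
            if keep_pair_scores:
                for k, asv_idx in enumerate(isrc):
                    if ok[k]:
                        records.append(
                            (taxon_ids[asv_idx], names[i], names[j], z[k])
                        )
    if degenerate:
        logger.warning("%d (asv, pair) phyloscore cells had zero null sd", degenerate)
    idx = pd.Index(taxon_ids, name="asv_id")
    return PhyloscoreTable(
        totals=pd.Series(totals, index=idx, name="total_phyloscore"),
        n_pairs_scored=pd.Series(n_scored, index=idx, name="n_pairs_scored"),
        pair_scores=pd.DataFrame(
            records, columns=["asv_id", "sample_a", "sample_b", "phyloscore"]
        ),
        n_degenerate=degenerate,
    )
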