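"""Phylofactorization of total phyloscores, consensus taxonomy, and
cross-group categorization of taxa under homogeneous selection.

Phylofactorization walks the edges of the phylogeny: each edge splits
the current set of taxa into a candidate clade and its outgroup, and a
two-sample contrast on the taxa's total phyloscores scores the split.
The most contrasting edge (largest |statistic|) is accepted as a factor
if its Bonferroni-adjusted p-value clears the significance level; the
clade is then set aside and the procedure recurses on the remaining
bins.  Factors whose clade mean is below the outgroup mean
(direction="lower") are the clades under homogeneous selection (HoS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy import stats

from .io import RANKS


@dataclass
class HoSClade:
    """One phylofactorization factor."""

    clade_id: int
    factor_index: int
    asv_members: frozenset
    contrast_stat: float
    contrast_p: float          # Bonferroni-adjusted within the step
    contrast_p_raw: float
    direction: str             # "lower" | "higher"
    n_asvs: int
    n_outgroup: int
    consensus_name: str | None = None
    consensus_rank: str | None = None


def _candidate_splits(tip_sets: list[frozenset], bin_tips: frozenset):
    """Unique proper nonempty clade sides within one bin.

    Tip sets of tree nodes form a laminar family; intersecting with the
    bin yields exactly the descendant sets of the bin's induced subtree.
    """
    seen = set()
    for ts in tip_sets:
        s = ts & bin_tips
        if s and len(s) < len(bin_tips) and s not in seen:
            seen.add(s)
            yield s


def _contrast(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    """Two-sample contrast of clade vs outgroup scores.

    Default is Student's pooled-variance t: as a max-|t| selection
    objective it is robust, whereas Welch's statistic explodes for tiny
    clades of near-identical scores (within-clade variance near zero)
    and factorization then extracts minuscule subclades.
    """
    if method == "student":
        res = stats.ttest_ind(x, y, equal_var=True)
    elif method == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
    elif method == "wilcoxon":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        # convert U to its normal-approximation z so that the statistic is
        # signed and magnitude-comparable across candidate edges
        n1, n2 = len(x), len(y)
        mu = n1 * n2 / 2.0
        sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        z = (res.statistic - mu) / sd if sd > 0 else 0.0
        return float(z), float(res.pvalue)
    else:
        raise ValueError(f"unknown contrast method {method!r}")
    return float(res.statistic), float(res.pvalue)


def phylofactorize(
    tree: skbio.TreeNode,
    total_phyloscores: pd.Series,
    alpha: float = 0.001,
    min_clade: int = 2,
    max_factors: int | None = None,
    method: str = "student",
) -> list[HoSClade]:
    """Extract clades with significantly contrasting total phyloscores.

    Iterative: every edge of each active bin's induced subtree is tested
    (clade vs outgroup contrast, pooled-variance t by default); the edge with the
    largest |statistic| is accepted when its p-value, Bonferroni-adjusted
    by the number of edges tested in the step, is below ``alpha``.  The
    accepted clade is frozen (factor clades are disjoint); its outgroup
    remainder stays an active bin.  Edges whose clade side has fewer than
    ``min_clade`` members, or with degenerate variance, are skipped.
    """
    scores = total_phyloscores.dropna()
    ids = set(scores.index)
    tip_sets = []
    for node in tree.traverse(include_self=True):
        if not node.is_tip():
            ts = frozenset(t.name for t in node.tips()) & ids
            if ts:
                tip_sets.append(frozenset(ts))
    bins = [frozenset(scores.index)]
    factors: list[HoSClade] = []
    while bins:
        if max_factors is not None and len(factors) >= max_factors:
            break
        best = None
        n_tested = 0
        for b, bin_tips in enumerate(bins):
            for clade in _candidate_splits(tip_sets, bin_tips):
                if len(clade) < min_clade:
                    continue
                out = bin_tips - clade
                x = scores[list(clade)].to_numpy()
                y = scores[list(out)].to_numpy()
                if x.size < 2 or y.size < 2:
                    continue
                if np.var(x) == 0 and np.var(y) == 0:
                    continue
                stat, p = _contrast(x, y, method)
                if not np.isfinite(stat):
                    continue
                n_tested += 1
                if best is None or abs(stat) > abs(best[0]):
                    best = (stat, p, b, clade, float(x.mean()), float(y.mean()))
        if best is None:
            break
        stat, p_raw, b, clade, mean_in, mean_out = best
        p_adj = min(1.0, p_raw * n_tested)
        if p_adj >= alpha:
            break
        outgroup = bins[b] - clade
        factors.append(
            HoSClade(
                clade_id=len(factors) + 1,
                factor_index=len(factors) + 1,
                asv_members=clade,
                contrast_stat=stat,
                contrast_p=p_adj,
                contrast_p_raw=p_raw,
                direction="lower" if mean_in < mean_out else "higher",
                n_asvs=len(clade),
                n_outgroup=len(outgroup),
            )
        )
        bins.pop(b)
        if len(outgroup) >= 2:
            bins.append(outgroup)
    return factors


def hos_filter(factors: list[HoSClade]) -> list[HoSClade]:
    """Clades under homogeneous selection: direction="lower" only."""
    return [f for f in factors if f.direction == "lower"]


def consensus_taxonomy(
    members,
    taxonomy: pd.DataFrame,
    agreement: float = 0.8,
) -> tuple[str | None, str | None]:
    """Deepest rank at which >= ``agreement`` of the clade's classified
    members share one name.  Returns (name, rank); ("Unclassified", None)
    when no member has any classification."""
    sub = taxonomy.reindex([m for m in members if m in taxonomy.index])
    if sub.empty or sub.isna().all().all():
        return "Unclassified", None
    for rank in reversed(RANKS):
        col = sub[rank].dropna()
        col = col[col != ""]
        if col.empty:
            continue
        counts = col.value_counts()
        top = counts.iloc[0]
        if top / len(col) >= agreement:
            return str(counts.index[0]), rank
    return "Unclassified", None


def annotate_clades(
    factors: list[HoSClade], taxonomy: pd.DataFrame, agreement: float = 0.8
) -> list[HoSClade]:
    for f in factors:
        name, rank = consensus_taxonomy(f.asv_members, taxonomy, agreement)
        f.consensus_name, f.consensus_rank = name, rank
    return factors


def clades_table(
    factors: list[HoSClade], report_min_clade: int | None = None
) -> pd.DataFrame:
    """Flat clade table; ``report_min_clade`` applies the display rule of
    keeping only clades with more than that many members."""
    rows = [
        {
            "clade_id": f.clade_id,
            "factor_index": f.factor_index,
            "n_asvs": f.n_asvs,
            "direction": f.direction,
            "contrast_stat": f.contrast_stat,
            "contrast_p": f.contrast_p,
            "contrast_p_raw": f.contrast_p_raw,
            "consensus_taxonomy": f.consensus_name,
            "consensus_rank": f.consensus_rank,
        }
        for f in factors
        if report_min_clade is None or f.n_asvs > report_min_clade
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "clade_id", "factor_index", "n_asvs", "direction",
            "contrast_stat", "contrast_p", "contrast_p_raw",
            "consensus_taxonomy", "consensus_rank",
        ],
    )


def membership_table(factors: list[HoSClade]) -> pd.DataFrame:
    rows = [
        {"asv_id": a, "clade_id": f.clade_id, "direction": f.direction}
        for f in factors
        for a in sorted(f.asv_members)
    ]
    return pd.DataFrame(rows, columns=["asv_id", "clade_id", "direction"])


def presence_categories(
    hos_asvs_group1: set,
    hos_asvs_group2: set,
    all_asvs: set,
    labels: tuple[str, str] = ("group1", "group2"),
) -> pd.DataFrame:
    """Partition taxa by where they carry the homogeneous-selection signal.

    Categories: exclusive to group 1, exclusive to group 2, shared
    (under HoS in both), or none.  Percentages are of the HoS union.
    """
    g1, g2 = set(hos_asvs_group1), set(hos_asvs_group2)
    union = g1 | g2
    rows = []
    for asv in sorted(all_asvs | union):
        if asv in g1 and asv in g2:
            cat = "shared"
        elif asv in g1:
            cat = f"{labels[0]}_exclusive"
        elif asv in g2:
            cat = f"{labels[1]}_exclusive"
        else:
            cat = "none"
        rows.append({"asv_id": asv, "category": cat})
    df = pd.DataFrame(rows, columns=["asv_id", "category"])
    n_union = len(union)
    counts = df[df.category != "none"]["category"].value_counts()
    df.attrs["summary"] = {
        cat: {
            "n": int(n),
            "percent_of_union": 100.0 * n / n_union if n_union else float("nan"),
        }
        for cat, n in counts.items()
    }
    return df
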