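"""Assembly-process classification of sample pairs.

The two-step decision rule of the null-model framework: the
phylogenetic signal (betaNTI) decides selection, and for pairs inside
the [-2, 2] window the compositional signal (RC_Bray) separates the
dispersal processes from drift.  Thresholds use strict inequalities
("lower than -2", "higher than +0.95"), so boundary values fall to the
stochastic interior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PROCESSES = (
    "homogeneous_selection",
    "variable_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "drift",
)


@dataclass(frozen=True)
class Thresholds:
    """Classification cutoffs; defaults are the framework's standard values."""

    beta_nti: float = 2.0
    rc_bray: float = 0.95
    drift_label: str = "drift"


def classify_pair(
    beta_nti: float,
    rc_bray: float | None = None,
    thresholds: Thresholds = Thresholds(),
) -> str:
    """Assign one (betaNTI, RC_Bray) pair to an assembly process.

    RC_Bray may be omitted only when |betaNTI| >= threshold, where the
    selection verdict does not depend on it.
    """
    t = thresholds
    if beta_nti < -t.beta_nti:
        return "homogeneous_selection"
    if beta_nti > t.beta_nti:
        return "variable_selection"
    if rc_bray is None or (isinstance(rc_bray, float) and np.isnan(rc_bray)):
        raise ValueError("RC_Bray required when |betaNTI| is within the threshold")
    if rc_bray < -t.rc_bray:
        return "homogenizing_dispersal"
    if rc_bray > t.rc_bray:
        return "dispersal_limitation"
    return t.drift_label


def classify_pairs(
    turnover: pd.DataFrame,
    composition: pd.DataFrame | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Merge betaNTI and RC_Bray tables and classify every pair.

    ``turnover`` needs columns sample_a, sample_b, beta_nti;
    ``composition`` (optional) sample_a, sample_b, rc_bray.  RC_Bray is
    left missing for pairs decided by betaNTI alone.
    """
    df = turnover.copy()
    if composition is not None and not composition.empty:
        df = df.merge(
            composition[["sample_a", "sample_b", "rc_bray", "bray_curtis_obs"]],
            on=["sample_a", "sample_b"],
            how="left",
        )
    else:
        df["rc_bray"] = np.nan
    df["process"] = [
        classify_pair(
            row.beta_nti,
            None if pd.isna(row.rc_bray) else float(row.rc_bray),
            thresholds,
        )
        for row in df.itertuples()
    ]
    return df


def pairs_needing_rc(
    turnover: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> list[tuple[str, str]]:
    """Sample pairs whose classification requires RC_Bray (|betaNTI| within
    the selection threshold)."""
    inside = turnover["beta_nti"].abs() <= thresholds.beta_nti
    return [
        (a, b)
        for a, b in zip(
            turnover.loc[inside, "sample_a"], turnover.loc[inside, "sample_b"]
        )
    ]


def summarize_group(classified: pd.DataFrame, group: str = "") -> pd.DataFrame:
    """Per-process counts and proportions for one group of pairs."""
    n = len(classified)
    rows = []
    counts = classified["process"].value_counts() if n else {}
    for proc in PROCESSES:
        c = int(counts.get(proc, 0)) if n else 0
        rows.append(
            {
                "group": group,
                "process": proc,
                "n_pairs": c,
                "proportion": c / n if n else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_pairs_total"] = n
    return out
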