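"""High-content siRNA screen statistics: z-scores against all wells of a
readout, per-target t-tests against the pooled non-targeting control,
readout-specific hit thresholds and multi-readout intersection counts.

Well tables are pandas DataFrames with columns
``target, readout, replicate, percent_positive``; the non-targeting control
is the target named ``NTC``. The EdU readout is tested two-sided and a hit
additionally requires a *decreased* mean (delayed S-phase progression); the
two pKAP1 readouts are tested one-sided for an *increase* in the percentage
of positive cells over the control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "READOUTS",
    "DEFAULT_ALPHA",
    "compute_zscores",
    "readout_pvalues",
    "call_hits",
    "score_screen",
    "overlap_hits",
]

READOUTS = ("edu", "pkap1_noatri", "pkap1_atri")
DEFAULT_ALPHA = {"edu": 0.05, "pkap1_noatri": 0.05, "pkap1_atri": 0.15}
NTC = "NTC"


def compute_zscores(wells: pd.DataFrame, include_controls: bool = True) -> pd.DataFrame:
    """Per-well z = (x - mu) / sigma within each readout.

    mu and sigma (sample sd, ddof=1) are taken over all wells of the
    readout, control wells included by default.
    """
    out = wells.copy()
    out["z"] = np.nan
    out["mu"] = np.nan
    out["sigma"] = np.nan
    for readout, grp in wells.groupby("readout"):
        ref = grp if include_controls else grp[grp["target"] != NTC]
        x = ref["percent_positive"].to_numpy(float)
        if len(x) < 2:
            raise ValueError(f"readout {readout!r}: need >=2 wells for a z-score")
        mu, sigma = x.mean(), x.std(ddof=1)
        if sigma == 0:
            raise ValueError(f"degenerate readout {readout!r}: zero standard deviation")
        idx = grp.index
        out.loc[idx, "z"] = (grp["percent_positive"] - mu) / sigma
        out.loc[idx, "mu"] = mu
        out.loc[idx, "sigma"] = sigma
    return out


def readout_pvalues(wells: pd.DataFrame, readout: str, equal_var: bool = True) -> pd.DataFrame:
    """Unpaired t of each target's replicates against pooled NTC replicates.

    EdU is two-sided; pKAP1 readouts are one-sided with the alternative that
    the target mean exceeds the NTC mean. Targets with fewer than two
    replicates get ``p = NaN`` and are flagged.
    """
    grp = wells[wells["readout"] == readout]
    ntc = grp.loc[grp["target"] == NTC, "percent_positive"].to_numpy(float)
    if len(ntc) < 2:
        raise ValueError(f"readout {readout!r}: need >=2 NTC replicates")
    alternative = "two-sided" if readout == "edu" else "greater"
    targets = grp[grp["target"] != NTC]
    sizes = targets.groupby("target")["percent_positive"].size()
    if sizes.nunique() == 1 and sizes.iloc[0] >= 2:
        # balanced design: one vectorized t-test across all targets
        pivot = targets.pivot_table(
            index="target", columns="replicate", values="percent_positive"
        )
        x = pivot.to_numpy(float)
        res = stats.ttest_ind(
            x, ntc[None, :], axis=1, equal_var=equal_var, alternative=alternative
        )
        return pd.DataFrame(
            {
                "target": pivot.index,
                "readout": readout,
                "mean_target": x.mean(axis=1),
                "mean_ntc": ntc.mean(),
                "p": np.asarray(res.pvalue, dtype=float),
                "flagged": False,
            }
        )
    rows = []
    for target, sub in targets.groupby("target"):
        x = sub["percent_positive"].to_numpy(float)
        if len(x) < 2:
            rows.append((target, readout, np.nan, np.nan, np.nan, True))
            continue
        res = stats.ttest_ind(x, ntc, equal_var=equal_var, alternative=alternative)
        rows.append((target, readout, x.mean(), ntc.mean(), float(res.pvalue), False))
    return pd.DataFrame(
        rows, columns=["target", "readout", "mean_target", "mean_ntc", "p", "flagged"]
    )


def call_hits(results: pd.DataFrame, alpha: dict[str, float] | None = None) -> pd.DataFrame:
    """Threshold hit calls: p < alpha[readout], with direction requirements.

    EdU hits must decrease the mean relative to NTC; pKAP1 hits carry the
    increase requirement through their one-sided alternative (an explicit
    mean check is applied as well for robustness on degenerate inputs).
    """
    alpha = alpha or DEFAULT_ALPHA
    out = results.copy()
    thr = out["readout"].map(alpha)
    sig = out["p"] < thr
    decreased = out["mean_target"] < out["mean_ntc"]
    increased = out["mean_target"] > out["mean_ntc"]
    direction = np.where(out["readout"] == "edu", decreased, increased)
    out["is_hit"] = (sig & direction).fillna(False)
    return out


def score_screen(
    wells: pd.DataFrame,
    alpha: dict[str, float] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Full per-target scoring: z (of the replicate-mean well), p and hit call."""
    pieces = []
    for readout in sorted(wells["readout"].unique()):
        pieces.append(readout_pvalues(wells, readout, equal_var=equal_var))
    res = call_hits(pd.concat(pieces, ignore_index=True), alpha)
    zw = compute_zscores(wells)
    zmean = (
        zw[zw["target"] != NTC]
        .groupby(["target", "readout"])["z"]
        .mean()
        .rename("z")
        .reset_index()
    )
    return res.merge(zmean, on=["target", "readout"], how="left")


def hit_sets(scored: pd.DataFrame) -> dict[str, set]:
    return {
        r: set(scored.loc[(scored["readout"] == r) & scored["is_hit"], "target"])
        for r in sorted(scored["readout"].unique())
    }


def overlap_hits(sets: dict[str, set]) -> dict:
    """Counts by intersection cardinality across the readout hit sets."""
    union = set().union(*sets.values()) if sets else set()
    membership = {t: sum(t in s for s in sets.values()) for t in union}
    by_card = {
        k: sorted(t for t, c in membership.items() if c == k)
        for k in range(1, len(sets) + 1)
    }
    return {
        "counts": {k: len(v) for k, v in by_card.items()},
        "members": by_card,
    }
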