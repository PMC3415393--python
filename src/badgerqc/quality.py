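"""Expression-array quality metrics that predict identity-matching power.

A poor expression array cannot predict genotypes regardless of sample
identity, so before chasing an apparent mismatch it pays to check array
quality.  Two crude metrics are provided: P95, the 95th percentile of
log-intensities (a signal-level indicator whose absolute value is
batch-dependent), and a rank-separation statistic comparing well-designed
('perfect' annotation tier) probes with probes mapping to intergenic
regions, which should show no signal.  The latter is invariant under any
monotone transform of intensities and therefore comparable across batches.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import DeltaStat, ExpressionMatrix


def p95_metric(values: pd.Series | np.ndarray, min_values: int = 20) -> tuple[float, float]:
    """(P95, P05) of an array's log-intensities, linear-interpolation
    percentile definition (scanner conventions differ; this one is pinned)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < min_values:
        raise ValueError(f"need at least {min_values} non-missing values, got {x.size}")
    p95, p05 = np.percentile(x, [95.0, 5.0], method="linear")
    return float(p95), float(p05)


def signal_separation_metric(
    values: pd.Series,
    probe_annotation: pd.DataFrame,
    min_tier_size: int = 10,
) -> float:
    """(mean rank of perfect-tier probes - mean rank of intergenic probes)
    divided by the number of ranked probes.

    Ranks ascend with intensity (mean rank for ties), so a healthy array
    with signal on designed probes and none on intergenic probes scores
    positive; an array of pure noise scores near 0; an array where only
    background structure remains can score substantially negative.
    """
    x = values.dropna()
    ann = probe_annotation.loc[x.index]
    tiers = ann["quality_tier"]
    perfect = tiers == "perfect"
    intergenic = tiers == "intergenic"
    if perfect.sum() < min_tier_size or intergenic.sum() < min_tier_size:
        raise ValueError(
            f"need >= {min_tier_size} perfect and intergenic probes "
            f"(got {int(perfect.sum())} / {int(intergenic.sum())})"
        )
    ranks = stats.rankdata(x.to_numpy(), method="average")
    return float((ranks[perfect.to_numpy()].mean() - ranks[intergenic.to_numpy()].mean()) / len(x))


def array_quality_table(expr: ExpressionMatrix) -> pd.DataFrame:
    """Both metrics for every array of an expression matrix."""
    rows = {}
    for a in expr.array_ids:
        col = expr.values[a]
        p95, p05 = p95_metric(col)
        rows[a] = {
            "p95": p95,
            "p05": p05,
            "signal_separation": signal_separation_metric(col, expr.probe_annotation),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def quality_vs_minscore(
    quality: pd.Series,
    deltas: dict[str, DeltaStat] | pd.Series,
    scheduled_empty: set[str] | None = None,
    n_bins: int = 4,
) -> dict:
    """Association between an array-quality metric and the minimum identity
    score per expression array.

    Returns the Spearman rank correlation, a binned summary (quality
    quartiles vs median min-score), and flags for arrays scheduled to be
    empty that nevertheless show signal (quality above the cohort median)
    and arrays with samples that apparently failed to hybridise (quality
    below the scheduled-empty maximum).
    """
    if isinstance(deltas, dict):
        min_scores = pd.Series({a: d.min_score for a, d in deltas.items()})
    else:
        min_scores = deltas.astype(float)
    common = quality.index.intersection(min_scores.index)
    if len(common) < 3:
        raise ValueError("need at least 3 arrays present in both inputs")
    q = quality.loc[common].astype(float)
    s = min_scores.loc[common]

    if q.nunique() <= 1 or s.nunique() <= 1:
        rho, pval = float("nan"), float("nan")
        note = "correlation undefined: a variable is constant"
    else:
        rho, pval = stats.spearmanr(q, s)
        rho, pval = float(rho), float(pval)
        note = None

    try:
        bins = pd.qcut(q, n_bins, duplicates="drop")
        table = s.groupby(bins, observed=True).median()
        binned = {str(iv): float(v) for iv, v in table.items()}
    except (ValueError, IndexError):
        binned = {}

    scheduled_empty = scheduled_empty or set()
    flags = []
    med = float(q.median())
    empties = [a for a in common if a in scheduled_empty]
    occupied = [a for a in common if a not in scheduled_empty]
    for a in empties:
        if q.loc[a] > med:
            flags.append({"array": a, "flag": "scheduled_empty_with_signal"})
    if empties:
        empty_max = float(q.loc[empties].max())
        for a in occupied:
            if q.loc[a] <= empty_max:
                flags.append({"array": a, "flag": "scheduled_sample_no_signal"})

    out = {"spearman_rho": rho, "spearman_p": pval, "binned_median_min_score": binned, "flags": flags}
    if note:
        out["note"] = note
    return out
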