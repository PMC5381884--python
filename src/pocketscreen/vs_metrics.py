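"""Virtual-screening evaluation metrics.

Retrospective screens rank a library of known ligands (true positives)
against decoys or against ligands of opposite pharmacology (false
positives).  This module builds the ROC step curve from a long-format
docking score table, computes the classical AUC and the early-recovery
weighted NSQ_AUC statistic, per-chemotype enrichment factors, and the
repeat-aware statistical comparison of binding pockets (mean ± SEM,
one-way ANOVA + Tukey HSD, or Welch's t-test for two pockets).

The NSQ_AUC statistic re-weights the false-positive axis by a square
root, so that discrimination among the first few percent of decoys
dominates the score::

    SQ_AUC  = integral of TPR d(sqrt(FPR))
    NSQ_AUC = 100 * (SQ_AUC - SQ_AUC_random) / (SQ_AUC_perfect - SQ_AUC_random)

with analytic references SQ_AUC_perfect = 1 and SQ_AUC_random = 1/3
(the diagonal TPR = FPR integrates to ∫ u² du).  Hence
NSQ_AUC = 150·SQ_AUC − 50, ranging from −50 (all decoys first) through
0 (random) to 100 (perfect recovery).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocResult",
    "EnrichmentResult",
    "PocketComparison",
    "best_of_repeats",
    "compute_roc",
    "roc_from_points",
    "sq_auc_from_points",
    "nsq_auc",
    "enrichment_factor",
    "per_repeat_nsq",
    "compare_pockets",
    "ligand_rank_fpr",
    "significance_stars",
    "CONTRASTS",
]

SQ_AUC_PERFECT = 1.0
SQ_AUC_RANDOM = 1.0 / 3.0

#: Supported ROC contrasts: column holding the class label and the value
#: treated as the true-positive class.
CONTRASTS = {
    "actives_vs_decoys": ("class_label", "active"),
    "agonists_vs_inhibitors": ("pharmacology", "agonist"),
    "inhibitors_vs_agonists": ("pharmacology", "inhibitor"),
}


@dataclass
class RocResult:
    """An ROC step curve plus its scalar summaries."""

    points: np.ndarray  # (n, 2) array of (FPR, TPR), from (0,0) to (1,1)
    auc: float
    sq_auc: float
    nsq_auc: float
    n_tp: int
    n_fp: int
    sq_auc_perfect: float = SQ_AUC_PERFECT
    sq_auc_random: float = SQ_AUC_RANDOM


@dataclass
class EnrichmentResult:
    """Enrichment factor EF_x for one chemotype at one fraction x%."""

    x: float
    chemotype: str
    tp: int
    n: int
    tp_x: int
    n_x: int
    ef: float | None  # None when the chemotype has no true positives


@dataclass
class PocketComparison:
    """Repeat-level NSQ_AUC comparison across binding pockets."""

    per_pocket: pd.DataFrame  # index pocket_id; columns mean, sem, n + values
    values: Mapping[str, Sequence[float]]
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    pairwise: pd.DataFrame  # pocket_a, pocket_b, statistic, df, p, stars, better
    method: str  # "tukey" or "welch"


def _require_columns(table: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"score table is missing columns: {missing}")


def best_of_repeats(table: pd.DataFrame, lower_is_better: bool = True) -> pd.DataFrame:
    """Collapse repeats to the best score per (ligand, pocket).

    Docking is stochastic, so each library is docked several times and the
    best-scoring repeat represents the ligand.  Deterministic: among tied
    best repeats the lowest repeat index wins.
    """
    _require_columns(table, ["ligand_id", "pocket_id", "repeat", "score"])
    ordered = table.sort_values(
        ["score", "repeat"], ascending=[lower_is_better, True], kind="mergesort"
    )
    best = ordered.groupby(["ligand_id", "pocket_id"], as_index=False, sort=True).first()
    return best.reset_index(drop=True)


def _roc_points(scores_tp: np.ndarray, scores_fp: np.ndarray, lower_is_better: bool) -> np.ndarray:
    """Build the ROC step curve by sweeping the score threshold.

    Tied scores advance TP and FP jointly, producing a diagonal segment;
    the curve is therefore independent of input order.
    """
    n_tp, n_fp = len(scores_tp), len(scores_fp)
    sign = 1.0 if lower_is_better else -1.0
    all_scores = np.concatenate([scores_tp, scores_fp]) * sign
    labels = np.concatenate([np.ones(n_tp, bool), np.zeros(n_fp, bool)])
    order = np.argsort(all_scores, kind="mergesort")
    sorted_scores = all_scores[order]
    sorted_labels = labels[order]

    tp_cum = np.cumsum(sorted_labels)
    fp_cum = np.cumsum(~sorted_labels)
    # keep only the last row of each tie group
    last_of_group = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    fpr = fp_cum[last_of_group] / n_fp
    tpr = tp_cum[last_of_group] / n_tp
    points = np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])
    return points


def sq_auc_from_points(points: np.ndarray) -> float:
    """Area under TPR as a function of u = sqrt(FPR).

    Each ROC segment is linear in FPR; its image under the square-root
    substitution is integrated in closed form, so diagonal (tied-score)
    segments contribute their exact curved area rather than a chord
    approximation.  For the segment (F0, y0) → (F1, y1) with slope
    s = Δy/ΔF::

        ∫ y du = (y0 − s·F0)(√F1 − √F0) + s(F1^{3/2} − F0^{3/2})/3
    """
    f = np.asarray(points, float)[:, 0]
    y = np.asarray(points, float)[:, 1]
    area = 0.0
    for i in range(len(f) - 1):
        f0, f1, y0, y1 = f[i], f[i + 1], y[i], y[i + 1]
        if f1 == f0:
            continue  # vertical segment: no width on the u axis
        s = (y1 - y0) / (f1 - f0)
        area += (y0 - s * f0) * (math.sqrt(f1) - math.sqrt(f0))
        area += s * (f1**1.5 - f0**1.5) / 3.0
    return area


def _trapezoid_auc(points: np.ndarray) -> float:
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def roc_from_points(points: np.ndarray, n_tp: int = 0, n_fp: int = 0) -> RocResult:
    """Wrap an explicit (FPR, TPR) polyline as a :class:`RocResult`."""
    points = np.asarray(points, float)
    if not (points[0] == (0.0, 0.0)).all() or not (points[-1] == (1.0, 1.0)).all():
        raise ValueError("ROC points must run from (0,0) to (1,1)")
    if (np.diff(points, axis=0) < 0).any():
        raise ValueError("ROC points must be monotone non-decreasing")
    sq = sq_auc_from_points(points)
    return RocResult(
        points=points,
        auc=_trapezoid_auc(points),
        sq_auc=sq,
        nsq_auc=100.0 * (sq - SQ_AUC_RANDOM) / (SQ_AUC_PERFECT - SQ_AUC_RANDOM),
        n_tp=n_tp,
        n_fp=n_fp,
    )


def compute_roc(
    table: pd.DataFrame,
    contrast: str = "actives_vs_decoys",
    lower_is_better: bool = True,
) -> RocResult:
    """ROC of true positives against false positives for one ranked table.

    ``contrast`` selects the label column and positive class (see
    :data:`CONTRASTS`).  For the pharmacology contrasts, rows whose label
    is neither class (decoys, unknowns) are excluded.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRASTS)}")
    col, positive = CONTRASTS[contrast]
    _require_columns(table, ["score", col])
    if col == "pharmacology":
        table = table[table[col].isin(["agonist", "inhibitor"])]
    labels = table[col].to_numpy()
    is_tp = labels == positive
    scores = table["score"].to_numpy(float)
    n_tp, n_fp = int(is_tp.sum()), int((~is_tp).sum())
    if n_tp == 0 or n_fp == 0:
        raise ValueError(
            f"contrast {contrast!r} needs both classes: "
            f"{n_tp} true positives, {n_fp} false positives"
        )
    points = _roc_points(scores[is_tp], scores[~is_tp], lower_is_better)
    sq = sq_auc_from_points(points)
    return RocResult(
        points=points,
        auc=_trapezoid_auc(points),
        sq_auc=sq,
        nsq_auc=100.0 * (sq - SQ_AUC_RANDOM) / (SQ_AUC_PERFECT - SQ_AUC_RANDOM),
        n_tp=n_tp,
        n_fp=n_fp,
    )


def nsq_auc(roc: RocResult) -> float:
    """Normalized square-root AUC of an ROC result (perfect 100, random 0)."""
    return roc.nsq_auc


def enrichment_factor(
    table: pd.DataFrame,
    x_percent: float,
    chemotype: str = "all",
    contrast: str = "actives_vs_decoys",
    lower_is_better: bool = True,
) -> EnrichmentResult:
    """EF_x = (TP_x / N_x) / (TP / N) for one chemotype.

    ``table`` must already be collapsed to one row per ligand (see
    :func:`best_of_repeats`).  N_x = round(x·N/100) with a minimum of 1;
    ties at the cut are broken by ligand id for determinism.  ``chemotype``
    "all" aggregates every true positive.
    """
    col, positive = CONTRASTS[contrast]
    _require_columns(table, ["ligand_id", "score", col, "chemotype"])
    ranked = table.sort_values(
        ["score", "ligand_id"], ascending=[lower_is_better, True], kind="mergesort"
    )
    n = len(ranked)
    is_tp = (ranked[col] == positive).to_numpy()
    if chemotype != "all":
        is_tp &= (ranked["chemotype"] == chemotype).to_numpy()
    tp = int(is_tp.sum())
    n_x = max(1, round(x_percent * n / 100.0))
    tp_x = int(is_tp[:n_x].sum())
    if tp == 0:
        warnings.warn(
            f"no true positives of chemotype {chemotype!r}: EF{x_percent:g} undefined",
            stacklevel=2,
        )
        ef = None
    else:
        ef = (tp_x / n_x) / (tp / n)
    return EnrichmentResult(x=x_percent, chemotype=chemotype, tp=tp, n=n, tp_x=tp_x, n_x=n_x, ef=ef)


def per_repeat_nsq(
    table: pd.DataFrame,
    contrast: str = "actives_vs_decoys",
    lower_is_better: bool = True,
) -> tuple[list[float], float, float]:
    """One NSQ_AUC per docking repeat, with mean and SEM.

    No best-of pooling: each repeat is scored as its own screen.  Ligands
    missing any repeat are dropped (with a warning) so every repeat ranks
    the same library.  Returns ``(values, mean, sem)`` with
    SEM = sample standard deviation / sqrt(R).
    """
    _require_columns(table, ["ligand_id", "repeat", "score"])
    repeats = sorted(table["repeat"].unique())
    if len(repeats) < 2:
        raise ValueError("per-repeat statistics need at least 2 repeats")
    counts = table.groupby("ligand_id")["repeat"].nunique()
    complete = counts[counts == len(repeats)].index
    dropped = counts.index.difference(complete)
    if len(dropped):
        warnings.warn(f"dropping {len(dropped)} ligand(s) with incomplete repeats", stacklevel=2)
        table = table[table["ligand_id"].isin(complete)]
    values = [
        compute_roc(table[table["repeat"] == r], contrast, lower_is_better).nsq_auc
        for r in repeats
    ]
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / math.sqrt(len(values)))
    return values, mean, sem


def significance_stars(p: float) -> str:
    """Star annotation convention: * ≤0.05, ** ≤0.01, *** ≤0.001, **** ≤0.0001."""
    if not np.isfinite(p):
        return "n/a"
    for cut, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p <= cut:
            return stars
    return "ns"


def compare_pockets(nsq_by_pocket: Mapping[str, Sequence[float]]) -> PocketComparison:
    """Compare binding pockets by their per-repeat NSQ_AUC values.

    More than two pockets: one-way ANOVA followed by Tukey's HSD.
    Exactly two: unpaired t-test with Welch's correction.  Each pairwise
    row reports which pocket had the higher mean ("better").
    """
    pockets = list(nsq_by_pocket)
    if len(pockets) < 2:
        raise ValueError("need at least two pockets to compare")
    groups = [np.asarray(nsq_by_pocket[p], float) for p in pockets]
    for p, g in zip(pockets, groups):
        if len(g) < 2:
            raise ValueError(f"pocket {p!r} has fewer than 2 repeat values")

    rows = {
        p: {"mean": g.mean(), "sem": g.std(ddof=1) / math.sqrt(len(g)), "n": len(g)}
        for p, g in zip(pockets, groups)
    }
    per_pocket = pd.DataFrame.from_dict(rows, orient="index")

    n_total = sum(len(g) for g in groups)
    df_between, df_within = len(groups) - 1, n_total - len(groups)
    if all(g.std() == 0 for g in groups) and len({g.mean() for g in groups}) == 1:
        anova_f, anova_p = float("nan"), float("nan")  # zero variance, equal means
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova_f, anova_p = stats.f_oneway(*groups)

    pairs = []
    if len(groups) > 2:
        method = "tukey"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tukey = stats.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                p_val = float(tukey.pvalue[i, j])
                pairs.append(
                    {
                        "pocket_a": pockets[i],
                        "pocket_b": pockets[j],
                        "statistic": float(tukey.statistic[i, j]),
                        "df": df_within,
                        "p": p_val,
                        "stars": significance_stars(p_val),
                        "better": pockets[i] if groups[i].mean() >= groups[j].mean() else pockets[j],
                    }
                )
    else:
        method = "welch"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        p_val = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
        pairs.append(
            {
                "pocket_a": pockets[0],
                "pocket_b": pockets[1],
                "statistic": float(res.statistic) if np.isfinite(res.statistic) else 0.0,
                "df": float(res.df) if np.isfinite(res.df) else df_within,
                "p": p_val,
                "stars": significance_stars(p_val),
                "better": pockets[0] if groups[0].mean() >= groups[1].mean() else pockets[1],
            }
        )

    return PocketComparison(
        per_pocket=per_pocket,
        values={p: list(map(float, g)) for p, g in zip(pockets, groups)},
        anova_f=float(anova_f),
        anova_df=(df_between, df_within),
        anova_p=float(anova_p),
        pairwise=pd.DataFrame(pairs),
        method=method,
    )


def ligand_rank_fpr(
    table: pd.DataFrame,
    ligand_id: str,
    contrast: str = "actives_vs_decoys",
    lower_is_better: bool = True,
) -> float:
    """FPR at which a named ligand (e.g. the co-crystal ligand) is recovered.

    Mirrors the dashed vertical marker on ROC plots: the fraction of false
    positives ranked at or above the ligand's score.
    """
    col, positive = CONTRASTS[contrast]
    _require_columns(table, ["ligand_id", "score", col])
    if ligand_id not in set(table["ligand_id"]):
        raise ValueError(f"ligand {ligand_id!r} not in table")
    score = float(table.loc[table["ligand_id"] == ligand_id, "score"].iloc[0])
    fp = table[table[col] != positive]["score"].to_numpy(float)
    if len(fp) == 0:
        raise ValueError("no false positives in table")
    better = (fp <= score) if lower_is_better else (fp >= score)
    return float(better.sum() / len(fp))
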