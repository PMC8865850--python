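"""Enrichment gating, correlation, and the group-comparison decision tree.

Three flow-cytometry gates quantify enrichment of genomically edited cells:

* ``none`` — all live single cells (no enrichment);
* ``transfection`` — cells positive for the transfection marker (BFP),
  regardless of reporter fluorescence;
* ``pear`` — cells positive for the reporter (GFP), regardless of BFP.

Editing% within each gate and fold change versus the ungated population are
reported.  Gating uses the *observed* fluorescence flags — what a sorter can
see — not the latent truth.

Group comparisons follow a pre-registered decision tree common in this
literature: Brown-Forsythe for homogeneity of variances and the
D'Agostino-Pearson omnibus K2 on pooled ANOVA residuals for normality; if
both pass, one-way ANOVA with Tukey's post hoc test; if homogeneity holds
but normality fails and the data are positive, a Box-Cox transform (lambda by
maximum likelihood over [-2, 2]) is applied and the assumptions re-checked;
otherwise Kruskal-Wallis with Dunn's post hoc test (Bonferroni-adjusted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GateResult",
    "GroupComparison",
    "compare_groups",
    "dunn_test",
    "gated_editing_rates",
    "pearson_r",
]

#: Significance level used for the assumption pretests in the decision tree.
ASSUMPTION_ALPHA = 0.05
GATES = ("none", "transfection", "pear")


@dataclass(frozen=True)
class GateResult:
    """Editing rate within one gate and its fold change versus no gating."""

    gate: str
    n_cells: int
    editing_pct: float
    fold_vs_none: float


def gated_editing_rates(cells: pd.DataFrame) -> dict[str, GateResult]:
    """Editing% under the three gates of a per-cell table.

    ``cells`` needs boolean columns ``genomic_edited``, ``bfp`` and ``gfp``.
    Empty gates are reported with ``n_cells=0`` and NaN rates, with a warning.
    """
    if len(cells) == 0:
        raise ValueError("empty population")
    masks = {
        "none": np.ones(len(cells), dtype=bool),
        "transfection": cells["bfp"].to_numpy(dtype=bool),
        "pear": cells["gfp"].to_numpy(dtype=bool),
    }
    edited = cells["genomic_edited"].to_numpy(dtype=bool)
    pcts: dict[str, float] = {}
    results: dict[str, GateResult] = {}
    for gate in GATES:
        m = masks[gate]
        n = int(m.sum())
        if n == 0:
            warnings.warn(f"gate {gate!r} is empty; editing undefined",
                          stacklevel=2)
            pcts[gate] = float("nan")
        else:
            pcts[gate] = 100.0 * edited[m].mean()
        base = pcts["none"]
        fold = pcts[gate] / base if base and base > 0 else float("nan")
        results[gate] = GateResult(
            gate=gate, n_cells=n, editing_pct=pcts[gate], fold_vs_none=fold
        )
    return results


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of the group-comparison decision tree."""

    path_taken: str  # anova_tukey | boxcox_anova_tukey | kruskal_dunn | no_variance
    brown_forsythe_p: float
    dagostino_K2_p: float
    omnibus_p: float
    pairwise: tuple[tuple[tuple[int, int], float], ...] = ()
    boxcox_lambda: Optional[float] = None


def _residual_normality_p(groups: list[np.ndarray]) -> float:
    residuals = np.concatenate([g - g.mean() for g in groups])
    if residuals.size >= 8:
        return float(stats.normaltest(residuals).pvalue)
    # K2 needs n >= 8; fall back to Shapiro-Wilk for tiny designs
    return float(stats.shapiro(residuals).pvalue)


def _boxcox_lambda_mle(data: np.ndarray, bounds=(-2.0, 2.0)) -> float:
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, data),
        bounds=bounds, method="bounded",
    )
    return float(res.x)


def _anova_tukey(groups: list[np.ndarray], path: str,
                 bf_p: float, k2_p: float,
                 lam: Optional[float]) -> GroupComparison:
    omnibus = float(stats.f_oneway(*groups).pvalue)
    tukey = stats.tukey_hsd(*groups)
    pairwise = tuple(
        ((i, j), float(tukey.pvalue[i, j]))
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    )
    return GroupComparison(
        path_taken=path, brown_forsythe_p=bf_p, dagostino_K2_p=k2_p,
        omnibus_p=omnibus, pairwise=pairwise, boxcox_lambda=lam,
    )


def dunn_test(
    groups: Sequence[np.ndarray], adjust: str = "bonferroni"
) -> list[tuple[tuple[int, int], float]]:
    """Dunn's rank-based pairwise test after Kruskal-Wallis.

    Z statistics use the pooled-rank means with the tie correction; two-sided
    p-values are Bonferroni-adjusted by default.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    rank_means = []
    start = 0
    for g in groups:
        rank_means.append(ranks[start : start + g.size].mean())
        start += g.size
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
            z = (rank_means[i] - rank_means[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            if adjust == "bonferroni":
                p = min(1.0, p * n_pairs)
            out.append(((i, j), float(p)))
    return out


def compare_groups(
    samples: Sequence[Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """Run the assumption-driven decision tree on replicate groups.

    ``samples`` is a list of >= 2 groups of replicate measurements.  Returns
    the path taken, the assumption-test p-values, the omnibus p-value and
    adjusted pairwise p-values.
    """
    if len(samples) < 2:
        raise ValueError("nothing to compare")
    groups = [np.asarray(g, dtype=float) for g in samples]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 replicates")

    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return GroupComparison(
            path_taken="no_variance",
            brown_forsythe_p=float("nan"), dagostino_K2_p=float("nan"),
            omnibus_p=float("nan"),
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bf_p = float(stats.levene(*groups, center="median").pvalue)
        k2_p = _residual_normality_p(groups)

        if bf_p > ASSUMPTION_ALPHA and k2_p > ASSUMPTION_ALPHA:
            return _anova_tukey(groups, "anova_tukey", bf_p, k2_p, None)

        # normality failed (variances fine): try a Box-Cox rescue on positive data
        if bf_p > ASSUMPTION_ALPHA and np.all(pooled > 0):
            lam = _boxcox_lambda_mle(pooled)
            tgroups = [stats.boxcox(g, lmbda=lam) for g in groups]
            bf_p2 = float(stats.levene(*tgroups, center="median").pvalue)
            k2_p2 = _residual_normality_p(tgroups)
            if bf_p2 > ASSUMPTION_ALPHA and k2_p2 > ASSUMPTION_ALPHA:
                return _anova_tukey(
                    tgroups, "boxcox_anova_tukey", bf_p2, k2_p2, lam
                )

        omnibus = float(stats.kruskal(*groups).pvalue)
        pairwise = tuple(dunn_test(groups))
    return GroupComparison(
        path_taken="kruskal_dunn", brown_forsythe_p=bf_p, dagostino_K2_p=k2_p,
        omnibus_p=omnibus, pairwise=pairwise,
    )
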