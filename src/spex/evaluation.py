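"""Metrics, repeated-run significance testing and residual analysis.

Covers: Spearman/Pearson/RMSE between predicted and observed expression;
Welch's unequal-variance t-test with Bonferroni correction across
experiments; Anderson-Darling normality screening of residuals; per-gene
"best" residual selection across loop-mediating factors; the mean +- 0.5 SD
residual cutoff; and the Venn classification of genes inside the cutoff
under two models.

Residuals are always observed minus predicted.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

log = logging.getLogger(__name__)


def _clean_pair(pred, obs) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError(f"shape mismatch: {pred.shape} vs {obs.shape}")
    if len(pred) < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(obs))):
        raise ValueError("non-finite values in metric input")
    return pred, obs


def spearman(pred, obs) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    pred, obs = _clean_pair(pred, obs)
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise DataError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(pred, obs).statistic)


def pearson(pred, obs) -> float:
    pred, obs = _clean_pair(pred, obs)
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise DataError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(pred, obs).statistic)


def rmse(pred, obs) -> float:
    pred, obs = _clean_pair(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def welch_test(a, b) -> tuple[float, float]:
    """Welch's two-sample t-test (Satterthwaite df), two-sided p.

    Two zero-variance samples with equal means are a degenerate null case
    and return (0, 1) with a log note.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch test needs at least 2 values per sample")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in Welch test input")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            log.info("Welch test: both samples constant and equal; p=1 by convention")
            return 0.0, 1.0
        raise DataError("Welch test degenerate: zero variance, unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, m * p)``; ``m`` defaults to the
    number of p-values and may not be smaller than it."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(pvals)
    if m < len(pvals):
        raise ValueError(f"m={m} smaller than the number of tests {len(pvals)}")
    return np.minimum(1.0, m * pvals)


@dataclass
class NormalityResult:
    statistic: float
    passed: bool
    critical_value: float
    level: float
    note: str = ""


def anderson_darling_normality(x, level: float = 0.01) -> NormalityResult:
    """Anderson-Darling test against the normal family with estimated
    mean/variance (case-3 critical values). ``passed`` means the sample is
    consistent with normality at the given level."""
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        raise ValueError("Anderson-Darling needs at least 8 observations")
    if np.ptp(x) == 0:
        return NormalityResult(math.inf, False, math.nan, level,
                               note="degenerate constant sample")
    with warnings.catch_warnings():
        # scipy >= 1.17 nudges toward p-value methods; the tabulated
        # estimated-parameter critical values are what we want here
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson(x, dist="norm")
    levels = np.asarray(res.significance_level, dtype=float) / 100.0
    if not np.any(np.isclose(levels, level)):
        raise ValueError(
            f"level {level} not among tabulated levels {sorted(set(levels))}"
        )
    cv = float(res.critical_values[np.argmax(np.isclose(levels, level))])
    a2 = float(res.statistic)
    return NormalityResult(a2, a2 < cv, cv, level)


def spex_best(residuals_by_factor: Mapping[str, pd.Series] | pd.DataFrame) -> pd.Series:
    """Per-gene residual closest to zero across factors (sign preserved).

    Factors must cover an identical gene set; ties go to the earlier factor
    in the declared order (logged).
    """
    if isinstance(residuals_by_factor, pd.DataFrame):
        frame = residuals_by_factor
    else:
        factors = list(residuals_by_factor)
        if not factors:
            raise ValueError("no factors given")
        genes = residuals_by_factor[factors[0]].index
        for f in factors[1:]:
            if not residuals_by_factor[f].index.equals(genes):
                missing = set(genes).symmetric_difference(residuals_by_factor[f].index)
                raise DataError(
                    f"factor {f!r} covers a different gene set "
                    f"(e.g. {sorted(missing)[:3]})"
                )
        frame = pd.DataFrame({f: residuals_by_factor[f] for f in factors})
    if frame.isna().any().any():
        raise DataError("missing residuals in spex_best input")
    abs_vals = frame.abs().to_numpy()
    # argmin returns the first (declared-order) factor on ties
    pick = abs_vals.argmin(axis=1)
    ties = (abs_vals == abs_vals.min(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        log.info("spex_best: %d ties broken by declared factor order", int(ties.sum()))
    out = pd.Series(
        frame.to_numpy()[np.arange(len(frame)), pick],
        index=frame.index,
        name="spex_best",
    )
    return out


def residual_cutoff(residuals, sd_frac: float = 0.5) -> tuple[float, float]:
    """Interval ``mean +- sd_frac * SD`` (sample SD, ddof=1) of a residual
    distribution. A printed asymmetric interval simply reflects a nonzero
    mean; the rule itself is symmetric about it."""
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) < 2:
        raise ValueError("need at least 2 residuals")
    if sd_frac <= 0:
        raise ValueError(f"sd_frac must be positive, got {sd_frac}")
    sd = float(np.std(residuals, ddof=1))
    if sd == 0:
        raise DataError("degenerate residual distribution (zero SD)")
    mean = float(np.mean(residuals))
    return mean - sd_frac * sd, mean + sd_frac * sd


def venn_classify(
    spex_res: pd.Series, baseline_res: pd.Series, interval: tuple[float, float]
) -> dict[str, int]:
    """Classify genes by cutoff membership of their residual under each
    model: both / spex_only / baseline_only / neither (a partition)."""
    if not spex_res.index.equals(baseline_res.index):
        if set(spex_res.index) != set(baseline_res.index):
            raise DataError("venn_classify: mismatched gene sets")
        baseline_res = baseline_res.reindex(spex_res.index)
    lo, hi = interval
    if not lo < hi:
        raise ValueError(f"invalid interval ({lo}, {hi})")
    in_spex = (spex_res >= lo) & (spex_res <= hi)
    in_base = (baseline_res >= lo) & (baseline_res <= hi)
    return {
        "both": int((in_spex & in_base).sum()),
        "spex_only": int((in_spex & ~in_base).sum()),
        "baseline_only": int((~in_spex & in_base).sum()),
        "neither": int((~in_spex & ~in_base).sum()),
    }


def grouped_comparison(runs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare repeated-run SCC between the spatial and baseline arms.

    ``runs`` needs columns experiment, factor, label ('baseline'/'spatial')
    and scc. Returns (per-experiment table, per-factor-group table): Welch t
    and p per experiment with Bonferroni adjustment across experiments, the
    mean SCC improvement, and pooled per-factor tests.
    """
    required = {"experiment", "factor", "label", "scc"}
    missing = required - set(runs.columns)
    if missing:
        raise DataError(f"runs table missing columns {sorted(missing)}")
    per_exp_rows = []
    for (factor, exp), grp in runs.groupby(["factor", "experiment"], sort=True):
        base = grp.loc[grp["label"] == "baseline", "scc"].to_numpy()
        spat = grp.loc[grp["label"] == "spatial", "scc"].to_numpy()
        if len(base) < 2:
            raise DataError(f"experiment {exp!r}: missing or too small baseline arm")
        if len(spat) < 2:
            raise DataError(f"experiment {exp!r}: missing or too small spatial arm")
        t, p = welch_test(spat, base)
        per_exp_rows.append({
            "factor": factor,
            "experiment": exp,
            "n_baseline": len(base),
            "n_spatial": len(spat),
            "mean_baseline_scc": float(np.mean(base)),
            "mean_spatial_scc": float(np.mean(spat)),
            "improvement": float(np.mean(spat) - np.mean(base)),
            "t": t,
            "p": p,
        })
    per_exp = pd.DataFrame(per_exp_rows)
    per_exp["p_adj"] = bonferroni(per_exp["p"].to_numpy())
    group_rows = []
    for factor, grp in runs.groupby("factor", sort=True):
        base = grp.loc[grp["label"] == "baseline", "scc"].to_numpy()
        spat = grp.loc[grp["label"] == "spatial", "scc"].to_numpy()
        t, p = welch_test(spat, base)
        group_rows.append({
            "factor": factor,
            "n_baseline": len(base),
            "n_spatial": len(spat),
            "mean_baseline_scc": float(np.mean(base)),
            "mean_spatial_scc": float(np.mean(spat)),
            "improvement": float(np.mean(spat) - np.mean(base)),
            "t": t,
            "p": p,
        })
    per_group = pd.DataFrame(group_rows)
    return per_exp, per_group


@dataclass
class ResidualReport:
    """Residual analysis of one test set under several factor models."""

    spex_best: pd.Series
    baseline: pd.Series
    cutoff: tuple[float, float]
    venn: dict[str, int]
    n_within_cutoff: int
    normality: NormalityResult


def residual_report(
    residuals_by_factor: Mapping[str, pd.Series],
    baseline_res: pd.Series,
    sd_frac: float = 0.5,
    normality_level: float = 0.01,
) -> ResidualReport:
    """SpEx-Best selection, cutoff interval, Venn classification and a
    normality screen, in one pass."""
    best = spex_best(residuals_by_factor)
    if not best.index.equals(baseline_res.index):
        if set(best.index) != set(baseline_res.index):
            raise DataError("baseline residuals cover a different gene set")
        baseline_res = baseline_res.reindex(best.index)
    cutoff = residual_cutoff(best.to_numpy(), sd_frac=sd_frac)
    venn = venn_classify(best, baseline_res, cutoff)
    return ResidualReport(
        spex_best=best,
        baseline=baseline_res,
        cutoff=cutoff,
        venn=venn,
        n_within_cutoff=venn["both"] + venn["spex_only"],
        normality=anderson_darling_normality(best.to_numpy(), level=normality_level),
    )
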