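"""Outcome statistics: correlations, bootstrap CIs, ROC and power analysis.

The prognostic layer links per-infant burst-power summaries to Bayley-III
neurodevelopmental scores:

* Pearson and partial Pearson correlations with percentile-bootstrap 95%
  confidence intervals; a result is *significant* only when p < .05 AND the
  bootstrap CI excludes zero (conjunction rule).
* ROC analysis of burst power against a binary abnormal-outcome flag
  (composite score < 85), with the cutoff chosen for maximal sensitivity
  and, among ties, maximal specificity. Higher power predicts abnormal.
* The Fisher-z sample-size formula for detecting a correlation of given R²
  with stated power and alpha.

No multiplicity correction is applied by default; a Benjamini–Hochberg
option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

DEFAULT_N_BOOT = 1000
DEFAULT_ALPHA = 0.05
ABNORMAL_CUTOFF = 85.0

COMPOSITES = ["cognitive", "motor", "language"]


@dataclass
class CorrelationResult:
    r: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    partial: bool = False
    covariate_name: str | None = None

    @property
    def significant(self) -> bool:
        """p < .05 AND the bootstrap 95% CI excludes zero."""
        return bool(self.p < DEFAULT_ALPHA and (self.ci_low > 0 or self.ci_high < 0))


@dataclass
class ROCResult:
    auc: float
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    chosen_cutoff: float
    chosen_sensitivity: float
    chosen_specificity: float
    n_abnormal: int
    n_normal: int


def _complete(*arrays) -> list[np.ndarray]:
    arrays = [np.asarray(a, float) for a in arrays]
    ok = np.logical_and.reduce([np.isfinite(a) for a in arrays])
    return [a[ok] for a in arrays]


def _boot_pearson(x: np.ndarray, y: np.ndarray, n_boot: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Vectorised percentile-bootstrap sample of Pearson r (paired resampling)."""
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / denom
    return r[np.isfinite(r)]


def pearson_with_bootstrap(x, y, n_boot: int = DEFAULT_N_BOOT,
                           seed: int = 0) -> CorrelationResult:
    """Pearson r with two-sided t-test p and percentile bootstrap 95% CI.

    Pairs with a missing value are dropped; degenerate bootstrap resamples
    (zero variance) are discarded from the percentile computation.
    """
    x, y = _complete(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    boots = _boot_pearson(x, y, n_boot, rng) if n_boot > 0 else np.array([r])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CorrelationResult(r=float(r), p=float(p), ci_low=float(lo),
                             ci_high=float(hi), n=int(x.size))


def _partial_r(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Partial correlation via residuals of least-squares fits on z."""
    zc = np.column_stack([np.ones_like(z), z])
    rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
    ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    # residuals that are numerically zero (x or y collinear with z) leave the
    # partial correlation undefined
    if sx <= 1e-10 * max(x.std(), 1e-300) or sy <= 1e-10 * max(y.std(), 1e-300):
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def partial_pearson(x, y, z, n_boot: int = DEFAULT_N_BOOT,
                    seed: int = 0) -> CorrelationResult:
    """Partial Pearson correlation of x and y controlling for z.

    Computed on residuals after linearly removing z from both variables
    (equivalent to the closed-form r_xy.z). p is from the t distribution
    with n-3 degrees of freedom; the CI is a percentile bootstrap over
    resampled (x, y, z) triples. A zero-variance covariate falls back to the
    plain Pearson correlation with a warning.
    """
    x, y, z = _complete(x, y, z)
    if x.size < 4:
        raise ValueError("need at least 4 complete triples")
    if z.std() == 0:
        warnings.warn("covariate has zero variance; returning plain Pearson",
                      stacklevel=2)
        res = pearson_with_bootstrap(x, y, n_boot=n_boot, seed=seed)
        res.partial = True
        return res
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r = _partial_r(x, y, z)
    n = x.size
    if not np.isfinite(r):
        warnings.warn("degenerate residuals (x or y collinear with z); "
                      "partial correlation undefined", stacklevel=2)
        return CorrelationResult(r=np.nan, p=np.nan, ci_low=np.nan,
                                 ci_high=np.nan, n=n, partial=True)
    df = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    p = float(2.0 * sps.t.sf(abs(t), df))
    rng = np.random.default_rng(seed)
    boots = []
    if n_boot > 0:
        idx = rng.integers(0, n, size=(n_boot, n))
        for row in idx:
            rb = _partial_r(x[row], y[row], z[row])
            if np.isfinite(rb):
                boots.append(rb)
    boots = np.asarray(boots) if boots else np.array([r])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CorrelationResult(r=float(r), p=p, ci_low=float(lo),
                             ci_high=float(hi), n=n, partial=True)


def roc_analysis(predictor, abnormal) -> ROCResult:
    """ROC of burst power against an abnormal-outcome flag.

    The predictor direction is fixed: higher power scores as abnormal (not
    auto-oriented, which would inflate AUC on null data). AUC is the
    trapezoidal area (equivalently the Mann–Whitney U statistic divided by
    n1*n0). The cutoff attains maximal sensitivity; among ties the one with
    maximal specificity is chosen, and an infant is called abnormal when
    power >= cutoff.
    """
    predictor, abnormal = _complete(predictor, np.asarray(abnormal, float))
    abnormal = abnormal.astype(bool)
    n1, n0 = int(abnormal.sum()), int((~abnormal).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    auc = float(roc_auc_score(abnormal, predictor))
    fpr, tpr, thr = roc_curve(abnormal, predictor)
    sens, spec = tpr, 1.0 - fpr
    best_sens = sens.max()
    ties = np.flatnonzero(sens >= best_sens - 1e-12)
    k = ties[np.argmax(spec[ties])]
    cutoff = float(thr[k]) if np.isfinite(thr[k]) else float(predictor.min())
    return ROCResult(
        auc=auc, thresholds=thr, sensitivities=sens, specificities=spec,
        chosen_cutoff=cutoff, chosen_sensitivity=float(sens[k]),
        chosen_specificity=float(spec[k]), n_abnormal=n1, n_normal=n0,
    )


def required_sample_size(r2: float, power: float = 0.80,
                         alpha: float = DEFAULT_ALPHA) -> int:
    """Minimum n to detect a correlation of squared magnitude r2.

    Fisher-z approximation for a two-sided test of Pearson r = sqrt(r2):

        n = ceil( ((z_{1-alpha/2} + z_{power}) / atanh(r))^2 + 3 )

    For r2 = 0.26, power = 0.80, alpha = 0.05 this gives 28.
    """
    if not (0 < r2 < 1 and 0 < power < 1 and 0 < alpha < 1):
        raise ValueError("r2, power and alpha must lie in (0, 1)")
    r = np.sqrt(r2)
    z_alpha = sps.norm.ppf(1.0 - alpha / 2.0)
    z_power = sps.norm.ppf(power)
    n = ((z_alpha + z_power) / np.arctanh(r)) ** 2 + 3.0
    return int(np.ceil(n - 1e-9))


def run_outcome_analysis(cohort: pd.DataFrame,
                         channels: list[str] | None = None,
                         outcomes: list[str] | None = None,
                         covariate: str = "mri_score",
                         n_boot: int = DEFAULT_N_BOOT,
                         seed: int = 0,
                         bh_correct: bool = False,
                         abnormal_cutoff: float = ABNORMAL_CUTOFF,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full outcome analysis of a cohort table.

    For every (channel, outcome) pair: plain and covariate-adjusted
    correlations between that channel's mean burst power and the outcome
    score; for every composite outcome: ROC of power against the
    abnormal flag (score < ``abnormal_cutoff``). Pairs with missing scores
    are dropped pairwise. Significance uses the conjunction rule; optional
    Benjamini–Hochberg correction recomputes the p criterion on adjusted
    p-values (off by default).

    Returns ``(correlations, rocs)`` long-format tables.
    """
    if len(cohort) < 3:
        raise ValueError("cohort must contain at least 3 infants")
    power_cols = [c for c in cohort.columns if c.startswith("power_")]
    all_channels = [c.removeprefix("power_").removesuffix("_uV2") for c in power_cols]
    channels = channels or all_channels
    outcomes = outcomes or [c for c in COMPOSITES if c in cohort.columns]
    rows = []
    rocs = []
    for ci, ch in enumerate(channels):
        col = f"power_{ch}_uV2"
        if col not in cohort.columns:
            raise KeyError(f"no power column for channel {ch!r}")
        for oi, outcome in enumerate(outcomes):
            sub_seed = seed + 7919 * ci + 104729 * oi
            plain = pearson_with_bootstrap(cohort[col], cohort[outcome],
                                           n_boot=n_boot, seed=sub_seed)
            results = [("plain", plain)]
            if covariate and covariate in cohort.columns:
                adj = partial_pearson(cohort[col], cohort[outcome],
                                      cohort[covariate], n_boot=n_boot,
                                      seed=sub_seed + 1)
                results.append(("adjusted", adj))
            for kind, res in results:
                rows.append({
                    "channel": ch, "outcome": outcome, "adjusted": kind == "adjusted",
                    "r": res.r, "p": res.p, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "n": res.n,
                    "significant": res.significant,
                })
            if outcome in COMPOSITES:
                flags = cohort[outcome] < abnormal_cutoff
                ok = cohort[outcome].notna() & cohort[col].notna()
                if flags[ok].nunique() == 2:
                    roc = roc_analysis(cohort.loc[ok, col], flags[ok])
                    rocs.append({
                        "outcome": outcome, "channel": ch, "auc": roc.auc,
                        "cutoff_uV2": roc.chosen_cutoff,
                        "sensitivity": roc.chosen_sensitivity,
                        "specificity": roc.chosen_specificity,
                        "n_abnormal": roc.n_abnormal, "n_normal": roc.n_normal,
                    })
    corr = pd.DataFrame(rows)
    if bh_correct and len(corr):
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(corr["p"].fillna(1.0),
                                            alpha=DEFAULT_ALPHA, method="fdr_bh")
        corr["p_bh"] = p_adj
        corr["significant"] = reject & (
            (corr["ci_low"] > 0) | (corr["ci_high"] < 0)
        )
    return corr, pd.DataFrame(rocs)
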