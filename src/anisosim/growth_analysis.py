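"""From per-subject directional scaling factors to growth curves and group tests.

A *scaling record* is one measurement ``s(i, j, d, k)``: subject ``i``, ROI
``j``, scaling direction ``d ∈ {1,2,3}``, reference image ``k``.  Records are
held in a pandas DataFrame with columns
``subject, age, sex, roi, direction, reference, scaling``.

The analysis chain:

* normalization of reference-relative factors by the neonate-baseline mean,
  so a factor of 1 means "birth size" and larger values measure expansion
  since birth along that direction;
* sex-balance weights: within a 2-year window centered on each subject's
  age, a female subject is weighted by the fraction of males in the window
  and vice versa, so locally over-represented sexes do not dominate the fit;
* weighted nonlinear least squares (multi-start trust-region
  Levenberg-Marquardt-type solver) for four saturating growth families —
  rational (degree 1 / degree 1), Weibull, Gompertz, exponential;
* model comparison by AICc and Akaike weights;
* two-tailed Mann-Whitney U tests per (age interval × ROI × direction) cell
  with Benjamini-Hochberg FDR control and the effect size
  ``d = (median(S_m) − median(S_f)) / (σ(S_m) + σ(S_f))``;
* reference-influence metrics: pairwise relative distance
  ``D_{k,l} = 2|s_k − s_l| / (s_k + s_l)`` and the relative standard
  deviation across references.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .pointset_estimation import FitReport
from .synthetic_fixtures import GROWTH_FAMILIES

logger = logging.getLogger(__name__)

__all__ = [
    "RECORD_COLUMNS",
    "GrowthFitResult",
    "GroupTestResult",
    "extract_scaling_factors",
    "normalize_to_baseline",
    "gender_balance_weights",
    "fit_growth_model",
    "goodness_stats",
    "akaike_weights",
    "select_model",
    "compare_groups",
    "reference_influence",
    "confidence_bands",
    "validate_records",
]

RECORD_COLUMNS = ("subject", "age", "sex", "roi", "direction", "reference", "scaling")

MODEL_N_PARAMS = {"rational": 3, "weibull": 4, "gompertz": 3, "exponential": 3}


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"scaling-record table is missing columns {sorted(missing)}")
    if (records["scaling"] <= 0).any():
        raise ValueError("scaling factors must be positive")
    if (records["age"] < 0).any():
        raise ValueError("ages must be nonnegative")
    return records


# ---------------------------------------------------------------------------
# Scaling-factor extraction and normalization
# ---------------------------------------------------------------------------

def extract_scaling_factors(report: FitReport) -> np.ndarray:
    """Per-direction scalings of an anisotropic-similarity fit, in frame order."""
    if report.transform.kind != "anisotropic_similarity" or report.decomposition is None:
        raise ValueError(
            "scaling factors require an anisotropic-similarity fit with its decomposition"
        )
    return report.decomposition.S.copy()


def normalize_to_baseline(
    records: pd.DataFrame, baseline_subjects: Iterable[str]
) -> pd.DataFrame:
    """Divide factors by the baseline-subject mean per (roi, direction, reference).

    The baseline group plays the role of a neonate cohort: after
    normalization its mean is exactly 1 and every factor reads as expansion
    since birth.  Raises if the baseline is empty for some cell, listing the
    offending (roi, direction) combinations.
    """
    validate_records(records)
    base_ids = set(baseline_subjects)
    if not base_ids:
        raise ValueError("baseline group is empty")
    out = records.copy()
    keys = ["roi", "direction", "reference"]
    base = records[records["subject"].isin(base_ids)]
    means = base.groupby(keys)["scaling"].mean()
    all_cells = records[keys].drop_duplicates()
    missing = [
        tuple(row)
        for row in all_cells.itertuples(index=False)
        if tuple(row) not in means.index
    ]
    if missing:
        raise ValueError(
            f"baseline group has no records for cells {missing[:10]}"
            + (" …" if len(missing) > 10 else "")
        )
    denom = out[keys].merge(means.rename("base_mean"), on=keys, how="left")["base_mean"]
    out["scaling"] = out["scaling"].to_numpy() / denom.to_numpy()
    return out


def gender_balance_weights(
    ages: np.ndarray, sexes: Sequence[str], window: float = 2.0
) -> np.ndarray:
    """Local sex-balance correction weights.

    For subject ``i``, count females ``n_f``, males ``n_m`` and total ``n``
    in the window ``[age_i − window/2, age_i + window/2]``; the weight is
    ``n_m/n`` for a female and ``n_f/n`` for a male.  A window containing a
    single sex yields zero weights there (logged once as a warning).
    """
    ages = np.asarray(ages, dtype=float)
    is_male = np.asarray([s == "male" for s in sexes])
    h = window / 2.0
    w = np.empty(len(ages))
    zero_cells = 0
    for i, a in enumerate(ages):
        sel = np.abs(ages - a) <= h
        n = int(sel.sum())
        n_m = int(is_male[sel].sum())
        n_f = n - n_m
        w[i] = (n_f if is_male[i] else n_m) / n
        if w[i] == 0:
            zero_cells += 1
    if zero_cells:
        logger.warning(
            "%d subjects received zero sex-balance weight (single-sex window)",
            zero_cells,
        )
    return w


# ---------------------------------------------------------------------------
# Growth models and goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class GrowthFitResult:
    """One fitted growth model on (age, scaling) data."""

    family: str
    coefficients: np.ndarray
    n: int
    p: int
    mse: float
    loglik: float
    aic: float
    aicc: float
    fitted: np.ndarray
    ages: np.ndarray
    values: np.ndarray
    weights: np.ndarray
    converged: bool = True
    akaike_weight: Optional[float] = None
    identifiability_warning: Optional[str] = None

    def predict(self, ages) -> np.ndarray:
        return GROWTH_FAMILIES[self.family](np.asarray(ages, dtype=float),
                                            *self.coefficients)


class FitFailedError(RuntimeError):
    """No start of the nonlinear solver converged."""


def goodness_stats(
    values: np.ndarray,
    fitted: np.ndarray,
    p: int,
    weights: Optional[np.ndarray] = None,
) -> Tuple[float, float, float, float]:
    """(MSE, AIC, AICc, log-likelihood) of a fitted curve.

    MSE is the plain mean of squared errors.  The log-likelihood is Gaussian
    with per-point variance ``σ²/w_i`` (weights normalized to mean 1) and the
    maximum-likelihood variance estimate ``σ̂² = (1/n) Σ w_i r_i²``.
    ``AIC = 2p − 2 ln L̂`` and ``AICc = AIC + 2p(p+1)/(n−p−1)``; ``p`` counts
    the curve coefficients.  AICc requires ``n > p + 1``.
    """
    y = np.asarray(values, dtype=float)
    yh = np.asarray(fitted, dtype=float)
    n = len(y)
    if n <= p + 1:
        raise ValueError(f"AICc needs n > p + 1 (n={n}, p={p})")
    r = y - yh
    mse = float(np.mean(r**2))
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.sum() <= 0:
            w = np.ones(n)
        w = w * (n / w.sum())
    sigma2 = float(w @ r**2) / n
    sigma2 = max(sigma2, 1e-300)
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)
        loglik = float(
            -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + 0.5 * logw[w > 0].sum()
        )
    aic = 2 * p - 2 * loglik
    aicc = aic + 2 * p * (p + 1) / (n - p - 1)
    return mse, aic, aicc, loglik


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Softmax of −½Δ over the candidate set; sums to 1."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    d = a - a.min()
    e = np.exp(-0.5 * d)
    return e / e.sum()


def _starting_points(family: str, ages, values, n_starts: int, seed: int):
    """Coarse grid of starts: asymptote near max(y), rates over decades."""
    rng = np.random.default_rng(seed)
    y = np.asarray(values, dtype=float)
    a0 = float(np.max(y))
    y0 = float(np.mean(y[np.argsort(ages)][: max(3, len(y) // 10)]))
    rates = [0.1, 0.5, 1.0, 2.0]
    starts = []
    for c in rates:
        if family == "rational":
            # y(0) = b/c, asymptote a
            starts.append([a0, y0 * c, c])
        elif family == "weibull":
            starts.append([a0, a0 - y0, c, 1.0])
        elif family == "gompertz":
            b = max(np.log(max(a0, 1e-6) / max(y0, 1e-6)), 1e-3)
            starts.append([a0, b, c])
        elif family == "exponential":
            starts.append([a0, y0 - a0, c])
    while len(starts) < n_starts:
        base = starts[len(starts) % len(rates)]
        jitter = rng.uniform(0.5, 1.5, size=len(base))
        starts.append(list(np.asarray(base) * jitter))
    return starts[:n_starts]


_BOUNDS = {
    # keep rates positive; the rational pole x = −c must stay left of age 0
    "rational": ([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
    "weibull": ([-np.inf, -np.inf, 1e-6, 1e-3], [np.inf, np.inf, np.inf, 10.0]),
    "gompertz": ([1e-9, 1e-9, 1e-6], [np.inf, np.inf, np.inf]),
    "exponential": ([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
}


def fit_growth_model(
    family: str,
    ages: np.ndarray,
    values: np.ndarray,
    weights: Optional[np.ndarray] = None,
    n_starts: int = 10,
    seed: int = 0,
) -> GrowthFitResult:
    """Weighted nonlinear least squares for one growth family, multi-start.

    Starts are drawn from a coarse grid (asymptote ≈ max(y), rates in
    {0.1, 0.5, 1, 2}) plus seeded jitter; the best converged start wins.  A
    near-singular Jacobian at the optimum (e.g. the rational family's
    ``b = a·c`` ridge on flat data) is reported via
    ``identifiability_warning`` rather than altered.
    """
    if family not in GROWTH_FAMILIES:
        raise ValueError(f"unknown growth family {family!r}")
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be nonnegative")
    p = MODEL_N_PARAMS[family]
    n = len(y)
    if n <= p:
        raise ValueError(f"need n > p data points (n={n}, p={p})")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    fun = GROWTH_FAMILIES[family]
    lo, hi = _BOUNDS[family]

    def residuals(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            pred = fun(ages, *theta)
        return sw * (np.nan_to_num(pred, nan=1e6, posinf=1e6, neginf=-1e6) - y)

    best = None
    for theta0 in _starting_points(family, ages, y, n_starts, seed):
        theta0 = np.clip(theta0, lo, hi)
        try:
            sol = optimize.least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None:
        raise FitFailedError(f"no start converged for the {family} model")

    theta = best.x
    fitted = fun(ages, *theta)
    mse, aic, aicc, loglik = goodness_stats(y, fitted, p, w)
    warning = None
    J = best.jac
    if J.size:
        sv = np.linalg.svd(J, compute_uv=False)
        if sv[0] > 0 and sv[-1] / sv[0] < 1e-8:
            warning = (
                f"near-singular Jacobian (cond ~ {sv[0] / max(sv[-1], 1e-300):.2g}); "
                "coefficients are not individually identifiable"
            )
            logger.warning("%s fit: %s", family, warning)
    return GrowthFitResult(
        family=family,
        coefficients=theta,
        n=n,
        p=p,
        mse=mse,
        loglik=loglik,
        aic=aic,
        aicc=aicc,
        fitted=fitted,
        ages=ages,
        values=y,
        weights=w,
        converged=bool(best.status > 0),
        identifiability_warning=warning,
    )


def select_model(
    ages: np.ndarray,
    values: np.ndarray,
    weights: Optional[np.ndarray] = None,
    families: Sequence[str] = ("rational", "weibull", "gompertz", "exponential"),
    n_starts: int = 10,
    seed: int = 0,
) -> Tuple[str, Dict[str, GrowthFitResult]]:
    """Fit every candidate family and pick the lowest AICc.

    Failed fits are recorded (absent from the table) and excluded from the
    comparison; Akaike weights are attached to the survivors.
    """
    table: Dict[str, GrowthFitResult] = {}
    for fam in families:
        try:
            table[fam] = fit_growth_model(
                fam, ages, values, weights, n_starts=n_starts, seed=seed
            )
        except (FitFailedError, ValueError) as exc:
            logger.warning("fit of %s failed: %s", fam, exc)
    if not table:
        raise FitFailedError("all candidate model fits failed")
    names = list(table)
    wts = akaike_weights([table[f].aicc for f in names])
    for f, w in zip(names, wts):
        table[f].akaike_weight = float(w)
    best = min(names, key=lambda f: table[f].aicc)
    return best, table


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupTestResult:
    roi: str
    direction: int
    interval: Tuple[float, float]
    n_male: int
    n_female: int
    p_value: float
    effect_size: float
    rejected: bool = False
    p_adjusted: float = np.nan
    small_sample: bool = False


DEFAULT_AGE_INTERVALS = ((0.0, 0.1), (0.1, 6.0), (6.0, 12.0), (12.0, np.inf))


def effect_size_d(male: np.ndarray, female: np.ndarray) -> float:
    """``d = (median(S_m) − median(S_f)) / (σ(S_m) + σ(S_f))``, sample σ (ddof=1)."""
    sm = np.std(male, ddof=1) if len(male) > 1 else 0.0
    sf = np.std(female, ddof=1) if len(female) > 1 else 0.0
    denom = sm + sf
    if denom == 0:
        return 0.0
    return float((np.median(male) - np.median(female)) / denom)


def _mwu_p(male: np.ndarray, female: np.ndarray) -> float:
    """Two-tailed Mann-Whitney p: exact for small tie-free samples, else normal."""
    n_tot = len(male) + len(female)
    has_ties = len(np.unique(np.concatenate([male, female]))) < n_tot
    method = "exact" if (n_tot <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(male, female, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def compare_groups(
    records: pd.DataFrame,
    age_intervals: Sequence[Tuple[float, float]] = DEFAULT_AGE_INTERVALS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Male-vs-female tests per (age interval × ROI × direction) cell.

    Intervals are half-open ``(lo, hi]`` except the first, which includes its
    lower bound (the neonate baseline at age 0).  BH-FDR at ``alpha`` is
    applied across the full family of computed tests.  Cells with an empty
    group are skipped with a warning; cells with fewer than 3 per group are
    flagged ``small_sample``.
    """
    validate_records(records)
    results: List[GroupTestResult] = []
    for lo, hi in age_intervals:
        if lo == age_intervals[0][0]:
            in_age = (records["age"] >= lo) & (records["age"] <= hi)
        else:
            in_age = (records["age"] > lo) & (records["age"] <= hi)
        sub = records[in_age]
        for (roi, direction), cell in sub.groupby(["roi", "direction"], sort=True):
            male = cell.loc[cell["sex"] == "male", "scaling"].to_numpy()
            female = cell.loc[cell["sex"] == "female", "scaling"].to_numpy()
            if len(male) == 0 or len(female) == 0:
                logger.warning(
                    "skipping cell roi=%s dir=%s interval=(%s, %s]: empty group",
                    roi, direction, lo, hi,
                )
                continue
            results.append(
                GroupTestResult(
                    roi=str(roi),
                    direction=int(direction),
                    interval=(float(lo), float(hi)),
                    n_male=len(male),
                    n_female=len(female),
                    p_value=_mwu_p(male, female),
                    effect_size=effect_size_d(male, female),
                    small_sample=min(len(male), len(female)) < 3,
                )
            )
    if not results:
        return pd.DataFrame(
            columns=[
                "roi", "direction", "interval_low", "interval_high", "n_male",
                "n_female", "p_value", "p_adjusted", "rejected", "effect_size",
                "small_sample",
            ]
        )
    pvals = np.array([r.p_value for r in results])
    rejected, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "roi": [r.roi for r in results],
            "direction": [r.direction for r in results],
            "interval_low": [r.interval[0] for r in results],
            "interval_high": [r.interval[1] for r in results],
            "n_male": [r.n_male for r in results],
            "n_female": [r.n_female for r in results],
            "p_value": pvals,
            "p_adjusted": p_adj,
            "rejected": rejected,
            "effect_size": [r.effect_size for r in results],
            "small_sample": [r.small_sample for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Reference-image influence
# ---------------------------------------------------------------------------

def reference_influence(records: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify how much the choice of reference image moves the factors.

    Returns ``(pairwise, relstd)``: the pairwise relative distance
    ``D_{k,l}(i,j,d) = 2|s_k − s_l| / (s_k + s_l)`` for every reference pair,
    and the per-measurement relative standard deviation
    ``D(i,j,d) = σ(s(i,j,d,·)) / mean(s(i,j,d,·))`` (sample σ, ddof=1).
    Incomplete (subject, roi, direction) cells are excluded; the count is
    reported via a logged warning.
    """
    validate_records(records)
    refs = sorted(records["reference"].unique())
    if len(refs) < 2:
        raise ValueError("reference influence needs at least 2 references")
    wide = records.pivot_table(
        index=["subject", "roi", "direction"],
        columns="reference",
        values="scaling",
    )
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.warning(
            "%d (subject, roi, direction) cells lack some references; excluded",
            n_dropped,
        )
    pair_rows = []
    for a in range(len(refs)):
        for b in range(a + 1, len(refs)):
            sk = complete[refs[a]].to_numpy()
            sl = complete[refs[b]].to_numpy()
            D = 2.0 * np.abs(sk - sl) / (sk + sl)
            df = complete.reset_index()[["subject", "roi", "direction"]].copy()
            df["reference_k"] = refs[a]
            df["reference_l"] = refs[b]
            df["D"] = D
            pair_rows.append(df)
    pairwise = pd.concat(pair_rows, ignore_index=True)
    vals = complete.to_numpy()
    relstd = complete.reset_index()[["subject", "roi", "direction"]].copy()
    relstd["D"] = np.std(vals, axis=1, ddof=1) / np.mean(vals, axis=1)
    relstd.attrs["n_dropped"] = n_dropped
    pairwise.attrs["n_dropped"] = n_dropped
    return pairwise, relstd


# ---------------------------------------------------------------------------
# Bootstrap confidence bands
# ---------------------------------------------------------------------------

def confidence_bands(
    fit: GrowthFitResult,
    level: float = 0.99,
    n_boot: int = 500,
    seed: int = 0,
    age_grid: Optional[np.ndarray] = None,
) -> Dict[str, np.ndarray]:
    """Pointwise percentile bootstrap band around a fitted growth curve.

    Cases (age, value, weight) are resampled with replacement and the model
    refit from the original solution; the band is the pointwise
    ``(1±level)/2`` percentile envelope over an age grid.  This is a
    *pointwise* band, not a simultaneous one, and is labelled as such in the
    returned dict.  If more than 20% of bootstrap refits fail, the band is
    flagged unreliable.
    """
    if not fit.converged:
        raise ValueError("confidence band needs a converged fit")
    rng = np.random.default_rng(seed)
    if age_grid is None:
        age_grid = np.linspace(float(fit.ages.min()), float(fit.ages.max()), 60)
    fun = GROWTH_FAMILIES[fit.family]
    lo_b, hi_b = _BOUNDS[fit.family]
    n = fit.n
    curves = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        a, v, w = fit.ages[idx], fit.values[idx], fit.weights[idx]
        sw = np.sqrt(w)

        def residuals(theta):
            with np.errstate(over="ignore", invalid="ignore"):
                pred = fun(a, *theta)
            return sw * (np.nan_to_num(pred, nan=1e6, posinf=1e6, neginf=-1e6) - v)

        try:
            sol = optimize.least_squares(
                residuals, np.clip(fit.coefficients, lo_b, hi_b),
                bounds=(lo_b, hi_b), method="trf", max_nfev=500,
            )
            if not np.all(np.isfinite(sol.x)):
                raise RuntimeError("non-finite solution")
            curves.append(fun(age_grid, *sol.x))
        except Exception:
            failures += 1
    if not curves:
        raise FitFailedError("every bootstrap refit failed")
    unreliable = failures > 0.2 * n_boot
    if unreliable:
        warnings.warn(
            f"{failures}/{n_boot} bootstrap refits failed; band unreliable",
            RuntimeWarning,
        )
    stackc = np.vstack(curves)
    q = (1.0 - level) / 2.0
    return {
        "ages": age_grid,
        "lower": np.quantile(stackc, q, axis=0),
        "upper": np.quantile(stackc, 1.0 - q, axis=0),
        "center": fit.predict(age_grid),
        "level": np.array(level),
        "kind": "pointwise bootstrap",
        "n_failed": np.array(failures),
        "unreliable": np.array(unreliable),
    }
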