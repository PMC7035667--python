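"""Reader-agreement statistics: weighted kappa, ICC, and verbal bands.

Two-reader designs only. Ordinal grades are compared with Cohen's
weighted kappa (linear weights by default; the scheme is always echoed
in the result metadata) with a seeded percentile-bootstrap confidence
interval. Continuous measurements are compared with the intraclass
correlation coefficient from the two-way mean-squares decomposition
(absolute-agreement, single-measures by default) with the standard
F-distribution confidence interval.

Verbal interpretation follows the Landis-Koch bands for kappa and the
Koo-Li bands for ICC (0.9 and above excellent, 0.75-0.9 good, half-open
upward).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f as f_dist
from sklearn.metrics import cohen_kappa_score

logger = logging.getLogger(__name__)

KAPPA_BANDS = (  # Landis-Koch; upper edges inclusive
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost_perfect"),
)

ICC_BANDS = (  # Koo-Li; lower edges inclusive
    (0.5, "poor"),
    (0.75, "moderate"),
    (0.9, "good"),
    (None, "excellent"),
)

ICC_FORMS = {
    "one_way_single": "ICC(1,1)",
    "two_way_consistency_single": "ICC(C,1)",
    "two_way_absolute_single": "ICC(A,1)",
    "one_way_average": "ICC(1,k)",
    "two_way_consistency_average": "ICC(C,k)",
    "two_way_absolute_average": "ICC(A,k)",
}


@dataclass(frozen=True)
class RatingSeries:
    """One rater's values over a fixed item set."""

    rater: str
    item_ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        if len(self.item_ids) != values.size:
            raise ValueError("item_ids and values must have equal length")


def _check_aligned(r1, r2) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(r1, RatingSeries) and isinstance(r2, RatingSeries):
        if r1.item_ids != r2.item_ids:
            raise ValueError("rating series must cover identical items in order")
        return r1.values, r2.values
    a1, a2 = np.asarray(r1, dtype=float), np.asarray(r2, dtype=float)
    if a1.shape != a2.shape or a1.ndim != 1:
        raise ValueError("ratings must be two equal-length 1-D series")
    return a1, a2


@dataclass
class AgreementResult:
    """Estimate, 95% CI, method metadata and verbal band for one comparison."""

    statistic: str  # weighted_kappa | icc | pearson_r
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    method: dict = field(default_factory=dict)
    band: str | None = None


def interpret_kappa(k: float) -> str:
    """Landis-Koch verbal band for a kappa value in [-1, 1]."""
    if not -1 <= k <= 1:
        raise ValueError(f"kappa must be in [-1, 1], got {k}")
    for edge, label in KAPPA_BANDS:
        if k <= edge:
            return label
    raise AssertionError("unreachable")


def interpret_icc(v: float) -> str:
    """Koo-Li verbal band for an ICC value in [-1, 1]."""
    if not -1 <= v <= 1:
        raise ValueError(f"ICC must be in [-1, 1], got {v}")
    for edge, label in ICC_BANDS:
        if edge is not None and v < edge:
            return label
    return "excellent"


def _kappa_point(
    v1: np.ndarray, v2: np.ndarray, n_categories: int, weights: str
) -> float:
    labels = np.arange(n_categories)
    return float(cohen_kappa_score(v1, v2, labels=labels, weights=weights))


def weighted_kappa(
    r1,
    r2,
    n_categories: int = 4,
    weights: str = "linear",
    seed: int = 0,
    n_boot: int = 2000,
    ci: bool = True,
) -> AgreementResult:
    """Cohen's weighted kappa for two ordinal raters.

    kappa = 1 - sum(w_ij O_ij) / sum(w_ij E_ij) with w_ij = |i-j|/(k-1)
    for linear weights or ((i-j)/(k-1))^2 for quadratic, O the observed
    and E the chance (marginal-product) contingency tables. The 95% CI
    is a seeded percentile bootstrap over items. When both raters use a
    single identical category the statistic is undefined and reported
    as NaN with a warning.
    """
    if weights not in ("linear", "quadratic"):
        raise ValueError("weights must be 'linear' or 'quadratic'")
    v1, v2 = _check_aligned(r1, r2)
    if v1.size < 2:
        raise ValueError("at least 2 items are required")
    for v in (v1, v2):
        if np.any((v < 0) | (v > n_categories - 1)) or np.any(v != np.round(v)):
            raise ValueError(f"ratings must be integers in 0..{n_categories - 1}")
    v1, v2 = v1.astype(int), v2.astype(int)
    method = {"weights": weights, "n_categories": n_categories}
    if len(np.unique(np.concatenate([v1, v2]))) == 1:
        logger.warning(
            "weighted_kappa: all ratings in one category; kappa undefined"
        )
        return AgreementResult("weighted_kappa", float("nan"), method=method)
    est = _kappa_point(v1, v2, n_categories, weights)
    lo = hi = None
    if ci:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, v1.size, size=(n_boot, v1.size))
        reps = np.array(
            [_kappa_point(v1[i], v2[i], n_categories, weights) for i in idx]
        )
        reps = reps[np.isfinite(reps)]
        lo, hi = (float(q) for q in np.percentile(reps, [2.5, 97.5]))
        method.update(
            {"ci_method": "percentile_bootstrap", "n_boot": n_boot, "seed": seed}
        )
    return AgreementResult(
        "weighted_kappa", est, lo, hi, method, interpret_kappa(est)
    )


def _mean_squares(v1: np.ndarray, v2: np.ndarray):
    """Two-way ANOVA mean squares for an n-items x 2-raters table."""
    data = np.stack([v1, v2], axis=1)
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)  # between items
    msc = ss_cols / (k - 1)  # between raters
    mse = ss_err / ((n - 1) * (k - 1))  # residual
    msw = (ss_total - ss_rows) / (n * (k - 1))  # within items (one-way)
    return msr, msc, mse, msw, n, k


def _spearman_brown(x: float, k: int) -> float:
    return k * x / (1 + (k - 1) * x)


def icc(
    r1,
    r2,
    form: str = "two_way_absolute_single",
    alpha: float = 0.05,
) -> AgreementResult:
    """Intraclass correlation coefficient for two raters.

    Computed from the two-way (or one-way) mean-squares decomposition
    for the chosen form, with the standard F-distribution confidence
    interval for that form. The default form (two-way random effects,
    absolute agreement, single measures) is the appropriate reliability
    index for inter-rater designs in which systematic reader offsets
    count as disagreement; the consistency form ignores such offsets.
    Undefined (NaN, with a warning) when all ratings are identical.
    """
    if form not in ICC_FORMS:
        raise ValueError(f"unknown ICC form {form!r}; one of {sorted(ICC_FORMS)}")
    v1, v2 = _check_aligned(r1, r2)
    if v1.size < 3:
        raise ValueError("ICC needs at least 3 items")
    if np.any(~np.isfinite(v1)) or np.any(~np.isfinite(v2)):
        raise ValueError("ratings must be finite")
    method = {"form": form, "icc_type": ICC_FORMS[form], "ci_method": "f_distribution"}
    msr, msc, mse, msw, n, k = _mean_squares(v1, v2)
    if np.isclose(msr, 0) and np.isclose(msw, 0):
        logger.warning("icc: zero between-item variance; ICC undefined")
        return AgreementResult("icc", float("nan"), method=method)
    q = 1 - alpha / 2
    if form in ("one_way_single", "one_way_average"):
        est1 = (msr - msw) / (msr + (k - 1) * msw)
        fobs = msr / msw
        fl = fobs / f_dist.ppf(q, n - 1, n * (k - 1))
        fu = fobs * f_dist.ppf(q, n * (k - 1), n - 1)
        lo1 = (fl - 1) / (fl + k - 1)
        hi1 = (fu - 1) / (fu + k - 1)
        if form == "one_way_single":
            est, lo, hi = est1, lo1, hi1
        else:
            est, lo, hi = 1 - 1 / fobs, 1 - 1 / fl, 1 - 1 / fu
    elif form in ("two_way_consistency_single", "two_way_consistency_average"):
        fobs = msr / mse
        fl = fobs / f_dist.ppf(q, n - 1, (n - 1) * (k - 1))
        fu = fobs * f_dist.ppf(q, (n - 1) * (k - 1), n - 1)
        if form == "two_way_consistency_single":
            est = (msr - mse) / (msr + (k - 1) * mse)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        else:
            est, lo, hi = (msr - mse) / msr, 1 - 1 / fl, 1 - 1 / fu
    else:  # absolute agreement
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        est1 = (msr - mse) / denom
        # Satterthwaite df for the absolute-agreement interval
        a = k * est1 / (n * (1 - est1)) if est1 != 1 else np.inf
        b = 1 + k * est1 * (n - 1) / (n * (1 - est1)) if est1 != 1 else np.inf
        if np.isfinite(a) and np.isfinite(b):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = f_dist.ppf(q, n - 1, v)
            f2 = f_dist.ppf(q, v, n - 1)
            lo1 = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi1 = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr
            )
        else:
            lo1 = hi1 = 1.0
        if form == "two_way_absolute_single":
            est, lo, hi = est1, lo1, hi1
        else:
            est = _spearman_brown(est1, k)
            lo, hi = _spearman_brown(lo1, k), _spearman_brown(hi1, k)
    if not np.isfinite(est):
        logger.warning("icc: estimate undefined for these ratings")
        return AgreementResult("icc", float("nan"), method=method)
    band = interpret_icc(est) if -1 <= est <= 1 else None
    return AgreementResult(
        "icc", float(est), float(lo), float(hi), method, band
    )


def band_tally(results: list[AgreementResult]) -> dict[str, dict]:
    """Counts and percentages per verbal band, per statistic family.

    Empty bands are listed explicitly with count 0.
    """
    if not results:
        raise ValueError("at least one result is required")
    out: dict[str, dict] = {}
    for family, bands in (
        ("weighted_kappa", [b for _, b in KAPPA_BANDS]),
        ("icc", [b for _, b in ICC_BANDS]),
        ("pearson_r", []),
    ):
        fam = [r for r in results if r.statistic == family]
        if not fam:
            continue
        labels = bands or sorted({r.band for r in fam if r.band})
        counts = {b: 0 for b in labels}
        for r in fam:
            if r.band is not None:
                counts[r.band] += 1
        total = sum(counts.values())
        out[family] = {
            "counts": counts,
            "percent": {
                b: (100.0 * c / total if total else 0.0) for b, c in counts.items()
            },
            "n": total,
        }
    return out
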