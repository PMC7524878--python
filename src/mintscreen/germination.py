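"""Germination inhibition estimation and sigmoidal dose-response fitting.

Inhibition is the percent reduction of mean germination under a treatment
relative to the matching (solvent) control,

    g = 100 * (1 - mean(treated germinated) / mean(control germinated)),

with a delta-method standard error from the replicate variances. Dose-
response curves are fitted with the four-parameter log-logistic

    f(d) = lower + (upper - lower) / (1 + (ec50 / d)^slope),

the standard sigmoid for germination and toxicity dose work; with scarce
dose levels a two-parameter variant (lower = 0, upper = 100) is used. Zero
dose cannot enter a log-logistic, so control data define the 0% anchor
rather than a d = 0 point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class FitError(ValueError):
    pass


class InhibitionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# inhibition
# ---------------------------------------------------------------------------

@dataclass
class InhibitionEstimate:
    percent: float
    se: float
    n_treated: int
    n_control: int


def inhibition_percent(
    treated_germinated, control_germinated
) -> InhibitionEstimate:
    """Percent inhibition of germination with a delta-method SE.

    Arguments are per-replicate germinated counts (any common scaling of
    treated and control counts leaves the estimate unchanged). Reported
    values are clamped to at most 100.
    """
    t = np.asarray(treated_germinated, dtype=float)
    c = np.asarray(control_germinated, dtype=float)
    if t.size < 1 or c.size < 1:
        raise InhibitionError("need at least one replicate each")
    mc, mt = c.mean(), t.mean()
    if mc <= 0:
        raise InhibitionError("control mean germination is zero")
    g = 100.0 * (1.0 - mt / mc)
    # delta method on g(mt, mc); SE of each mean from replicate variance
    se_t2 = t.var(ddof=1) / t.size if t.size > 1 else 0.0
    se_c2 = c.var(ddof=1) / c.size if c.size > 1 else 0.0
    se = 100.0 * math.sqrt(se_t2 / mc**2 + (mt**2 / mc**4) * se_c2)
    return InhibitionEstimate(min(g, 100.0), se, t.size, c.size)


def inhibition_table(
    counts: pd.DataFrame, control_column: str = "control"
) -> pd.DataFrame:
    """Per-(treatment, dose) inhibition from a germination count table.

    ``counts`` needs columns treatment, dose, replicate, sown, germinated,
    and a column naming each row's control treatment. Control rows (empty
    control field) are the references.
    """
    controls = {
        name: sub["germinated"].to_numpy()
        for name, sub in counts[counts[control_column].fillna("") == ""].groupby(
            "treatment"
        )
    }
    rows = []
    treated = counts[counts[control_column].fillna("") != ""]
    for (treatment, dose), sub in treated.groupby(["treatment", "dose"]):
        ctrl_name = sub[control_column].iloc[0]
        if ctrl_name not in controls:
            raise InhibitionError(f"missing control rows for {ctrl_name!r}")
        est = inhibition_percent(sub["germinated"].to_numpy(), controls[ctrl_name])
        rows.append((treatment, dose, est.percent, est.se))
    return pd.DataFrame(rows, columns=["treatment", "dose", "inhibition", "se"])


# ---------------------------------------------------------------------------
# dose-response fitting
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    lower: float
    upper: float
    ec50: float
    slope: float
    rss: float
    converged: bool
    se: dict[str, float]
    model: str  # "LL.4" or "LL.2"

    def predict(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        return self.lower + (self.upper - self.lower) / (
            1.0 + (self.ec50 / d) ** self.slope
        )


def _ll4(d, lower, upper, ec50, slope):
    return lower + (upper - lower) / (1.0 + (ec50 / d) ** slope)


def _ll2(d, ec50, slope):
    return _ll4(d, 0.0, 100.0, ec50, slope)


def fit_dose_response(
    doses,
    responses,
    se=None,
    model: str = "auto",
) -> DoseResponseFit:
    """Least-squares log-logistic fit with multi-start initialization.

    ``model`` is ``"LL.4"``, ``"LL.2"`` (lower fixed at 0, upper at 100), or
    ``"auto"``: LL.4 when there are >= 4 points over >= 3 distinct positive
    doses, else LL.2 (needing >= 2 distinct doses). Optimizer stalls yield
    ``converged=False`` rather than an exception. The EC50 starting grid is
    geometric over the observed dose range and slopes start from
    {0.5, 1, 2, 4}.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape:
        raise FitError("doses and responses differ in length")
    if np.any(d <= 0):
        raise FitError("non-positive dose in a log-logistic model")
    distinct = np.unique(d)
    if np.allclose(y, y[0]):
        raise FitError(
            "all responses identical; fit a flat model instead of a sigmoid"
        )
    if model == "auto":
        model = "LL.4" if (d.size >= 4 and distinct.size >= 3) else "LL.2"
    if model == "LL.4" and (d.size < 4 or distinct.size < 3):
        raise FitError("LL.4 needs >= 4 points over >= 3 distinct doses")
    if model == "LL.2" and distinct.size < 2:
        raise FitError("LL.2 needs >= 2 distinct doses")

    sigma = None
    if se is not None:
        sigma = np.clip(np.asarray(se, dtype=float), 1e-6, None)

    ec50_grid = np.geomspace(distinct.min(), distinct.max(), 5)
    slope_grid = [0.5, 1.0, 2.0, 4.0]
    span = float(y.max() - y.min())

    best = None
    for e0 in ec50_grid:
        for s0 in slope_grid:
            try:
                if model == "LL.4":
                    p0 = [float(y.min()), float(y.max()), e0, s0]
                    bounds = (
                        [-50.0, -50.0, distinct.min() / 1e3, 0.01],
                        [150.0, 150.0, distinct.max() * 1e3, 50.0],
                    )
                    popt, pcov = curve_fit(
                        _ll4, d, y, p0=p0, sigma=sigma, bounds=bounds,
                        maxfev=20000,
                    )
                    resid = y - _ll4(d, *popt)
                else:
                    p0 = [e0, s0]
                    bounds = (
                        [distinct.min() / 1e3, 0.01],
                        [distinct.max() * 1e3, 50.0],
                    )
                    popt, pcov = curve_fit(
                        _ll2, d, y, p0=p0, sigma=sigma, bounds=bounds,
                        maxfev=20000,
                    )
                    resid = y - _ll2(d, *popt)
            except (RuntimeError, ValueError):
                continue
            rss = float(resid @ resid)
            if best is None or rss < best[0]:
                best = (rss, popt, pcov)

    names = (
        ["lower", "upper", "ec50", "slope"] if model == "LL.4"
        else ["ec50", "slope"]
    )
    if best is None:
        return DoseResponseFit(
            0.0, 100.0, float("nan"), float("nan"), float("nan"),
            converged=False, se={k: float("nan") for k in names}, model=model,
        )
    rss, popt, pcov = best
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    ses = {k: float(v) for k, v in zip(names, perr)}
    if model == "LL.4":
        lower, upper, ec50, slope = map(float, popt)
        if lower > upper:  # re-express with the conventional orientation
            lower, upper, slope = upper, lower, -slope
    else:
        lower, upper = 0.0, 100.0
        ec50, slope = map(float, popt)
    converged = bool(
        np.isfinite(ec50) and ec50 > 0
        and (span < 1e-9 or rss < max(1e3, 1e6 * span))
    )
    return DoseResponseFit(lower, upper, ec50, slope, rss, converged, ses, model)


# ---------------------------------------------------------------------------
# EC50 fold change
# ---------------------------------------------------------------------------

@dataclass
class FoldChange:
    ratio: float
    log_se: float  # SE of ln(ratio)

    @property
    def ci95(self) -> tuple[float, float]:
        lo = self.ratio * math.exp(-1.96 * self.log_se)
        hi = self.ratio * math.exp(1.96 * self.log_se)
        return lo, hi


def ec50_fold_change(fit_a: DoseResponseFit, fit_b: DoseResponseFit) -> FoldChange:
    """EC50 ratio a/b with a log-scale propagated standard error."""
    for name, fit in (("a", fit_a), ("b", fit_b)):
        if not fit.converged:
            raise FitError(f"fit {name} did not converge")
    ratio = fit_a.ec50 / fit_b.ec50
    log_se = math.sqrt(
        (fit_a.se.get("ec50", 0.0) / fit_a.ec50) ** 2
        + (fit_b.se.get("ec50", 0.0) / fit_b.ec50) ** 2
    )
    return FoldChange(ratio, log_se)
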