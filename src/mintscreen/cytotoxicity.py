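"""Cytotoxicity readouts: Evans-Blue mortality and AO/EB nucleus classes.

Evans-Blue dye exclusion gives a per-replicate mortality percentage
(stained / scored); condition estimates are means with standard errors
over replicates. The AO/EB double stain grades plasma-membrane
permeabilization by nucleus color: the red fraction r = red / (red +
green) of each nucleus is thresholded into green / orange / red classes
(half-open intervals, configurable thresholds). Line comparisons fit each
cell line's mortality dose series with the log-logistic model and report
the EC50 fold difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .germination import DoseResponseFit, FoldChange, ec50_fold_change, fit_dose_response

#: default red-fraction class boundaries: green < t_low <= orange < t_high <= red
DEFAULT_THRESHOLDS = (0.33, 0.66)

CLASSES = ("green", "orange", "red")


class MortalityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Evans Blue mortality
# ---------------------------------------------------------------------------

@dataclass
class MortalityEstimate:
    percent: float
    se: float
    replicates: int


def mortality_percent(stained, scored) -> MortalityEstimate:
    """Mean percent mortality with SE over replicates.

    ``stained`` and ``scored`` are per-replicate counts; mortality is
    100 * stained / scored per replicate, viability its complement.
    """
    s = np.asarray(stained, dtype=float)
    n = np.asarray(scored, dtype=float)
    if s.size < 1:
        raise MortalityError("need at least one replicate")
    if np.any(n < 1):
        raise MortalityError("zero cells scored in a replicate")
    if np.any(s > n) or np.any(s < 0):
        raise MortalityError("stained counts outside [0, scored]")
    pct = 100.0 * s / n
    se = float(pct.std(ddof=1) / np.sqrt(pct.size)) if pct.size > 1 else 0.0
    return MortalityEstimate(float(pct.mean()), se, int(pct.size))


def mortality_table(records: pd.DataFrame) -> pd.DataFrame:
    """Condition-level mortality from a replicate count table.

    ``records`` needs columns compound, line, dose, time, scored, stained;
    replicates are the rows sharing a (compound, line, dose, time) key.
    """
    rows = []
    for key, sub in records.groupby(["compound", "line", "dose", "time"]):
        est = mortality_percent(sub["stained"].to_numpy(), sub["scored"].to_numpy())
        rows.append((*key, est.percent, est.se, est.replicates))
    return pd.DataFrame(
        rows,
        columns=["compound", "line", "dose", "time", "mortality", "se",
                 "replicates"],
    )


# ---------------------------------------------------------------------------
# AO/EB nucleus classification
# ---------------------------------------------------------------------------

class UnclassifiableNucleus(ValueError):
    pass


def classify_nucleus(
    green: float, red: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Class of one nucleus from its green/red intensities.

    green if r < t_low; orange if t_low <= r < t_high; red if r >= t_high,
    with r = red / (red + green). Both intensities zero is unclassifiable.
    """
    t_low, t_high = thresholds
    if not 0.0 <= t_low < t_high <= 1.0:
        raise ValueError(f"invalid thresholds {thresholds}")
    if green < 0 or red < 0:
        raise ValueError("negative intensity")
    total = green + red
    if total == 0:
        raise UnclassifiableNucleus("both intensities are zero")
    r = red / total
    if r < t_low:
        return "green"
    if r < t_high:
        return "orange"
    return "red"


@dataclass
class ClassDistribution:
    compound: str
    dose: float
    counts: dict[str, int]
    unclassifiable: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.total
        return {k: v / n for k, v in self.counts.items()}


def class_frequency_distribution(
    records: pd.DataFrame,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> list[ClassDistribution]:
    """Green/orange/red frequency distribution per (compound, dose).

    ``records`` needs columns compound, dose, green, red. Unclassifiable
    nuclei (both intensities 0) are tallied but excluded from frequencies;
    a condition with no classifiable nucleus is an error.
    """
    out = []
    for (compound, dose), sub in records.groupby(["compound", "dose"]):
        counts = {c: 0 for c in CLASSES}
        unclassifiable = 0
        for green, red in zip(sub["green"], sub["red"]):
            try:
                counts[classify_nucleus(green, red, thresholds)] += 1
            except UnclassifiableNucleus:
                unclassifiable += 1
        if sum(counts.values()) == 0:
            raise MortalityError(
                f"no classifiable nuclei for {compound!r} at dose {dose}"
            )
        out.append(ClassDistribution(compound, dose, counts, unclassifiable))
    return out


# ---------------------------------------------------------------------------
# line sensitivity
# ---------------------------------------------------------------------------

@dataclass
class LineSensitivity:
    fold: FoldChange
    fit_a: DoseResponseFit
    fit_b: DoseResponseFit


def line_sensitivity(
    series_a: pd.DataFrame,
    series_b: pd.DataFrame,
    model: str = "LL.2",
) -> LineSensitivity:
    """EC50 fold difference between two mortality dose series.

    Each series needs columns dose and mortality (a per-dose percentage,
    e.g. from :func:`mortality_table`); the ratio reported is
    EC50(a) / EC50(b), so a value above 1 means line b is the more
    sensitive. Fits are unweighted: with a handful of replicates the
    empirical per-dose SEs are noisy and collapse toward zero at saturating
    doses, which would misweight the fit far more than equal weights do.
    """
    fits = []
    for name, series in (("a", series_a), ("b", series_b)):
        if series["dose"].nunique() < 4:
            raise MortalityError(f"series {name}: need >= 4 dose points")
        fits.append(
            fit_dose_response(
                series["dose"].to_numpy(),
                series["mortality"].to_numpy(),
                model=model,
            )
        )
    fold = ec50_fold_change(fits[0], fits[1])
    return LineSensitivity(fold, fits[0], fits[1])
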