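"""Back/forward-adjustment of male carapace length to the mating year.

Lobsters grow by moulting, roughly once a year for small males and less
often for large ones.  From mark-recapture records of males measured in two
consecutive years we fit (i) a logistic regression of moult probability on
CL at first capture and (ii) a linear regression of the yearly increment on
CL over the moulted subset.  A male's size in the mating year is then

    CL_adjusted = CL_measured + (year_female - year_male) * g(CL) * p_moult(CL)

evaluated once at the measured size (a single-step extrapolation; negative
year differences subtract growth).  A moult is inferred when the measured
year-to-year difference is 5 mm or more; smaller differences are treated as
measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import statsmodels.api as sm

from .records import GrowthRecord, Individual

__all__ = ["GrowthModel", "infer_moult", "fit_growth_model", "adjust_cl"]

MOULT_THRESHOLD_MM = 5.0


@dataclass
class GrowthModel:
    """Fitted moult-probability (logistic) and increment (linear) sub-models."""

    moult_intercept: float
    moult_slope: float
    growth_intercept: float
    growth_slope: float
    moult_se: tuple[float, float]
    growth_se: tuple[float, float]
    threshold: float = MOULT_THRESHOLD_MM
    n_records: int = 0
    separation_flag: bool = False

    def p_moult(self, cl: float | np.ndarray) -> float | np.ndarray:
        eta = self.moult_intercept + self.moult_slope * np.asarray(cl, dtype=float)
        out = 1.0 / (1.0 + np.exp(-eta))
        return float(out) if np.isscalar(cl) else out

    def increment(self, cl: float | np.ndarray) -> float | np.ndarray:
        out = self.growth_intercept + self.growth_slope * np.asarray(cl, dtype=float)
        return float(out) if np.isscalar(cl) else out

    def to_text(self, path: str | Path) -> None:
        lines = [
            f"moult_intercept\t{self.moult_intercept!r}",
            f"moult_slope\t{self.moult_slope!r}",
            f"growth_intercept\t{self.growth_intercept!r}",
            f"growth_slope\t{self.growth_slope!r}",
            f"threshold\t{self.threshold!r}",
            f"n_records\t{self.n_records}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "GrowthModel":
        vals = {}
        for line in Path(path).read_text().splitlines():
            key, _, val = line.partition("\t")
            vals[key] = float(val)
        return cls(
            moult_intercept=vals["moult_intercept"],
            moult_slope=vals["moult_slope"],
            growth_intercept=vals["growth_intercept"],
            growth_slope=vals["growth_slope"],
            moult_se=(float("nan"), float("nan")),
            growth_se=(float("nan"), float("nan")),
            threshold=vals.get("threshold", MOULT_THRESHOLD_MM),
            n_records=int(vals.get("n_records", 0)),
        )


def infer_moult(record: GrowthRecord, threshold: float = MOULT_THRESHOLD_MM) -> bool:
    """Moulted iff the year-to-year CL difference is >= threshold (5 mm)."""
    return record.delta >= threshold


def is_suspect(record: GrowthRecord, threshold: float = MOULT_THRESHOLD_MM) -> bool:
    """Shrinkage beyond the measurement-error band flags a bad record."""
    return record.delta <= -threshold


def fit_growth_model(
    records: list[GrowthRecord], threshold: float = MOULT_THRESHOLD_MM
) -> GrowthModel:
    """Fit both growth sub-models from consecutive-year capture records.

    The logistic moult model uses all non-suspect records; the linear
    increment model uses the moulted subset only.  Complete separation in
    the logistic fit falls back to a ridge-penalised fit and sets
    ``separation_flag``.
    """
    clean = [r for r in records if not is_suspect(r, threshold)]
    if len(clean) < 20:
        raise ValueError("need >= 20 usable growth records")
    cl = np.array([r.cl_first for r in clean])
    if cl.max() - cl.min() < 20:
        raise ValueError("growth records must span >= 20 mm of CL")
    moulted = np.array([infer_moult(r, threshold) for r in clean], dtype=float)
    X = sm.add_constant(cl)
    separation = False
    try:
        logit_fit = sm.Logit(moulted, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(logit_fit.bse)) or np.any(np.abs(logit_fit.params) > 1e3):
            raise np.linalg.LinAlgError
        moult_params = logit_fit.params
        moult_se = tuple(float(s) for s in logit_fit.bse)
    except Exception:
        separation = True
        logit_fit = sm.Logit(moulted, X).fit_regularized(alpha=1.0, disp=0)
        moult_params = logit_fit.params
        moult_se = (float("nan"), float("nan"))
    grew = [r for r in clean if infer_moult(r, threshold)]
    if len(grew) < 3:
        raise ValueError("too few moulted records to fit the increment model")
    gx = sm.add_constant(np.array([r.cl_first for r in grew]))
    gy = np.array([r.delta for r in grew])
    ols_fit = sm.OLS(gy, gx).fit()
    return GrowthModel(
        moult_intercept=float(moult_params[0]),
        moult_slope=float(moult_params[1]),
        growth_intercept=float(ols_fit.params[0]),
        growth_slope=float(ols_fit.params[1]),
        moult_se=moult_se,
        growth_se=tuple(float(s) for s in ols_fit.bse),
        threshold=threshold,
        n_records=len(clean),
        separation_flag=separation,
    )


def adjust_cl(male: Individual, year_f: int, model: GrowthModel) -> float:
    """Eq.-of-motion for male size: measured CL plus (or minus) expected
    growth over the year gap to the female's sampling year."""
    if model is None:
        raise ValueError("growth model not fitted")
    diff = year_f - male.year
    return float(male.cl + diff * model.increment(male.cl) * model.p_moult(male.cl))
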