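"""Station-level neuston statistics and frozen-fraction INP spectra.

Covers the quantitative treatment of the flow-cytometry count data
(enrichment factors, virus-to-host ratios, correlations, the
wind x salinity interaction model) and the droplet-freezing assay
(cumulative frozen fraction -> ice-nucleating-particle concentrations via
Poisson statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .errors import ParameterError, UndefinedStatisticError, ValidationError

# ---------------------------------------------------------------------------
# Enrichment factors and virus-host ratios
# ---------------------------------------------------------------------------


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (display convention for EFs).

    numpy/python round() is banker's rounding; printed tables use the
    conventional half-up rule (1.75 -> 1.8).
    """
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class EFResult:
    """SML/SSW enrichment factor: >1 enrichment, <1 depletion."""

    ef: Optional[float]
    specimen: str = "vlp"
    defined: bool = True

    @property
    def display(self) -> Optional[float]:
        if self.ef is None or not self.defined:
            return None
        return round_half_up(self.ef, 1)


def enrichment_factor(sml, ssw, specimen: str = "vlp") -> EFResult:
    """EF = concentration in the SML over its SSW counterpart.

    ``None``/NaN inputs (not determined) propagate; a zero SSW reference
    yields a flagged undefined result rather than an exception.
    """
    if sml is None or ssw is None or (isinstance(sml, float) and math.isnan(sml)) \
            or (isinstance(ssw, float) and math.isnan(ssw)):
        return EFResult(ef=None, specimen=specimen, defined=False)
    if sml < 0 or ssw < 0:
        raise ValidationError("concentrations must be >= 0")
    if ssw == 0:
        return EFResult(ef=None, specimen=specimen, defined=False)
    return EFResult(ef=float(sml) / float(ssw), specimen=specimen)


def virus_host_ratio(vlp, prok) -> float:
    """VLP-to-prokaryote ratio (dimensionless); NaN when undefined."""
    if vlp is None or prok is None:
        return float("nan")
    vlp = float(vlp)
    prok = float(prok)
    if math.isnan(vlp) or math.isnan(prok) or prok <= 0:
        return float("nan")
    return vlp / prok


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    corr: float
    t: Optional[float]
    df: int
    p: float
    n: int


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with t statistic and df = n - 2.

    Pairwise deletion removes positions where either value is missing.
    Spearman is Pearson on average ranks; its p-value comes from the same
    t approximation (cor.test's large-sample default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValidationError(f"need n >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in x or y")
    if method == "pearson":
        r = float(st.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(st.spearmanr(x, y).statistic)
    else:
        raise ParameterError(f"unknown method {method!r}")
    df = n - 2
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = 2.0 * st.t.sf(abs(t), df)
    return CorrelationResult(method=method, corr=r, t=t, df=df, p=float(p), n=n)


# ---------------------------------------------------------------------------
# Interaction linear model (EF ~ a * b)
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    adjusted_r2: float
    f_value: float
    df_model: int
    df_error: int
    p: float
    aic: float
    coefficients: pd.DataFrame
    residuals: np.ndarray


def _gaussian_aic(llf: float, n_params_mean: int) -> float:
    # k counts the mean parameters plus the error variance, and llf keeps
    # the 2*pi constant — the convention of R's stats::AIC on lm fits.
    return -2.0 * llf + 2.0 * (n_params_mean + 1)


def fit_interaction_model(response, a, b) -> ModelFit:
    """OLS of ``response ~ a + b + a:b`` with intercept.

    Reports adjusted R^2, the overall F test, and AIC under the Gaussian
    likelihood convention that includes the 2*pi constant and counts the
    error variance as a parameter.
    """
    y = np.asarray(response, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = y.size
    if n <= 4:
        raise ValidationError("need n > 4 observations for the interaction model")
    X = np.column_stack([np.ones(n), a, b, a * b])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise UndefinedStatisticError("rank-deficient design (singular fit)")
    res = sm.OLS(y, X).fit()
    coefs = pd.DataFrame(
        {
            "term": ["intercept", "a", "b", "a:b"],
            "estimate": res.params,
            "std_error": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    return ModelFit(
        adjusted_r2=float(res.rsquared_adj),
        f_value=float(res.fvalue),
        df_model=int(res.df_model),
        df_error=int(res.df_resid),
        p=float(res.f_pvalue),
        aic=_gaussian_aic(res.llf, X.shape[1]),
        coefficients=coefs,
        residuals=np.asarray(res.resid),
    )


# ---------------------------------------------------------------------------
# Ice-nucleating particles from cumulative frozen fractions
# ---------------------------------------------------------------------------


@dataclass
class FreezingAssay:
    """Cumulative droplet-freezing assay on filter punches.

    ``temperatures`` are degrees C on the imaging grid (0.1 K cadence),
    ``frozen`` the cumulative number of frozen wells at each temperature.
    Geometry: each well holds one punch (``punch_d_mm`` diameter) from a
    ``filter_d_mm`` filter through which ``v_filtered_ml`` of sample water
    passed, immersed in ``v_well_ul`` of ultrapure water.
    """

    temperatures: np.ndarray
    frozen: np.ndarray
    total_wells: int = 24
    v_well_ul: float = 50.0
    punch_d_mm: float = 1.0
    filter_d_mm: float = 47.0
    v_filtered_ml: float = 500.0

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.frozen = np.asarray(self.frozen, dtype=int)
        if self.temperatures.shape != self.frozen.shape:
            raise ValidationError("temperature and frozen arrays differ in length")
        if (self.frozen < 0).any() or (self.frozen > self.total_wells).any():
            raise ValidationError("frozen counts must lie in [0, total_wells]")
        order = np.argsort(self.temperatures)[::-1]  # warm -> cold
        if np.any(np.diff(self.frozen[order]) < 0):
            raise ValidationError("cumulative frozen counts must be nondecreasing with cooling")
        for fld in ("v_well_ul", "punch_d_mm", "filter_d_mm", "v_filtered_ml"):
            if getattr(self, fld) <= 0:
                raise ParameterError(f"{fld} must be positive")


def inp_spectrum(assay: FreezingAssay, censored_correction: float = 0.5) -> pd.DataFrame:
    """Cumulative INP concentration spectrum from a freezing assay.

    Under Poisson statistics the expected INP per well active at or above
    temperature T is lambda(T) = -ln(1 - f(T)) with f the frozen fraction.
    ``c_well_per_ml`` scales lambda by the well suspension volume;
    ``c_source_per_ml`` refers it back to the filtered source water via the
    punch-to-filter area fraction.  Fully frozen trays (f = 1) are censored:
    a half-count continuity correction gives a lower bound and the row is
    flagged rather than dropped.
    """
    f = assay.frozen / assay.total_wells
    censored = f >= 1.0
    f_eff = np.where(censored, (assay.frozen - censored_correction) / assay.total_wells, f)
    lam = -np.log1p(-f_eff)  # INP per well
    v_well_ml = assay.v_well_ul / 1000.0
    area_frac = (assay.punch_d_mm / assay.filter_d_mm) ** 2  # ratio of pi r^2
    v_source_ml = assay.v_filtered_ml * area_frac
    return pd.DataFrame(
        {
            "temperature": assay.temperatures,
            "f_frozen": f,
            "inp_per_well": lam,
            "c_well_per_ml": lam / v_well_ml,
            "c_source_per_ml": lam / v_source_ml,
            "censored": censored,
        }
    )


# ---------------------------------------------------------------------------
# Station-table conveniences
# ---------------------------------------------------------------------------


def ef_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Recompute EF(SML/SSW) per specimen for every station row."""
    rows = []
    for _, row in counts.iterrows():
        rec = {"station": row["station"], "date": row["date"]}
        for spec in ("vlp", "prok", "euk"):
            res = enrichment_factor(row.get(f"{spec}_sml"), row.get(f"{spec}_ssw"), spec)
            rec[f"ef_{spec}"] = res.ef if res.defined else float("nan")
            rec[f"ef_{spec}_display"] = res.display if res.defined else float("nan")
        rows.append(rec)
    return pd.DataFrame(rows)


def virus_host_ratio_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Recompute VLP/prokaryote ratios per compartment for every row."""
    out = {"station": counts["station"], "date": counts["date"]}
    for comp in ("foam", "sml", "ssw", "prc"):
        out[f"vhr_{comp}"] = [
            virus_host_ratio(v, p)
            for v, p in zip(counts[f"vlp_{comp}"], counts[f"prok_{comp}"])
        ]
    return pd.DataFrame(out)
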