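"""N2O emission potential, temperature sensitivity, Q10 and MAT response.

Each sample's flux is measured at five incubation temperatures (8, 15, 20,
25, 35 C). The emission potential is the rate at the 25 C denitrification
optimum; temperature sensitivity is the coefficient of variation of the
five rates; Q10 is the factor by which flux multiplies per 10 C warming,
estimated either from a log-linear fit across all temperatures (default) or
from the ratio of rates 10 C apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import INCUBATION_TEMPS, validate_gene_signals

logger = logging.getLogger("corepair")


@dataclass
class RegressionFit:
    """One fitted MAT-response model."""

    model: str            # "exponential" (y = a e^(bx)) or "linear"
    a: float
    b: float
    r2: float
    aic: float
    p_slope: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "exponential":
            return self.a * np.exp(self.b * x)
        return self.a + self.b * x


def emission_potential(rates: Mapping[float, float]) -> float:
    """Rate at the 25 C incubation (the denitrification optimum)."""
    for t, rate in rates.items():
        if abs(float(t) - 25.0) < 1e-9:
            return float(rate)
    raise ValueError("no rate measured at 25 C; potential undefined")


def temperature_sensitivity(rates: Mapping[float, float]) -> float:
    """Coefficient of variation (sample SD / mean) of the five rates."""
    values = np.asarray(list(rates.values()), dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two temperatures for a CV")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("mean rate is zero; CV undefined")
    return float(values.std(ddof=1) / mean)


def q10(rates: Mapping[float, float], method: str = "loglinear") -> float:
    """Temperature sensitivity as the multiplication factor per 10 C.

    ``loglinear`` fits ln(rate) = c + b*T over all positive rates and
    returns e^(10b). ``ratio`` averages rate(T+10)/rate(T) over every pair
    of temperatures 10 C apart (15->25 and 25->35 in the standard design).
    """
    temps = np.asarray([float(t) for t in rates], dtype=float)
    vals = np.asarray([float(rates[t]) for t in rates], dtype=float)
    if method == "loglinear":
        pos = vals > 0
        if (~pos).any():
            logger.warning("dropping %d nonpositive rate(s) from log-linear "
                           "Q10 fit", int((~pos).sum()))
        if pos.sum() < 2:
            raise ValueError("fewer than 2 positive rates; Q10 undefined")
        b, _ = np.polyfit(temps[pos], np.log(vals[pos]), 1)
        return float(np.exp(10.0 * b))
    if method == "ratio":
        ratios = []
        lookup = {round(float(t), 6): float(rates[t]) for t in rates}
        for t in sorted(lookup):
            upper = round(t + 10.0, 6)
            if upper in lookup and lookup[t] > 0:
                ratios.append(lookup[upper] / lookup[t])
        if not ratios:
            raise ValueError("no temperature pairs 10 C apart; Q10 "
                             "undefined under the ratio method")
        return float(np.mean(ratios))
    raise ValueError(f"unknown Q10 method {method!r}")


def profiles_from_fluxes(flux: pd.DataFrame,
                         q10_method: str = "loglinear") -> pd.DataFrame:
    """Per-sample emission profile from a long flux table.

    Returns a DataFrame indexed by sample id with the five rates, the
    potential, the CV temperature sensitivity and Q10.
    """
    rows = []
    for sample_id, sub in flux.groupby("sample_id", sort=False):
        rates = dict(zip(sub["temperature_C"].astype(float), sub["rate"]))
        row = {"sample_id": sample_id}
        for t in INCUBATION_TEMPS:
            row[f"rate_{t:g}C"] = rates.get(t, np.nan)
        row["potential"] = emission_potential(rates)
        row["temp_sensitivity_cv"] = temperature_sensitivity(rates)
        row["q10"] = q10(rates, method=q10_method)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def field_means(profiles: pd.DataFrame, metadata: pd.DataFrame
                ) -> pd.DataFrame:
    """Field-level means of the profile statistics plus the field MAT."""
    merged = profiles.join(metadata.set_index("sample_id")
                           [["field_id", "zone", "mat"]])
    numeric = merged.groupby("field_id").mean(numeric_only=True)
    zones = merged.groupby("field_id")["zone"].first()
    numeric["zone"] = zones
    return numeric


def _aic_from_rss(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * float(np.log(rss / n)) + 2 * k


def _ols_slope_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float,
                                                         float]:
    res = stats.linregress(x, y)
    return res.intercept, res.slope, res.rvalue ** 2, res.pvalue


def fit_mat_response(x: np.ndarray, y: np.ndarray
                     ) -> tuple[RegressionFit, RegressionFit, str]:
    """Fit exponential and linear MAT responses; pick the winner by AIC.

    The exponential model y = a e^(bx) is estimated by least squares on
    ln(y); its AIC uses back-transformed residuals on the original response
    scale so the two models are compared on commensurable likelihoods.
    Nonpositive responses are dropped (from both fits, keeping n equal)
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = y > 0
    if (~pos).any():
        logger.warning("dropping %d nonpositive response value(s) for the "
                       "exponential fit", int((~pos).sum()))
        x, y = x[pos], y[pos]
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 positive observations")
    c, b_exp, r2_exp, p_exp = _ols_slope_p(x, np.log(y))
    a_exp = float(np.exp(c))
    rss_exp = float(np.sum((y - a_exp * np.exp(b_exp * x)) ** 2))
    exp_fit = RegressionFit("exponential", a_exp, float(b_exp), float(r2_exp),
                            _aic_from_rss(rss_exp, n, 3), float(p_exp), n)
    a_lin, b_lin, r2_lin, p_lin = _ols_slope_p(x, y)
    rss_lin = float(np.sum((y - (a_lin + b_lin * x)) ** 2))
    lin_fit = RegressionFit("linear", float(a_lin), float(b_lin),
                            float(r2_lin), _aic_from_rss(rss_lin, n, 3),
                            float(p_lin), n)
    winner = "exponential" if exp_fit.aic < lin_fit.aic else "linear"
    return exp_fit, lin_fit, winner


def normalize_gene_signal(genes: pd.DataFrame) -> pd.DataFrame:
    """Divide each probe intensity by its sample's mean detected intensity.

    A probe is "detected" when its intensity is positive; each sample's
    normalizer is the mean over its detected probes, so the normalized
    detected intensities average 1 within every sample.
    """
    genes = validate_gene_signals(genes)
    out = genes.copy()
    detected = out.loc[out["intensity"] > 0]
    if detected.empty:
        raise ValueError("no detected probes in any sample")
    means = detected.groupby("sample_id")["intensity"].mean()
    empty = set(out["sample_id"]) - set(means.index)
    if empty:
        raise ValueError(
            f"sample {sorted(empty)[0]!r} has zero detected probes; "
            "normalization undefined")
    out["intensity"] = out["intensity"] / out["sample_id"].map(means)
    return out
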