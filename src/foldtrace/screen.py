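"""HTS quality control, percent-activity normalization and hit calling.

The screening window is summarized by the z' factor,
1 - 3(sigma_pos + sigma_neg)/|mu_pos - mu_neg| (sample standard
deviations); compound signals are expressed as percent activity of a
reference corrector's maximal effect; hits are compounds strictly above the
activity cutoff.  A four-parameter logistic (4PL) fitter supports EC50/Emax
extraction from concentration-response curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ValidationError


def zprime(positive, negative) -> float:
    """Screening-window coefficient from control-well signals."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValidationError("need >= 2 wells per control role")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise ValidationError("no screening window: control means are equal")
    sd_p, sd_n = pos.std(ddof=1), neg.std(ddof=1)
    return float(1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n))


def percent_activity(signal, baseline: float, reference_max: float):
    """100 x (signal - baseline) / (reference_max - baseline)."""
    if reference_max == baseline:
        raise ValidationError("degenerate reference window (reference_max == baseline)")
    signal = np.asarray(signal, dtype=float)
    out = 100.0 * (signal - baseline) / (reference_max - baseline)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ScreenHits:
    """Hit list and hit rate of one screening pass."""

    hits: tuple[str, ...]
    cutoff: float
    n_screened: int

    @property
    def hit_rate(self) -> float:
        """Percent of screened compounds called hits (full precision)."""
        return 100.0 * len(self.hits) / self.n_screened

    @property
    def hit_rate_rounded(self) -> float:
        return round(self.hit_rate, 2)

    def summary(self) -> str:
        return (
            f"{len(self.hits)} hits of {self.n_screened} screened at cutoff "
            f">{self.cutoff:g}% activity ({self.hit_rate:.2f}% hit rate)"
        )


def call_hits(
    activities: pd.Series | dict[str, float],
    cutoff: float = 13.0,
    n_screened: int | None = None,
) -> ScreenHits:
    """Compounds with percent activity strictly above the cutoff.

    ``n_screened`` defaults to the number of activities but may exceed it
    (e.g. a confirmation pass counted against the primary screen size).
    """
    s = pd.Series(activities, dtype=float)
    if n_screened is None:
        n_screened = len(s)
    if n_screened <= 0:
        raise ValidationError("n_screened must be > 0")
    hits = tuple(s.index[s > cutoff].astype(str))
    return ScreenHits(hits=hits, cutoff=float(cutoff), n_screened=int(n_screened))


@dataclass(frozen=True)
class PlateQC:
    z_prime: float
    pos_mean: float
    pos_sd: float
    neg_mean: float
    neg_sd: float
    n_pos: int
    n_neg: int

    def summary(self) -> str:
        return (
            f"z' = {self.z_prime:.2f} (pos {self.pos_mean:.1f} +/- "
            f"{self.pos_sd:.1f}, n={self.n_pos}; neg {self.neg_mean:.1f} +/- "
            f"{self.neg_sd:.1f}, n={self.n_neg})"
        )


def plate_qc(plate: pd.DataFrame) -> PlateQC:
    """z' and control statistics from a plate table (well, role, signal)."""
    pos = plate.loc[plate["role"] == "positive_control", "signal"].to_numpy(float)
    neg = plate.loc[plate["role"] == "negative_control", "signal"].to_numpy(float)
    return PlateQC(
        z_prime=zprime(pos, neg),
        pos_mean=float(pos.mean()),
        pos_sd=float(pos.std(ddof=1)),
        neg_mean=float(neg.mean()),
        neg_sd=float(neg.std(ddof=1)),
        n_pos=pos.size,
        n_neg=neg.size,
    )


def plate_activities(plate: pd.DataFrame) -> pd.Series:
    """Percent activity of compound wells vs the plate's own controls."""
    qc = plate_qc(plate)
    cpd = plate[plate["role"] == "compound"]
    act = percent_activity(cpd["signal"].to_numpy(float), qc.neg_mean, qc.pos_mean)
    return pd.Series(act, index=cpd["compound"].astype(str).to_numpy())


def _four_pl(log_c: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - log_c) * hill))


@dataclass(frozen=True)
class DoseResponseResults:
    """4PL fit of a concentration-response curve."""

    ec50: float
    emax: float
    baseline: float
    hill: float
    converged: bool
    flag: str
    residuals: np.ndarray

    def summary(self) -> str:
        if not self.converged:
            return f"4PL fit failed: {self.flag}"
        return (
            f"EC50 = {self.ec50:.4g}, Emax = {self.emax:.4g}, "
            f"baseline = {self.baseline:.4g}, Hill = {self.hill:.3g}"
        )


class DoseResponseModel:
    """Four-parameter logistic concentration-response model.

    Concentrations must be positive with >= 4 distinct values; the fit is
    parameterized in log10 concentration with the EC50 bounded to the tested
    concentration range x [0.01, 100].
    """

    def __init__(self, concentrations, responses):
        c = np.asarray(concentrations, dtype=float)
        r = np.asarray(responses, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValidationError("concentrations and responses must match, 1-D")
        if np.any(c <= 0):
            raise ValidationError("concentrations must be > 0")
        if np.unique(c).size < 4:
            raise ValidationError("need >= 4 distinct concentrations")
        if not np.all(np.isfinite(r)):
            raise ValidationError("responses must be finite")
        self.concentrations = c
        self.responses = r

    def fit(self) -> DoseResponseResults:
        c, r = self.concentrations, self.responses
        span = float(r.max() - r.min())
        if span <= 0 or span < 1e-12 * max(1.0, abs(float(r.mean()))):
            return DoseResponseResults(
                ec50=np.nan,
                emax=np.nan,
                baseline=float(r.mean()),
                hill=np.nan,
                converged=False,
                flag="flat response",
                residuals=r - r.mean(),
            )
        log_c = np.log10(c)
        lo, hi = log_c.min() - 2.0, log_c.max() + 2.0
        p0 = [float(r.min()), float(r.max()), float(np.median(log_c)), 1.0]
        bounds = (
            [-np.inf, -np.inf, lo, 0.05],
            [np.inf, np.inf, hi, 20.0],
        )
        try:
            popt, _ = curve_fit(
                _four_pl, log_c, r, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:
            return DoseResponseResults(
                ec50=np.nan,
                emax=np.nan,
                baseline=np.nan,
                hill=np.nan,
                converged=False,
                flag=f"no convergence: {exc}",
                residuals=np.full_like(r, np.nan),
            )
        bottom, top, log_ec50, hill = popt
        residuals = r - _four_pl(log_c, *popt)
        return DoseResponseResults(
            ec50=float(10.0**log_ec50),
            emax=float(top),
            baseline=float(bottom),
            hill=float(hill),
            converged=True,
            flag="",
            residuals=residuals,
        )


def fit_4pl(concentrations, responses) -> DoseResponseResults:
    """Convenience wrapper: DoseResponseModel(...).fit()."""
    return DoseResponseModel(concentrations, responses).fit()
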