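"""Kinetic estimators on normalized band time courses.

The headline quantities of the pulse-chase assay are ratio and regression
estimators, not full ODE fits:

* **ER folding efficiency** — the heavy C-band signal after a fixed chase
  (default 2.5 h) as a fraction of the heavy B-band signal directly after
  the pulse.  On a pulse-max-normalized time course this is simply the
  normalized heavy-C value at the efficiency timepoint, computed per
  replicate and averaged (mean +/- SEM).
* **Post-folding half-life** — ordinary least squares of ln(abundance)
  versus chase time on the decaying pool; t_1/2 = ln 2 / |slope|.  Points
  below a signal floor (default 5% of the series maximum) are excluded as
  noise-dominated.
* **Pulse labeling fraction** — heavy / (heavy + light) of the B pool at
  the end of the pulse.
* **Wash-out formation check** — ratio of new heavy-C formation between
  washed and unwashed chase conditions; a small ratio confirms that the
  corrector was actually removed.

`PulseChaseModel` wraps the estimators behind a fit()/results interface;
the standalone functions below are the primitive operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .quant import quantify
from .simulate import CFTR_PEPTIDES, DEFAULT_REFERENCE_PEPTIDE

_LN2 = float(np.log(2.0))


def _require_normalized(tc: pd.DataFrame) -> None:
    if "normalized_abundance" not in tc.columns:
        raise ValidationError(
            "time course lacks a 'normalized_abundance' column; apply "
            "quant.normalize_to_pulse_max first"
        )


@dataclass(frozen=True)
class FoldingEfficiencyResult:
    """Per-treatment ER folding efficiency (replicate mean +/- SEM)."""

    efficiency_time: float
    replicates: pd.DataFrame  # experiment_id, treatment, replicate_id, efficiency
    table: pd.DataFrame  # treatment, efficiency, sem, n

    def value(self, treatment: str) -> float:
        sub = self.table[self.table["treatment"] == treatment]
        if sub.empty:
            raise KeyError(treatment)
        return float(sub["efficiency"].iloc[0])


def folding_efficiency(
    tc: pd.DataFrame, efficiency_time: float = 2.5
) -> FoldingEfficiencyResult:
    """Heavy-C/heavy-B(anchor) ratio per replicate, averaged per treatment."""
    _require_normalized(tc)
    sub = tc[(tc["band"] == "C") & (tc["isotopolog"] == "heavy")]
    at_t = sub[np.isclose(sub["timepoint_h"], efficiency_time)]
    if at_t.empty:
        avail = sorted(sub["timepoint_h"].unique())
        raise ValidationError(
            f"no heavy C-band values at efficiency time {efficiency_time}; "
            f"available timepoints: {avail}"
        )
    reps = at_t[["experiment_id", "treatment", "replicate_id", "normalized_abundance"]]
    reps = reps.rename(columns={"normalized_abundance": "efficiency"}).reset_index(
        drop=True
    )
    table = (
        reps.groupby("treatment", sort=True)["efficiency"]
        .agg(
            efficiency="mean",
            sem=lambda v: float(stats.sem(v)) if len(v) > 1 else np.nan,
            n="count",
        )
        .reset_index()
    )
    return FoldingEfficiencyResult(
        efficiency_time=float(efficiency_time), replicates=reps, table=table
    )


@dataclass(frozen=True)
class HalfLifeResult:
    """Half-life from OLS of log-abundance vs time for one treatment."""

    treatment: str
    t_half: float  # hours; +inf when non-decaying
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    non_decaying: bool


def half_life(
    tc: pd.DataFrame,
    band: str = "C",
    isotopolog: str = "light",
    treatment: str | None = None,
    floor_fraction: float = 0.05,
    value_column: str | None = None,
) -> dict[str, HalfLifeResult]:
    """Per-treatment half-life by linear regression of the logarithmic data.

    All replicate points above the signal floor (``floor_fraction`` x the
    series maximum) enter one OLS fit of ln(value) on time.  A non-negative
    slope is flagged non-decaying (t_half = +inf).
    """
    if value_column is None:
        value_column = (
            "normalized_abundance" if "normalized_abundance" in tc.columns else "abundance"
        )
    sub = tc[(tc["band"] == band) & (tc["isotopolog"] == isotopolog)]
    if treatment is not None:
        sub = sub[sub["treatment"] == treatment]
    if sub.empty:
        raise ValidationError(f"no {isotopolog} {band}-band data to regress")
    out: dict[str, HalfLifeResult] = {}
    for trt, grp in sub.groupby("treatment", sort=True):
        values = grp[value_column].to_numpy(dtype=float)
        times = grp["timepoint_h"].to_numpy(dtype=float)
        floor = floor_fraction * float(np.max(values))
        usable = (values > 0) & (values > floor)
        if np.unique(times[usable]).size < 3:
            raise ValidationError(
                f"insufficient decay data for treatment {trt!r}: fewer than 3 "
                "usable timepoints above the signal floor"
            )
        fit = stats.linregress(times[usable], np.log(values[usable]))
        non_decaying = fit.slope >= 0
        t_half = np.inf if non_decaying else _LN2 / abs(fit.slope)
        out[trt] = HalfLifeResult(
            treatment=trt,
            t_half=float(t_half),
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=float(fit.rvalue**2),
            n_points=int(usable.sum()),
            non_decaying=bool(non_decaying),
        )
    return out


def labeling_fraction(tc: pd.DataFrame, time: float = 0.0) -> pd.DataFrame:
    """Heavy fraction of the B pool at the end of the pulse, per treatment.

    Computed per replicate as heavy/(heavy+light) and averaged; works on raw
    or normalized abundances (the ratio is scale-free within a sample).
    """
    sub = tc[(tc["band"] == "B") & np.isclose(tc["timepoint_h"], time)]
    if sub.empty:
        raise ValidationError(f"no B-band values at time {time}")
    wide = sub.pivot_table(
        index=["experiment_id", "treatment", "replicate_id"],
        columns="isotopolog",
        values="abundance",
    ).reset_index()
    if "heavy" not in wide or "light" not in wide:
        raise ValidationError("both isotopologs required at the pulse-end timepoint")
    total = wide["heavy"] + wide["light"]
    if (total <= 0).any():
        bad = sorted(wide.loc[total <= 0, "treatment"].unique())
        raise ValidationError(f"zero total B-pool signal for treatment(s): {bad}")
    wide["fraction"] = wide["heavy"] / total
    return (
        wide.groupby("treatment", sort=True)["fraction"]
        .agg(fraction="mean", n="count")
        .reset_index()
    )


@dataclass(frozen=True)
class WashoutResult:
    """New heavy-C formation in washed vs unwashed chase conditions."""

    ratio: float
    formed_washed: float
    formed_unwashed: float
    window: tuple[float, float]
    status: str  # "confirmed" | "not confirmed" | "not evaluable"


def washout_formation_check(
    tc_washed: pd.DataFrame,
    tc_unwashed: pd.DataFrame,
    band: str = "C",
    isotopolog: str = "heavy",
    threshold: float = 0.25,
    min_formation: float = 1e-9,
    value_column: str = "abundance",
) -> WashoutResult:
    """Compare heavy-C formation over the common chase window.

    Formation is the rise of the replicate-mean pool between the first and
    last common timepoint.  A washed/unwashed ratio below ``threshold``
    confirms wash-out; near-zero unwashed formation is not evaluable.
    """

    def mean_series(tc: pd.DataFrame) -> pd.Series:
        sub = tc[(tc["band"] == band) & (tc["isotopolog"] == isotopolog)]
        if sub.empty:
            raise ValidationError(f"no {isotopolog} {band}-band data")
        return sub.groupby("timepoint_h", sort=True)[value_column].mean()

    washed, unwashed = mean_series(tc_washed), mean_series(tc_unwashed)
    common = sorted(set(washed.index) & set(unwashed.index))
    if len(common) < 2:
        raise ValidationError("conditions share fewer than 2 chase timepoints")
    t0, t1 = common[0], common[-1]
    formed_w = float(washed[t1] - washed[t0])
    formed_u = float(unwashed[t1] - unwashed[t0])
    if formed_u <= min_formation:
        return WashoutResult(
            ratio=np.nan,
            formed_washed=formed_w,
            formed_unwashed=formed_u,
            window=(float(t0), float(t1)),
            status="not evaluable",
        )
    ratio = formed_w / formed_u
    status = "confirmed" if ratio < threshold else "not confirmed"
    return WashoutResult(
        ratio=float(ratio),
        formed_washed=formed_w,
        formed_unwashed=formed_u,
        window=(float(t0), float(t1)),
        status=status,
    )


class PulseChaseModel:
    """Folding-efficiency model over a normalized band time course.

    Parameters
    ----------
    timecourse : DataFrame
        Band time course with a ``normalized_abundance`` column (see
        `quant.normalize_to_pulse_max`).
    efficiency_time : float
        Chase time at which B->C conversion is read out, hours.
    """

    def __init__(self, timecourse: pd.DataFrame, efficiency_time: float = 2.5):
        _require_normalized(timecourse)
        self.timecourse = timecourse
        self.efficiency_time = float(efficiency_time)

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        reference: str = DEFAULT_REFERENCE_PEPTIDE,
        peptides: tuple[str, ...] = CFTR_PEPTIDES,
        wt_treatment: str = "WT",
        response_factors=None,
        efficiency_time: float = 2.5,
        anchor_time: float = 0.0,
    ) -> "PulseChaseModel":
        """Build the model from a transition-level table via the quant chain."""
        tc = quantify(
            records,
            reference=reference,
            peptides=peptides,
            wt_treatment=wt_treatment,
            response_factors=response_factors,
            anchor_time=anchor_time,
        )
        return cls(tc, efficiency_time=efficiency_time)

    def fit(self) -> "PulseChaseResults":
        eff = folding_efficiency(self.timecourse, self.efficiency_time)
        try:
            lab = labeling_fraction(self.timecourse)
        except ValidationError:
            lab = None
        return PulseChaseResults(model=self, efficiency=eff, labeling=lab)


@dataclass
class PulseChaseResults:
    """Estimates from a fitted pulse-chase model."""

    model: PulseChaseModel
    efficiency: FoldingEfficiencyResult
    labeling: pd.DataFrame | None

    def half_life(
        self,
        band: str = "C",
        isotopolog: str = "light",
        floor_fraction: float = 0.05,
    ) -> dict[str, HalfLifeResult]:
        return half_life(
            self.model.timecourse,
            band=band,
            isotopolog=isotopolog,
            floor_fraction=floor_fraction,
        )

    def summary(self) -> str:
        lines = [
            "Pulse-chase folding efficiency "
            f"(heavy C at {self.model.efficiency_time:g} h / heavy B at pulse end)",
            f"{'treatment':<22}{'efficiency':>12}{'SEM':>10}{'n':>4}",
        ]
        for _, row in self.efficiency.table.iterrows():
            sem = f"{row['sem']:.4f}" if np.isfinite(row["sem"]) else "   --"
            lines.append(
                f"{row['treatment']:<22}{row['efficiency']:>12.4f}{sem:>10}"
                f"{int(row['n']):>4}"
            )
        if self.labeling is not None:
            lines.append("")
            lines.append("B-pool heavy labeling fraction at pulse end")
            for _, row in self.labeling.iterrows():
                lines.append(
                    f"{row['treatment']:<22}{row['fraction']:>12.4f}"
                    f"{int(row['n']):>14}"
                )
        return "\n".join(lines)

    def plot(self, ax=None, band: str = "B", isotopolog: str = "heavy"):
        """Plot the normalized time course of one pool per treatment."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tc = self.model.timecourse
        sub = tc[(tc["band"] == band) & (tc["isotopolog"] == isotopolog)]
        for trt, grp in sub.groupby("treatment"):
            mean = grp.groupby("timepoint_h")["normalized_abundance"].mean()
            ax.plot(mean.index, mean.values, marker="o", label=trt)
        ax.set_xlabel("chase time (h)")
        ax.set_ylabel(f"normalized {isotopolog} {band}-band")
        ax.legend(fontsize="small")
        return ax
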