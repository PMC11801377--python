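"""From transition-level tables to calibrated, normalized band time courses.

The stage mirrors the targeted-MS workflow: fragment-ion intensities are
summed per peptide, peptide signals are calibrated by relative response
factors anchored to a reference peptide (computed on the light isotopolog of
the wild-type samples), calibrated peptides are rolled up to a band-level
abundance, and the band time course is normalized to the heavy B-band value
directly after the pulse so that the normalized heavy-C value *is* the
folding-efficiency estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .simulate import DEFAULT_REFERENCE_PEPTIDE, QC_PEPTIDES, TRANSITION_COLUMNS

logger = logging.getLogger(__name__)

#: Grouping key of one quantified peptide observation.
PEPTIDE_KEY = [
    "experiment_id",
    "sample_id",
    "treatment",
    "timepoint_h",
    "band",
    "isotopolog",
    "peptide",
    "replicate_id",
]

#: Columns that are constant within a sample and carried through unchanged.
PASSTHROUGH = ["uv_exposed", "compound"]

BAND_KEY = [
    "experiment_id",
    "treatment",
    "timepoint_h",
    "band",
    "isotopolog",
    "replicate_id",
]


def _validate_records(records: pd.DataFrame) -> None:
    missing = [c for c in PEPTIDE_KEY + ["fragment_id", "intensity"] if c not in records]
    if missing:
        raise ValidationError(f"transition table missing columns: {missing}")
    bad_band = set(records["band"].unique()) - {"B", "C"}
    if bad_band:
        raise ValidationError(f"band must be 'B' or 'C', found {sorted(bad_band)}")
    bad_iso = set(records["isotopolog"].unique()) - {"heavy", "light"}
    if bad_iso:
        raise ValidationError(
            f"isotopolog must be 'heavy' or 'light', found {sorted(bad_iso)}"
        )
    if (records["intensity"] < 0).any():
        n = int((records["intensity"] < 0).sum())
        raise ValidationError(f"{n} transition rows have negative intensity")


def sum_fragments(
    records: pd.DataFrame, fragment_bounds: tuple[int, int] = (3, 6)
) -> pd.DataFrame:
    """Sum fragment-ion intensities into one value per peptide observation.

    Returns a PeptideQuant table with columns ``PEPTIDE_KEY`` + value +
    fragments_summed (+ passthrough columns when present).  Keys whose
    fragment count falls outside ``fragment_bounds`` are kept but logged.
    """
    _validate_records(records)
    keys = PEPTIDE_KEY + [c for c in PASSTHROUGH if c in records.columns]
    grouped = (
        records.groupby(keys, sort=True, dropna=False)["intensity"]
        .agg(value="sum", fragments_summed="count")
        .reset_index()
    )
    lo, hi = fragment_bounds
    off = grouped[(grouped["fragments_summed"] < lo) | (grouped["fragments_summed"] > hi)]
    if len(off):
        logger.warning(
            "%d peptide observations have fragment counts outside [%d, %d]",
            len(off),
            lo,
            hi,
        )
    return grouped


@dataclass(frozen=True)
class ResponseFactorTable:
    """Per-(experiment, peptide) relative ionization response factors.

    ``table`` has columns experiment_id, peptide, factor; the reference
    peptide's factor is exactly 1 in every experiment.
    """

    table: pd.DataFrame
    reference: str

    def __post_init__(self) -> None:
        f = self.table["factor"]
        if not np.all(np.isfinite(f)) or (f <= 0).any():
            raise ValidationError("response factors must be finite and > 0")

    def for_experiment(self, experiment_id: str) -> dict[str, float]:
        sub = self.table[self.table["experiment_id"] == experiment_id]
        return dict(zip(sub["peptide"], sub["factor"]))


def compute_response_factors(
    quant: pd.DataFrame,
    reference: str = DEFAULT_REFERENCE_PEPTIDE,
    wt_treatment: str = "WT",
    isotopolog: str = "light",
) -> ResponseFactorTable:
    """Per-experiment response factors from WT light-isotopolog signals.

    For every contributing sample/band the ratio intensity(p)/intensity(ref)
    is formed, and ratios are averaged per (experiment, peptide).  The
    reference peptide must be present with nonzero signal wherever another
    peptide is quantified.
    """
    sub = quant[(quant["treatment"] == wt_treatment) & (quant["isotopolog"] == isotopolog)]
    if sub.empty:
        raise ValidationError(
            f"no rows with treatment={wt_treatment!r} and isotopolog={isotopolog!r}"
        )
    unit_cols = ["experiment_id", "sample_id", "band"]
    ratios = []
    for unit, grp in sub.groupby(unit_cols, sort=True):
        ref_rows = grp[grp["peptide"] == reference]
        if ref_rows.empty or float(ref_rows["value"].iloc[0]) <= 0:
            raise ValidationError(
                f"reference peptide {reference!r} absent or zero in sample "
                f"{unit[1]!r} (band {unit[2]})"
            )
        ref_val = float(ref_rows["value"].iloc[0])
        g = grp[["experiment_id", "peptide", "value"]].copy()
        g["ratio"] = g["value"] / ref_val
        ratios.append(g[["experiment_id", "peptide", "ratio"]])
    table = (
        pd.concat(ratios, ignore_index=True)
        .groupby(["experiment_id", "peptide"], sort=True)["ratio"]
        .mean()
        .rename("factor")
        .reset_index()
    )
    # Enforce exactness for the reference (mean of exact-1 ratios).
    table.loc[table["peptide"] == reference, "factor"] = 1.0
    return ResponseFactorTable(table=table, reference=reference)


def normalize_peptides(quant: pd.DataFrame, rf: ResponseFactorTable) -> pd.DataFrame:
    """Divide every peptide value by its response factor (per experiment)."""
    merged = quant.merge(rf.table, on=["experiment_id", "peptide"], how="left")
    missing = merged[merged["factor"].isna()]
    if len(missing):
        peps = sorted(missing["peptide"].unique())
        raise ValidationError(f"no response factor for peptide(s): {peps}")
    out = merged.copy()
    out["value"] = out["value"] / out["factor"]
    return out.drop(columns=["factor"])


def band_abundance(
    normalized: pd.DataFrame, peptides: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Roll calibrated peptide values up to band-level abundances.

    The roll-up is the mean of the response-factor-normalized peptide values
    (after calibration each peptide estimates the same protein abundance);
    peptides missing from a sample are simply omitted from the mean.
    """
    sub = normalized
    if peptides is not None:
        sub = normalized[normalized["peptide"].isin(peptides)]
    if sub.empty:
        raise ValidationError("no peptide observations to roll up")
    tc = (
        sub.groupby(BAND_KEY, sort=True)["value"]
        .agg(abundance="mean", n_peptides="count")
        .reset_index()
    )
    return tc


def normalize_to_pulse_max(
    tc: pd.DataFrame,
    anchor_time: float = 0.0,
    anchor_band: str = "B",
    anchor_isotopolog: str = "heavy",
) -> pd.DataFrame:
    """Normalize each replicate series to its heavy-B value at the anchor.

    Adds a ``normalized_abundance`` column: every value of a
    (experiment, treatment, replicate) series is divided by that series'
    heavy-B abundance at ``anchor_time`` (directly after the pulse), so the
    normalized heavy-B anchor equals 1.  Idempotent on already-normalized
    values.
    """
    series_cols = ["experiment_id", "treatment", "replicate_id"]
    anchors = tc[
        (tc["band"] == anchor_band)
        & (tc["isotopolog"] == anchor_isotopolog)
        & np.isclose(tc["timepoint_h"], anchor_time)
    ][series_cols + ["abundance"]].rename(columns={"abundance": "_anchor"})
    merged = tc.merge(anchors, on=series_cols, how="left")
    no_anchor = merged[merged["_anchor"].isna()]
    if len(no_anchor):
        missing = sorted(no_anchor["treatment"].unique())
        raise ValidationError(
            f"no {anchor_isotopolog} {anchor_band}-band value at anchor time "
            f"{anchor_time} for treatment(s): {missing}"
        )
    bad = merged[merged["_anchor"] <= 0]
    if len(bad):
        raise ValidationError(
            "anchor value <= 0 for treatment(s): "
            f"{sorted(bad['treatment'].unique())}"
        )
    out = merged.copy()
    out["normalized_abundance"] = out["abundance"] / out["_anchor"]
    return out.drop(columns=["_anchor"])


def qc_band_separation(
    quant: pd.DataFrame,
    qc_peptides: dict[str, tuple[str, ...]] = QC_PEPTIDES,
    threshold: float = 0.20,
) -> pd.DataFrame:
    """Check gel-excision precision via band-comigration QC peptides.

    For every sample and QC peptide, the signal observed in the *unexpected*
    band must stay below ``threshold`` x the signal in the expected band.
    Returns one row per (sample, peptide) with status pass/fail, plus
    'not evaluable' when the QC peptide is absent.
    """
    expected_band = {p: b for b, peps in qc_peptides.items() for p in peps}
    rows = []
    for (exp, sample), grp in quant.groupby(["experiment_id", "sample_id"], sort=True):
        for pep, band in sorted(expected_band.items()):
            obs = grp[grp["peptide"] == pep]
            if obs.empty:
                rows.append((exp, sample, pep, band, np.nan, np.nan, "not evaluable"))
                continue
            in_band = float(obs[obs["band"] == band]["value"].sum())
            off_band = float(obs[obs["band"] != band]["value"].sum())
            if in_band <= 0:
                rows.append((exp, sample, pep, band, in_band, off_band, "fail"))
                continue
            ratio = off_band / in_band
            status = "pass" if ratio <= threshold else "fail"
            rows.append((exp, sample, pep, band, in_band, off_band, status))
    report = pd.DataFrame(
        rows,
        columns=[
            "experiment_id",
            "sample_id",
            "peptide",
            "expected_band",
            "expected_signal",
            "offband_signal",
            "status",
        ],
    )
    return report


def response_factors_from_dict(
    factors: dict[str, float],
    experiments: list[str],
    reference: str = DEFAULT_REFERENCE_PEPTIDE,
) -> ResponseFactorTable:
    """Build a ResponseFactorTable from known factors (e.g. a calibration)."""
    rows = [
        {"experiment_id": e, "peptide": p, "factor": float(f)}
        for e in experiments
        for p, f in sorted(factors.items())
    ]
    return ResponseFactorTable(table=pd.DataFrame(rows), reference=reference)


def quantify(
    records: pd.DataFrame,
    reference: str = DEFAULT_REFERENCE_PEPTIDE,
    peptides: tuple[str, ...] | None = None,
    wt_treatment: str = "WT",
    response_factors: dict[str, float] | ResponseFactorTable | None = None,
    anchor_time: float = 0.0,
    fragment_bounds: tuple[int, int] = (3, 6),
) -> pd.DataFrame:
    """Full quant chain: sum, calibrate, roll up, pulse-max-normalize.

    Response factors are calibrated from the WT light-isotopolog samples
    unless a known table/dict is supplied (for designs without WT samples).
    """
    pq = sum_fragments(records, fragment_bounds=fragment_bounds)
    if response_factors is None:
        rf = compute_response_factors(
            pq, reference=reference, wt_treatment=wt_treatment
        )
    elif isinstance(response_factors, ResponseFactorTable):
        rf = response_factors
    else:
        rf = response_factors_from_dict(
            response_factors,
            experiments=sorted(pq["experiment_id"].unique()),
            reference=reference,
        )
    if peptides is not None:
        pq = pq[pq["peptide"].isin(set(peptides))]
    normalized = normalize_peptides(pq, rf)
    tc = band_abundance(normalized, peptides=peptides)
    return normalize_to_pulse_max(tc, anchor_time=anchor_time)
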