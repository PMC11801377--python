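"""Photo-crosslink peptide footprinting: detection and site localization.

A photo-activatable probe that is covalently captured onto the protein under
UV destroys the unmodified form of every tryptic peptide overlapping the
attachment site, so the binding site reveals itself as a *loss of signal* of
one or a few peptides in the probe+UV condition.  The stage:

1. double normalization — each peptide signal is divided by the summed
   protein signal of its sample (removes loading/injection differences) and
   then by that peptide's average normalized signal across all conditions
   (removes per-peptide response factors);
2. one-sided two-sample t-tests for a loss of signal in each
   (test, control) comparison — pooled-variance by default, Welch optional —
   with technical replicates averaged per experiment first so the test's n
   is the number of independent experiments;
3. Benjamini-Hochberg adjustment within each comparison's family of
   testable peptides;
4. localization — flagged peptide spans are intersected and extended
   upstream to the immediately preceding tryptic cleavage residue (a
   modification on that K/R would equally abolish the observed peptide).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .proteolysis import Peptide, ProteinDigest
from .quant import sum_fragments
from .simulate import PARENT_COMPOUNDS, condition_label

#: Condition column used throughout: the `treatment` label of the table
#: (e.g. "IDOR-6A+UV"), which encodes compound x UV.
CONDITION = "treatment"


def normalize_footprint(quant: pd.DataFrame) -> pd.DataFrame:
    """Doubly-normalized peptide table (see module docstring).

    Expects a summed PeptideQuant table; returns it with a ``normalized``
    column.  After normalization the grand mean of every peptide across all
    its observations equals 1, and values are invariant to uniform
    rescaling of any single sample.
    """
    df = quant.copy()
    sample_cols = ["experiment_id", "sample_id"]
    totals = df.groupby(sample_cols)["value"].transform("sum")
    zero = df.loc[totals <= 0, "sample_id"].unique()
    if len(zero):
        raise ValidationError(f"zero total signal in sample(s): {sorted(zero)}")
    n_peps = df.groupby(sample_cols)["peptide"].transform("nunique")
    if (n_peps < 2).any():
        bad = sorted(df.loc[n_peps < 2, "sample_id"].unique())
        raise ValidationError(f"fewer than 2 peptides in sample(s): {bad}")
    step1 = df["value"] / totals
    pep_mean = step1.groupby(df["peptide"]).transform("mean")
    df["normalized"] = step1 / pep_mean
    return df


def _degenerate_p(test_mean: float, control_mean: float) -> float:
    """Zero-variance-in-both-groups rule for the one-sided test."""
    if np.isclose(test_mean, control_mean):
        return 1.0
    return 0.0 if test_mean < control_mean else 1.0


def depletion_test(
    norm: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    aggregate_technical: bool = True,
    equal_var: bool = True,
) -> pd.DataFrame:
    """One-sided t-tests for loss of signal, per peptide and comparison.

    Technical replicates are averaged within experiment before testing (the
    independent unit is the experiment).  The pooled-variance (Student) test
    is the default: with ~4 experiments per group the Welch-Satterthwaite
    approximation is measurably conservative, while the pooled test is exact
    under homoscedasticity; pass ``equal_var=False`` for Welch.  Peptides
    with fewer than 2 observations in either group are reported as not
    testable (p = NaN).  Returns columns peptide, comparison, test, control,
    ratio, p, n_test, n_control, testable.
    """
    if "normalized" not in norm.columns:
        raise ValidationError("run normalize_footprint first ('normalized' missing)")
    unit = ["peptide", "experiment_id"] if aggregate_technical else [
        "peptide",
        "experiment_id",
        "replicate_id",
    ]
    rows = []
    for test_cond, control_cond in comparisons:
        comparison = f"{test_cond} vs {control_cond}"
        sub = norm[norm[CONDITION].isin([test_cond, control_cond])]
        if sub.empty:
            raise ValidationError(
                f"no data for comparison {comparison!r}; conditions present: "
                f"{sorted(norm[CONDITION].unique())}"
            )
        agg = (
            sub.groupby([CONDITION] + unit, sort=True)["normalized"]
            .mean()
            .reset_index()
        )
        for pep, grp in agg.groupby("peptide", sort=True):
            a = grp.loc[grp[CONDITION] == test_cond, "normalized"].to_numpy()
            b = grp.loc[grp[CONDITION] == control_cond, "normalized"].to_numpy()
            testable = a.size >= 2 and b.size >= 2
            if not testable:
                p = np.nan
            elif np.var(a) == 0 and np.var(b) == 0:
                p = _degenerate_p(float(a.mean()), float(b.mean()))
            else:
                p = float(
                    stats.ttest_ind(
                        a, b, equal_var=equal_var, alternative="less"
                    ).pvalue
                )
            ratio = float(a.mean() / b.mean()) if a.size and b.size and b.mean() != 0 else np.nan
            rows.append(
                (pep, comparison, test_cond, control_cond, ratio, p, a.size, b.size, testable)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide",
            "comparison",
            "test",
            "control",
            "ratio",
            "p",
            "n_test",
            "n_control",
            "testable",
        ],
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_and_flag(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust within each comparison's family of testable peptides."""
    out = results.copy()
    out["p_adj"] = np.nan
    for _, idx in out.groupby("comparison").groups.items():
        mask = out.loc[idx, "testable"].to_numpy()
        fam = np.asarray(idx)[mask]
        if fam.size:
            out.loc[fam, "p_adj"] = bh_adjust(out.loc[fam, "p"].to_numpy())
    out["flagged"] = out["p_adj"] < alpha
    return out


@dataclass(frozen=True)
class CrosslinkSite:
    """Localized crosslink window, 1-based inclusive residue coordinates."""

    start: int
    end: int
    peptides: tuple[str, ...]
    note: str = ""


def localize_site(
    flagged: list[Peptide] | list[tuple[str, int, int]],
    digest: ProteinDigest,
) -> list[CrosslinkSite]:
    """Crosslink window(s) from flagged (depleted) peptide spans.

    Overlapping flagged spans form one site whose window is the intersection
    of the spans, extended upstream to include the tryptic cleavage residue
    immediately preceding it.  Disjoint groups of spans are reported as
    separate sites; an empty flagged set yields no sites.
    """
    spans: list[tuple[int, int, str]] = []
    for item in flagged:
        if isinstance(item, Peptide):
            seq, start, end = item.sequence, item.start, item.end
        else:
            seq, start, end = item
        if start < 1 or end > len(digest.sequence) or start > end:
            raise ValidationError(f"span ({start}, {end}) outside protein")
        spans.append((start, end, seq))
    if not spans:
        return []
    spans.sort()
    components: list[list[tuple[int, int, str]]] = [[spans[0]]]
    for s in spans[1:]:
        if s[0] <= max(e for _, e, _ in components[-1]):
            components[-1].append(s)
        else:
            components.append([s])
    sites = []
    for comp in components:
        start = max(s for s, _, _ in comp)
        end = min(e for _, e, _ in comp)
        note = ""
        if start > end:  # chained overlaps without a common core
            start = min(s for s, _, _ in comp)
            end = max(e for _, e, _ in comp)
            note = "no common core; union of overlapping spans reported"
        if start > 1 and digest.sequence[start - 2] in "KR":
            start -= 1
        sites.append(
            CrosslinkSite(
                start=start,
                end=end,
                peptides=tuple(seq for _, _, seq in comp),
                note=note,
            )
        )
    return sites


def default_comparisons(conditions: list[str]) -> list[tuple[str, str]]:
    """The study's comparisons: probe+UV vs no-UV, and probe+UV vs parent+UV."""
    comparisons = []
    compounds = sorted({c[: -len("+UV")] for c in conditions if c.endswith("+UV")})
    for cpd in compounds:
        uv, no_uv = condition_label(cpd, True), condition_label(cpd, False)
        if uv in conditions and no_uv in conditions:
            comparisons.append((uv, no_uv))
    for probe, parent in sorted(PARENT_COMPOUNDS.items()):
        puv, par_uv = condition_label(probe, True), condition_label(parent, True)
        if puv in conditions and par_uv in conditions:
            comparisons.append((puv, par_uv))
    return comparisons


class FootprintModel:
    """Depletion-detection model over a transition-level footprint table."""

    def __init__(
        self,
        records: pd.DataFrame,
        comparisons: list[tuple[str, str]] | None = None,
        aggregate_technical: bool = True,
        equal_var: bool = True,
        fragment_bounds: tuple[int, int] = (3, 6),
    ):
        self.records = records
        self.quant = sum_fragments(records, fragment_bounds=fragment_bounds)
        self.norm = normalize_footprint(self.quant)
        if comparisons is None:
            comparisons = default_comparisons(sorted(self.norm[CONDITION].unique()))
        if not comparisons:
            raise ValidationError("no comparisons could be derived from the data")
        self.comparisons = comparisons
        self.aggregate_technical = aggregate_technical
        self.equal_var = equal_var

    def fit(self, alpha: float = 0.05) -> "FootprintResults":
        raw = depletion_test(
            self.norm,
            self.comparisons,
            aggregate_technical=self.aggregate_technical,
            equal_var=self.equal_var,
        )
        table = adjust_and_flag(raw, alpha=alpha)
        return FootprintResults(model=self, alpha=alpha, table=table)


@dataclass
class FootprintResults:
    """Per-peptide, per-comparison depletion statistics with BH flags."""

    model: FootprintModel
    alpha: float
    table: pd.DataFrame

    def flagged_peptides(self, comparison: str | None = None) -> list[str]:
        sub = self.table[self.table["flagged"]]
        if comparison is not None:
            sub = sub[sub["comparison"] == comparison]
        return sorted(sub["peptide"].unique())

    def localize(
        self,
        digest: ProteinDigest,
        comparison: str | None = None,
    ) -> list[CrosslinkSite]:
        """Map flagged peptides onto the protein via the digest."""
        flagged = []
        for pep in self.flagged_peptides(comparison):
            try:
                flagged.append(digest.find(pep))
            except KeyError:
                continue
        return localize_site(flagged, digest)

    def summary(self) -> str:
        n_flag = int(self.table["flagged"].sum())
        n_test = int(self.table["testable"].sum())
        lines = [
            f"Footprint depletion test: {n_test} testable peptide x comparison "
            f"pairs, {n_flag} flagged at alpha={self.alpha:g}",
        ]
        for _, row in self.table[self.table["flagged"]].iterrows():
            lines.append(
                f"  {row['peptide']:<20} {row['comparison']:<32} "
                f"ratio={row['ratio']:.3f} p_adj={row['p_adj']:.2e}"
            )
        return "\n".join(lines)
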