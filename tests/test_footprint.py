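"""Footprinting: normalization, testing, BH, digestion, localization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import foldtrace as ft
from foldtrace.errors import ValidationError
from foldtrace.footprint import (
    FootprintModel,
    adjust_and_flag,
    bh_adjust,
    depletion_test,
    localize_site,
    normalize_footprint,
)
from foldtrace.proteolysis import CFTR_NTERM, cleavage_sites, coverage, digest
from foldtrace.quant import sum_fragments
from foldtrace.simulate import FootprintDesign, simulate_footprint_dataset


def peptide_quant(rows):
    """rows: (sample, condition, experiment, replicate, peptide, value)."""
    return pd.DataFrame(
        [
            {
                "experiment_id": exp,
                "sample_id": sample,
                "treatment": cond,
                "timepoint_h": 0.0,
                "band": "B",
                "isotopolog": "light",
                "peptide": pep,
                "replicate_id": rep,
                "value": float(v),
            }
            for sample, cond, exp, rep, pep, v in rows
        ]
    )


# ------------------------------------------------------------ normalization


def brute_force_normalize(df):
    """Two-pass literal iteration oracle for the double normalization."""
    out = []
    for _, row in df.iterrows():
        total = df[
            (df["experiment_id"] == row["experiment_id"])
            & (df["sample_id"] == row["sample_id"])
        ]["value"].sum()
        out.append(row["value"] / total)
    step1 = pd.Series(out, index=df.index)
    final = []
    for i, row in df.iterrows():
        mean = step1[df.index[df["peptide"] == row["peptide"]]].mean()
        final.append(step1[i] / mean)
    return np.array(final)


def test_normalize_footprint_matches_brute_force(rng):
    rows = []
    for s in range(6):
        for p in range(5):
            rows.append(
                (
                    f"s{s}",
                    f"cond{s % 3}",
                    f"exp{s % 2}",
                    "tr1",
                    f"PEP{p}K",
                    rng.uniform(10, 1000),
                )
            )
    df = peptide_quant(rows)
    norm = normalize_footprint(df)
    assert np.allclose(norm["normalized"].to_numpy(), brute_force_normalize(df), rtol=1e-12)
    # per-peptide grand mean equals 1 (second normalization)
    means = norm.groupby("peptide")["normalized"].mean()
    assert np.allclose(means, 1.0, rtol=1e-12)


def test_normalize_footprint_scale_invariance_and_identity(rng):
    rows = [
        ("s1", "a", "e1", "tr1", "P1K", 100.0),
        ("s1", "a", "e1", "tr1", "P2K", 300.0),
        ("s2", "a", "e1", "tr1", "P1K", 100.0),
        ("s2", "a", "e1", "tr1", "P2K", 300.0),
    ]
    df = peptide_quant(rows)
    norm = normalize_footprint(df)
    # identical samples in a single condition: all normalized values 1
    assert np.allclose(norm["normalized"], 1.0, rtol=1e-12)
    scaled = df.copy()
    scaled.loc[scaled["sample_id"] == "s2", "value"] *= 13.7
    assert np.allclose(
        normalize_footprint(scaled)["normalized"], norm["normalized"], rtol=1e-12
    )


def test_normalize_footprint_zero_sample_total():
    df = peptide_quant(
        [("s1", "a", "e1", "tr1", "P1K", 0.0), ("s1", "a", "e1", "tr1", "P2K", 0.0)]
    )
    with pytest.raises(ValidationError, match="s1"):
        normalize_footprint(df)


# ------------------------------------------------------------ t-tests


def _norm_from_groups(test_vals, control_vals):
    rows = []
    for i, v in enumerate(test_vals):
        rows.append((f"t{i}", "probe+UV", f"e{i}", "tr1", "PEPK", v))
    for i, v in enumerate(control_vals):
        rows.append((f"c{i}", "ctrl", f"e{i}", "tr1", "PEPK", v))
    df = peptide_quant(rows)
    df["normalized"] = df["value"]
    return df


def test_depletion_test_equal_means_gives_half():
    norm = _norm_from_groups([1.0, 1.1, 0.9, 1.0], [0.9, 1.0, 1.1, 1.0])
    res = depletion_test(norm, [("probe+UV", "ctrl")])
    assert res["p"].iloc[0] == pytest.approx(0.5, abs=1e-12)


def test_depletion_test_strong_loss_significant():
    norm = _norm_from_groups([5.0, 5.1, 4.9, 5.0], [10.0, 10.1, 9.9, 10.0])
    res = depletion_test(norm, [("probe+UV", "ctrl")])
    assert res["p"].iloc[0] < 1e-4
    assert res["ratio"].iloc[0] == pytest.approx(0.5, abs=0.01)


def test_depletion_test_degenerate_zero_variance():
    equal = _norm_from_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert depletion_test(equal, [("probe+UV", "ctrl")])["p"].iloc[0] == 1.0
    lower = _norm_from_groups([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
    assert depletion_test(lower, [("probe+UV", "ctrl")])["p"].iloc[0] == 0.0


def test_depletion_test_insufficient_observations_not_testable():
    norm = _norm_from_groups([1.0], [2.0, 2.1])
    res = depletion_test(norm, [("probe+UV", "ctrl")])
    assert not res["testable"].iloc[0]
    assert np.isnan(res["p"].iloc[0])


def test_technical_replicates_aggregate_to_experiment_units():
    """The t-test n is the number of experiments, not raw samples."""
    rows = []
    for e in range(4):
        for tr in ("tr1", "tr2"):
            rows.append((f"t{e}{tr}", "probe+UV", f"e{e}", tr, "PEPK", 1.0 + 0.01 * e))
            rows.append((f"c{e}{tr}", "ctrl", f"e{e}", tr, "PEPK", 2.0 + 0.01 * e))
    df = peptide_quant(rows)
    df["normalized"] = df["value"]
    res = depletion_test(df, [("probe+UV", "ctrl")])
    assert res["n_test"].iloc[0] == 4 and res["n_control"].iloc[0] == 4


# ------------------------------------------------------------ BH adjustment


def brute_force_bh(p):
    """Literal step-up: sort, p*m/i, enforce monotonicity from the largest."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)


def test_bh_trivia():
    assert bh_adjust([0.05]) == pytest.approx([0.05])
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, rtol=1e-12)


def test_bh_matches_literal_oracle(rng):
    for _ in range(200):
        p = rng.uniform(0, 1, size=rng.integers(1, 60))
        assert np.allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-12, atol=1e-15)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_dominates_raw_and_is_order_invariant(p):
    adj = bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    assert np.all(adj <= 1.0)
    perm = np.random.default_rng(0).permutation(len(p))
    assert np.allclose(bh_adjust(np.asarray(p)[perm]), adj[perm], rtol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.2])
    with pytest.raises(ValidationError):
        bh_adjust([-0.1])


# ------------------------------------------------------------ digestion


def test_proline_rule_on_off_worked_example():
    on = digest("SKLFFSWTRPILRK", proline_rule=True)
    assert [p.sequence for p in on.peptides] == ["SK", "LFFSWTRPILR", "K"]
    off = digest("SKLFFSWTRPILRK", proline_rule=False)
    assert [p.sequence for p in off.peptides] == ["SK", "LFFSWTR", "PILR", "K"]


def test_digest_spans_match_sequence_and_tile():
    dig = digest(CFTR_NTERM, proline_rule=True)
    for p in dig.peptides:
        assert CFTR_NTERM[p.start - 1 : p.end] == p.sequence
    assert "".join(p.sequence for p in dig.peptides) == CFTR_NTERM


def test_digest_both_universes_cover_both_forms():
    dig = digest(CFTR_NTERM, proline_rule="both")
    assert "LFFSWTR" in dig and "LFFSWTRPILR" in dig
    assert dig.find("LFFSWTR").start == 15 and dig.find("LFFSWTR").end == 21
    assert dig.find("LFFSWTRPILR").end == 25
    assert 14 in cleavage_sites(CFTR_NTERM, proline_rule=False)


def test_digest_missed_cleavages():
    dig = digest("AKCKDK", max_missed_cleavages=2, proline_rule=False)
    seqs = {(p.sequence, p.missed_cleavages) for p in dig.peptides}
    assert ("AK", 0) in seqs and ("AKCK", 1) in seqs and ("AKCKDK", 2) in seqs


def test_digest_invalid_residue_reports_position():
    with pytest.raises(ValidationError, match="position 3"):
        digest("AKXK")


@given(
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60),
    st.booleans(),
)
def test_digest_reconstruction_property(seq, rule):
    """0-missed peptides tile the protein without gaps or overlaps."""
    dig = digest(seq, max_missed_cleavages=0, proline_rule=rule)
    assert "".join(p.sequence for p in dig.peptides) == seq
    pos = 1
    for p in sorted(dig.peptides, key=lambda q: q.start):
        assert p.start == pos
        pos = p.end + 1
    assert pos == len(seq) + 1


def test_digest_agrees_with_pyteomics():
    """Independent cross-check against an established digestion engine."""
    parser = pytest.importorskip("pyteomics.parser")
    seq = CFTR_NTERM
    ours = {p.sequence for p in digest(seq, max_missed_cleavages=1, proline_rule=True).peptides}
    theirs = parser.cleave(seq, r"[KR](?!P)", missed_cleavages=1, min_length=1)
    assert ours == set(theirs)


# ------------------------------------------------------------ coverage


def test_coverage_trivia():
    assert coverage([], 20) == 0.0
    assert coverage([(1, 10), (5, 14)], 20) == pytest.approx(70.0)
    with pytest.raises(ValidationError):
        coverage([(0, 5)], 20)
    with pytest.raises(ValidationError):
        coverage([(18, 22)], 20)


def test_coverage_matches_brute_force(rng):
    for _ in range(200):
        length = int(rng.integers(10, 200))
        spans = [
            (int(s), int(min(length, s + rng.integers(0, 20))))
            for s in rng.integers(1, length + 1, size=rng.integers(0, 12))
        ]
        residues = set()
        for s, e in spans:
            residues |= set(range(s, e + 1))
        expected = 100.0 * len(residues) / length
        assert coverage(spans, length) == pytest.approx(expected, rel=1e-12)


def test_full_digest_covers_everything():
    dig = digest(CFTR_NTERM, max_missed_cleavages=0, proline_rule=True)
    assert coverage(dig.peptides, len(CFTR_NTERM)) == pytest.approx(100.0)


# ------------------------------------------------------------ localization


def test_localize_lasso_window():
    """Flagged spans 15-21 and 15-25 with K14 upstream give window 14-21."""
    dig = digest(CFTR_NTERM, proline_rule="both")
    sites = localize_site(
        [dig.find("LFFSWTR"), dig.find("LFFSWTRPILR")], dig
    )
    assert len(sites) == 1
    assert (sites[0].start, sites[0].end) == (14, 21)
    assert set(sites[0].peptides) == {"LFFSWTR", "LFFSWTRPILR"}


def test_localize_single_span_extends_to_preceding_cleavage():
    seq = "A" * 98 + "R" + "C" * 11 + "K" + "D" * 5
    dig = digest(seq, proline_rule=False)
    sites = localize_site([("C" * 11, 100, 110)], dig)
    assert (sites[0].start, sites[0].end) == (99, 110)


def test_localize_empty_and_disjoint():
    dig = digest(CFTR_NTERM, proline_rule="both")
    assert localize_site([], dig) == []
    sites = localize_site([("LFFSWTR", 15, 21), ("LELSDIYQIPSVDSADNLSEK", 32, 52)], dig)
    assert len(sites) == 2


# ------------------------------------------------------------ end-to-end


def test_footprint_model_reproduces_two_peptide_phenotype():
    """Depletion 0.5 on the overlapping pair: exactly those two flagged in
    the probe-vs-parent comparison, localizing to window 14-21."""
    design = FootprintDesign(depletion=ft.LASSO_DEPLETION)
    records, _ = simulate_footprint_dataset(design, seed=3)
    results = FootprintModel(records).fit(alpha=0.05)
    comparison = "IDOR-6A+UV vs IDOR-6+UV"
    assert results.flagged_peptides(comparison) == ["LFFSWTR", "LFFSWTRPILR"]
    dig = digest(CFTR_NTERM, proline_rule="both")
    sites = results.localize(dig, comparison)
    assert (sites[0].start, sites[0].end) == (14, 21)
    # no depletion signal without UV against the parent compound
    no_uv = "IDOR-6A vs IDOR-6"
    sub = results.table[results.table["comparison"] == no_uv]
    assert not sub["flagged"].any()


def test_adjust_and_flag_families_are_per_comparison():
    raw = pd.DataFrame(
        {
            "peptide": ["P1", "P2", "P1", "P2"],
            "comparison": ["a", "a", "b", "b"],
            "test": "t",
            "control": "c",
            "ratio": 1.0,
            "p": [0.01, 0.04, 0.5, 0.9],
            "n_test": 4,
            "n_control": 4,
            "testable": True,
        }
    )
    out = adjust_and_flag(raw, alpha=0.05)
    a = out[out["comparison"] == "a"]["p_adj"].to_numpy()
    assert np.allclose(a, [0.02, 0.04])
    assert out[out["comparison"] == "b"]["p_adj"].iloc[0] == pytest.approx(0.9)
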