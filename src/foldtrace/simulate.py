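"""Synthetic-data generators emulating the study's three experimental designs.

Everything downstream of chromatogram integration is generated here:
transition-level (fragment-ion) intensity tables for SILAC pulse-chase and
chase assays, DIA-style crosslink footprinting tables with targeted peptide
depletion, and HTS plates with control wells.  All randomness is driven by an
explicit seed; with zero noise every intensity equals its model expectation
exactly, so the generators double as ground-truth oracles for the analysis
stages.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import (
    KineticParams,
    Segment,
    Trajectory,
    pulse_chase_schedule,
    simulate_segments,
    simulate_trajectory,
)
from .proteolysis import CFTR_NTERM, digest

#: The eight proteotypic CFTR peptides quantified in the pulse-chase assay.
CFTR_PEPTIDES = (
    "AVQPLLLGR",
    "GQLLAVAGSTGAGK",
    "NSILNPINSIR",
    "LSLVPDSEQGEAILPR",
    "ISVISTGPTLQAR",
    "STLLSAFLR",
    "VFIFSGTFR",
    "VADEVGLR",
)

DEFAULT_REFERENCE_PEPTIDE = "AVQPLLLGR"

#: Gel-excision QC peptides from proteins comigrating with the C band (CLTC,
#: SMC4) or the B band (MED23, LRPPRC).
QC_PEPTIDES: dict[str, tuple[str, ...]] = {
    "C": ("VANVELYYR", "HELIEFR", "VLDAIIQEK", "LLEENVSAFK"),
    "B": ("LFDLLYPEK", "YNIVTLDR", "SSLLLGFR", "IPENIYR"),
}

#: Ground-truth relative ionization response factors, anchored to the
#: reference peptide (= 1).  Values span the order-of-magnitude spread typical
#: of tryptic peptides.
DEFAULT_RESPONSE_FACTORS: dict[str, float] = {
    "AVQPLLLGR": 1.0,
    "GQLLAVAGSTGAGK": 0.45,
    "NSILNPINSIR": 1.8,
    "LSLVPDSEQGEAILPR": 0.25,
    "ISVISTGPTLQAR": 3.0,
    "STLLSAFLR": 0.8,
    "VFIFSGTFR": 1.4,
    "VADEVGLR": 0.6,
}

TRANSITION_COLUMNS = [
    "experiment_id",
    "sample_id",
    "treatment",
    "timepoint_h",
    "band",
    "isotopolog",
    "peptide",
    "fragment_id",
    "replicate_id",
    "uv_exposed",
    "compound",
    "intensity",
]

_LN2 = float(np.log(2.0))


def kinetic_preset(name: str) -> KineticParams:
    """Named kinetic parameter presets reproducing the study's regimes.

    The WT preset is tuned so a 30-min pulse labels ~30% of the B pool
    (k_mat + k_degB = 0.713/h) with folding efficiency 0.19 and an 18-h
    mature-pool half-life; the F508del presets label ~50% (turnover
    ln2/0.5 per hour, i.e. the heavy B pool is gone within 2.5 h of chase)
    with per-treatment folding efficiencies and a 5.5-h mature half-life.
    """
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown kinetic preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def _params(a: float, phi: float, k_deg_c: float) -> KineticParams:
    return KineticParams(
        synthesis_rate=100.0,
        k_mat=phi * a,
        k_deg_b=(1.0 - phi) * a,
        k_deg_c=k_deg_c,
        pulse_duration=0.5,
    )


_A_WT = 0.713
_A_F508 = _LN2 / 0.5
PRESETS: dict[str, KineticParams] = {
    "WT": _params(_A_WT, 0.19, _LN2 / 18.0),
    "F508del": _params(_A_F508, 0.005, _LN2 / 5.5),
    "F508del+TEZ": _params(_A_F508, 0.024, _LN2 / 5.5),
    "F508del+ELX": _params(_A_F508, 0.067, _LN2 / 5.5),
    "F508del+TEZ+ELX": _params(_A_F508, 0.14, _LN2 / 5.5),
    "F508del+IDOR-3": _params(_A_F508, 0.24, _LN2 / 5.5),
    "F508del+IDOR-4": _params(_A_F508, 0.31, _LN2 / 5.5),
}


def _n_fragments(peptide: str, lo: int, hi: int) -> int:
    """Deterministic fragment count in [lo, hi], stable across runs."""
    return lo + zlib.crc32(peptide.encode()) % (hi - lo + 1)


def _fragment_weights(n: int) -> np.ndarray:
    """Fixed fragment intensity shares summing to 1 (triangular profile)."""
    w = np.arange(1, n + 1, dtype=float)
    return w / w.sum()


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-preserving multiplicative lognormal noise at the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


@dataclass(frozen=True)
class PulseChaseDesign:
    """Experimental layout of a SILAC pulse-chase (or inverse chase) assay.

    ``scheme='heavy_pulse'`` is the folding-efficiency design: a 30-min heavy
    pulse from the pre-pulse light steady state, then a light chase, with
    ``timepoints`` measured from the end of the pulse (0 = directly after the
    pulse).  ``scheme='heavy_chase'`` is the half-life design: the whole pool
    is equilibrated with light label, then chased with heavy medium from t=0.
    """

    treatments: Mapping[str, KineticParams]
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.5, 4.0, 6.0)
    n_replicates: int = 3
    scheme: str = "heavy_pulse"
    washout: Mapping[str, KineticParams] | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("heavy_pulse", "heavy_chase"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        if not self.treatments:
            raise ValidationError("design needs at least one treatment")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        tps = tuple(self.timepoints)
        if len(tps) == 0 or any(t < 0 for t in tps):
            raise ValidationError("timepoints must be non-negative")
        if self.scheme == "heavy_pulse" and 0.0 not in tps:
            raise ValidationError(
                "a pulse-chase design must include timepoint 0 (directly after "
                "the pulse)"
            )


def treatment_trajectory(
    design: PulseChaseDesign, treatment: str
) -> tuple[np.ndarray, Trajectory]:
    """Ground-truth trajectory for one treatment, on the design's timepoints.

    Returns (reported timepoints, trajectory); for the heavy-pulse scheme the
    trajectory is evaluated at pulse_duration + timepoint so that reported
    time 0 is the end of the pulse.
    """
    params = design.treatments[treatment]
    tps = np.asarray(sorted(set(design.timepoints)), dtype=float)
    washed = design.washout.get(treatment) if design.washout else None
    if design.scheme == "heavy_pulse":
        abs_times = params.pulse_duration + tps
        if washed is None:
            traj = simulate_trajectory(
                params, pulse_chase_schedule(params.pulse_duration), abs_times
            )
        else:
            segs = [
                Segment(0.0, params, "heavy"),
                Segment(params.pulse_duration, washed, "light"),
            ]
            traj = simulate_segments(segs, abs_times)
    else:
        chase = washed if washed is not None else params
        if chase is params:
            traj = simulate_trajectory(params, [(0.0, "heavy")], tps)
        else:
            # Pools equilibrated under `params`, chase dynamics under `washed`.
            b0, c0 = params.steady_state()
            base = simulate_segments(
                [Segment(0.0, chase, "heavy")], tps, initial="empty"
            )
            # Superpose the decay of the initial light pools (linear system).
            hom = _decay_of_initial_pools(chase, b0, c0, tps)
            traj = _combine(base, hom, tps, b0, c0)
            return tps, traj
    return tps, traj


def _decay_of_initial_pools(
    params: KineticParams, b0: float, c0: float, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form decay of initial light pools with no synthesis input."""
    a, c = params.turnover_b, params.k_deg_c
    t = np.asarray(times, dtype=float)
    b = b0 * np.exp(-a * t)
    if abs(a - c) > 1e-12 * max(a, c, 1.0):
        conv = params.k_mat * b0 * (np.exp(-a * t) - np.exp(-c * t)) / (c - a)
    else:
        conv = params.k_mat * b0 * t * np.exp(-a * t)
    cc = c0 * np.exp(-c * t) + conv
    degraded = (b0 + c0) - b - cc
    return b, cc, degraded


def _combine(
    base: Trajectory,
    hom: tuple[np.ndarray, np.ndarray, np.ndarray],
    times: np.ndarray,
    b0: float,
    c0: float,
) -> Trajectory:
    bl, cl, dl = hom
    return Trajectory(
        times=times,
        b_heavy=base.b_heavy,
        c_heavy=base.c_heavy,
        degraded_heavy=base.degraded_heavy,
        synthesized_heavy=base.synthesized_heavy,
        b_light=bl,
        c_light=cl,
        degraded_light=dl,
        synthesized_light=np.zeros_like(times),
        initial_pools=(0.0, 0.0, b0, c0),
    )


def simulate_pulse_chase_dataset(
    design: PulseChaseDesign,
    response_factors: Mapping[str, float] | None = None,
    noise_cv: float = 0.10,
    seed: int = 0,
    include_qc: bool = False,
    qc_bleed: float = 0.05,
    qc_intensity: float = 500.0,
    experiment_id: str = "exp1",
    fragment_range: tuple[int, int] = (4, 6),
) -> tuple[pd.DataFrame, dict]:
    """Transition-level table for a SILAC pulse-chase experiment.

    Each of the eight CFTR peptides emits 4-6 fragments whose expected
    intensities sum to pool abundance x the peptide's response factor;
    per-fragment multiplicative lognormal noise at ``noise_cv`` is applied.
    Returns the table and a ground-truth dict (parameters, response factors,
    per-treatment pool trajectories).
    """
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rf = dict(response_factors or DEFAULT_RESPONSE_FACTORS)
    if any(v <= 0 for v in rf.values()):
        raise ValidationError("response factors must be > 0")
    rng = np.random.default_rng(seed)

    rows: list[tuple] = []
    truth: dict = {
        "seed": int(seed),
        "noise_cv": float(noise_cv),
        "response_factors": {k: float(v) for k, v in rf.items()},
        "treatments": {},
    }
    peptides = sorted(rf)
    lo, hi = fragment_range
    for treatment in sorted(design.treatments):
        params = design.treatments[treatment]
        tps, traj = treatment_trajectory(design, treatment)
        truth["treatments"][treatment] = {
            "params": asdict(params),
            "folding_efficiency": params.folding_efficiency,
            "timepoints": [float(t) for t in tps],
            "pools": {
                f"{band}_{iso}": [float(v) for v in traj.pool(band, iso)]
                for band in ("b", "c")
                for iso in ("heavy", "light")
            },
        }
        for rep in range(1, design.n_replicates + 1):
            replicate_id = f"r{rep}"
            for k, tp in enumerate(tps):
                sample_id = f"{treatment}|t{tp:g}|{replicate_id}"
                for band in ("B", "C"):
                    for iso in ("heavy", "light"):
                        pool = float(traj.pool(band.lower(), iso)[k])
                        for pep in peptides:
                            n = _n_fragments(pep, lo, hi)
                            w = _fragment_weights(n)
                            noise = _lognormal_factors(rng, noise_cv, n)
                            for j in range(n):
                                rows.append(
                                    (
                                        experiment_id,
                                        sample_id,
                                        treatment,
                                        float(tp),
                                        band,
                                        iso,
                                        pep,
                                        f"y{j + 1}",
                                        replicate_id,
                                        False,
                                        "",
                                        pool * rf[pep] * w[j] * noise[j],
                                    )
                                )
                        if include_qc and iso == "light":
                            for exp_band, qpeps in QC_PEPTIDES.items():
                                level = qc_intensity * (
                                    (1.0 - qc_bleed) if band == exp_band else qc_bleed
                                )
                                for pep in qpeps:
                                    n = _n_fragments(pep, lo, hi)
                                    w = _fragment_weights(n)
                                    noise = _lognormal_factors(rng, noise_cv, n)
                                    for j in range(n):
                                        rows.append(
                                            (
                                                experiment_id,
                                                sample_id,
                                                treatment,
                                                float(tp),
                                                band,
                                                iso,
                                                pep,
                                                f"y{j + 1}",
                                                replicate_id,
                                                False,
                                                "",
                                                level * w[j] * noise[j],
                                            )
                                        )
    df = pd.DataFrame(rows, columns=TRANSITION_COLUMNS)
    return df, truth


# ---------------------------------------------------------------------------
# Crosslink footprinting
# ---------------------------------------------------------------------------

FOOTPRINT_COMPOUNDS = ("IDOR-5", "IDOR-5A", "IDOR-6", "IDOR-6A", "IDOR-6B")

#: Photoactive aryl-azide probe -> non-photoactive parent macrocycle.
PARENT_COMPOUNDS = {"IDOR-5A": "IDOR-5", "IDOR-6A": "IDOR-6", "IDOR-6B": "IDOR-6"}


def condition_label(compound: str, uv: bool) -> str:
    return f"{compound}+UV" if uv else compound


@dataclass(frozen=True)
class PeptideSpan:
    sequence: str
    start: int  # 1-based inclusive
    end: int


def _default_universe(n_peptides: int) -> tuple[PeptideSpan, ...]:
    """Deterministic ~80-peptide tryptic universe on a synthetic protein.

    The protein begins with the real CFTR N-terminal sequence (so the
    overlapping lasso peptides LFFSWTR / LFFSWTRPILR exist at their true
    spans) and continues with a fixed-seed random sequence.  Both
    proline-rule universes are included, mirroring DIA detection of both
    forms.
    """
    rng = np.random.default_rng(20240301)
    aa = np.array(list("ACDEFGHILMNPQSTVWY"))  # K/R added separately
    tail = []
    while sum(len(s) for s in tail) < 1400:
        seg = "".join(rng.choice(aa, size=rng.integers(5, 15)))
        tail.append(seg + rng.choice(["K", "R"]))
    protein = CFTR_NTERM + "".join(tail)
    dig = digest(protein, max_missed_cleavages=0, proline_rule="both")
    spans: list[PeptideSpan] = []
    seen = set()
    for p in sorted(dig.peptides, key=lambda p: (p.start, p.end)):
        if 5 <= len(p.sequence) <= 25 and (p.start, p.end) not in seen:
            seen.add((p.start, p.end))
            spans.append(PeptideSpan(p.sequence, p.start, p.end))
        if len(spans) == n_peptides:
            break
    return tuple(spans)


@dataclass(frozen=True)
class FootprintDesign:
    """Design of a photo-crosslink peptide-footprinting experiment.

    ``depletion`` maps peptide sequence -> multiplicative factor in (0, 1]
    applied to its expectation only in the condition where ``probe`` is
    present AND the sample was UV-exposed (covalent capture destroys the
    unmodified peptide).  Factor 1.0 means unaffected.
    """

    peptides: tuple[PeptideSpan, ...] = ()
    compounds: tuple[str, ...] = FOOTPRINT_COMPOUNDS
    n_experiments: int = 4
    n_technical: int = 2
    depletion: Mapping[str, float] = field(default_factory=dict)
    probe: str = "IDOR-6A"
    noise_cv: float = 0.10

    def __post_init__(self) -> None:
        if not self.peptides:
            object.__setattr__(self, "peptides", _default_universe(80))
        for pep, f in self.depletion.items():
            if not (0 < f <= 1):
                raise ValidationError(
                    f"depletion factor for {pep} must be in (0, 1], got {f}"
                )
        known = {p.sequence for p in self.peptides}
        missing = sorted(set(self.depletion) - known)
        if missing:
            raise ValidationError(f"depleted peptides not in universe: {missing}")
        if self.n_experiments < 1 or self.n_technical < 1:
            raise ValidationError("need >= 1 experiment and technical replicate")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.probe not in self.compounds:
            raise ValidationError(f"probe {self.probe!r} not among compounds")

    def span_of(self, peptide: str) -> PeptideSpan:
        for p in self.peptides:
            if p.sequence == peptide:
                return p
        raise KeyError(peptide)


#: Depletion preset reproducing the lasso-domain crosslink phenotype: the
#: IDOR-6A probe halves both overlapping N-terminal peptides under UV.
LASSO_DEPLETION = {"LFFSWTR": 0.5, "LFFSWTRPILR": 0.5}


def _peptide_baseline(peptide: str) -> float:
    """Fixed per-peptide baseline intensity (spread ~3x across peptides)."""
    return 1000.0 * (0.5 + (zlib.crc32(peptide.encode()) % 1000) / 999.0)


def simulate_footprint_dataset(
    design: FootprintDesign, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Transition-level table for the probe x UV crosslink experiment.

    Each peptide emits 3-5 fragments; a depleted peptide's expectation is
    baseline x depletion factor only under (probe, UV).  Vectorized; same
    seed and design give a bit-identical table.
    """
    rng = np.random.default_rng(seed)
    peptides = [p.sequence for p in design.peptides]
    n_frag = np.array([_n_fragments(p, 3, 5) for p in peptides])
    base = np.array([_peptide_baseline(p) for p in peptides])
    weights = [_fragment_weights(n) for n in n_frag]

    pep_col, frag_col, exp_col = [], [], []
    for p, n, w in zip(peptides, n_frag, weights):
        for j in range(n):
            pep_col.append(p)
            frag_col.append(f"y{j + 1}")
    frag_expect = np.concatenate([base[i] * weights[i] for i in range(len(peptides))])
    frag_pep = np.array(pep_col)
    depl = np.array([design.depletion.get(p, 1.0) for p in frag_pep])

    frames = []
    for compound in design.compounds:
        for uv in (False, True):
            active = uv and compound == design.probe
            expect = frag_expect * (depl if active else 1.0)
            for e in range(1, design.n_experiments + 1):
                for r in range(1, design.n_technical + 1):
                    noise = _lognormal_factors(rng, design.noise_cv, expect.size)
                    frames.append(
                        pd.DataFrame(
                            {
                                "experiment_id": f"exp{e}",
                                "sample_id": f"{condition_label(compound, uv)}|exp{e}|tr{r}",
                                "treatment": condition_label(compound, uv),
                                "timepoint_h": 0.0,
                                "band": "B",
                                "isotopolog": "light",
                                "peptide": frag_pep,
                                "fragment_id": frag_col,
                                "replicate_id": f"tr{r}",
                                "uv_exposed": uv,
                                "compound": compound,
                                "intensity": expect * noise,
                            }
                        )
                    )
    df = pd.concat(frames, ignore_index=True)[TRANSITION_COLUMNS]
    truth = {
        "seed": int(seed),
        "noise_cv": design.noise_cv,
        "probe": design.probe,
        "depletion": dict(design.depletion),
        "baseline": {p: float(b) for p, b in zip(peptides, base)},
        "spans": {p.sequence: [p.start, p.end] for p in design.peptides},
    }
    return df, truth


# ---------------------------------------------------------------------------
# HTS plates
# ---------------------------------------------------------------------------


def default_plate_layout(n_wells: int = 384, n_controls: int = 16) -> pd.DataFrame:
    """Layout with `n_controls` wells per control role, remainder compounds."""
    if n_wells < 2 * n_controls + 1:
        raise ValidationError("plate too small for requested controls")
    roles = (
        ["positive_control"] * n_controls
        + ["negative_control"] * n_controls
        + ["compound"] * (n_wells - 2 * n_controls)
    )
    wells = [f"W{i + 1:03d}" for i in range(n_wells)]
    compounds = [""] * (2 * n_controls) + [
        f"CPD-{i + 1:05d}" for i in range(n_wells - 2 * n_controls)
    ]
    return pd.DataFrame({"well": wells, "role": roles, "compound": compounds})


def simulate_plate(
    layout: pd.DataFrame | None = None,
    pos_mean: float = 100.0,
    pos_sd: float = 5.0,
    neg_mean: float = 0.0,
    neg_sd: float = 2.0,
    compound_effects: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate raw signals for one screening plate.

    Control wells are drawn from the stated normal distributions; compound
    wells get signal = neg_mean + effect% / 100 * (pos_mean - neg_mean) plus
    negative-control noise.  The default effect distribution makes ~0.15% of
    compounds active (uniform 15-80% activity), emulating a primary-screen
    hit rate of roughly one per thousand.
    """
    if pos_sd < 0 or neg_sd < 0:
        raise ValidationError("control standard deviations must be >= 0")
    if layout is None:
        layout = default_plate_layout()
    required = {"positive_control", "negative_control"}
    missing = required - set(layout["role"])
    if missing:
        raise ValidationError(f"layout missing control role(s): {sorted(missing)}")
    rng = np.random.default_rng(seed)
    df = layout.copy()
    signal = np.empty(len(df))
    for role, mu, sd in (
        ("positive_control", pos_mean, pos_sd),
        ("negative_control", neg_mean, neg_sd),
    ):
        mask = (df["role"] == role).to_numpy()
        signal[mask] = rng.normal(mu, sd, mask.sum()) if sd > 0 else mu
    mask = (df["role"] == "compound").to_numpy()
    n_cpd = int(mask.sum())
    if n_cpd:
        if compound_effects is None:
            effects = _default_compound_effects(rng, n_cpd)
        else:
            effects = np.asarray(compound_effects(rng, n_cpd), dtype=float)
        noise = rng.normal(0.0, neg_sd, n_cpd) if neg_sd > 0 else 0.0
        signal[mask] = neg_mean + effects / 100.0 * (pos_mean - neg_mean) + noise
    df["signal"] = signal
    return df


def _default_compound_effects(rng: np.random.Generator, n: int) -> np.ndarray:
    effects = rng.normal(0.0, 3.0, n)
    active = rng.random(n) < 0.0015
    effects[active] = rng.uniform(15.0, 80.0, int(active.sum()))
    return effects
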