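import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_transition_table(rows):
    """Build a transition table from (sample, band, iso, peptide, frag, I) rows."""
    from foldtrace.simulate import TRANSITION_COLUMNS

    records = []
    for sample, band, iso, pep, frag, intensity in rows:
        records.append(
            {
                "experiment_id": "exp1",
                "sample_id": sample,
                "treatment": sample.split("|")[0],
                "timepoint_h": 0.0,
                "band": band,
                "isotopolog": iso,
                "peptide": pep,
                "fragment_id": frag,
                "replicate_id": "r1",
                "uv_exposed": False,
                "compound": "",
                "intensity": float(intensity),
            }
        )
    return pd.DataFrame(records, columns=TRANSITION_COLUMNS)


@pytest.fixture
def wt_noiseless():
    """Noiseless WT pulse-chase dataset with its ground truth."""
    import foldtrace as ft

    design = ft.PulseChaseDesign(
        treatments={"WT": ft.kinetic_preset("WT")}, n_replicates=2
    )
    df, truth = ft.simulate_pulse_chase_dataset(design, noise_cv=0.0, seed=7)
    return df, truth
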