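import numpy as np
import pandas as pd
import pytest

from berrydeg.io_tables import validate_annotation, validate_design
from berrydeg.simulate import SimulationConfig, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_design():
    """2 treatments x 2 stages x 2 replicates, the standard study layout."""
    rows = []
    for treatment in ("SDI", "RDI"):
        for stage in ("V", "M"):
            for rep in (1, 2):
                rows.append(
                    {"sample_id": f"{treatment[0]}{stage}{rep}", "treatment": treatment,
                     "stage": stage, "replicate": rep}
                )
    return validate_design(pd.DataFrame(rows))


def make_annotation(ids, lengths=None, categories=None):
    n = len(ids)
    return validate_annotation(
        pd.DataFrame(
            {
                "transcript_id": list(ids),
                "length_bp": lengths if lengths is not None else [1000] * n,
                "functional_category": categories if categories is not None else ["Unknown"] * n,
            }
        )
    )


@pytest.fixture
def noise_free_planted():
    """Noise-free simulation: 20 up + 20 down at fold 4 per stage, 160 others.

    From the viewpoint of one stage's comparison that is 40 planted DEGs and
    160 transcripts that should stay unregulated.
    """
    cfg = SimulationConfig(
        n_transcripts=200, n_up=20, n_down=20, fold_change=4.0,
        n_psi_linked=0, n_short=0, n_inactive=0,
        replicate_noise_sd=0.0, psi_noise_sd=0.0, seed=7,
    )
    counts, ann, design, truth = simulate_counts(cfg)
    return cfg, counts, ann, design, truth
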