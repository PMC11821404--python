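import numpy as np
import pandas as pd
import pytest

from synofab.fab_core import ToleranceModel
from synofab.fab_quant import StandardMab
from synofab.proteome_compare import ProteinQuantTable
from synofab.synthetic_data import CohortConfig, generate_cohort

STANDARDS = [
    StandardMab("trastuzumab", 47_637.0, 20.0, 200.0),
    StandardMab("alemtuzumab", 47_176.0, 23.5, 200.0),
]

SMALL_PROTEOME = {
    "n_plasma_proteins": 60,
    "n_sf_only_proteins_per_category": 6,
    "log10_lfq_mean": 7.0,
    "log10_lfq_sd": 1.0,
    "plasma_sf_log_noise_sd": 0.3,
    "missing_rate": 0.05,
}


@pytest.fixture
def tol() -> ToleranceModel:
    return ToleranceModel(sigma_mass_da=1.5, sigma_rt_min=0.05)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-patient cohort, modest size; shared across read-only tests."""
    config = CohortConfig(
        n_patients=2,
        clones_per_sample_range=(60, 80),
        intensity_cv=0.1,
        seed=7,
        proteome_params=SMALL_PROTEOME,
    )
    return generate_cohort(config)


def toy_quant_table(n_patients: int = 9) -> ProteinQuantTable:
    """Hand-specified 5-gene table exercising the detection filter.

    Detected-sample counts (plasma, SF): g1 (6, 0) keep; g2 (5, 5) drop;
    g3 (9, 9) keep; g4 (0, 6) keep; g5 (3, 2) drop.
    """
    samples = [f"P{i:02d}_plasma" for i in range(1, n_patients + 1)] + [
        f"P{i:02d}_SF" for i in range(1, n_patients + 1)
    ]
    meta = pd.DataFrame(
        {
            "patient": [s.split("_")[0] for s in samples],
            "fluid": ["plasma" if s.endswith("plasma") else "SF" for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    counts = {
        "g1": (6, 0),
        "g2": (5, 5),
        "g3": (9, 9),
        "g4": (0, 6),
        "g5": (3, 2),
    }
    pep = pd.DataFrame(0, index=list(counts), columns=samples, dtype=int)
    lfq = pd.DataFrame(np.nan, index=list(counts), columns=samples, dtype=float)
    rng = np.random.default_rng(0)
    for g, (np_, ns) in counts.items():
        for s in samples[:np_]:
            pep.loc[g, s] = 5
            lfq.loc[g, s] = float(rng.uniform(1e6, 1e8))
        for s in samples[n_patients : n_patients + ns]:
            pep.loc[g, s] = 5
            lfq.loc[g, s] = float(rng.uniform(1e6, 1e8))
    return ProteinQuantTable(lfq=lfq, peptides=pep, samples=meta)
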