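import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from arrayqc.simulate import ReplicateDesign, SimulationConfig, simulate_all

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated study shared across tests (read-only)."""
    cfg = SimulationConfig(
        seed=7, n_loci=600, n_chromosomes=2, n_individuals=30,
        replicate_design=ReplicateDesign(4, 2, 2, 1))
    manifest, cohort, calls, truth, profiles = simulate_all(cfg)
    return {"config": cfg, "manifest": manifest, "cohort": cohort,
            "calls": calls, "truth": truth, "profiles": profiles}


def make_calls(genotypes: dict, gc_score: float = 0.9) -> pd.DataFrame:
    """Small call table from {sample_id: [genotype codes]} (shared probes)."""
    rows = []
    for sample, genos in genotypes.items():
        for i, g in enumerate(genos):
            rows.append((sample, f"P{i:06d}", np.int8(g),
                         gc_score if g != -1 else 0.1, 1.0, 1.0, 0.0,
                         {0: 0.0, 1: 0.5, 2: 1.0, -1: 0.5}[int(g)]))
    return pd.DataFrame(rows, columns=["sample_id", "probe_id", "genotype",
                                       "gc_score", "x_raw", "y_raw", "lrr",
                                       "baf"])


def make_cohort(samples: list[tuple]) -> pd.DataFrame:
    """Cohort from (sample_id, individual_id, input_type[, source]) tuples."""
    rows = []
    for i, rec in enumerate(samples):
        sid, ind, itype = rec[:3]
        source = rec[3] if len(rec) > 3 else "blood"
        rows.append((sid, ind, itype, source, f"PL{i // 96:03d}",
                     f"C{i // 4:04d}", i % 4 + 1, "F"))
    return pd.DataFrame(rows, columns=["sample_id", "individual_id",
                                       "input_type", "source_material",
                                       "plate_id", "chip_id", "chip_position",
                                       "reported_sex"])
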