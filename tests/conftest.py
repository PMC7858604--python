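import numpy as np
import pandas as pd
import pytest

import shiftmethyl as sm


@pytest.fixture(scope="session")
def cohort_sheet():
    """Default 21 SWD + 11 control paired sheet (64 samples)."""
    return sm.generate_cohort(sm.CohortConfig(seed=11))


@pytest.fixture()
def tiny_sheet():
    """1 SWD + 1 control subject, both periods, no covariates."""
    rows = []
    for subject, group in (("S1", "swd"), ("C1", "control")):
        for period in ("work", "vacation"):
            rows.append({
                "sample_id": f"{subject}_{period}",
                "subject": subject,
                "group": group,
                "period": period,
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def null_dataset(cohort_sheet):
    """A no-effect methylome on the default cohort."""
    effects = sm.EffectConfig(n_probes=400, frac_affected_swd=0.0,
                              frac_affected_ctrl=0.0, noise_sd=1.0)
    matrix, truth = sm.generate_methylome(cohort_sheet, effects, seed=5)
    return matrix, truth


@pytest.fixture(scope="session")
def annotated_bundle():
    """Small end-to-end bundle with annotation and gene sets."""
    bundle = sm.simulate_dataset(
        sm.CohortConfig(n_swd=10, n_control=6, seed=21),
        sm.EffectConfig(n_probes=200, frac_affected_swd=0.15, noise_sd=0.5,
                        recovery_probe_ids=(0, 1), recovery_link_strength=0.8),
        sm.LibraryConfig(n_genes=40, n_pathways=5, probes_per_gene=5,
                         genes_per_pathway=8),
        seed=21,
    )
    return bundle
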