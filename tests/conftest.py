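import pytest

from tnmismatch import (
    compute_residual_matrix,
    default_config,
    discretize_residuals,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Default six-archetype cohort (n=300) shared across tests."""
    cfg = default_config(n_participants=300, seed=11)
    tau, fdg, rois, participants, labels = generate_cohort(cfg)
    return {"cfg": cfg, "tau": tau, "fdg": fdg, "rois": rois,
            "participants": participants, "labels": labels}


@pytest.fixture(scope="session")
def default_residuals(default_cohort):
    """Residual set (continuous + discretized) for the shared cohort."""
    rset = compute_residual_matrix(default_cohort["tau"], default_cohort["fdg"],
                                   default_cohort["rois"])
    return discretize_residuals(rset)
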