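import numpy as np
import pytest

import endodx as e


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """Small, well-separated image cohort for end-to-end committee tests.

    6 + 6 patients x 40 frames, strong texture signal (separation 6,
    low noise, lesion visible 90% of positive frames) so a trained
    backend separates classes reliably in seconds.
    """
    root = tmp_path_factory.mktemp("tiny_cohort")
    cfg = e.SyntheticCohortConfig(
        n_pos=6, n_neg=6, frames_per_patient=40, master_seed=7,
        separation=6.0, noise_sd=0.5, ar1_rho=0.5,
        lesion_dwell=10.0, lesion_fraction=0.9, image_size=64)
    records, manifest = e.generate_frame_images(cfg, root)
    return {"config": cfg, "records": records, "manifest": manifest, "root": root}


@pytest.fixture(scope="session")
def tiny_committee(tiny_cohort):
    """A full (k=3, R=2) committee run over the tiny cohort."""
    records = tiny_cohort["records"]
    assignment = e.balanced_partition(records, k=3, seed=7)
    plan = e.TrainingPlan(
        k_folds=3, r_repeats=2, master_seed=7,
        prep=e.FramePrepConfig(target_size=64, pool_size=400,
                               epoch_size=200, n_epochs=2))
    store = e.run_committee(plan, records, assignment, tiny_cohort["root"])
    return {"plan": plan, "assignment": assignment, "store": store,
            "labels": {r.patient_id: r.label for r in records}}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
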