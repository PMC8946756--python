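import numpy as np
import pytest

from lowernet.networks import NETWORK_NAMES, default_synthetic_model
from lowernet.preproc import preprocess_run
from lowernet.synthcohort import BoldRun, CohortSpec, generate_subject, synthetic_masks


@pytest.fixture(scope="session")
def model():
    return default_synthetic_model()


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec()


@pytest.fixture(scope="session")
def node_templates(model, default_spec):
    """Node-ROI union masks per network (the ground-truth templates)."""
    shape = default_spec.grid_shape
    return {net: model.network_mask(net, shape) for net in NETWORK_NAMES}


@pytest.fixture(scope="session")
def mcs_subject(model, default_spec):
    """One preprocessed MCS subject (coupling 0.5), shared across tests."""
    rec, run, struct = generate_subject(
        default_spec, model, "sub-mcs", "MCS", "traumatic", np.random.SeedSequence(1234)
    )
    pre, report = preprocess_run(run)
    return {"record": rec, "raw": run, "pre": pre, "structural": struct, "report": report}


def make_toy_run(
    shape=(6, 6, 6),
    t=60,
    tr=2.8,
    rng_seed=0,
    data=None,
):
    """A minimal BoldRun on a small grid with simple tissue masks."""
    rng = np.random.default_rng(rng_seed)
    if data is None:
        data = rng.standard_normal((*shape, t)).astype(np.float32)
    brain = np.ones(shape, dtype=bool)
    wm = np.zeros(shape, dtype=bool)
    wm[0, 0, :] = True
    csf = np.zeros(shape, dtype=bool)
    csf[0, 1, :] = True
    gm = brain & ~wm & ~csf
    return BoldRun(
        data=data,
        tr_seconds=tr,
        brain_mask=brain,
        gm_mask=gm,
        wm_mask=wm,
        csf_mask=csf,
        motion_params=np.zeros((t, 6)),
    )
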