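import numpy as np
import pytest

import fluoroscreen as fs

#: Archetype mix used by end-to-end fixtures: every behavior class present.
RICH_MIX = {
    "pan_binder": 0.125,
    "wt_selective": 0.125,
    "p301s_selective": 0.125,
    "monomer_binder": 0.125,
    "bright_artifact": 0.125,
    "inert": 0.375,
}

SMALL_CONDITIONS = [("WT", 7), ("P301S", 7), ("WT", 10), ("P301S", 10)]


@pytest.fixture(scope="session")
def noise_free_screen() -> fs.ScreenDataset:
    """24 dyes x 4 fibril conditions, all archetypes planted, zero noise."""
    return fs.gen_screen(
        n_dyes=24, conditions=SMALL_CONDITIONS, archetype_mix=RICH_MIX,
        noise_sd=0.0, seed=11,
    )


@pytest.fixture()
def flat_control() -> fs.MeltCurve:
    ramp = fs.default_ramp()
    return fs.MeltCurve(ramp, np.zeros_like(ramp), fs.DEFAULT_PADSF_CHANNELS[0])


def make_curve(rfu, channel=None) -> fs.MeltCurve:
    ramp = fs.default_ramp()
    channel = channel or fs.DEFAULT_PADSF_CHANNELS[0]
    rfu = np.broadcast_to(np.asarray(rfu, dtype=float), ramp.shape).copy()
    return fs.MeltCurve(ramp, rfu, channel)
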