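"""Shared fixtures: canonical parameter sets and synthetic-data factories."""

import numpy as np
import pytest

from lagoon import analysis as an
from lagoon import kinetics as kin
from lagoon import traces as tr
from lagoon import uncaging as unc


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def scavenger():
    """10 U/ml hexokinase, linearized (k = 1.389 s⁻¹)."""
    return unc.ScavengerParams(activity=10.0)


@pytest.fixture(scope="session")
def photolysis(scavenger):
    """Photolysis anchored to a 40-µM effective concentration at 5 W cm⁻²
    with 2 mM caged NTP and the 10 U/ml scavenger."""
    return unc.calibrate_photolysis(40.0, 5.0, scavenger, 2000.0)


@pytest.fixture(scope="session")
def diffusion():
    return unc.DiffusionParams(D=300.0)


@pytest.fixture()
def noiseless_optics():
    """Forward optical model with no noise, crosstalk or bleaching."""
    return tr.OpticalModel(
        bleedthrough=0.0, direct_excitation=0.0, gamma=1.0,
        sigma=(0.0, 0.0, 0.0),
        donor_bleach_half_life=1e9, acceptor_bleach_half_life=1e9,
        frame_rate=10.0, aa_interleave=1,
    )


@pytest.fixture()
def realistic_optics():
    return tr.OpticalModel(
        bleedthrough=0.10, direct_excitation=0.05, gamma=1.2,
        sigma=(0.03, 0.03, 0.03),
        donor_bleach_half_life=180.0, acceptor_bleach_half_life=90.0,
        frame_rate=10.0, aa_interleave=10,
    )


def staircase_paths(n_traces, rng, step=0.1, dwell_s=2.5, n_steps=4,
                    initial=0.3, frame_interval=0.1, jitter_s=0.5):
    """Ground-truth staircase StatePaths with annotated step times."""
    paths = []
    for i in range(n_traces):
        t = np.cumsum(dwell_s + rng.uniform(-jitter_s, jitter_s, n_steps))
        values = initial + step * np.arange(1, n_steps + 1)
        import pandas as pd

        events = pd.DataFrame(
            {"time": t, "state": values, "n_turnovers": 1,
             "pulse_idx": np.arange(n_steps), "binding_time": t - 0.3}
        )
        paths.append(
            kin.StatePath(kind="steps", initial=initial, times=t, values=values,
                          events=events,
                          meta={"trace_id": i, "duration": t[-1] + dwell_s,
                                "frame_interval": frame_interval})
        )
    return paths


@pytest.fixture()
def make_staircase_paths():
    return staircase_paths


def correction_for(om: tr.OpticalModel) -> an.CorrectionParams:
    """Correction parameters matching a generator's optical model."""
    return an.CorrectionParams(alpha=om.direct_excitation, beta=om.bleedthrough,
                               gamma=1.0 / om.gamma)


@pytest.fixture()
def matching_correction():
    return correction_for
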