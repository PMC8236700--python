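"""Shared fixtures: step protocol traces and fitted digital phantoms.

The phantom + volume-fit combinations are expensive enough to share
session-wide; every fixture is fully deterministic (fixed seeds).
"""

from __future__ import annotations

import dataclasses
import warnings
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import settings

from cvrkit.phantom import PhantomSpec, generate_bold, generate_geometry
from cvrkit.response_models import fit_volume
from cvrkit.stimulus import ProtocolSpec, build_step_protocol, resample_to_frames

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


def fit_phantom(spec: PhantomSpec) -> SimpleNamespace:
    geometry = generate_geometry(spec)
    data = generate_bold(geometry, spec)
    with warnings.catch_warnings():
        # noiseless voxels fit perfectly (SSE == 0 -> BIC -inf sentinel)
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_volume(data.series, data.petco2_frames)
    return SimpleNamespace(spec=spec, geometry=geometry, data=data, fit=fit)


@pytest.fixture(scope="session")
def frames_trace():
    """Default step protocol resampled to the 150-frame, TR 2.4 s grid."""
    protocol = build_step_protocol(ProtocolSpec(), 0.5)
    return resample_to_frames(protocol, 2.4, 150)


@pytest.fixture(scope="session")
def default_phantom():
    """Default noisy phantom (distinct per-tissue dynamics) plus its fit."""
    return fit_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def zero_delay_phantom():
    """Noiseless phantom with zero net delay: the sequential tau/TD search
    is exactly self-consistent here, so recovery is exact at pure voxels."""
    spec = dataclasses.replace(PhantomSpec(), noise_sd=0.0, td=(2.0, 2.0, 2.0))
    return fit_phantom(spec)


@pytest.fixture(scope="session")
def equal_dynamics_phantom():
    """Noiseless phantom where all tissues share tau and TD, so every
    metric map is an exactly linear mixture of the class values."""
    spec = dataclasses.replace(
        PhantomSpec(), noise_sd=0.0, tau=(24.0, 24.0, 24.0), td=(2.0, 2.0, 2.0)
    )
    return fit_phantom(spec)
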