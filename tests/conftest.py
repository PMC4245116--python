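"""Shared fixtures: synthetic datasets reused across the suite.

Simulation studies run at 50 dpi — the physics is dpi-invariant (verified
by the scale-invariance tests) and the lower resolution keeps the suite
fast; single-organ oracle tests use the native 300 dpi.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ricedeficit import features, synth

SIM_DPI = 50


def noise_free(profile: synth.SymptomProfile) -> synth.SymptomProfile:
    """Copy of a profile with all stochastic components switched off."""
    return dataclasses.replace(
        profile, noise_sd=0.0, geometry_jitter=0.0, color_jitter_sd=0.0
    )


@pytest.fixture(scope="session")
def profiles():
    return synth.default_profiles()


@pytest.fixture(scope="session")
def small_dataset():
    return synth.generate_dataset(6, dpi=SIM_DPI, seed=7)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return features.extract_table(small_dataset.samples)


@pytest.fixture(scope="session")
def multi_seed_tables():
    """Feature tables for 20 independent simulated studies.

    Study conditions: default symptom profiles, 50 plants per class,
    per-channel noise sd 8 (the profile default).  All three focal leaf
    positions are extracted.
    """
    tables = []
    for seed in range(20):
        ds = synth.generate_dataset(50, dpi=SIM_DPI, seed=seed)
        tables.append(features.extract_table(ds.samples))
    return tables


@pytest.fixture(scope="session")
def noise_free_samples():
    """One noise-free plant per class at 50 dpi (deterministic geometry)."""
    profs = {k: noise_free(v) for k, v in synth.default_profiles().items()}
    ds = synth.generate_dataset(1, profiles=profs, dpi=SIM_DPI, seed=0)
    return ds
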