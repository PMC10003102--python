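import numpy as np
import pandas as pd
import pytest

from wpbmorph import synthetic


@pytest.fixture
def sphere_profiles_t0():
    """1e4 monodisperse 300 nm spheres sectioned with zero slab thickness."""
    spec = synthetic.SpherePopulationSpec(
        n_spheres=10_000, diameter_model="fixed", diameter_nm=300.0,
        section_thickness_nm=0.0, axis_jitter_sd=0.0, seed=7,
    )
    return synthetic.generate_section_profiles(spec)


@pytest.fixture
def jittered_profiles():
    """1e4 jittered profiles for exercising the sphericity filter."""
    spec = synthetic.SpherePopulationSpec(
        n_spheres=10_000, diameter_model="fixed", diameter_nm=300.0,
        section_thickness_nm=60.0, axis_jitter_sd=0.12, seed=11,
    )
    profiles, _ = synthetic.generate_section_profiles(spec)
    return profiles


@pytest.fixture
def two_group_ph_measurements():
    """Two pH populations (5.4 vs 5.7, sd 0.1, n=100 each) as one table."""
    frames = []
    for group, mean, seed in (("ctrl", 5.4, 21), ("dcm", 5.7, 22)):
        spec = synthetic.PhSceneSpec(
            n_organelles=100, true_ph_mean=mean, true_ph_sd=0.1,
            noise_sd=0.005, seed=seed,
        )
        meas, _, _ = synthetic.generate_ph_measurements(spec)
        meas = meas.copy()
        meas["group"] = group
        meas["organelle_id"] = group + "_" + meas["organelle_id"]
        frames.append(meas)
    return pd.concat(frames, ignore_index=True)
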