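"""Shared synthetic fixtures.

Everything is generated programmatically with fixed seeds; module-scoped
fixtures keep the heavier cohorts to one construction per session.
"""

import numpy as np
import pandas as pd
import pytest

from methrisk.deconv import build_reference_panel
from methrisk.simulate import (
    EffectSpec,
    generate_cohort,
    generate_profiles,
    generate_reference_samples,
    feasible_effect_cpgs,
)


@pytest.fixture(scope="session")
def profiles_small():
    profiles, annotation = generate_profiles(500, seed=11, markers_per_type=25)
    return profiles, annotation


@pytest.fixture(scope="session")
def reference_small(profiles_small):
    profiles, _ = profiles_small
    return generate_reference_samples(profiles, n_per_type=20, seed=12)


@pytest.fixture(scope="session")
def panel_small(reference_small):
    ref_beta, ref_labels = reference_small
    return build_reference_panel(ref_beta, ref_labels, p_adj_max=0.01, delta_min=0.5)


@pytest.fixture(scope="session")
def cohort_small(profiles_small):
    """Case/control cohort with a planted epithelial shift of 0.15 at 60 CpGs."""
    profiles, _ = profiles_small
    markers = set(profiles.loc[profiles["is_marker"], "cpg_id"])
    feasible = [c for c in feasible_effect_cpgs(profiles, 0.15) if c not in markers]
    rng = np.random.default_rng(13)
    informative = tuple(sorted(rng.choice(feasible, size=60, replace=False)))
    effect = EffectSpec(informative, 0.15, "epithelial")
    beta, sheet, detection_p, truth = generate_cohort(
        profiles, n_cases=60, n_controls=140, effect=effect, noise_sd=0.02,
        detection_fail_rate=0.0, seed=14, keep_component_draws=True,
    )
    return beta, sheet, detection_p, truth


@pytest.fixture()
def toy_beta():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0.05, 0.95, size=(20, 8))
    return pd.DataFrame(
        vals,
        index=pd.Index([f"cg{i:03d}" for i in range(20)], name="cpg_id"),
        columns=[f"s{i}" for i in range(8)],
    )
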