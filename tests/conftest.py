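from __future__ import annotations

import pytest

from cvoplan.radiometrics import canonicalize
from cvoplan.simulate import CohortParams, GroundTruthHip, render_landmarks, simulate_cohort


def make_hip(A=3.3, B=9.3, theta=21.7, side="right", extent=0.8, hip_id="H001") -> GroundTruthHip:
    return GroundTruthHip(
        hip_id=hip_id,
        side=side,
        A=A,
        B=B,
        theta=theta,
        necrosis_extent=extent,
        arc_radius=22.5,
        head_radius=25.0,
        nsa_pre=135.0,
    )


@pytest.fixture
def reference_hip() -> GroundTruthHip:
    """One hip at the clinical cohort means (A=3.3, B=9.3, theta=21.7)."""
    return make_hip()


@pytest.fixture
def noiseless_pair(reference_hip):
    """Raw pre/post landmark sets for the reference hip, no digitization noise."""
    return render_landmarks(reference_hip, noise_sd=0.0, seed=0)


@pytest.fixture
def canonical_pre(noiseless_pair):
    return canonicalize(noiseless_pair[0])


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Ten-hip cohort rendered without noise, with its ground-truth table."""
    params = CohortParams(n=10, seed=11, noise_sd=0.0)
    sets, truth = simulate_cohort(params)
    return sets, truth
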