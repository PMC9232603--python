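import pandas as pd
import pytest

from heelraise import (
    SynthesisParams,
    generate_cohort,
    generate_session,
    phase_features,
    segment_session,
)


def noiseless_params(**overrides) -> SynthesisParams:
    """Deterministic, noise-free synthesis parameters."""
    base = dict(
        seed=2,
        duration_jitter_cv=0.0,
        noise_sd=0.0,
        force_noise=0.0,
        angle_noise_deg=0.0,
        motion_burst_g=0.0,
    )
    base.update(overrides)
    return SynthesisParams(**base)


@pytest.fixture(scope="session")
def noiseless_session():
    return generate_session(noiseless_params())


@pytest.fixture(scope="session")
def default_session():
    return generate_session(SynthesisParams(seed=1))


def cohort_feature_table(
    seed: int = 0,
    variants=("DL-EV", "DL-IV", "SL-EV", "SL-IV"),
    include_emg: bool = False,
) -> pd.DataFrame:
    """Segment a 5-subject synthetic cohort and stack its phase features."""
    frames = []
    base = SynthesisParams(include_emg=include_emg, include_grid_cop=False)
    for session, _ in generate_cohort(5, seed=seed, variants=variants, base_params=base):
        feats = phase_features(session, segment_session(session))
        feats["subject"] = session.metadata["subject"]
        feats["variant"] = session.metadata["variant"]
        frames.append(feats)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def cohort_features():
    return cohort_feature_table(seed=0)
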