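"""Shared fixtures: a small trained + calibrated model bundle.

Training at desk scale (a handful of short synthetic recordings) is enough
for the functional properties the unit tests check; the acceptance tests
train their own larger model.
"""

import pytest
from hypothesis import settings

from neoeeg.model import EncoderConfig, NeonatalModel, train

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from neoeeg.pipeline import (
    ModelBundle,
    calibrate,
    prepare_training_example,
    task_inlier_features,
)
from neoeeg.synthetic_data import GenerationConfig, generate_recording

TRAIN_PMAS = (28, 31, 34, 37, 40, 43, 29, 33, 38, 42)


@pytest.fixture(scope="session")
def small_bundle():
    examples = []
    for i, pma in enumerate(TRAIN_PMAS):
        # two longer recordings so wake bouts (exponential inter-arrival,
        # median 90 min) are represented in the sleep labels
        cfg = GenerationConfig(
            pma_weeks=pma,
            duration_min=100 if i < 2 else 24,
            seed=100 + i,
            artifact_rate=0.2,
            novelty_rate=0.02,
        )
        rec, truth = generate_recording(cfg)
        examples.append(prepare_training_example(rec, truth))
    model = train(NeonatalModel(EncoderConfig()), examples, seed=0)

    # calibration set: independent recordings drawn from the same
    # conditions as deployment data (routine artifact content included),
    # so the 1st-percentile attention threshold reflects real maxima
    cal_recs = []
    for i, pma in enumerate((28, 31, 34, 37, 40, 44)):
        cfg = GenerationConfig(
            pma_weeks=pma, duration_min=30, seed=200 + i,
            artifact_rate=0.2, novelty_rate=0.02,
        )
        rec, _ = generate_recording(cfg)
        cal_recs.append(rec)
    return calibrate(
        ModelBundle(model=model),
        cal_recs,
        seed=7,
        task_features=task_inlier_features(examples),
    )


@pytest.fixture(scope="session")
def heldout_recording():
    """One held-out recording with injections, plus its ground truth."""
    cfg = GenerationConfig(
        pma_weeks=30, duration_min=40, seed=999, artifact_rate=0.25, novelty_rate=0.03
    )
    return generate_recording(cfg), cfg


@pytest.fixture(scope="session")
def clean_recording():
    cfg = GenerationConfig(
        pma_weeks=36, duration_min=40, seed=555, artifact_rate=0.0, novelty_rate=0.0
    )
    return generate_recording(cfg), cfg
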