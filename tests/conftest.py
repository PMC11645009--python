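"""Shared fixtures: label map, synthetic corpora, and trained-model runs.

The expensive fixtures are session-scoped so the loss-comparison and
end-to-end checks share one set of trained networks.
"""

from __future__ import annotations

import numpy as np
import pytest

from sefast.detection import DetectorSpec
from sefast.evaluation import train_and_evaluate
from sefast.formats import LabelMap
from sefast.network import NetConfig
from sefast.synthetic import RenderConfig, generate_corpus


@pytest.fixture(scope="session")
def labels() -> LabelMap:
    return LabelMap.default()


@pytest.fixture(scope="session")
def small_corpus():
    """8 stratified videos × 4 s at desk-scale resolution (fast to build)."""
    return generate_corpus(n_videos=8, duration_s=4, seed=42)


@pytest.fixture(scope="session")
def study_corpus():
    """The scaled-down study corpus: 32 stratified videos, 256×144 @ 10 fps.

    Eight seconds per video keeps the clip count (256) CPU-tractable while
    preserving the reference class imbalance exactly.
    """
    return generate_corpus(
        n_videos=32, duration_s=8, cfg=RenderConfig(width=256, height=144, fps=10),
        seed=123, stratified=True,
    )


@pytest.fixture(scope="session")
def comparison_runs(study_corpus):
    """Trained tiny networks for cw_f vs bce_f (r=2), three seeds each.

    cw_f runs additionally carry an end-to-end evaluation through the oracle
    detector (mild jitter, 5% dropped boxes, occasional false positives).
    """
    cfg = NetConfig.tiny()
    runs: dict[str, list] = {"bce_f": [], "cw_f": []}
    for seed in (0, 1, 2):
        for loss_kind in ("bce_f", "cw_f"):
            detector = (
                DetectorSpec(jitter_sd=0.01, drop_rate=0.05,
                             false_positive_rate=0.02, seed=1000 + seed)
                if loss_kind == "cw_f" else None
            )
            runs[loss_kind].append(
                train_and_evaluate(
                    study_corpus, cfg, loss_kind=loss_kind, r=2, seed=seed,
                    epochs=5, detector=detector,
                )
            )
    return runs
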