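import numpy as np
import pytest

import taphunter as th


@pytest.fixture(scope="session")
def strong_dataset():
    """276/94 synthetic set with the default TAP motif at effect size 2."""
    return th.generate(th.default_tap_profile(2.0), 276, 94, seed=11).peptides


@pytest.fixture(scope="session")
def null_dataset():
    """276/94 synthetic set with no class signal (effect size 0)."""
    return th.generate(th.default_tap_profile(0.0), 276, 94, seed=11).peptides


@pytest.fixture(scope="session")
def anchor_config():
    """The reference encoding: N-terminal trio plus the C-terminal residue."""
    return th.EncodingConfig(positions=(1, 2, 3, 9))


@pytest.fixture(scope="session")
def trained_strong_model(strong_dataset, anchor_config):
    X, y = th.encode_set(strong_dataset, anchor_config)
    return th.train(X, y, config_id=anchor_config.config_id), X, y


def brute_force_decision(model: "th.TrainedModel", x: np.ndarray) -> float:
    """Independent plain-Python re-summation of the SVM decision function."""
    import math

    spec = model.kernel
    total = model.bias
    for coef, sv in zip(model.dual_coefs, model.support_vectors):
        if spec.kind == "linear":
            k = float(np.dot(sv, x))
        elif spec.kind == "polynomial":
            k = (spec.gamma * float(np.dot(sv, x)) + spec.coef0) ** spec.degree
        else:
            d2 = sum((a - b) ** 2 for a, b in zip(sv, x))
            k = math.exp(-spec.gamma * d2)
        total += coef * k
    return total


def brute_force_auc(scores, labels) -> float:
    """All-pairs Mann-Whitney AUC with ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
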