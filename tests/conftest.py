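import numpy as np
import pytest
from hypothesis import settings

import eegoat as eo
from eegoat.classifiers import ClassifierSpec
from eegoat.cli import RunConfig, build_feature_matrix

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

#: Base seed for the study-condition runs (fixed, arbitrary).
FULL_SEED = 11


@pytest.fixture(scope="session")
def full_feature_matrix():
    """300×11 feature matrix from the full-size benchmark-shaped synthetic
    dataset (5 sets × 100 channels × 4097 points), default sampling design."""
    fm, _ = build_feature_matrix(RunConfig(base_seed=FULL_SEED))
    return fm


@pytest.fixture(scope="session")
def small_feature_matrix():
    """Reduced pipeline output (30 channels × 512 points → 90 rows) for
    fast classifier/evaluation tests."""
    cfg = RunConfig(n_channels=30, n_points=512, base_seed=3)
    fm, _ = build_feature_matrix(cfg)
    return fm


def make_xor(seed: int, n: int = 400, sd: float = 0.25):
    """Four Gaussian clusters at (±1, ±1) with alternating labels."""
    rng = np.random.default_rng(seed)
    pts, lab = [], []
    for cx, cy, label in [(1, 1, 1), (-1, -1, 1), (1, -1, 0), (-1, 1, 0)]:
        pts.append(rng.normal((cx, cy), sd, (n // 4, 2)))
        lab += [label] * (n // 4)
    return np.vstack(pts), np.array(lab)


@pytest.fixture(scope="session")
def xor_accuracies():
    """Held-out accuracy of the full LMT vs the depth-0 boosted logistic
    model on the XOR layout, paired over 10 seeds."""
    lmt_accs, linear_accs = [], []
    for s in range(10):
        X_tr, y_tr = make_xor(s)
        X_te, y_te = make_xor(1000 + s)
        tree = eo.fit_lmt(X_tr, y_tr, seed=s)
        linear = eo.fit_simple_logistic(X_tr, y_tr, seed=s)
        lmt_accs.append(float(np.mean(tree.predict(X_te) == y_te)))
        linear_accs.append(float(np.mean(linear.predict(X_te) == y_te)))
    return lmt_accs, linear_accs


@pytest.fixture(scope="session")
def lmt_repeat_report(full_feature_matrix):
    """LMT, stratified 10-fold CV repeated 20 times on the full synthetic
    feature matrix — the whole-pipeline evaluation under study conditions."""
    return eo.repeat_experiment(
        full_feature_matrix, ClassifierSpec("LMT"), k=10, n_repeats=20, base_seed=7
    )


# Confusion matrices implied by the published per-class tables on balanced
# 100-per-class data: rows = actual, cols = predicted, class order
# healthy / seizure-free / seizure.
TABLE2_CONFUSION = np.array([[95, 5, 0], [6, 92, 2], [0, 1, 99]])
TABLE4_CONFUSION = np.array([[4, 0, 96], [0, 4, 96], [0, 0, 100]])
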