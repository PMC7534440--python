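"""Shared fixtures: one default synthetic study reused across the suite.

The default study conditions are a 500-feature x 120-sample compendium with
5 planted modules (Laplace member weights, super-Gaussian activations,
noise sd 0.1), 5 module-paired annotations plus 45 decoys, and a threshold
model trained on 200 simulated components.  Expensive artifacts are built
once per session.
"""

import hypothesis
import numpy as np
import pandas as pd
import pytest

import icamod as im

hypothesis.settings.register_profile("suite", deadline=None, derandomize=True)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def spec():
    return im.SyntheticSpec()


@pytest.fixture(scope="session")
def compendium(spec):
    return im.generate_compendium(spec)


@pytest.fixture(scope="session")
def annotations(spec, compendium):
    _, modules, _ = compendium
    return im.generate_annotations(modules, spec, n_decoys=45)


@pytest.fixture(scope="session")
def threshold_model():
    training = im.generate_component_training(n_components=200, seed=7)
    return im.fit_threshold_model(training, seed=7)


@pytest.fixture(scope="session")
def decomposition(compendium):
    X, _, _ = compendium
    return im.orient_components(im.decompose(X, 5, seed=1))


@pytest.fixture(scope="session")
def partitioned(decomposition, threshold_model):
    return im.model_partition(decomposition, threshold_model)


@pytest.fixture(scope="session")
def weighted_matrix(decomposition, partitioned, annotations):
    E = im.build_E(partitioned, annotations)
    H = im.build_H(decomposition.S)
    return im.build_R(H, E, normalize=True, feature_ids=decomposition.feature_ids)


def best_match_f1(true_modules, P):
    """Hungarian best-match F1 between planted member sets and recovered
    per-component sets (union of the 'a' and 'b' hemi-modules)."""
    from scipy.optimize import linear_sum_assignment

    sets = P.hemi_sets()
    recovered = [
        sets[f"{c}a"] | sets[f"{c}b"] for c in P.component_ids
    ]

    def f1(a, b):
        inter = len(a & b)
        return 0.0 if inter == 0 else 2 * inter / (len(a) + len(b))

    F = np.array([[f1(m, r) for r in recovered] for m in true_modules])
    ri, ci = linear_sum_assignment(-F)
    return F[ri, ci]


@pytest.fixture(scope="session")
def contrast_series(compendium):
    """A module-1-loading contrast aligned to the compendium features."""
    X, _, S_true = compendium
    w = np.zeros(S_true.shape[1])
    w[0] = 1.0
    x = im.generate_contrast(S_true, w, noise_sd=0.1, seed=42)
    return pd.Series(x, index=X.feature_ids)
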