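"""Shared helper for generating random labelled training sets in tests."""

import numpy as np

from isofinger.fingerprint_lda import EndmemberTrainingSet


def random_training(rng, n_classes=3, p=6, n_per_class=8, sep=4.0):
    X, labels = [], []
    for c in range(n_classes):
        mu = rng.normal(0, sep, size=p)
        A = rng.normal(0, 1, size=(p, p))
        cov = A @ A.T / p + np.eye(p)
        X.append(rng.multivariate_normal(mu, cov, size=n_per_class))
        labels += [f"c{c}"] * n_per_class
    X = np.vstack(X)
    ids = tuple(f"s{i}" for i in range(X.shape[0]))
    analytes = tuple(f"A{i}" for i in range(p))
    return EndmemberTrainingSet(X, np.asarray(labels), analytes, ids)
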