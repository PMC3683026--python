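"""Shared fixtures: all test data is generated programmatically and seeded."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import eegdetect as ed
from eegdetect.features import extract_feature_matrix
from eegdetect.preprocess import Epoch, make_epoch_pairs


@pytest.fixture(scope="session")
def montage():
    return ed.default_montage()


@pytest.fixture(scope="session")
def sim_channels():
    return ed.SimConfig().channels


def make_epoch(data: np.ndarray, labels, montage_kind: str, fs: float = 200.0,
               index: int = 0) -> Epoch:
    return Epoch(np.asarray(data, dtype=float), tuple(labels), fs, montage_kind, index)


@dataclass
class TrainBundle:
    """A preprocessed, feature-extracted labeled training set plus a model."""

    recording: object
    truth: object
    uni: list
    bip: list
    X: np.ndarray
    names: tuple
    y: np.ndarray
    model: object


@pytest.fixture(scope="session")
def train_bundle() -> TrainBundle:
    """50 normal / 25 spike / 15 seizure epochs, extracted and fitted once."""
    rec, gt = ed.simulate_dataset(50, 25, 15, seed=11)
    uni, bip = make_epoch_pairs(rec, truth_labels=gt.labels)
    X, names, _, y = extract_feature_matrix(uni, bip)
    model = ed.train_svm(X, y, feature_names=names)
    return TrainBundle(rec, gt, uni, bip, X, names, y, model)


@pytest.fixture(scope="session")
def informative_benchmark():
    """300 epochs, 100 features of which only #3 and #7 carry the class.

    The two informative features determine the label jointly (opposite
    shifts), all other features are pure noise.
    """
    rng = np.random.default_rng(1234)
    n, p = 300, 100
    y = np.array(["a"] * 150 + ["b"] * 150, dtype=object)
    rng.shuffle(y)
    X = rng.standard_normal((n, p))
    sign = np.where(y == "a", 1.0, -1.0)
    X[:, 3] += 1.5 * sign
    X[:, 7] -= 1.5 * sign
    return X, y
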