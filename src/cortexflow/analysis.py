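"""Representational-similarity analysis and linear probes.

Response similarity matrices (RSMs) compare population responses across a
stimulus set: Pearson correlation (diagonal 1, entries in [-1, 1]) or
Euclidean distance (diagonal 0, entries >= 0), with rows grouped by class
and then configuration index so class structure appears as diagonal blocks.
Cross-speed RSMs correlate the responses to matched dot configurations
moving at two speeds.  Linear probes quantify what a frozen layer encodes
by training the multi-class perceptron on its responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .classifiers import perceptron_accuracy, perceptron_train


class DegenerateProbeError(ValueError):
    """Probe asked to separate fewer than two classes."""


@dataclass
class RSM:
    """A square similarity/distance matrix over layer responses."""

    matrix: np.ndarray
    row_labels: list  # (class, config-index) per row
    measure: str  # "pearson" | "euclidean"
    layer: str = ""
    undefined_rows: np.ndarray | None = None  # zero-variance responses (pearson)


def _sort_rows(responses, labels, configs):
    responses = np.asarray(responses, dtype=float)
    labels = np.asarray(labels)
    if configs is None:
        configs = np.zeros(len(labels), dtype=int)
    configs = np.asarray(configs)
    order = np.lexsort((configs, labels))
    return responses[order], [(labels[i], configs[i]) for i in order]


def pearson_rsm(responses, labels, configs=None, layer="") -> RSM:
    """Pairwise Pearson correlations, rows grouped by class then config.

    Zero-variance responses have undefined correlation; their rows/columns
    are NaN and flagged in ``undefined_rows`` rather than coerced to 0.
    """
    R, row_labels = _sort_rows(responses, labels, configs)
    if len(R) < 2:
        raise ValueError("need at least two responses")
    sd = R.std(axis=1)
    bad = sd == 0
    M = np.full((len(R), len(R)), np.nan)
    good = ~bad
    if good.sum() >= 2:
        M[np.ix_(good, good)] = np.corrcoef(R[good])
    M[np.diag_indices(len(R))[0][good], np.diag_indices(len(R))[1][good]] = 1.0
    return RSM(M, row_labels, "pearson", layer, undefined_rows=bad)


def euclidean_rsm(responses, labels, configs=None, layer="") -> RSM:
    """Pairwise Euclidean distances, rows grouped by class then config."""
    R, row_labels = _sort_rows(responses, labels, configs)
    return RSM(cdist(R, R), row_labels, "euclidean", layer)


def cross_speed_rsm(responses_speed1, responses_speed2, layer="") -> RSM:
    """Pearson r between config-a speed-1 and config-b speed-2 responses.

    The diagonal holds matched-configuration pairs; a strong diagonal means
    the layer responds alike to both speeds of the same dot pattern.
    """
    R1 = np.asarray(responses_speed1, dtype=float)
    R2 = np.asarray(responses_speed2, dtype=float)
    if R1.shape != R2.shape:
        raise ValueError("speed-1 and speed-2 response sets must match in shape")
    n = len(R1)
    Z1 = R1 - R1.mean(axis=1, keepdims=True)
    Z2 = R2 - R2.mean(axis=1, keepdims=True)
    s1 = np.linalg.norm(Z1, axis=1)
    s2 = np.linalg.norm(Z2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = (Z1 @ Z2.T) / np.outer(s1, s2)
    labels = [("s1xs2", i) for i in range(n)]
    return RSM(M, labels, "pearson", layer)


def probe_classifier(
    layer_responses,
    labels,
    train_mask,
    seed=None,
    epochs: int = 500,
) -> float:
    """Test accuracy of a perceptron probe on a frozen layer's responses."""
    X = np.asarray(layer_responses, dtype=float)
    y = np.asarray(labels)
    train_mask = np.asarray(train_mask, dtype=bool)
    if len(np.unique(y[train_mask])) < 2:
        raise DegenerateProbeError("probe needs at least two classes")
    # standardize features on the training split for conditioning
    mu = X[train_mask].mean(axis=0)
    sd = X[train_mask].std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    model = perceptron_train(Xs[train_mask], y[train_mask], epochs=epochs, seed=seed)
    return perceptron_accuracy(model, Xs[~train_mask], y[~train_mask])


def selectivity_summary(rsm: RSM) -> dict:
    """Within/between-class mean similarity and their difference.

    Uses off-diagonal entries only.  For Euclidean RSMs the difference sign
    is flipped so that positive always means "within-class more similar".
    """
    labels = np.array([l for l, _ in rsm.row_labels])
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    M = rsm.matrix
    n = len(M)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(n, dtype=bool)
    valid = np.isfinite(M)
    within = float(np.nanmean(M[same & off & valid]))
    between = float(np.nanmean(M[~same & valid]))
    diff = within - between
    if rsm.measure == "euclidean":
        diff = -diff
    return {"within": within, "between": between, "difference": diff}
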