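"""Correlation of learned features with labeled semantic attributes.

Each learned feature column is scored against each binary attribute column
with the Pearson correlation over instances,

    r = sum_i (x_i - xbar)(y_i - ybar)
        / sqrt( sum_i (x_i - xbar)^2 * sum_i (y_i - ybar)^2 ),

and for every attribute the feature with the largest |r| is reported with
its signed correlation.  The analysis is model-agnostic: any feature matrix
(DBN readout or otherwise) with one row per instance can be scored.
Constant features have undefined correlation and are excluded from the
best-match search rather than treated as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CorrelationReport",
    "pearson_correlation",
    "correlation_matrix",
    "match_attributes",
    "activity_attribute_correlation",
]


@dataclass
class CorrelationReport:
    """Attribute x feature correlation matrix with per-attribute best match.

    ``best_feature[a]`` is -1 (and ``best_r[a]`` NaN) when every feature's
    correlation with attribute ``a`` is undefined.
    """

    r_matrix: np.ndarray  # (n_attributes, n_features), NaN where undefined
    best_feature: np.ndarray  # int, -1 if unmatched
    best_r: np.ndarray  # signed r at the best feature


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r of two equal-length vectors; NaN if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(xc * yc) / denom)


def _centered_corr(features: np.ndarray, attributes: np.ndarray) -> np.ndarray:
    """Vectorized (attributes x features) Pearson matrix, NaN for constants."""
    f = features - features.mean(axis=0)
    a = attributes - attributes.mean(axis=0)
    f_norm = np.sqrt(np.sum(f**2, axis=0))
    a_norm = np.sqrt(np.sum(a**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a.T @ f) / np.outer(a_norm, f_norm)
    r[:, f_norm == 0.0] = np.nan
    r[a_norm == 0.0, :] = np.nan
    return r


def correlation_matrix(features: np.ndarray, attributes: np.ndarray) -> CorrelationReport:
    """Score every (attribute, feature) pair and locate the best match per
    attribute (largest |r|, ties to the lowest feature index)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    attributes = np.atleast_2d(np.asarray(attributes, dtype=float))
    if features.shape[0] != attributes.shape[0]:
        raise ValueError("features and attributes must have equal row counts")
    if features.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if features.shape[1] == 0 or attributes.shape[1] == 0:
        raise ValueError("need at least one feature and one attribute column")
    r = _centered_corr(features, attributes)
    n_attr = r.shape[0]
    best_feature = np.full(n_attr, -1, dtype=int)
    best_r = np.full(n_attr, np.nan)
    abs_r = np.abs(r)
    for a in range(n_attr):
        row = abs_r[a]
        if np.all(np.isnan(row)):
            continue
        # nanargmax returns the first index on ties
        j = int(np.nanargmax(row))
        best_feature[a] = j
        best_r[a] = r[a, j]
    return CorrelationReport(r, best_feature, best_r)


def match_attributes(report: CorrelationReport) -> list[tuple[int, float]]:
    """Per-attribute (best feature index, signed r); (-1, NaN) if unmatched."""
    return [
        (int(j), float(r)) for j, r in zip(report.best_feature, report.best_r)
    ]


def activity_attribute_correlation(
    activity_onehots: np.ndarray, attributes: np.ndarray
) -> np.ndarray:
    """Pearson correlation of activity indicator columns with attribute
    columns — the activity-by-attribute association matrix of a dataset."""
    activity_onehots = np.atleast_2d(np.asarray(activity_onehots, dtype=float))
    attributes = np.atleast_2d(np.asarray(attributes, dtype=float))
    if activity_onehots.shape[0] != attributes.shape[0]:
        raise ValueError("row counts must match")
    # rows: activity columns; cols: attribute columns
    return _centered_corr(attributes, activity_onehots)
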