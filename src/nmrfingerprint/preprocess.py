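"""Normalization and scaling of bucket tables.

Probabilistic quotient normalization (PQN) removes per-sample dilution: each
sample is first integral-normalized to a common total area, a reference
spectrum is formed as the bucket-wise median, and each sample is divided by
the median of its bucket-wise quotients against that reference.  Autoscaling
(mean-centering and unit-variance scaling per bucket) follows before
multivariate analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import BucketTable

__all__ = ["NormalizationResult", "pqn_normalize", "autoscale", "write_dilution_factors"]

logger = logging.getLogger(__name__)


@dataclass
class NormalizationResult:
    table: BucketTable
    dilution_factors: dict[str, float]
    reference: np.ndarray


def pqn_normalize(
    table: BucketTable,
    reference_mode: str = "median_all",
    subset: Sequence[str] | None = None,
    integral_prestep: bool = True,
) -> NormalizationResult:
    """Probabilistic quotient normalization of a bucket table.

    Steps: (1) integral-normalize every sample to the mean total area;
    (2) reference = bucket-wise median over the reference samples (all
    samples, or ``subset`` when ``reference_mode="median_subset"``);
    (3) quotients ``q_ij = x_ij / r_j`` over buckets with positive reference;
    (4) per-sample quotient median ``d_i``; (5) divide sample i by ``d_i``.

    The recorded dilution factor composes the integral step with ``d_i``, so
    ``normalized = raw / factor`` bucket-wise.  Dilution is identifiable only
    up to one global scale (the common-area constant).
    """
    X = table.values
    n = table.n_samples
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        bad = table.samples[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has non-positive total intensity")
    if n == 1:
        logger.warning("single-sample table: PQN is a no-op, factor set to 1")
        return NormalizationResult(
            table=BucketTable(table.samples, table.buckets, X.copy()),
            dilution_factors={table.samples[0]: 1.0},
            reference=X[0].copy(),
        )

    if integral_prestep:
        # fixed target area (the conventional constant 100): keeps PQN exactly
        # invariant to per-sample multiplicative scaling
        common_area = 100.0
        integral_factor = totals / common_area          # raw = factor * normalized
        Y = X / integral_factor[:, None]
    else:
        integral_factor = np.ones(n)
        Y = X.copy()

    if reference_mode == "median_all":
        ref_rows = Y
    elif reference_mode == "median_subset":
        if not subset:
            raise ValueError("reference_mode='median_subset' requires a sample subset")
        idx = [table.samples.index(s) for s in subset]
        ref_rows = Y[idx]
    else:
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    reference = np.median(ref_rows, axis=0)

    pos = reference > 0
    if not pos.any():
        raise ValueError("reference spectrum has no positive buckets")
    d = np.empty(n)
    for i in range(n):
        if not np.any(Y[i, pos] > 0):
            raise ValueError(
                f"sample {table.samples[i]!r} shares no positive bucket with the reference"
            )
        d[i] = float(np.median(Y[i, pos] / reference[pos]))
    normalized = Y / d[:, None]
    factors = integral_factor * d
    return NormalizationResult(
        table=BucketTable(table.samples, table.buckets, normalized),
        dilution_factors={s: float(f) for s, f in zip(table.samples, factors)},
        reference=reference,
    )


def autoscale(
    table: BucketTable | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean-center and scale each bucket to unit sample standard deviation.

    Zero-variance buckets carry no discriminatory information and are dropped
    with a logged warning.  The sample standard deviation uses the n−1
    denominator.

    Returns
    -------
    (scaled matrix over kept buckets, bucket means, bucket standard
    deviations, boolean mask of kept buckets) — means/sds are over the kept
    buckets only.
    """
    X = table.values if isinstance(table, BucketTable) else np.asarray(table, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("autoscaling requires at least 2 samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    kept = sds > 0
    if not kept.any():
        raise ValueError("all buckets have zero variance")
    if not kept.all():
        logger.warning("dropping %d zero-variance buckets", int((~kept).sum()))
    Z = (X[:, kept] - means[kept]) / sds[kept]
    return Z, means[kept], sds[kept], kept


def write_dilution_factors(result: NormalizationResult, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": list(result.dilution_factors),
            "factor": list(result.dilution_factors.values()),
        }
    ).to_csv(path, sep="\t", index=False)
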