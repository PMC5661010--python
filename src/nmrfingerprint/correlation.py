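"""Inter-bucket correlation analysis and per-group intensity summaries.

Metabolites are typically represented by several buckets (multiplet peaks);
on dilution-corrected data those buckets should rise and fall together across
samples.  High pairwise Pearson correlation among a metabolite's buckets
therefore confirms the identification, while low correlation flags peak
overlap or misassignment.  Group summaries report the quantiles drawn in the
boxplots of key-metabolite intensities: median, 25–75% box, 5–95% whiskers.

Correlations are computed on PQN-normalized (not autoscaled) intensities;
autoscaling is an affine per-bucket transform with positive slope, so Pearson
r is unchanged either way.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import BucketTable

__all__ = [
    "MetaboliteConsistency",
    "GroupSummary",
    "bucket_correlations",
    "metabolite_consistency",
    "group_intensity_summary",
    "write_consistency_report",
    "write_group_summaries",
]


@dataclass
class MetaboliteConsistency:
    metabolite: str
    bucket_ids: list[str]
    n_buckets: int
    min_r: float
    median_r: float
    status: str  # confirmed | low_correlation | single_bucket


@dataclass
class GroupSummary:
    bucket_id: str
    group: str
    median: float
    q25: float
    q75: float
    p5: float
    p95: float
    n: int


def bucket_correlations(table: BucketTable) -> pd.DataFrame:
    """Pearson correlation over samples for every bucket pair.

    Zero-variance buckets have undefined correlations, recorded as NaN.
    """
    if table.n_samples < 3:
        raise ValueError("bucket correlations require at least 3 samples")
    X = table.values
    sds = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    degenerate = sds == 0
    R[degenerate, :] = np.nan
    R[:, degenerate] = np.nan
    np.fill_diagonal(R, np.where(degenerate, np.nan, 1.0))
    return pd.DataFrame(R, index=table.bucket_ids, columns=table.bucket_ids)


def metabolite_consistency(
    corr: pd.DataFrame,
    annotation: Mapping[str, Sequence[str]],
    r_min: float = 0.7,
) -> list[MetaboliteConsistency]:
    """Assess identification confidence per metabolite from bucket correlations.

    ``annotation`` maps metabolite name → bucket IDs.  A metabolite with ≥ 2
    buckets is ``confirmed`` when the minimum pairwise r among its buckets is
    at least ``r_min``, otherwise ``low_correlation``; single-bucket
    metabolites cannot be cross-checked and are labelled ``single_bucket``.
    Output is sorted by min_r ascending so problem cases surface first.
    """
    out: list[MetaboliteConsistency] = []
    for met, bucket_ids in annotation.items():
        bucket_ids = list(bucket_ids)
        if not bucket_ids:
            raise ValueError(f"metabolite {met!r} has no assigned buckets")
        if len(bucket_ids) == 1:
            out.append(
                MetaboliteConsistency(met, bucket_ids, 1, float("nan"), float("nan"),
                                      "single_bucket")
            )
            continue
        sub = corr.loc[bucket_ids, bucket_ids].to_numpy()
        iu = np.triu_indices(len(bucket_ids), k=1)
        pairs = sub[iu]
        min_r = float(np.nanmin(pairs))
        median_r = float(np.nanmedian(pairs))
        status = "confirmed" if min_r >= r_min else "low_correlation"
        out.append(
            MetaboliteConsistency(met, bucket_ids, len(bucket_ids), min_r, median_r, status)
        )
    out.sort(key=lambda c: (np.inf if np.isnan(c.min_r) else c.min_r, c.metabolite))
    return out


def group_intensity_summary(
    table: BucketTable,
    labels: Mapping[str, str],
    bucket_ids: Sequence[str] | None = None,
) -> list[GroupSummary]:
    """Quantile summary of bucket intensities per group.

    Reports median, quartiles (25–75% box) and 5/95% whisker quantiles using
    linear interpolation between order statistics (the type-7 convention, the
    numpy default), so summaries are bit-reproducible.
    """
    if bucket_ids is None:
        bucket_ids = table.bucket_ids
    ids = table.bucket_ids
    idx = {b: ids.index(b) for b in bucket_ids}
    groups = sorted(set(labels[s] for s in table.samples))
    out: list[GroupSummary] = []
    for b in bucket_ids:
        col = table.values[:, idx[b]]
        for grp in groups:
            sel = [i for i, s in enumerate(table.samples) if labels[s] == grp]
            if not sel:
                raise ValueError(f"group {grp!r} has no samples")
            v = col[sel]
            p5, q25, med, q75, p95 = np.percentile(v, [5, 25, 50, 75, 95])
            out.append(
                GroupSummary(b, grp, float(med), float(q25), float(q75),
                             float(p5), float(p95), len(sel))
            )
    return out


def write_consistency_report(
    records: Sequence[MetaboliteConsistency], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "metabolite": [r.metabolite for r in records],
            "n_buckets": [r.n_buckets for r in records],
            "bucket_ids": [";".join(r.bucket_ids) for r in records],
            "min_r": [r.min_r for r in records],
            "median_r": [r.median_r for r in records],
            "status": [r.status for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_group_summaries(records: Sequence[GroupSummary], path: str | Path) -> None:
    pd.DataFrame(
        {
            "bucket_id": [r.bucket_id for r in records],
            "group": [r.group for r in records],
            "median": [r.median for r in records],
            "q25": [r.q25 for r in records],
            "q75": [r.q75 for r in records],
            "p5": [r.p5 for r in records],
            "p95": [r.p95 for r in records],
            "n": [r.n for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
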