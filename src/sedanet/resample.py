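"""Prevalence/abundance filtering and fixed-depth resampling (rarefaction).

Families are retained when present (count > 0) in at least ``min_samples``
samples and carrying at least ``min_total`` reads in total — two
conjunctive conditions.  Rarefaction draws a fixed number of reads per
sample, by default without replacement (multivariate hypergeometric), and
aggregates a configurable number of iterations by their arithmetic mean,
kept as real numbers: the downstream rank statistics are insensitive to
the scale and rounding would discard information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, InputError


def filter_families(cm: CountMatrix, min_samples: int = 3,
                    min_total: int = 10) -> CountMatrix:
    """Keep families present in >= min_samples samples with >= min_total reads."""
    if min_samples > cm.shape[0]:
        raise InputError("min_samples exceeds the number of samples")
    presence = (cm.counts > 0).sum(axis=0)
    totals = cm.counts.sum(axis=0)
    keep = cm.counts.columns[(presence >= min_samples) & (totals >= min_total)]
    return cm.select_families(list(keep))


@dataclass
class ResampledMatrix:
    """Result of repeated fixed-depth resampling of a count table."""

    base: CountMatrix
    depth: int
    n_iter: int
    aggregate: pd.DataFrame          # samples x families, mean over iterations
    iterations: np.ndarray | None = None  # n_iter x samples x families

    @property
    def ages(self) -> pd.Series:
        return self.base.ages


def rarefy(cm: CountMatrix, depth: int, n_iter: int = 500, seed: int = 0,
           replace: bool = False, keep_iterations: bool = False
           ) -> ResampledMatrix:
    """Resample every sample to exactly ``depth`` reads, ``n_iter`` times.

    Without replacement each iteration is a multivariate hypergeometric
    draw (classical rarefaction), so no cell ever exceeds its base count;
    with replacement it is a multinomial draw from the sample's observed
    proportions.  Deterministic under ``seed``.
    """
    if depth <= 0 or n_iter <= 0:
        raise InputError("depth and n_iter must be positive")
    totals = cm.sample_totals()
    if not replace:
        low = totals[totals < depth]
        if len(low):
            raise InputError(
                "sample total below resampling depth "
                f"{depth}: {dict(low)} (drop the sample or use replace=True)")
    rng = np.random.default_rng(seed)
    counts = cm.counts.to_numpy()
    n, f = counts.shape
    agg = np.zeros((n, f), dtype=float)
    iters = np.empty((n_iter, n, f), dtype=np.int64) if keep_iterations else None
    for it in range(n_iter):
        for i in range(n):
            if replace:
                p = counts[i] / counts[i].sum()
                draw = rng.multinomial(depth, p)
            else:
                draw = rng.multivariate_hypergeometric(counts[i], depth)
            agg[i] += draw
            if iters is not None:
                iters[it, i] = draw
    agg /= n_iter
    aggregate = pd.DataFrame(agg, index=cm.counts.index, columns=cm.counts.columns)
    return ResampledMatrix(cm, depth, n_iter, aggregate, iters)


def proportions(table: pd.DataFrame | CountMatrix) -> pd.DataFrame:
    """Row-normalise a samples x families table to fractions summing to 1."""
    df = table.counts if isinstance(table, CountMatrix) else table
    totals = df.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise InputError(f"zero-total samples: {bad}")
    return df.div(totals, axis=0)
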