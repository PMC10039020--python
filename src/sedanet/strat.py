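"""Stratigraphic diagnostics: ratios, autocorrelation screen, CONISS.

CONISS (constrained incremental sum of squares) is agglomerative
clustering in stratigraphic order: only adjacent clusters may merge, and
each merge is the one minimising the increase in total within-cluster
sum of squares (Grimm 1987).  The increase for merging clusters A and B
with centroids c_A, c_B is

    delta(A, B) = |A| |B| / (|A| + |B|) * ||c_A - c_B||^2,

and the cumulative heights therefore sum to the within-group sum of
squares of the undivided dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _sm_acf
from scipy import stats

from .io import CountMatrix, InputError, TaxonAnnotation
from .resample import proportions


def pb_ratio(pelagic: CountMatrix | pd.DataFrame,
             benthic: CountMatrix | pd.DataFrame) -> pd.Series:
    """Per-sample ratio of pelagic to benthic read totals."""
    pel = pelagic.counts if isinstance(pelagic, CountMatrix) else pelagic
    ben = benthic.counts if isinstance(benthic, CountMatrix) else benthic
    if not pel.index.equals(ben.index):
        raise InputError("pelagic and benthic matrices disagree on samples")
    p = pel.sum(axis=1).astype(float)
    b = ben.sum(axis=1).astype(float)
    if (b == 0).any():
        warnings.warn("zero benthic total in some samples; ratio set to NaN")
    out = p / b.replace(0, np.nan)
    out.name = "pelagic_benthic_ratio"
    return out


def group_ratio(cm: CountMatrix | pd.DataFrame, ann: TaxonAnnotation,
                group_a: str | list[str], group_b: str | list[str]
                ) -> pd.Series:
    """Per-sample ratio of reads in functional group(s) A over group(s) B.

    Either side may be a single label or a list of labels (e.g. the
    phototrophic-bacteria : phototrophic-protists ratio pools several
    protist groups on the denominator).
    """
    df = cm.counts if isinstance(cm, CountMatrix) else cm
    ga = [group_a] if isinstance(group_a, str) else list(group_a)
    gb = [group_b] if isinstance(group_b, str) else list(group_b)
    fa = [f for f in df.columns if f in ann.table.index
          and ann.group_of(f) in ga]
    fb = [f for f in df.columns if f in ann.table.index
          and ann.group_of(f) in gb]
    a = df[fa].sum(axis=1).astype(float)
    b = df[fb].sum(axis=1).astype(float)
    if (b == 0).any():
        warnings.warn(f"zero {gb!r} total in some samples; ratio NaN")
    out = a / b.replace(0, np.nan)
    out.name = f"{'+'.join(ga)}:{'+'.join(gb)}"
    return out


def acf_screen(cm: CountMatrix | pd.DataFrame, max_lag: int = 5,
               level: float = 0.95) -> pd.DataFrame:
    """Flag families whose sample autocorrelation exceeds the white-noise band.

    The band is +/- z * n^(-1/2) (large-sample normal approximation) —
    a screen, not a formal test, at the core's modest sample counts.
    Constant series are flagged undefined.
    """
    df = cm.counts if isinstance(cm, CountMatrix) else cm
    n = len(df)
    if n < 5:
        raise InputError("need at least 5 samples for the ACF screen")
    z = stats.norm.ppf(0.5 + level / 2)
    band = z / np.sqrt(n)
    rows = []
    for fam in df.columns:
        x = df[fam].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"family": fam, "max_abs_acf": np.nan,
                         "flagged": False, "undefined": True})
            continue
        r = _sm_acf(x, nlags=max_lag, fft=False)[1:]
        rows.append({"family": fam, "max_abs_acf": float(np.abs(r).max()),
                     "flagged": bool((np.abs(r) > band).any()),
                     "undefined": False})
    out = pd.DataFrame(rows).set_index("family")
    out.attrs["band"] = float(band)
    return out


@dataclass
class ConissResult:
    """Stratigraphically constrained agglomeration record.

    ``merges`` lists (left cluster id, right cluster id, increment) in
    merge order; original samples are clusters 0..n-1 and merge k creates
    cluster n+k (scipy linkage convention).  ``heights`` is the running
    cumulative within-cluster sum of squares.
    """

    merges: list[tuple[int, int, float]]
    heights: np.ndarray
    sample_ids: list[str]

    @property
    def total_ss(self) -> float:
        return float(self.heights[-1]) if len(self.heights) else 0.0

    def zones(self, k: int) -> np.ndarray:
        """Zone label per sample after undoing the last k-1 merges."""
        n = len(self.sample_ids)
        if not 1 <= k <= n:
            raise InputError("k must be in [1, n_samples]")
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for step, (a, b, _) in enumerate(self.merges[: n - k]):
            members[n + step] = members.pop(a) + members.pop(b)
        labels = np.empty(n, dtype=int)
        # zones numbered in stratigraphic order
        for z, cid in enumerate(sorted(members, key=lambda c: min(members[c]))):
            labels[members[cid]] = z
        return labels


def coniss(matrix: pd.DataFrame | CountMatrix,
           transform: str = "proportions") -> ConissResult:
    """Constrained incremental sum-of-squares clustering of a record.

    Samples must be in stratigraphic order (the CountMatrix guarantees
    it).  ``transform='proportions'`` row-normalises first — the standard
    choice for percentage diagrams; 'none' clusters the raw values.
    """
    df = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    ids = list(df.index)
    if transform == "proportions":
        X = proportions(df).to_numpy(dtype=float)
    elif transform == "none":
        X = df.to_numpy(dtype=float)
    else:
        raise InputError(f"unknown transform {transform!r}")
    if not np.isfinite(X).all():
        raise InputError("non-finite values in the clustering matrix")
    n = X.shape[0]
    if n < 2:
        raise InputError("need at least 2 samples")

    # active clusters as (id, size, vector sum), in stratigraphic order
    order = list(range(n))
    size = {i: 1 for i in range(n)}
    vsum = {i: X[i].copy() for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    heights = []
    total = 0.0
    next_id = n

    def delta(a: int, b: int) -> float:
        ca = vsum[a] / size[a]
        cb = vsum[b] / size[b]
        w = size[a] * size[b] / (size[a] + size[b])
        return float(w * np.dot(ca - cb, ca - cb))

    while len(order) > 1:
        incs = [delta(order[k], order[k + 1]) for k in range(len(order) - 1)]
        k = int(np.argmin(incs))  # ties -> youngest pair
        a, b = order[k], order[k + 1]
        total += incs[k]
        merges.append((a, b, incs[k]))
        heights.append(total)
        size[next_id] = size[a] + size[b]
        vsum[next_id] = vsum[a] + vsum[b]
        order[k:k + 2] = [next_id]
        next_id += 1
    return ConissResult(merges, np.asarray(heights), ids)


def display_filter(matrix: pd.DataFrame | CountMatrix,
                   min_samples: int = 3, min_prop: float = 0.015
                   ) -> list[str]:
    """Families shown in stratigraphic diagrams: present in >= min_samples
    samples and reaching >= min_prop relative abundance in at least one
    sample (after resampling)."""
    df = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    prop = proportions(df)
    presence = (df > 0).sum(axis=0)
    keep = (presence >= min_samples) & (prop.max(axis=0) >= min_prop)
    return list(df.columns[keep])
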