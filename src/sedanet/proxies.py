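"""Proxy alignment and per-family environmental association tagging.

Proxy records (IP25, SST) live on their own age grids and are linearly
interpolated to the sample ages; ages outside the proxy range come back
as missing.  A missing run at the young end — the common case when a
biomarker record stops before the core top — is filled with the mean of
the three youngest interpolated values.  Families are then tested one by
one against the aligned proxy with Spearman rank correlation,
Benjamini-Hochberg adjusted within the proxy's test battery, and tagged
(``ice`` for the sea-ice proxy, ``warm`` for SST) when the correlation is
positive beyond ``rho_min`` with adjusted p below ``alpha``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import InputError, ProxySeries
from .spearman import bh_adjust


def interpolate_to_ages(proxy: ProxySeries, ages) -> np.ndarray:
    """Piecewise-linear interpolation of a proxy at the given ages.

    Ages outside the proxy's span are returned as NaN (no extrapolation);
    young-end gaps can subsequently be filled with :func:`tail_fill`.
    """
    ages = np.asarray(ages, dtype=float)
    out = np.interp(ages, proxy.ages, proxy.values)
    out[(ages < proxy.ages[0]) | (ages > proxy.ages[-1])] = np.nan
    return out


def tail_fill(values, n_mean: int = 3) -> np.ndarray:
    """Fill a missing run at the young end of an age-ordered value vector.

    ``values`` is ordered young -> old.  Each leading NaN is replaced by
    the mean of the ``n_mean`` youngest non-missing values.  Gaps anywhere
    else are an error: only the young-end extrapolation gap has a defined
    fill rule.
    """
    vals = np.asarray(values, dtype=float).copy()
    missing = np.isnan(vals)
    if not missing.any():
        return vals
    head = int(np.argmax(~missing)) if (~missing).any() else len(vals)
    if missing[head:].any():
        raise InputError("missing values beyond the young-end run")
    if (~missing).sum() < n_mean:
        raise InputError(f"need at least {n_mean} non-missing values")
    vals[:head] = vals[head:head + n_mean].mean()
    return vals


def correlate_env(abundances: pd.DataFrame, env, proxy_name: str,
                  tag: str, alpha: float = 0.1, rho_min: float = 0.4
                  ) -> pd.DataFrame:
    """Spearman-correlate every family with one aligned proxy series.

    Returns a DataFrame with columns family, proxy, rho, p_raw, p_adj and
    tag (``tag`` where rho > rho_min and p_adj < alpha, else "none").
    Constant family columns are excluded from the BH battery and left
    untagged with NaN statistics.
    """
    env = np.asarray(env, dtype=float)
    if len(env) != len(abundances):
        raise InputError("env vector length != number of samples")
    if np.isnan(env).any():
        raise InputError("env vector contains missing values (tail_fill first)")
    if np.ptp(env) == 0:
        raise InputError("constant env vector: rank correlation undefined")
    rows = []
    for fam in abundances.columns:
        x = abundances[fam].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((fam, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(x, env)
        rows.append((fam, rho, p))
    out = pd.DataFrame(rows, columns=["family", "rho", "p_raw"])
    out.insert(1, "proxy", proxy_name)
    tested = out["p_raw"].notna()
    p_adj = np.full(len(out), np.nan)
    p_adj[tested.to_numpy()] = bh_adjust(out.loc[tested, "p_raw"].to_numpy())
    out["p_adj"] = p_adj
    hit = tested & (out["rho"] > rho_min) & (out["p_adj"] < alpha)
    out["tag"] = np.where(hit, tag, "none")
    return out
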