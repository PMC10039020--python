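"""Synthetic sediment-core communities with known ground truth.

The generator emulates the structure the downstream statistics assume: a
compositional multinomial count table of ~150-200 families over ~25
time-ordered samples, driven by two anticorrelated environmental
trajectories (a sea-ice-like driver and an SST-like driver), with latent
module factors producing block-positive correlation, structural zero
inflation, and uneven sequencing depth.  Every stochastic choice is keyed
to a single integer seed so fixtures are reproducible byte for byte.

Model for family f at sample t (log scale):

    log a_ft = intercept_f + beta_f . driver(t) + module factor_m(f),t + eps_ft

Per-sample proportions are the softmax of log-abundances (with structural
zeros injected before normalisation), and counts are a single multinomial
draw per sample at a depth drawn uniformly from ``depth_range`` — so each
sample total equals its drawn depth exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (CountMatrix, InputError, ProxySeries, TaxonAnnotation,
                 write_annotation, write_count_table, write_proxy_csv)

# round-robin functional groups; habitat/trophic implied by the group
_GROUPS = [
    ("centric diatoms", "pelagic", "phototrophic"),
    ("pennate diatoms", "pelagic", "phototrophic"),
    ("phototrophic bacteria", "pelagic", "phototrophic"),
    ("heterotrophic protists", "pelagic", "heterotrophic"),
    ("copepods", "pelagic", "heterotrophic"),
    ("fish", "pelagic", "heterotrophic"),
    ("bivalves", "benthic", "heterotrophic"),
    ("macroalgae", "benthic", "phototrophic"),
]


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated community."""

    module_of: dict[str, int]           # family -> latent module id (-1 = none)
    env_driver_of: dict[str, str]       # family -> {ice, warm, neutral}
    beta: dict[str, list[float]]        # family -> [loading on ice, on warm]
    true_partial_graph: list[list[str]]  # within-module family pairs
    driver_series: dict[str, list[float]]  # driver values at sample ages
    sample_ages: list[float]
    driver_params: dict                 # parametric form, evaluable anywhere

    def driver(self, name: str, ages: np.ndarray) -> np.ndarray:
        """Evaluate a latent driver at arbitrary ages."""
        p = self.driver_params
        ice = _smooth_eval(p["ice"], ages)
        if name == "ice":
            return ice
        other = _smooth_eval(p["aux"], ages)
        r = p["driver_corr"]
        return r * ice + np.sqrt(1.0 - r * r) * other

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _smooth_params(rng: np.random.Generator, ages: np.ndarray) -> dict:
    """Random smooth trajectory: two sinusoids + linear trend, standardised
    so the values at the sample ages have mean 0 and sd 1."""
    span = float(ages.max() - ages.min())
    p = {
        "amp": rng.uniform(0.5, 1.5, size=2).tolist(),
        "period": (span * rng.uniform([0.4, 0.15], [1.2, 0.35])).tolist(),
        "phase": rng.uniform(0, 2 * np.pi, size=2).tolist(),
        "trend": float(rng.uniform(-1.0, 1.0) / max(span, 1e-9)),
        "loc": 0.0, "scale": 1.0,
    }
    raw = _smooth_eval(p, ages)
    p["loc"] = float(raw.mean())
    p["scale"] = float(raw.std()) or 1.0
    return p


def _smooth_eval(p: dict, ages: np.ndarray) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    out = p["trend"] * ages
    for a, per, ph in zip(p["amp"], p["period"], p["phase"]):
        out = out + a * np.sin(2 * np.pi * ages / per + ph)
    return (out - p["loc"]) / p["scale"]


def generate_community(n_samples: int = 25,
                       n_families: int = 160,
                       depth_range: tuple[int, int] = (10_000, 40_000),
                       zero_inflation: float = 0.05,
                       seed: int = 0,
                       *,
                       frac_ice: float = 0.25,
                       frac_warm: float = 0.65,
                       beta_strength: float = 1.5,
                       module_sd: float = 0.5,
                       noise_sd: float = 0.3,
                       driver_corr: float = -0.7,
                       ) -> tuple[CountMatrix, TaxonAnnotation, SyntheticTruth]:
    """Generate a count table, annotation and ground truth.

    Families split into an ice-driven module (loading ``+beta_strength`` on
    the sea-ice driver), a warm-driven module (loading on the SST driver),
    and neutral families with no environmental response and no module
    factor.  ``driver_corr`` sets the construction correlation between the
    two drivers (anticorrelated by default, as sea-ice cover and SST are).
    """
    if n_samples < 4 or n_families < 4:
        raise InputError("need n_samples >= 4 and n_families >= 4")
    if not (0 <= zero_inflation < 1):
        raise InputError("zero_inflation must be in [0, 1)")
    lo, hi = depth_range
    if lo <= 0 or hi < lo:
        raise InputError("invalid depth_range")
    if not (-1 <= driver_corr <= 1):
        raise InputError("driver_corr must be in [-1, 1]")

    rng = np.random.default_rng(seed)
    ages = np.linspace(1.0, 25.0, n_samples)  # kyr BP, young -> old

    params = {
        "ice": _smooth_params(rng, ages),
        "aux": _smooth_params(rng, ages),
        "driver_corr": driver_corr,
    }
    truth_stub = SyntheticTruth({}, {}, {}, [], {}, ages.tolist(), params)
    ice = truth_stub.driver("ice", ages)
    warm = truth_stub.driver("warm", ages)

    families = [f"fam{i:03d}" for i in range(n_families)]
    n_ice = int(round(frac_ice * n_families))
    n_warm = int(round(frac_warm * n_families))
    driver_of, module_of, beta = {}, {}, {}
    for i, fam in enumerate(families):
        if i < n_ice:
            driver_of[fam], module_of[fam] = "ice", 0
            beta[fam] = [beta_strength, 0.0]
        elif i < n_ice + n_warm:
            driver_of[fam], module_of[fam] = "warm", 1
            beta[fam] = [0.0, beta_strength]
        else:
            driver_of[fam], module_of[fam] = "neutral", -1
            beta[fam] = [0.0, 0.0]

    intercepts = rng.normal(0.0, 1.0, size=n_families)
    b = np.array([beta[f] for f in families])          # F x 2
    drivers = np.column_stack([ice, warm])             # T x 2
    loga = intercepts[None, :] + drivers @ b.T         # T x F
    for m in (0, 1):
        members = np.array([module_of[f] == m for f in families])
        loga[:, members] += rng.normal(0.0, module_sd, size=n_samples)[:, None]
    loga += rng.normal(0.0, noise_sd, size=loga.shape)

    props = np.exp(loga - loga.max(axis=1, keepdims=True))
    if zero_inflation > 0:
        # structural zeros before normalisation: sample totals stay exact
        props[rng.random(loga.shape) < zero_inflation] = 0.0
    props /= props.sum(axis=1, keepdims=True)

    depths = rng.integers(lo, hi + 1, size=n_samples)
    counts = np.vstack([rng.multinomial(d, p) for d, p in zip(depths, props)])

    sample_ids = [f"s{i:02d}" for i in range(n_samples)]
    cm = CountMatrix(pd.DataFrame(counts, index=sample_ids, columns=families),
                     pd.Series(ages, index=sample_ids))

    rows = []
    for i, fam in enumerate(families):
        grp, hab, tro = _GROUPS[i % len(_GROUPS)]
        rows.append({"family": fam, "habitat": hab,
                     "functional_group": grp, "trophic": tro})
    ann = TaxonAnnotation(pd.DataFrame(rows).set_index("family"))

    pairs = [[a, bfam] for m in (0, 1)
             for k, a in enumerate(families) if module_of[a] == m
             for bfam in families[k + 1:] if module_of[bfam] == m]
    truth = SyntheticTruth(module_of, driver_of, beta, pairs,
                           {"ice": ice.tolist(), "warm": warm.tolist()},
                           ages.tolist(), params)
    return cm, ann, truth


def generate_proxies(truth: SyntheticTruth,
                     knot_offset: float = 0.3,
                     noise_sd: float = 0.1,
                     seed: int = 0,
                     truncate_young: bool = False,
                     refine: int = 2,
                     ) -> tuple[ProxySeries, ProxySeries]:
    """Noisy proxy observations of the latent drivers on an offset age grid.

    Knot ages are the sample ages shifted ``knot_offset`` kyr towards the
    old end (extended one sampling step past both ends) and subdivided
    ``refine``-fold — biomarker records are typically finer-resolution
    than the sediment sampling — so interpolation back to the sample ages
    is genuinely exercised.  With ``truncate_young`` the IP25 series
    starts after the youngest three samples, exercising the young-end
    tail-fill rule (assumes 0 <= knot_offset < sample spacing).
    """
    ages = np.asarray(truth.sample_ages)
    rng = np.random.default_rng(seed)
    step = float(np.mean(np.diff(ages))) if len(ages) > 1 else 1.0
    base = np.concatenate([[ages[0] - step], ages, [ages[-1] + step]])
    base = base + knot_offset
    pos = np.linspace(0, len(base) - 1, (len(base) - 1) * max(1, refine) + 1)
    knots = np.interp(pos, np.arange(len(base)), base)
    ip_knots = knots[knots > ages[2] + 1e-12] if truncate_young else knots
    out = []
    for name, kn in (("ice", ip_knots), ("warm", knots)):
        vals = truth.driver(name, kn)
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=len(kn))
        out.append(ProxySeries(kn, vals, name="IP25" if name == "ice" else "SST"))
    return out[0], out[1]


def write_fixture_bundle(outdir: str | Path,
                         seed: int = 0,
                         truncate_young: bool = True,
                         **community_kwargs) -> dict[str, Path]:
    """Write counts.tsv, annotation.tsv, ip25.csv, sst.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, ann, truth = generate_community(seed=seed, **community_kwargs)
    ip25, sst = generate_proxies(truth, seed=seed + 1,
                                 truncate_young=truncate_young)
    paths = {
        "counts": outdir / "counts.tsv",
        "annotation": outdir / "annotation.tsv",
        "ip25": outdir / "ip25.csv",
        "sst": outdir / "sst.csv",
        "truth": outdir / "truth.json",
    }
    write_count_table(cm, paths["counts"])
    write_annotation(ann, paths["annotation"])
    write_proxy_csv(ip25, paths["ip25"])
    write_proxy_csv(sst, paths["sst"])
    truth.to_json(paths["truth"])
    return paths
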