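"""Posterior simulation scenarios: turning the fitted model into predictions.

Four simulation sets interrogate the fitted growth model, always holding the
non-focal covariates at their dataset averages:

1. per-taxon response curves — sweep one taxon's (standardized Hellinger)
   abundance over its observed range;
2. community contrast — predicted BAI under the community/N-mineralization
   profile of the five trees with the highest vs the five with the lowest
   abundance of a target taxon, with a paired-difference significance flag;
3. the same two community profiles swept along the N-mineralization
   gradient, reporting the high-minus-low difference curve;
4. local vs random community — a baseline growth curve along the gradient
   under the average community, against per-location point predictions using
   each location's own community and N mineralization.

Curves report the systematic component exp(D) per coefficient draw (the
log-normal median); a flag adds the log-normal mean correction and/or
observation noise.  All randomness is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FitSummary, ModelData, PosteriorSamples

__all__ = [
    "CoefficientDraws",
    "ScenarioResult",
    "ContrastResult",
    "draw_coefficients",
    "taxon_response_curve",
    "community_contrast",
    "contrast_along_gradient",
    "local_vs_random",
]


@dataclass
class CoefficientDraws:
    """Coefficient draws for scenario prediction (a, b draws when available)."""

    values: np.ndarray  # (n_draws, n_coef)
    names: list[str]
    ab: np.ndarray | None = None  # (n_draws, 2)


@dataclass
class ScenarioResult:
    """A predicted-BAI curve: grid (raw units), mean and 95% interval."""

    varying: str
    grid: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_draws: int
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.varying: self.grid, "bai_mean": self.mean, "bai_lo": self.lo, "bai_hi": self.hi}
        )


@dataclass
class ContrastResult:
    """High- vs low-abundance community contrast for one target taxon."""

    taxon: str
    high: tuple[float, float, float]  # mean, lo, hi
    low: tuple[float, float, float]
    diff: tuple[float, float, float]
    significant: bool
    trees_high: list[str]
    trees_low: list[str]
    profile_high: dict
    profile_low: dict
    n_draws: int


def _nearest_pd(cov: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
    if np.all(vals > 0):
        return cov
    import logging

    logging.getLogger(__name__).warning(
        "draw_coefficients: covariance not positive definite, clipping eigenvalues"
    )
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T


def draw_coefficients(
    fit: PosteriorSamples | FitSummary, n_draws: int = 4000, seed: int = 0
) -> CoefficientDraws:
    """Coefficient draws for simulation.

    Raw posterior draws are resampled with replacement; a summary-only fit
    samples a multivariate normal with the posterior mean vector and full
    coefficient covariance (nearest-PD repaired if needed).
    """
    rng = np.random.default_rng(seed)
    if isinstance(fit, PosteriorSamples):
        flat = fit.stacked
        idx = rng.integers(0, flat.shape[0], size=n_draws)
        coef_idx = [i for i, nm in enumerate(fit.names) if nm not in ("a", "b")]
        ab_idx = [fit.names.index("a"), fit.names.index("b")]
        return CoefficientDraws(
            values=flat[np.ix_(idx, coef_idx)],
            names=[fit.names[i] for i in coef_idx],
            ab=flat[np.ix_(idx, ab_idx)],
        )
    cov = _nearest_pd(fit.coef_cov)
    if np.allclose(cov, 0):
        values = np.tile(fit.coef_mean, (n_draws, 1))
    else:
        values = rng.multivariate_normal(fit.coef_mean, cov, size=n_draws, method="svd")
    return CoefficientDraws(values=values, names=list(fit.coef_names))


def _profile_x(
    data: ModelData, names: list[str], nmin_s: float, myco_s: np.ndarray
) -> np.ndarray:
    """Assemble the design row for a covariate profile.

    Alpha-block covariates sit at their dataset averages except N
    mineralization; the fungal quadratic and interaction terms derive from
    the profile's standardized abundances.
    """
    alpha_base = data.blocks["alpha"].mean(axis=0).copy()
    alpha_base[2] = nmin_s
    lookup: dict[str, float] = {}
    for i, nm in enumerate(data.names["alpha"]):
        lookup[nm] = alpha_base[i]
    for j, t in enumerate(data.taxa):
        lookup[f"beta_{t}"] = myco_s[j]
        lookup[f"gamma_{t}"] = myco_s[j] ** 2
        lookup[f"mu_{t}"] = nmin_s * myco_s[j]
    return np.array([lookup[nm] for nm in names])


def _predict(
    draws: CoefficientDraws,
    data: ModelData,
    nmin_s: float,
    myco_s: np.ndarray,
    mean_correction: bool = False,
    include_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    x = _profile_x(data, draws.names, nmin_s, myco_s)
    d = draws.values @ x
    if (mean_correction or include_noise) and draws.ab is not None:
        sigma2 = draws.ab[:, 0] + draws.ab[:, 1] * float(np.mean(data.ln_dbh_raw))
        sigma2 = np.clip(sigma2, 0.0, None)
        if mean_correction:
            d = d + 0.5 * sigma2
        if include_noise:
            rng = rng or np.random.default_rng(0)
            d = d + np.sqrt(sigma2) * rng.standard_normal(d.size)
    return np.exp(d)


def _summ(pred: np.ndarray) -> tuple[float, float, float]:
    lo, hi = np.percentile(pred, [2.5, 97.5])
    return float(np.mean(pred)), float(lo), float(hi)


def _myco_std(data: ModelData, raw: np.ndarray) -> np.ndarray:
    return (np.asarray(raw, float) - data.myco_mean) / data.myco_sd


def _nmin_std(data: ModelData, raw: float) -> float:
    return (raw - data.nmin_mean) / data.nmin_sd


def taxon_response_curve(
    fit: PosteriorSamples | FitSummary,
    data: ModelData,
    taxon_index: int,
    n_grid: int = 50,
    n_draws: int = 4000,
    seed: int = 0,
    mean_correction: bool = False,
) -> ScenarioResult:
    """Simulation set 1: BAI along one taxon's observed abundance range,
    N mineralization and the other six taxa held at their averages."""
    if not 1 <= taxon_index <= data.n_taxa:
        raise ValueError("taxon_index out of range")
    j = taxon_index - 1
    draws = draw_coefficients(fit, n_draws, seed)
    col = data.blocks["beta"][:, j]
    grid_s = np.linspace(col.min(), col.max(), n_grid)
    mean = np.empty(n_grid)
    lo = np.empty(n_grid)
    hi = np.empty(n_grid)
    for k, g in enumerate(grid_s):
        myco_s = np.zeros(data.n_taxa)
        myco_s[j] = g
        mean[k], lo[k], hi[k] = _summ(
            _predict(draws, data, 0.0, myco_s, mean_correction=mean_correction)
        )
    return ScenarioResult(
        varying=f"abundance_{data.taxa[j]}",
        grid=grid_s * data.myco_sd[j] + data.myco_mean[j],
        mean=mean,
        lo=lo,
        hi=hi,
        n_draws=n_draws,
        metadata={"set": 1, "taxon": data.taxa[j], "grid_standardized": grid_s},
    )


def _quintet_profiles(data: ModelData, taxon_index: int):
    """High/low five-tree profiles for a target taxon (ties by tree id)."""
    if data.myco_raw is None or data.nmin_raw_by_tree is None:
        raise ValueError("data lacks per-tree community information")
    if data.myco_raw.shape[0] < 5:
        raise ValueError("need at least 5 trees")
    j = taxon_index - 1
    target = data.myco_raw.iloc[:, j]
    order_hi = sorted(target.index, key=lambda t: (-target[t], t))
    order_lo = sorted(target.index, key=lambda t: (target[t], t))
    out = {}
    for label, trees in (("high", order_hi[:5]), ("low", order_lo[:5])):
        myco_raw = data.myco_raw.loc[trees].mean(axis=0).to_numpy()
        nmin_raw = float(data.nmin_raw_by_tree.loc[trees].mean())
        out[label] = {
            "trees": list(trees),
            "myco_raw": myco_raw,
            "nmin_raw": nmin_raw,
            "myco_s": _myco_std(data, myco_raw),
            "nmin_s": _nmin_std(data, nmin_raw),
        }
    return out


def community_contrast(
    fit: PosteriorSamples | FitSummary,
    data: ModelData,
    taxon_index: int,
    n_draws: int = 4000,
    seed: int = 0,
) -> ContrastResult:
    """Simulation set 2: BAI under the five-highest vs five-lowest abundance
    community profiles of a target taxon; paired 95% interval of the
    difference decides significance."""
    profiles = _quintet_profiles(data, taxon_index)
    draws = draw_coefficients(fit, n_draws, seed)
    pred = {
        label: _predict(draws, data, p["nmin_s"], p["myco_s"])
        for label, p in profiles.items()
    }
    diff = pred["high"] - pred["low"]
    dm, dl, dh = _summ(diff)
    return ContrastResult(
        taxon=data.taxa[taxon_index - 1],
        high=_summ(pred["high"]),
        low=_summ(pred["low"]),
        diff=(dm, dl, dh),
        significant=bool(dl > 0 or dh < 0),
        trees_high=profiles["high"]["trees"],
        trees_low=profiles["low"]["trees"],
        profile_high={k: profiles["high"][k] for k in ("myco_raw", "nmin_raw")},
        profile_low={k: profiles["low"][k] for k in ("myco_raw", "nmin_raw")},
        n_draws=n_draws,
    )


def contrast_along_gradient(
    fit: PosteriorSamples | FitSummary,
    data: ModelData,
    taxon_index: int,
    n_grid: int = 50,
    n_draws: int = 4000,
    seed: int = 0,
) -> ScenarioResult:
    """Simulation set 3: the set-2 community profiles held fixed while N
    mineralization sweeps its observed range; reports the high-minus-low
    difference in predicted BAI (mean and 95% interval of the paired
    difference)."""
    profiles = _quintet_profiles(data, taxon_index)
    draws = draw_coefficients(fit, n_draws, seed)
    nmin_col = data.blocks["alpha"][:, 2]
    grid_s = np.linspace(nmin_col.min(), nmin_col.max(), n_grid)
    mean = np.empty(n_grid)
    lo = np.empty(n_grid)
    hi = np.empty(n_grid)
    for k, g in enumerate(grid_s):
        d = _predict(draws, data, g, profiles["high"]["myco_s"]) - _predict(
            draws, data, g, profiles["low"]["myco_s"]
        )
        mean[k], lo[k], hi[k] = _summ(d)
    return ScenarioResult(
        varying="nmin",
        grid=grid_s * data.nmin_sd + data.nmin_mean,
        mean=mean,
        lo=lo,
        hi=hi,
        n_draws=n_draws,
        metadata={
            "set": 3,
            "taxon": data.taxa[taxon_index - 1],
            "grid_standardized": grid_s,
            "profiles": profiles,
        },
    )


@dataclass
class LocalVsRandomResult:
    baseline: ScenarioResult
    locations: pd.DataFrame  # per-location prediction, interval and flag


def local_vs_random(
    fit: PosteriorSamples | FitSummary,
    data: ModelData,
    location_profiles: pd.DataFrame | None = None,
    n_grid: int = 50,
    n_draws: int = 4000,
    seed: int = 0,
) -> LocalVsRandomResult:
    """Simulation set 4: baseline growth curve along the N-mineralization
    gradient under the average community, against per-location predictions
    using each location's own community and N mineralization.

    ``location_profiles`` (index = location; columns = ``nmin`` plus the
    seven taxa, raw Hellinger scale) defaults to averages over each
    location's sampled trees.
    """
    draws = draw_coefficients(fit, n_draws, seed)
    if location_profiles is None:
        tree_loc = (
            pd.DataFrame({"tree_id": data.tree_ids, "location": data.locations})
            .drop_duplicates()
            .set_index("tree_id")["location"]
        )
        rows = []
        for loc, trees in tree_loc.groupby(tree_loc).groups.items():
            trees = [t for t in trees if t in data.myco_raw.index]
            if not trees:
                import logging

                logging.getLogger(__name__).warning("location %s has no trees; skipped", loc)
                continue
            prof = {"location": loc, "nmin": float(data.nmin_raw_by_tree.loc[trees].mean())}
            for j, t in enumerate(data.taxa):
                prof[t] = float(data.myco_raw.loc[trees, t].mean())
            rows.append(prof)
        location_profiles = pd.DataFrame(rows).set_index("location")

    nmin_col = data.blocks["alpha"][:, 2]
    grid_s = np.linspace(nmin_col.min(), nmin_col.max(), n_grid)
    base = np.empty((3, n_grid))
    for k, g in enumerate(grid_s):
        base[:, k] = _summ(_predict(draws, data, g, np.zeros(data.n_taxa)))
    baseline = ScenarioResult(
        varying="nmin",
        grid=grid_s * data.nmin_sd + data.nmin_mean,
        mean=base[0],
        lo=base[1],
        hi=base[2],
        n_draws=n_draws,
        metadata={"set": 4, "grid_standardized": grid_s},
    )
    recs = []
    for loc, row in location_profiles.iterrows():
        nmin_s = _nmin_std(data, float(row["nmin"]))
        myco_s = _myco_std(data, row[data.taxa].to_numpy(dtype=float))
        m, l, h = _summ(_predict(draws, data, nmin_s, myco_s))
        b_lo = float(np.interp(nmin_s, grid_s, baseline.lo))
        b_hi = float(np.interp(nmin_s, grid_s, baseline.hi))
        flag = "above" if l > b_hi else ("below" if h < b_lo else "overlap")
        recs.append(
            {
                "location": loc,
                "nmin": float(row["nmin"]),
                "bai_mean": m,
                "bai_lo": l,
                "bai_hi": h,
                "baseline_lo": b_lo,
                "baseline_hi": b_hi,
                "flag": flag,
            }
        )
    return LocalVsRandomResult(baseline=baseline, locations=pd.DataFrame(recs))
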