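"""Hierarchical Bayesian log-normal growth model.

For each tree species independently, yearly basal area increment is modeled
as

    BAI_{i,y} ~ LogNormal(D_{i,y}, sigma2_{i,y})

with process mean

    D = alpha0 + alpha1*ln(dbh) + alpha2*Nmin + alpha3*BAIS_{y-1}
        + alpha4*age + alpha5*minMayT
        + sum_j beta_j*Myco_j + sum_j gamma_j*Myco_j^2
        + sum_j mu_j*Nmin*Myco_j

and a variance that grows with tree size, sigma2 = a + b*ln(dbh).  Continuous
covariates are z-scored over the model rows; the fungal covariates are
standardized Hellinger abundances of the selected taxa, squared and
interacted after standardization.  Priors are diffuse: Normal(0, 1000) on
alpha, mu and b (second argument read as a variance; a precision reading is
available), logNormal(1, 1000) on a, and the linear and quadratic fungal
blocks each draw from MVN(0, Omega^-1) with a shared Wishart(I_7, 7) prior
on the precision matrix Omega, which lets the model express codependence
among taxa effects.

Sampling is Metropolis-within-Gibbs over the blocks
(alpha | beta | gamma | mu | (a, b) | Omega): random-walk proposals
preconditioned by each block's conditional Gaussian covariance, scalar
proposal scales adapted only during burn-in toward ~30% acceptance, and a
conjugate Wishart update for Omega (Metropolis when Omega is read as a
covariance matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityMatrix, TaxaSelection

logger = logging.getLogger(__name__)

__all__ = [
    "PriorConfig",
    "ModelData",
    "ModelParams",
    "PosteriorSamples",
    "FitSummary",
    "build_design",
    "log_likelihood",
    "log_prior",
    "fit_mcmc",
    "summarize",
    "dic",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class PriorConfig:
    """Diffuse prior settings.

    ``scale_is_variance`` selects whether the second argument of the
    Normal/logNormal priors is a variance (default) or a precision (the
    Gibbs-software convention).  ``wishart_on`` selects whether the Wishart
    prior sits on the precision matrix (default, conjugate) or on the
    covariance matrix of the fungal coefficient blocks.
    """

    normal_scale: float = 1000.0
    a_meanlog: float = 1.0
    a_scale: float = 1000.0
    scale_is_variance: bool = True
    wishart_df: float | None = None  # defaults to block dimension
    wishart_on: str = "precision"

    @property
    def normal_var(self) -> float:
        return self.normal_scale if self.scale_is_variance else 1.0 / self.normal_scale

    @property
    def a_var(self) -> float:
        return self.a_scale if self.scale_is_variance else 1.0 / self.a_scale


#: blocks whose coefficients draw from the shared-Omega multivariate normal
_MVN_BLOCKS = ("beta", "gamma")


@dataclass
class ModelData:
    """Design matrices and response for one species' growth model.

    ``blocks`` maps block name ("alpha", "beta", "gamma", "mu") to a design
    matrix of shape (n_rows, block_dim); ``names`` maps block name to the
    coefficient names.  ``ln_dbh_raw`` (unstandardized, start-of-year) drives
    the variance function.  Standardization moments are retained so the
    scenario engine can move between raw and standardized covariate scales.
    """

    bai: np.ndarray
    ln_dbh_raw: np.ndarray
    blocks: dict[str, np.ndarray]
    names: dict[str, list[str]]
    taxa: list[str]
    tree_ids: np.ndarray
    years: np.ndarray
    locations: np.ndarray
    myco_mean: np.ndarray
    myco_sd: np.ndarray
    nmin_mean: float
    nmin_sd: float
    myco_raw: pd.DataFrame | None = None  # per-tree Hellinger abundances
    nmin_raw_by_tree: pd.Series | None = None

    def __post_init__(self) -> None:
        self.bai = np.asarray(self.bai, dtype=float)
        if np.any(self.bai <= 0):
            raise ValueError("BAI must be strictly positive in model rows")
        self.ln_bai = np.log(self.bai)
        n = self.bai.size
        for name, x in self.blocks.items():
            if x.shape[0] != n:
                raise ValueError(f"block {name}: row mismatch")
            if np.any(~np.isfinite(x)):
                raise ValueError(f"block {name}: non-finite design entries")

    @property
    def n_rows(self) -> int:
        return self.bai.size

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def block_means(self) -> dict[str, np.ndarray]:
        return {b: x.mean(axis=0) for b, x in self.blocks.items()}

    @classmethod
    def minimal(cls, bai: np.ndarray, ln_dbh_raw: np.ndarray | None = None) -> "ModelData":
        """Intercept-only data set (used for reduced/degenerate model checks)."""
        bai = np.asarray(bai, dtype=float)
        n = bai.size
        if ln_dbh_raw is None:
            ln_dbh_raw = np.zeros(n)
        return cls(
            bai=bai,
            ln_dbh_raw=np.asarray(ln_dbh_raw, dtype=float),
            blocks={"alpha": np.ones((n, 1))},
            names={"alpha": ["alpha0_intercept"]},
            taxa=[],
            tree_ids=np.array([f"t{i}" for i in range(n)]),
            years=np.arange(n),
            locations=np.zeros(n, dtype=int),
            myco_mean=np.zeros(0),
            myco_sd=np.ones(0),
            nmin_mean=0.0,
            nmin_sd=1.0,
        )


@dataclass
class ModelParams:
    """One point in parameter space (all symbols of the process model)."""

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    mu: np.ndarray
    a: float
    b: float
    omega: np.ndarray | None = None

    def coef_blocks(self) -> dict[str, np.ndarray]:
        return {
            "alpha": np.atleast_1d(np.asarray(self.alpha, dtype=float)),
            "beta": np.atleast_1d(np.asarray(self.beta, dtype=float)),
            "gamma": np.atleast_1d(np.asarray(self.gamma, dtype=float)),
            "mu": np.atleast_1d(np.asarray(self.mu, dtype=float)),
        }


def _zscore(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1))
    if s == 0:
        raise ValueError("constant covariate column cannot be standardized")
    return (x - m) / s, m, s


def build_design(
    growth: pd.DataFrame,
    community: CommunityMatrix,
    selection: TaxaSelection,
    extra_covariates: tuple[str, ...] = (),
    standardize_myco: bool = True,
) -> ModelData:
    """Join growth and community tables into model design matrices.

    Drops each tree's first year (no lag), z-scores the continuous
    covariates over the model rows, and forms the quadratic and
    Nmin-interaction fungal terms from the standardized copies.
    ``standardize_myco=False`` keeps the Hellinger abundances on their raw
    scale (squares and interactions still formed consistently).
    """
    if community.state != "hellinger":
        raise ValueError("build_design expects a Hellinger-transformed community")
    g = growth.sort_values(["tree_id", "year"]).reset_index(drop=True)
    trees = g["tree_id"].astype(str).unique()
    comm_df = community.to_frame()
    missing = sorted(set(trees) - set(comm_df.index.astype(str)))
    if missing:
        raise ValueError(f"trees absent from community matrix: {missing}")

    # lag of the per-tree standardized BAI; first year per tree has none
    g["bais_lag"] = g.groupby("tree_id")["bais"].shift(1)
    rows = g[g["bais_lag"].notna()].reset_index(drop=True)

    myco_tree = comm_df.loc[rows["tree_id"].astype(str), selection.selected]
    myco = myco_tree.to_numpy(dtype=float)

    ln_dbh_raw = np.log(rows["dbh_prev"].to_numpy(dtype=float))
    lnd_s, _, _ = _zscore(ln_dbh_raw)
    nmin_s, nmin_mean, nmin_sd = _zscore(rows["nmin"].to_numpy(dtype=float))
    age_s, _, _ = _zscore(rows["age"].to_numpy(dtype=float))
    mmt_s, _, _ = _zscore(rows["min_may_t"].to_numpy(dtype=float))
    bais_lag = rows["bais_lag"].to_numpy(dtype=float)

    if standardize_myco:
        myco_mean = myco.mean(axis=0)
        myco_sd = myco.std(axis=0, ddof=1)
        if np.any(myco_sd == 0):
            raise ValueError("constant fungal abundance column")
        myco_s = (myco - myco_mean) / myco_sd
    else:
        myco_mean = np.zeros(myco.shape[1])
        myco_sd = np.ones(myco.shape[1])
        myco_s = myco

    alpha_cols = [np.ones(rows.shape[0]), lnd_s, nmin_s, bais_lag, age_s, mmt_s]
    alpha_names = [
        "alpha0_intercept",
        "alpha1_ln_dbh",
        "alpha2_nmin",
        "alpha3_bais_lag",
        "alpha4_age",
        "alpha5_min_may_t",
    ]
    for c in extra_covariates:
        xc, _, _ = _zscore(rows[c].to_numpy(dtype=float))
        alpha_cols.append(xc)
        alpha_names.append(f"alpha_{c}")

    taxa = list(selection.selected)
    blocks = {
        "alpha": np.column_stack(alpha_cols),
        "beta": myco_s,
        "gamma": myco_s**2,
        "mu": nmin_s[:, None] * myco_s,
    }
    names = {
        "alpha": alpha_names,
        "beta": [f"beta_{t}" for t in taxa],
        "gamma": [f"gamma_{t}" for t in taxa],
        "mu": [f"mu_{t}" for t in taxa],
    }
    per_tree = comm_df.loc[[str(t) for t in trees], taxa]
    nmin_by_tree = rows.groupby("tree_id")["nmin"].first()
    return ModelData(
        bai=rows["bai"].to_numpy(dtype=float),
        ln_dbh_raw=ln_dbh_raw,
        blocks=blocks,
        names=names,
        taxa=taxa,
        tree_ids=rows["tree_id"].to_numpy(),
        years=rows["year"].to_numpy(),
        locations=rows["location"].to_numpy(),
        myco_mean=myco_mean,
        myco_sd=myco_sd,
        nmin_mean=nmin_mean,
        nmin_sd=nmin_sd,
        myco_raw=per_tree,
        nmin_raw_by_tree=nmin_by_tree,
    )


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------


def _process_mean(params: ModelParams, data: ModelData) -> np.ndarray:
    d = np.zeros(data.n_rows)
    for b, theta in params.coef_blocks().items():
        if theta.size and b in data.blocks:
            d += data.blocks[b] @ theta
    return d


def log_likelihood(params: ModelParams, data: ModelData) -> float:
    """Log-normal log-likelihood; -inf sentinel if sigma2 <= 0 anywhere."""
    sigma2 = params.a + params.b * data.ln_dbh_raw
    if params.a <= 0 or np.any(sigma2 <= 0):
        return -np.inf
    d = _process_mean(params, data)
    resid = data.ln_bai - d
    return float(
        -0.5 * np.sum(np.log(2.0 * np.pi * sigma2))
        - np.sum(data.ln_bai)
        - np.sum(resid**2 / (2.0 * sigma2))
    )


def _mvn_prec_logpdf(x: np.ndarray, omega: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -np.inf
    return float(0.5 * logdet - 0.5 * x.size * _LOG2PI - 0.5 * x @ omega @ x)


def log_prior(params: ModelParams, prior: PriorConfig | None = None) -> float:
    """Sum of all log prior densities (second arguments read per config)."""
    prior = prior or PriorConfig()
    v = prior.normal_var
    lp = 0.0
    for name in ("alpha", "mu"):
        x = params.coef_blocks()[name]
        if x.size:
            lp += float(-0.5 * x.size * np.log(2.0 * np.pi * v) - 0.5 * np.sum(x**2) / v)
    lp += float(-0.5 * np.log(2.0 * np.pi * v) - 0.5 * params.b**2 / v)
    if params.a <= 0:
        return -np.inf
    av = prior.a_var
    la = np.log(params.a)
    lp += float(
        -la - 0.5 * np.log(2.0 * np.pi * av) - 0.5 * (la - prior.a_meanlog) ** 2 / av
    )
    beta = params.coef_blocks()["beta"]
    gamma = params.coef_blocks()["gamma"]
    if beta.size or gamma.size:
        d = max(beta.size, gamma.size)
        omega = params.omega if params.omega is not None else np.eye(d)
        try:
            if prior.wishart_on == "precision":
                for x in (beta, gamma):
                    if x.size:
                        lp += _mvn_prec_logpdf(x, omega)
            else:
                for x in (beta, gamma):
                    if x.size:
                        lp += float(stats.multivariate_normal.logpdf(x, cov=omega))
            df = prior.wishart_df or d
            lp += float(stats.wishart.logpdf(omega, df=df, scale=np.eye(d)))
        except (np.linalg.LinAlgError, ValueError):
            return -np.inf
        sign, _ = np.linalg.slogdet(omega)
        if sign <= 0 or not np.allclose(omega, omega.T):
            return -np.inf
    return lp


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """MCMC draws (burn-in excluded, thinned) with diagnostics.

    ``draws`` has shape (chains, n_stored, n_params); ``omega_draws``
    (chains, n_stored, d, d) when the shared precision matrix is sampled.
    ``loglik_draws`` caches the sampler's own log-likelihood at each stored
    draw so posterior-consistency can be audited.
    """

    draws: np.ndarray
    names: list[str]
    omega_draws: np.ndarray | None
    loglik_draws: np.ndarray
    rhat: pd.Series | None
    ess: pd.Series | None
    acceptance: dict[str, np.ndarray]
    seed: int
    settings: dict
    data: ModelData | None = None
    prior: PriorConfig = field(default_factory=PriorConfig)

    @property
    def stacked(self) -> np.ndarray:
        """All chains concatenated, shape (chains * n_stored, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def params_at(self, chain: int, idx: int) -> ModelParams:
        vec = self.draws[chain, idx]
        return _vector_to_params(vec, self.names, self._block_dims(), self.omega_draws, chain, idx)

    def _block_dims(self) -> dict[str, int]:
        dims: dict[str, int] = {}
        for nm in self.names:
            b = nm.split("_", 1)[0] if not nm.startswith("alpha") else "alpha"
            if nm in ("a", "b"):
                continue
            dims[b] = dims.get(b, 0) + 1
        return dims

    def mean_params(self) -> ModelParams:
        return self.params_from_vector(self.stacked.mean(axis=0), mean_omega=True)

    def params_from_vector(self, vec: np.ndarray, mean_omega: bool = False) -> ModelParams:
        blocks: dict[str, list[float]] = {"alpha": [], "beta": [], "gamma": [], "mu": []}
        a = b = 0.0
        for nm, v in zip(self.names, vec):
            if nm == "a":
                a = v
            elif nm == "b":
                b = v
            else:
                blocks[_block_of(nm)].append(v)
        omega = None
        if self.omega_draws is not None:
            omega = (
                self.omega_draws.reshape(-1, *self.omega_draws.shape[-2:]).mean(axis=0)
                if mean_omega
                else self.omega_draws[0, -1]
            )
        return ModelParams(
            alpha=np.array(blocks["alpha"]),
            beta=np.array(blocks["beta"]),
            gamma=np.array(blocks["gamma"]),
            mu=np.array(blocks["mu"]),
            a=a,
            b=b,
            omega=omega,
        )


def _block_of(name: str) -> str:
    for b in ("alpha", "beta", "gamma", "mu"):
        if name.startswith(b):
            return b
    raise KeyError(name)


def _vector_to_params(vec, names, dims, omega_draws, chain, idx) -> ModelParams:
    blocks: dict[str, list[float]] = {"alpha": [], "beta": [], "gamma": [], "mu": []}
    a = b = 0.0
    for nm, v in zip(names, vec):
        if nm == "a":
            a = v
        elif nm == "b":
            b = v
        else:
            blocks[_block_of(nm)].append(v)
    omega = omega_draws[chain, idx] if omega_draws is not None else None
    return ModelParams(
        alpha=np.array(blocks["alpha"]),
        beta=np.array(blocks["beta"]),
        gamma=np.array(blocks["gamma"]),
        mu=np.array(blocks["mu"]),
        a=a,
        b=b,
        omega=omega,
    )


def _init_state(data: ModelData, active: list[str], fix_variance, rng, prior: PriorConfig):
    """Weighted-least-squares style starting point with per-chain jitter."""
    xs = [data.blocks[b] for b in active]
    x = np.column_stack(xs)
    n, p = x.shape
    theta = np.linalg.solve(x.T @ x + 1e-6 * np.eye(p), x.T @ data.ln_bai)
    resid = data.ln_bai - x @ theta
    if fix_variance is not None:
        a0, b0 = fix_variance
    else:
        u = np.column_stack([np.ones(n), data.ln_dbh_raw])
        try:
            ab = np.linalg.solve(u.T @ u + 1e-8 * np.eye(2), u.T @ resid**2)
            a0, b0 = float(ab[0]), float(ab[1])
        except np.linalg.LinAlgError:
            a0, b0 = float(np.mean(resid**2)), 0.0
        s2 = a0 + b0 * data.ln_dbh_raw
        if a0 <= 1e-6 or np.any(s2 <= 1e-6):
            a0, b0 = max(float(np.mean(resid**2)), 1e-4), 0.0
    sigma2 = a0 + b0 * data.ln_dbh_raw
    if np.any(sigma2 <= 0):
        raise ValueError("variance function non-positive at initialization")
    state = {}
    off = 0
    for b in active:
        d = data.blocks[b].shape[1]
        state[b] = theta[off : off + d].copy()
        off += d
    # mild overdispersion across chains helps rhat detect non-convergence
    for b in active:
        state[b] = state[b] + 0.05 * rng.standard_normal(state[b].size) * (
            np.abs(state[b]) + 0.05
        )
    return state, a0, b0


def _joint_chol(data, active, sigma2, omega, prior: PriorConfig):
    """Cholesky of the full-conditional covariance over all coefficient blocks.

    Cross-block posterior correlations (intercept vs quadratic terms, linear
    vs interaction terms) throttle pure blockwise updates; a joint move
    preconditioned by this covariance restores mixing.
    """
    x = np.column_stack([data.blocks[b] for b in active])
    w = 1.0 / sigma2
    info = (x * w[:, None]).T @ x
    off = 0
    for b in active:
        d = data.blocks[b].shape[1]
        sl = slice(off, off + d)
        if b in _MVN_BLOCKS and omega is not None and prior.wishart_on == "precision":
            info[sl, sl] += omega
        elif b in _MVN_BLOCKS and omega is not None:
            info[sl, sl] += np.linalg.inv(omega)
        else:
            info[sl, sl] += np.eye(d) / prior.normal_var
        off += d
    cov = np.linalg.inv(info)
    cov = 0.5 * (cov + cov.T)
    try:
        return np.linalg.cholesky(cov), x
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0])), x


def _conditional_chol(data, block, sigma2, omega, prior: PriorConfig):
    x = data.blocks[block]
    w = 1.0 / sigma2
    info = (x * w[:, None]).T @ x
    d = x.shape[1]
    if block in _MVN_BLOCKS and omega is not None and prior.wishart_on == "precision":
        info = info + omega
    elif block in _MVN_BLOCKS and omega is not None:
        info = info + np.linalg.inv(omega)
    else:
        info = info + np.eye(d) / prior.normal_var
    cov = np.linalg.inv(info)
    cov = 0.5 * (cov + cov.T)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(cov + 1e-10 * np.eye(d))


def _ab_chol(data, a, b):
    """Fisher-information proposal shape for the variance pair.

    Computed in centered coordinates sigma2 = c + b*(ln_dbh - mean) where the
    information matrix is well conditioned, then sheared back to (a, b); the
    raw parameterization is nearly collinear because ln(dbh) varies little.
    """
    lbar = float(np.mean(data.ln_dbh_raw))
    sigma2 = a + b * data.ln_dbh_raw
    u = np.column_stack([np.ones(data.n_rows), data.ln_dbh_raw - lbar])
    info = 0.5 * (u / sigma2[:, None] ** 2).T @ u + 1e-10 * np.eye(2)
    cov = np.linalg.inv(info)
    cov = 0.5 * (cov + cov.T)
    lc = np.linalg.cholesky(cov)
    shear = np.array([[1.0, -lbar], [0.0, 1.0]])  # (c, b) -> (a, b)
    return shear @ lc


def fit_mcmc(
    data: ModelData,
    chains: int = 3,
    iterations: int = 50000,
    burn_in: int = 10000,
    thin: int = 10,
    seed: int = 0,
    prior: PriorConfig | None = None,
    fix_variance: tuple[float, float] | None = None,
    include_quadratic: bool = True,
    include_interaction: bool = True,
    adapt_target: float = 0.3,
) -> PosteriorSamples:
    """Sample the posterior by adaptive Metropolis-within-Gibbs.

    Proposal scales adapt only during burn-in (frozen afterwards, so the
    retained chain has the correct invariant distribution); per-chain seeds
    derive deterministically from ``seed``.  Draws are thinned by ``thin``.
    """
    prior = prior or PriorConfig()
    active = ["alpha"]
    for b, keep in (("beta", True), ("gamma", include_quadratic), ("mu", include_interaction)):
        if keep and b in data.blocks and data.blocks[b].shape[1] > 0:
            active.append(b)
    mvn_active = [b for b in active if b in _MVN_BLOCKS]
    d_omega = data.blocks[mvn_active[0]].shape[1] if mvn_active else 0
    wdf = prior.wishart_df or d_omega

    names: list[str] = []
    for b in active:
        names.extend(data.names[b])
    names += ["a", "b"]
    n_par = len(names)
    n_stored = iterations // thin

    all_draws = np.empty((chains, n_stored, n_par))
    all_omega = np.empty((chains, n_stored, d_omega, d_omega)) if mvn_active else None
    all_ll = np.empty((chains, n_stored))
    acc_out: dict[str, list] = {b: [] for b in active + ["joint", "ab"]}

    sum_ln_bai = float(np.sum(data.ln_bai))
    seeds = np.random.SeedSequence(seed).spawn(chains)

    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        state, a_cur, b_cur = _init_state(data, active, fix_variance, rng, prior)
        omega = np.eye(d_omega) if mvn_active else None
        sigma2 = a_cur + b_cur * data.ln_dbh_raw
        chol = {b: _conditional_chol(data, b, sigma2, omega, prior) for b in active}
        chol_joint, x_joint = _joint_chol(data, active, sigma2, omega, prior)
        n_coef = x_joint.shape[1]
        log_scale = {b: np.log(2.38 / np.sqrt(data.blocks[b].shape[1])) for b in active}
        log_scale["joint"] = np.log(2.38 / np.sqrt(n_coef))
        if fix_variance is None:
            chol["ab"] = _ab_chol(data, a_cur, b_cur)
            log_scale["ab"] = np.log(2.38 / np.sqrt(2.0))
        acc_win = {b: 0 for b in log_scale}
        acc_post = {b: 0 for b in log_scale}

        d_vec = np.zeros(data.n_rows)
        for b in active:
            d_vec += data.blocks[b] @ state[b]
        resid = data.ln_bai - d_vec
        inv2s = 0.5 / sigma2
        const = -0.5 * float(np.sum(np.log(2.0 * np.pi * sigma2))) - sum_ln_bai
        quad = float(np.sum(resid**2 * inv2s))

        total = burn_in + iterations
        store_i = 0
        for it in range(total):
            in_burn = it < burn_in
            for b in active:
                x = data.blocks[b]
                cur = state[b]
                step = np.exp(log_scale[b]) * (chol[b] @ rng.standard_normal(cur.size))
                prop = cur + step
                delta = x @ step
                resid_new = resid - delta
                quad_new = float(np.sum(resid_new**2 * inv2s))
                if b in _MVN_BLOCKS and prior.wishart_on == "precision":
                    dprior = -0.5 * float(prop @ omega @ prop - cur @ omega @ cur)
                elif b in _MVN_BLOCKS:
                    oinv = np.linalg.inv(omega)
                    dprior = -0.5 * float(prop @ oinv @ prop - cur @ oinv @ cur)
                else:
                    dprior = -0.5 * float(prop @ prop - cur @ cur) / prior.normal_var
                if np.log(rng.random()) < (quad - quad_new) + dprior:
                    state[b] = prop
                    resid = resid_new
                    quad = quad_new
                    acc_win[b] += 1
                    if not in_burn:
                        acc_post[b] += 1
            # joint move across all coefficient blocks (cross-block mixing)
            step = np.exp(log_scale["joint"]) * (chol_joint @ rng.standard_normal(n_coef))
            resid_new = resid - x_joint @ step
            quad_new = float(np.sum(resid_new**2 * inv2s))
            dprior = 0.0
            off = 0
            for b in active:
                d_b = data.blocks[b].shape[1]
                prop = state[b] + step[off : off + d_b]
                cur = state[b]
                if b in _MVN_BLOCKS and prior.wishart_on == "precision":
                    dprior += -0.5 * float(prop @ omega @ prop - cur @ omega @ cur)
                elif b in _MVN_BLOCKS:
                    oinv = np.linalg.inv(omega)
                    dprior += -0.5 * float(prop @ oinv @ prop - cur @ oinv @ cur)
                else:
                    dprior += -0.5 * float(prop @ prop - cur @ cur) / prior.normal_var
                off += d_b
            if np.log(rng.random()) < (quad - quad_new) + dprior:
                off = 0
                for b in active:
                    d_b = data.blocks[b].shape[1]
                    state[b] = state[b] + step[off : off + d_b]
                    off += d_b
                resid = resid_new
                quad = quad_new
                acc_win["joint"] += 1
                if not in_burn:
                    acc_post["joint"] += 1
            if fix_variance is None:
                step = np.exp(log_scale["ab"]) * (chol["ab"] @ rng.standard_normal(2))
                a_p, b_p = a_cur + step[0], b_cur + step[1]
                s2_p = a_p + b_p * data.ln_dbh_raw
                if a_p > 0 and np.all(s2_p > 0):
                    const_p = -0.5 * float(np.sum(np.log(2.0 * np.pi * s2_p))) - sum_ln_bai
                    quad_p = float(np.sum(resid**2 / (2.0 * s2_p)))
                    la_c, la_p = np.log(a_cur), np.log(a_p)
                    dprior = (
                        -la_p
                        - 0.5 * (la_p - prior.a_meanlog) ** 2 / prior.a_var
                        + la_c
                        + 0.5 * (la_c - prior.a_meanlog) ** 2 / prior.a_var
                        - 0.5 * (b_p**2 - b_cur**2) / prior.normal_var
                    )
                    ll_new = const_p - quad_p
                    ll_old = const - quad
                    if np.log(rng.random()) < (ll_new - ll_old) + dprior:
                        a_cur, b_cur, sigma2 = a_p, b_p, s2_p
                        inv2s = 0.5 / sigma2
                        const, quad = const_p, quad_p
                        acc_win["ab"] += 1
                        if not in_burn:
                            acc_post["ab"] += 1
            if mvn_active:
                if prior.wishart_on == "precision":
                    # conjugate: Omega | beta, gamma ~ Wishart
                    s = np.eye(d_omega)
                    for b in mvn_active:
                        s = s + np.outer(state[b], state[b])
                    omega = stats.wishart.rvs(
                        df=wdf + len(mvn_active), scale=np.linalg.inv(s), random_state=rng
                    )
                else:
                    pert = rng.standard_normal((d_omega, d_omega)) * 0.05
                    prop_o = omega + 0.5 * (pert + pert.T)
                    lp_new = _omega_cov_logdens(prop_o, state, mvn_active, wdf)
                    lp_old = _omega_cov_logdens(omega, state, mvn_active, wdf)
                    if np.log(rng.random()) < lp_new - lp_old:
                        omega = prop_o

            if in_burn:
                if (it + 1) % 25 == 0:
                    for b in log_scale:
                        rate = acc_win[b] / 25.0
                        log_scale[b] = np.clip(
                            log_scale[b] + 0.25 * (rate - adapt_target), -8.0, 3.0
                        )
                        acc_win[b] = 0
                if it + 1 == burn_in // 2 and burn_in >= 100:
                    chol.update(
                        {b: _conditional_chol(data, b, sigma2, omega, prior) for b in active}
                    )
                    chol_joint, x_joint = _joint_chol(data, active, sigma2, omega, prior)
                    if fix_variance is None:
                        chol["ab"] = _ab_chol(data, a_cur, b_cur)
            else:
                j = it - burn_in
                if (j + 1) % thin == 0 and store_i < n_stored:
                    vec = np.concatenate([state[b] for b in active] + [[a_cur, b_cur]])
                    all_draws[c, store_i] = vec
                    if all_omega is not None:
                        all_omega[c, store_i] = omega
                    all_ll[c, store_i] = const - quad
                    store_i += 1
        for b in acc_out:
            if b in acc_post:
                acc_out[b].append(acc_post[b] / max(iterations, 1))

    rhat = ess = None
    if chains >= 2 and n_stored >= 4:
        import arviz as az

        varying = [
            i for i in range(n_par) if np.ptp(all_draws[:, :, i]) > 0
        ]  # fixed parameters (e.g. a, b under fix_variance) have no rhat
        dset = az.convert_to_dataset({names[i]: all_draws[:, :, i] for i in varying})
        names_v = [names[i] for i in varying]
        rhat_ds, ess_ds = az.rhat(dset), az.ess(dset)
        rhat = pd.Series({nm: float(rhat_ds[nm]) for nm in names_v})
        ess = pd.Series({nm: float(ess_ds[nm]) for nm in names_v})
        bad = rhat[rhat > 1.1]
        if len(bad):
            logger.warning("rhat > 1.1 for parameters: %s", list(bad.index))

    return PosteriorSamples(
        draws=all_draws,
        names=names,
        omega_draws=all_omega,
        loglik_draws=all_ll,
        rhat=rhat,
        ess=ess,
        acceptance={b: np.array(v) for b, v in acc_out.items() if v},
        seed=seed,
        settings={
            "chains": chains,
            "iterations": iterations,
            "burn_in": burn_in,
            "thin": thin,
            "include_quadratic": include_quadratic,
            "include_interaction": include_interaction,
            "fix_variance": fix_variance,
        },
        data=data,
        prior=prior,
    )


def _omega_cov_logdens(omega, state, mvn_active, wdf):
    sign, _ = np.linalg.slogdet(omega)
    if sign <= 0:
        return -np.inf
    d = omega.shape[0]
    try:
        lp = float(stats.wishart.logpdf(omega, df=wdf, scale=np.eye(d)))
        for b in mvn_active:
            lp += float(stats.multivariate_normal.logpdf(state[b], cov=omega))
    except (np.linalg.LinAlgError, ValueError):
        return -np.inf
    return lp


# ---------------------------------------------------------------------------
# Summaries, DIC
# ---------------------------------------------------------------------------


@dataclass
class FitSummary:
    """Posterior summary: per-parameter table, fungal-block correlations,
    full coefficient covariance (for the scenario engine), and fit R^2."""

    table: pd.DataFrame
    coef_names: list[str]
    coef_mean: np.ndarray
    coef_cov: np.ndarray
    fungal_corr: pd.DataFrame | None
    r2: float | None


def summarize(posterior: PosteriorSamples, data: ModelData | None = None) -> FitSummary:
    """Means, SDs, 95% credible intervals, CI-based significance flags,
    fungal coefficient correlations, and R^2 of the posterior-mean prediction."""
    flat = posterior.stacked
    names = posterior.names
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
    table = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "ci_2.5": lo,
            "ci_97.5": hi,
            "significant": (lo > 0) | (hi < 0),
        },
        index=names,
    )
    coef_idx = [i for i, nm in enumerate(names) if nm not in ("a", "b")]
    coef_names = [names[i] for i in coef_idx]
    coef_draws = flat[:, coef_idx]
    coef_cov = np.cov(coef_draws, rowvar=False)
    coef_cov = np.atleast_2d(coef_cov)
    fungal_idx = [
        i for i, nm in enumerate(coef_names) if _block_of(nm) in ("beta", "gamma", "mu")
    ]
    fungal_corr = None
    if len(fungal_idx) >= 2:
        sub = coef_draws[:, fungal_idx]
        fungal_corr = pd.DataFrame(
            np.corrcoef(sub, rowvar=False),
            index=[coef_names[i] for i in fungal_idx],
            columns=[coef_names[i] for i in fungal_idx],
        )
    r2 = None
    data = data if data is not None else posterior.data
    if data is not None:
        d_mean = np.zeros(data.n_rows)
        for b, x in data.blocks.items():
            bn = [i for i, nm in enumerate(names) if nm in data.names[b]]
            if bn:
                d_mean += x @ mean[bn]
        pred = np.exp(d_mean)
        r = np.corrcoef(pred, data.bai)[0, 1]
        r2 = float(r**2)
    return FitSummary(
        table=table,
        coef_names=coef_names,
        coef_mean=mean[coef_idx],
        coef_cov=coef_cov,
        fungal_corr=fungal_corr,
        r2=r2,
    )


@dataclass
class DicResult:
    dic: float
    mean_deviance: float
    p_d: float
    fallback: bool = False


def _deviance_draws(posterior: PosteriorSamples, data: ModelData) -> np.ndarray:
    names = posterior.names
    flat = posterior.stacked
    d_all = np.zeros((data.n_rows, flat.shape[0]))
    for b, x in data.blocks.items():
        idx = [i for i, nm in enumerate(names) if nm in data.names[b]]
        if idx:
            d_all += x @ flat[:, idx].T
    ia, ib = names.index("a"), names.index("b")
    sigma2 = flat[:, ia][None, :] + flat[:, ib][None, :] * data.ln_dbh_raw[:, None]
    resid = data.ln_bai[:, None] - d_all
    ll = (
        -0.5 * np.sum(np.log(2.0 * np.pi * sigma2), axis=0)
        - np.sum(data.ln_bai)
        - np.sum(resid**2 / (2.0 * sigma2), axis=0)
    )
    return -2.0 * ll


def dic(posterior: PosteriorSamples, data: ModelData | None = None) -> DicResult:
    """Deviance information criterion: DIC = mean deviance + p_D, with
    p_D = mean deviance - deviance at the posterior mean.  Falls back to the
    half-variance-of-deviance estimate when the posterior mean is outside the
    valid variance region."""
    data = data if data is not None else posterior.data
    if data is None:
        raise ValueError("dic needs the ModelData the posterior was fitted to")
    dev = _deviance_draws(posterior, data)
    dbar = float(np.mean(dev))
    theta_bar = posterior.mean_params()
    ll_at_mean = log_likelihood(theta_bar, data)
    if np.isfinite(ll_at_mean):
        p_d = dbar - (-2.0 * ll_at_mean)
        return DicResult(dic=dbar + p_d, mean_deviance=dbar, p_d=p_d)
    p_d = float(np.var(dev) / 2.0)
    logger.warning("dic: posterior mean outside valid region; using half-variance p_D")
    return DicResult(dic=dbar + p_d, mean_deviance=dbar, p_d=p_d, fallback=True)
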