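"""Bayesian Gaussian-process covariation engine.

For each animal's CLR series (one per Dirichlet Monte-Carlo instance) the
taxa x timepoints matrix Y is modelled as matrix-normal with unknown row
(taxon) covariance Sigma and known column covariance K, a squared-
exponential kernel over the sampling days plus a nugget — the kernel
absorbs the irregular temporal spacing and autocorrelation between
samples.  With an inverse-Wishart prior Sigma ~ IW(nu, Xi) and a per-taxon
constant mean, the posterior is conjugate:

    Sigma | Y  ~  IW(nu + T,  Xi + (Y - M) K^{-1} (Y - M)^T)

Posterior draws of Sigma are converted to correlation matrices and pooled
across Dirichlet instances and animals within a group; taxon pairs whose
95% equal-tailed credible interval excludes zero are significant, and
pairs whose |median rho| exceeds 0.5 are "strong" associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .preprocess import ClrInstance


@dataclass
class GPConfig:
    """Kernel and prior settings for the covariation model.

    lengthscale (days) and nugget control the temporal kernel; the default
    10-day lengthscale spans the dense 2-day sampling while leaving the
    sparse weekly-monthly tail nearly independent.  prior_dof defaults to
    D + 3 (weakly informative with a proper mean) and prior_scale to the
    identity.
    """

    lengthscale: float = 10.0
    kernel_var: float = 1.0
    nugget: float = 0.1
    prior_dof: float | None = None
    prior_scale: np.ndarray | None = None
    n_posterior_draws: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lengthscale <= 0:
            raise ValueError("lengthscale must be > 0")
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.n_posterior_draws < 1:
            raise ValueError("need at least one posterior draw")

    def kernel(self, days: np.ndarray) -> np.ndarray:
        d = np.subtract.outer(days, days)
        return (self.kernel_var * np.exp(-0.5 * (d / self.lengthscale) ** 2)
                + self.nugget * np.eye(len(days)))


@dataclass
class GPPosterior:
    """Pooled Monte-Carlo draws of the taxon-taxon correlation matrix."""

    draws: np.ndarray                       # n_draws x D x D
    taxon_ids: list[str]
    provenance: dict = field(default_factory=dict)
    covariance_draws: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def median_correlation(self) -> np.ndarray:
        return np.median(self.draws, axis=0)


def _to_correlation(cov: np.ndarray) -> np.ndarray:
    """Batched covariance -> correlation conversion."""
    sd = np.sqrt(np.einsum("...ii->...i", cov))
    corr = cov / (sd[..., :, None] * sd[..., None, :])
    ii = np.arange(cov.shape[-1])
    corr[..., ii, ii] = 1.0
    return np.clip(corr, -1.0, 1.0)


def fit_gp_posterior(instances: list[ClrInstance], config: GPConfig,
                     store_covariance: bool = False,
                     provenance: dict | None = None) -> GPPosterior:
    """Posterior over the taxon correlation matrix, pooled over instances.

    Each instance (one Dirichlet replicate of one animal's series) is fit
    independently under the conjugate matrix-normal/inverse-Wishart model
    with a per-taxon constant mean; ``n_posterior_draws`` correlation draws
    per instance are pooled into the returned posterior.
    """
    if not instances:
        raise ValueError("no instances supplied")
    d = instances[0].values.shape[0]
    taxa = instances[0].taxon_ids or [f"taxon{i}" for i in range(d)]
    nu = config.prior_dof if config.prior_dof is not None else d + 3
    if nu <= d + 1:
        raise ValueError(f"prior_dof must exceed n_taxa + 1 = {d + 1} for a proper "
                         "prior mean")
    xi = config.prior_scale if config.prior_scale is not None else np.eye(d)
    xi = np.asarray(xi, dtype=float)
    if xi.shape != (d, d):
        raise ValueError("prior_scale dimensions do not match the taxon set")

    rng = np.random.default_rng(config.seed)
    kernel_cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
    all_corr, all_cov = [], []
    for inst in instances:
        y = inst.values
        if y.shape[0] != d:
            raise ValueError("instances do not share a taxon set")
        t = y.shape[1]
        if t < 3:
            raise ValueError("each instance needs at least 3 timepoints")
        key = inst.days.tobytes()
        if key not in kernel_cache:
            k = config.kernel(inst.days)
            try:
                chol = np.linalg.cholesky(k)
            except np.linalg.LinAlgError as err:
                raise ValueError(
                    "temporal kernel is not positive definite (duplicate days?); "
                    "set a nugget > 0") from err
            kernel_cache[key] = (k, chol)
        _, chol = kernel_cache[key]
        yc = y - y.mean(axis=1, keepdims=True)
        z = np.linalg.solve(chol, yc.T)          # K^{-1/2} (Y-M)^T
        sse = z.T @ z                            # (Y-M) K^{-1} (Y-M)^T
        scale = xi + sse
        scale = (scale + scale.T) / 2
        cov_draws = invwishart.rvs(df=nu + t, scale=scale,
                                   size=config.n_posterior_draws, random_state=rng)
        cov_draws = cov_draws.reshape(config.n_posterior_draws, d, d)
        all_corr.append(_to_correlation(cov_draws.copy()))
        if store_covariance:
            all_cov.append(cov_draws)
    return GPPosterior(draws=np.concatenate(all_corr, axis=0),
                       taxon_ids=list(taxa),
                       provenance=provenance or {},
                       covariance_draws=(np.concatenate(all_cov, axis=0)
                                         if store_covariance else None))


def summarize_associations(post: GPPosterior,
                           strong_threshold: float = 0.5) -> pd.DataFrame:
    """Edge table over unordered taxon pairs, sorted by |median rho|.

    Columns: taxon_i, taxon_j, rho_median, ci_low, ci_high (95% equal-
    tailed), significant (CI excludes zero), strong (|median| strictly
    above the threshold), sign.  The two flags are stored independently.
    """
    if post.n_draws < 2:
        raise ValueError("need at least 2 pooled draws")
    d = len(post.taxon_ids)
    iu, ju = np.triu_indices(d, k=1)
    pair_draws = post.draws[:, iu, ju]           # n_draws x n_pairs
    med = np.median(pair_draws, axis=0)
    lo, hi = np.percentile(pair_draws, [2.5, 97.5], axis=0)
    edges = pd.DataFrame({
        "taxon_i": [post.taxon_ids[i] for i in iu],
        "taxon_j": [post.taxon_ids[j] for j in ju],
        "rho_median": med,
        "ci_low": lo,
        "ci_high": hi,
    })
    edges["significant"] = (edges["ci_low"] > 0) | (edges["ci_high"] < 0)
    edges["strong"] = edges["rho_median"].abs() > strong_threshold
    edges["sign"] = np.sign(edges["rho_median"]).astype(int)
    return (edges.sort_values("rho_median", key=lambda s: s.abs(), ascending=False)
            .reset_index(drop=True))


def _strong_set(edges: pd.DataFrame) -> dict[frozenset, int]:
    strong = edges[edges["strong"]]
    return {frozenset((r.taxon_i, r.taxon_j)): int(r.sign)
            for r in strong.itertuples()}


def compare_networks(edges_a: pd.DataFrame, edges_b: pd.DataFrame) -> dict:
    """Shared/unique strong-edge report between two association networks."""
    a, b = _strong_set(edges_a), _strong_set(edges_b)
    shared = sorted(set(a) & set(b), key=sorted)
    only_a = sorted(set(a) - set(b), key=sorted)
    only_b = sorted(set(b) - set(a), key=sorted)
    flips = [p for p in shared if a[p] != b[p]]
    return {
        "n_strong_a": len(a),
        "n_strong_b": len(b),
        "n_shared": len(shared),
        "n_unique_a": len(only_a),
        "n_unique_b": len(only_b),
        "shared": [tuple(sorted(p)) for p in shared],
        "unique_a": [tuple(sorted(p)) for p in only_a],
        "unique_b": [tuple(sorted(p)) for p in only_b],
        "shared_positive": sum(1 for p in shared if a[p] > 0 and b[p] > 0),
        "shared_negative": sum(1 for p in shared if a[p] < 0 and b[p] < 0),
        "sign_flips": [tuple(sorted(p)) for p in flips],
        "signs_by_network": {
            "a": {"positive": sum(1 for s in a.values() if s > 0),
                  "negative": sum(1 for s in a.values() if s < 0)},
            "b": {"positive": sum(1 for s in b.values() if s > 0),
                  "negative": sum(1 for s in b.values() if s < 0)},
        },
    }


def log_ratio_trajectory(instances: list[ClrInstance], taxon: str) -> pd.DataFrame:
    """Per-day CLR percentiles (2.5/25/50/75/97.5) of one taxon across
    Dirichlet instances — the posterior-predictive-style band used to
    classify treatment-phase trends of resistant taxa."""
    if not instances:
        raise ValueError("no instances supplied")
    taxa = instances[0].taxon_ids or []
    if taxon not in taxa:
        raise KeyError(f"unknown taxon {taxon!r}")
    row = taxa.index(taxon)
    by_day: dict[float, list[np.ndarray]] = {}
    for inst in instances:
        for j, day in enumerate(inst.days):
            by_day.setdefault(float(day), []).append(inst.values[row, j])
    rows = []
    for day in sorted(by_day):
        vals = np.asarray(by_day[day])
        q = np.percentile(vals, [2.5, 25, 50, 75, 97.5])
        rows.append({"day": day, "p2.5": q[0], "p25": q[1], "median": q[2],
                     "p75": q[3], "p97.5": q[4], "n": len(vals)})
    return pd.DataFrame(rows)


def classify_treatment_trend(traj: pd.DataFrame,
                             treatment_window: tuple[int, int] = (0, 6),
                             tol: float = 0.0) -> str:
    """Rising / flat / falling call for the treatment-phase CLR median
    relative to the pretreatment mean."""
    pre = traj.loc[traj["day"] < treatment_window[0], "median"]
    treat = traj.loc[(traj["day"] >= treatment_window[0])
                     & (traj["day"] <= treatment_window[1]), "median"]
    if pre.empty or treat.empty:
        raise ValueError("trajectory must cover pretreatment and treatment days")
    delta = treat.mean() - pre.mean()
    if delta > tol:
        return "rising"
    if delta < -tol:
        return "falling"
    return "flat"
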