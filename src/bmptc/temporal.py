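"""Model-based temporal clustering and responder categorization.

Time profiles (six log2 ratios per probe, one cell line) are scaled to unit
Euclidean length so clustering groups by profile *shape*, then fitted with
finite Gaussian mixtures under several covariance families — spherical or
diagonal, with component-specific or shared (equal) volume, plus fully
unconstrained — and the (family, K) pair maximizing the Bayesian Information
Criterion, BIC = 2*loglik - p*ln(n), is selected. Each probe is assigned to
its maximum-responsibility cluster, and each cluster is labelled with a
responder category from the earliest time its mean original-scale profile
crosses the regulation threshold:

* 0.5 h or 1 h  -> early
* 3 h or 6 h    -> early_intermediate
* 12 h          -> late_intermediate
* 24 h          -> late (regulated exclusively at the final time point)
* never         -> undetermined

EM is run with deterministic seeded k-means multi-starts; the log-likelihood
is checked to be non-decreasing on every fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .io_model import CANONICAL_TIMES, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

FAMILIES = (
    "spherical_equal",
    "spherical_varying",
    "diagonal_equal",
    "diagonal_varying",
    "full",
)

CATEGORIES = ("early", "early_intermediate", "late_intermediate", "late", "undetermined")

_CATEGORY_BY_TIME = {0.5: "early", 1.0: "early",
                     3.0: "early_intermediate", 6.0: "early_intermediate",
                     12.0: "late_intermediate", 24.0: "late"}

_LOG2PI = np.log(2.0 * np.pi)
VAR_FLOOR = 1e-6


def scale_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Scale each row (a six-point log2-ratio time profile) to unit length.

    All-zero profiles cannot be scaled and are excluded with a warning.
    """
    if profiles.shape[1] != len(CANONICAL_TIMES):
        raise ValidationError(f"profiles must have {len(CANONICAL_TIMES)} time points")
    if profiles.isna().any().any():
        raise ValidationError("profiles must be complete (no missing values)")
    norms = np.linalg.norm(profiles.to_numpy(dtype=float), axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("excluding %d all-zero profiles from unit scaling", int(zero.sum()))
    kept = profiles.loc[~zero]
    return kept.div(norms[~zero], axis=0)


# -- Gaussian mixture EM ------------------------------------------------------


def _n_cov_params(family: str, k: int, d: int) -> int:
    return {
        "spherical_equal": 1,
        "spherical_varying": k,
        "diagonal_equal": d,
        "diagonal_varying": k * d,
        "full": k * d * (d + 1) // 2,
    }[family]


def _log_gauss(X: np.ndarray, means: np.ndarray, covs: list[np.ndarray], family: str) -> np.ndarray:
    """n x K matrix of per-component log densities."""
    n, d = X.shape
    k = means.shape[0]
    out = np.empty((n, k))
    if family == "full":
        for j in range(k):
            chol = np.linalg.cholesky(covs[j])
            diff = X - means[j]
            sol = np.linalg.solve(chol, diff.T)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            out[:, j] = -0.5 * (d * _LOG2PI + logdet + maha)
    else:
        # covs[j] is a length-d diagonal (spherical stored as constant diagonal)
        for j in range(k):
            var = covs[j]
            diff2 = (X - means[j]) ** 2
            out[:, j] = -0.5 * (d * _LOG2PI + np.sum(np.log(var)) + np.sum(diff2 / var, axis=1))
    return out


@dataclass
class MixtureFit:
    """One fitted Gaussian mixture with its BIC (larger is better)."""

    family: str
    n_components: int
    weights: np.ndarray
    means: np.ndarray
    covariances: list[np.ndarray]
    log_likelihood: float
    bic: float
    n_samples: int
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        logp = _log_gauss(X, self.means, self.covariances, self.family) + np.log(self.weights)
        return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.responsibilities(X), axis=1)


def _m_step(X: np.ndarray, resp: np.ndarray, family: str) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    n, d = X.shape
    nk = resp.sum(axis=0) + 1e-10
    weights = nk / nk.sum()
    means = (resp.T @ X) / nk[:, None]
    covs: list[np.ndarray] = []
    k = resp.shape[1]
    if family == "full":
        for j in range(k):
            diff = X - means[j]
            cov = (resp[:, j, None] * diff).T @ diff / nk[j]
            cov[np.diag_indices(d)] += VAR_FLOOR
            covs.append(cov)
    else:
        # per-component, per-dimension weighted squared deviations
        sq = np.stack([(resp[:, j, None] * (X - means[j]) ** 2).sum(axis=0) for j in range(k)])
        if family == "spherical_varying":
            var = sq.sum(axis=1) / (nk * d)
            covs = [np.full(d, max(v, VAR_FLOOR)) for v in var]
        elif family == "spherical_equal":
            v = max(sq.sum() / (n * d), VAR_FLOOR)
            covs = [np.full(d, v) for _ in range(k)]
        elif family == "diagonal_varying":
            covs = [np.maximum(sq[j] / nk[j], VAR_FLOOR) for j in range(k)]
        elif family == "diagonal_equal":
            shared = np.maximum(sq.sum(axis=0) / n, VAR_FLOOR)
            covs = [shared.copy() for _ in range(k)]
        else:
            raise ValueError(f"unknown family {family!r}")
    return weights, means, covs


def _em_single(
    X: np.ndarray, k: int, family: str, rng_seed: int,
    max_iter: int = 500, tol: float = 1e-8,
    start: tuple[np.ndarray, np.ndarray, list[np.ndarray]] | None = None,
    trace: list[float] | None = None,
) -> MixtureFit:
    n, d = X.shape
    if start is not None:
        weights, means, covs = start
    else:
        if k == 1:
            labels = np.zeros(n, dtype=int)
        else:
            labels = KMeans(n_clusters=k, n_init=1, random_state=rng_seed).fit_predict(X)
        resp = np.zeros((n, k))
        resp[np.arange(n), labels] = 1.0
        weights, means, covs = _m_step(X, resp, family)

    trace = list(trace) if trace else []
    converged = False
    prev = (weights, means, covs)
    for _ in range(max_iter):
        logp = _log_gauss(X, means, covs, family) + np.log(weights)
        lognorm = logsumexp(logp, axis=1)
        ll = float(lognorm.sum())
        if trace and ll < trace[-1] - 1e-7 * max(1.0, abs(trace[-1])):
            # the variance floor makes the M-step inexact for degenerate
            # components; when it binds hard enough to lower the likelihood,
            # stop and keep the previous (better) parameters
            weights, means, covs = prev
            converged = True
            break
        if trace and abs(ll - trace[-1]) < tol * max(1.0, abs(trace[-1])):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        prev = (weights, means, covs)
        resp = np.exp(logp - lognorm[:, None])
        weights, means, covs = _m_step(X, resp, family)

    p = (k - 1) + k * d + _n_cov_params(family, k, d)
    bic = 2.0 * trace[-1] - p * np.log(n)
    return MixtureFit(family, k, weights, means, covs, trace[-1], bic, n,
                      loglik_trace=trace, converged=converged)


def fit_mixture(
    profiles: pd.DataFrame | np.ndarray,
    k_range: tuple[int, int] = (2, 25),
    families: tuple[str, ...] = FAMILIES,
    seed: int = 0,
    n_init: int = 10,
    return_trace: bool = False,
) -> MixtureFit | tuple[MixtureFit, pd.DataFrame]:
    """Fit mixtures over all (family, K) and return the BIC-maximizing one.

    Each (family, K) gets ``n_init`` deterministic k-means-seeded EM runs;
    the run with the best log-likelihood represents that pair. When
    ``return_trace`` is set, the per-(family, K) BIC table is also returned.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValidationError("profiles must be a 2-D array")
    n = X.shape[0]
    k_min, k_max = k_range
    if k_min < 1 or k_max < k_min:
        raise ValidationError(f"invalid K range {k_range}")
    if n < 2 * k_max:
        raise ValidationError(f"n={n} too small for K up to {k_max} (need n >= 2*K)")
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValidationError(f"unknown families: {sorted(unknown)}")

    best: MixtureFit | None = None
    rows = []
    ss = np.random.SeedSequence(seed)
    for family in families:
        for k in range(k_min, k_max + 1):
            restart_seeds = ss.spawn(1)[0].generate_state(n_init) % (2**31 - 1)
            # short-run multistart: a few EM steps per seeded k-means start,
            # then only the best start is polished to convergence
            best_short: MixtureFit | None = None
            for rs in restart_seeds:
                fit = _em_single(X, k, family, int(rs), max_iter=25)
                if best_short is None or fit.log_likelihood > best_short.log_likelihood:
                    best_short = fit
            assert best_short is not None
            best_run = best_short
            if not best_short.converged:
                best_run = _em_single(
                    X, k, family, 0,
                    start=(best_short.weights, best_short.means, best_short.covariances),
                    trace=best_short.loglik_trace,
                )
            rows.append({"family": family, "K": k, "bic": best_run.bic,
                         "log_likelihood": best_run.log_likelihood})
            if best is None or best_run.bic > best.bic:
                best = best_run
    assert best is not None
    if return_trace:
        return best, pd.DataFrame(rows)
    return best


# -- responder categorization -------------------------------------------------


def classify_category(mean_profile: np.ndarray, regulation_threshold: float = 2.0) -> str:
    """Responder category from the earliest threshold-crossing time point."""
    v = np.asarray(mean_profile, dtype=float)
    if v.shape != (len(CANONICAL_TIMES),):
        raise ValidationError(f"profile must have {len(CANONICAL_TIMES)} values")
    cut = np.log2(regulation_threshold)
    for t, val in zip(CANONICAL_TIMES, v):
        if abs(val) >= cut:
            return _CATEGORY_BY_TIME[t]
    return "undetermined"


@dataclass
class TemporalCluster:
    cluster_id: int
    members: list[str]
    mean_profile: np.ndarray  # original log2 scale
    category: str

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class TemporalConfig:
    k_min: int = 2
    k_max: int = 25
    families: tuple[str, ...] = FAMILIES
    seed: int = 0
    n_init: int = 10
    regulation_threshold: float = 2.0
    classify_mode: str = "cluster"  # or "probe"


def temporal_pipeline(
    matrix: ExpressionMatrix, config: TemporalConfig = TemporalConfig()
) -> tuple[list[TemporalCluster], pd.DataFrame, pd.DataFrame]:
    """Scale -> mixture fit -> assign -> categorize for one cell line.

    ``matrix`` holds the cell-line-filter survivors of a single (cell line,
    ligand). Returns the clusters, a per-category summary table shaped like
    the temporal-cluster report (category, cluster ids, genes per cluster,
    totals) and the BIC trace. The effective K ceiling is capped at n//2.
    """
    pairs = {(e.cell_line, e.ligand) for e in matrix.events}
    if len(pairs) != 1:
        raise ValidationError("temporal clustering runs on one (cell line, ligand)")
    profiles = matrix.data.dropna(axis=0)
    scaled = scale_profiles(profiles)
    if scaled.empty:
        return [], _summary_frame([]), pd.DataFrame(columns=["family", "K", "bic", "log_likelihood"])
    n = scaled.shape[0]
    k_max = min(config.k_max, n // 2)
    if k_max < config.k_min:
        raise ValidationError(f"too few profiles (n={n}) for K >= {config.k_min}")
    best, trace = fit_mixture(
        scaled, (config.k_min, k_max), config.families,
        seed=config.seed, n_init=config.n_init, return_trace=True,
    )
    labels = best.predict(scaled.to_numpy(dtype=float))
    clusters: list[TemporalCluster] = []
    for j in range(best.n_components):
        members = list(scaled.index[labels == j])
        if not members:
            continue
        mean_profile = profiles.loc[members].to_numpy(dtype=float).mean(axis=0)
        cat = classify_category(mean_profile, config.regulation_threshold)
        clusters.append(TemporalCluster(len(clusters) + 1, members, mean_profile, cat))
    if config.classify_mode == "probe":
        # re-derive categories per probe and re-label clusters by majority
        for c in clusters:
            cats = [classify_category(profiles.loc[m].to_numpy(dtype=float),
                                      config.regulation_threshold) for m in c.members]
            c.category = max(CATEGORIES, key=cats.count)
    return clusters, _summary_frame(clusters), trace


def _summary_frame(clusters: list[TemporalCluster]) -> pd.DataFrame:
    rows = [
        {"category": cat,
         "cluster_ids": ";".join(str(c.cluster_id) for c in clusters if c.category == cat),
         "n_clusters": sum(c.category == cat for c in clusters),
         "n_probes": sum(c.size for c in clusters if c.category == cat)}
        for cat in CATEGORIES
    ]
    return pd.DataFrame(rows, columns=["category", "cluster_ids", "n_clusters", "n_probes"])


def probe_categories(clusters: list[TemporalCluster]) -> dict[str, str]:
    """probe_id -> category of its assigned cluster."""
    return {m: c.category for c in clusters for m in c.members}
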