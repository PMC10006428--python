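"""Gaussian-mixture analysis of paralog Ks distributions for WGD detection.

A whole-genome duplication leaves a synchronous burst of paralog pairs whose
Ks values form a hump in the genome-wide Ks distribution. The model fitted
here is a k-component univariate Gaussian mixture over Ks values inside a
fit range (default 0.05-5.0: the lower cutoff removes allelic/recent
duplicates, the upper removes saturated pairs). Out-of-range values are
discarded rather than modelled with a truncated likelihood — adequate for
locating the density summit, which is the quantity of interest.

The EM fit is written out in full (rather than delegated) so its defining
invariant — the log-likelihood never decreases across iterations — is
asserted on every step; scikit-learn's GaussianMixture serves as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import ValidationError
from .io_formats import KsRecord

_LOG_2PI = np.log(2.0 * np.pi)
_MIN_SD = 1e-3


@dataclass(frozen=True)
class KsMixtureFit:
    n_components: int
    weights: tuple
    means: tuple
    sds: tuple
    log_likelihood: float
    bic: float
    summit: float
    converged: bool
    fit_range: tuple
    n_used: int

    def density(self, x) -> np.ndarray:
        """Fitted mixture density evaluated at x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        w = np.asarray(self.weights)[:, None]
        m = np.asarray(self.means)[:, None]
        s = np.asarray(self.sds)[:, None]
        comp = np.exp(-0.5 * ((x[None, :] - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        return (w * comp).sum(axis=0)


def _as_values(ks) -> np.ndarray:
    if len(ks) and isinstance(ks[0], KsRecord):
        return np.array([r.ks for r in ks], dtype=float)
    return np.asarray(ks, dtype=float)


def _log_gauss(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    # (k, n) matrix of component log-densities
    z = (x[None, :] - means[:, None]) / sds[:, None]
    return -0.5 * z**2 - np.log(sds)[:, None] - 0.5 * _LOG_2PI


def _em_once(
    x: np.ndarray,
    init_means: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    k = len(init_means)
    n = len(x)
    means = init_means.copy()
    sds = np.full(k, max(x.std(), _MIN_SD))
    weights = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        log_comp = _log_gauss(x, means, sds) + np.log(weights)[:, None]
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(log_norm.sum())
        if ll < prev_ll - 1e-9:
            raise RuntimeError(
                f"EM log-likelihood decreased ({prev_ll:.10g} -> {ll:.10g})"
            )
        if ll - prev_ll < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        resp = np.exp(log_comp - log_norm[None, :])  # (k, n)
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp @ x) / nk
        var = (resp * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk
        sds = np.maximum(np.sqrt(var), _MIN_SD)
    return weights, means, sds, prev_ll, converged


def fit_ks_mixture(
    ks,
    n_components: int,
    fit_range: tuple[float, float] = (0.05, 5.0),
    n_starts: int = 10,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> KsMixtureFit:
    """EM-fit a Gaussian mixture to Ks values inside ``fit_range``.

    Best of ``n_starts`` seeded restarts (initial means drawn from data
    quantiles with jitter) by log-likelihood; convergence when the
    log-likelihood improves by less than ``tol``. Non-convergence is
    flagged on the returned fit, not raised.
    """
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    x = _as_values(ks)
    lo, hi = fit_range
    x = x[(x >= lo) & (x <= hi)]
    if len(x) < 10 * n_components:
        raise ValidationError(
            f"need >= {10 * n_components} Ks values in range, got {len(x)}"
        )
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        q = np.linspace(0.1, 0.9, n_components)
        init = np.quantile(x, q)
        if s > 0:  # first start is the plain quantile grid
            init = init + rng.normal(0.0, x.std() * 0.25, size=n_components)
            init = np.clip(init, lo, hi)
        weights, means, sds, ll, converged = _em_once(x, init, max_iter, tol)
        if best is None or ll > best[3]:
            best = (weights, means, sds, ll, converged)
    weights, means, sds, ll, converged = best
    order = np.argsort(means)
    weights, means, sds = weights[order], means[order], sds[order]
    n_params = 3 * n_components - 1
    bic = -2.0 * ll + n_params * np.log(len(x))
    fit = KsMixtureFit(
        n_components, tuple(weights), tuple(means), tuple(sds),
        ll, float(bic), float("nan"), converged, (lo, hi), len(x),
    )
    summit = density_summit(fit, search_range=(lo, hi))
    return KsMixtureFit(
        n_components, tuple(weights), tuple(means), tuple(sds),
        ll, float(bic), summit, converged, (lo, hi), len(x),
    )


def select_components(ks, k_max: int, seed: int | None = 0, **kwargs) -> KsMixtureFit:
    """Fit k = 1..k_max mixtures and return the minimum-BIC fit (ties -> smaller k)."""
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    best = None
    for k in range(1, k_max + 1):
        try:
            fit = fit_ks_mixture(ks, k, seed=seed, **kwargs)
        except ValidationError:
            break  # too few points for this and all larger k
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise ValidationError("no component count could be fitted")
    return best


def density_summit(
    fit: KsMixtureFit,
    search_range: tuple[float, float] | None = None,
    grid_step: float = 0.01,
) -> float:
    """Grid argmax of the fitted mixture density over ``search_range``."""
    lo, hi = search_range if search_range is not None else fit.fit_range
    if hi <= lo:
        raise ValidationError("empty search range")
    grid = np.arange(lo, hi + grid_step / 2.0, grid_step)
    dens = fit.density(grid)
    i = int(np.argmax(dens))
    if i in (0, len(grid) - 1):
        warnings.warn(
            f"density summit at search-range boundary ({grid[i]:.3g})",
            stacklevel=2,
        )
    return float(grid[i])


def compare_ortholog_ks(
    tables: dict[str, list],
    bins: int = 50,
    value_range: tuple[float, float] = (0.0, 5.0),
):
    """Common-binned density estimates of several Ks tables (for overlay plots).

    Returns a DataFrame with bin midpoints and one density column per table.
    """
    import pandas as pd

    if not tables:
        raise ValidationError("need at least one Ks table")
    edges = np.linspace(value_range[0], value_range[1], bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    out = {"ks_mid": mids}
    for name, recs in tables.items():
        x = _as_values(recs)
        dens, _ = np.histogram(x, bins=edges, density=True)
        out[name] = dens
    return pd.DataFrame(out)
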