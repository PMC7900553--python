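"""Pixel-color Gaussian mixture model and reference-based stain normalization.

The color distribution of an H&E slide is modeled as a 3-component Gaussian
mixture over pixel colors,

    P(x) = sum_n W_n * N(x | V_n, C_n),      0 <= W_n <= 1,  sum_n W_n = 1,

with one component each for nuclei (hematoxylin, dark blue-purple), cytoplasm
(eosin, pink) and background (white glass).  The mixture is fitted per slide
by expectation-maximization on the pixel colors; normalization hard-assigns
each pixel to its most responsible component and maps it to the matched
component of a reference slide's mixture by the whitening-coloring transform

    x' = V_ref + C_ref^{1/2} C_src^{-1/2} (x - V_src).

Colors live in RGB scaled to [0, 1] by default; optical density
(-log10((rgb+1)/256)) is available for fitting via ``color_space="od"``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger("histomut")

_LUMA = np.array([0.299, 0.587, 0.114])


class NotSPDError(np.linalg.LinAlgError):
    """A covariance matrix is not symmetric positive-definite."""


@dataclass
class StainGMM:
    """Mixture weights W, component color means V and covariances C."""

    weights: np.ndarray       # (N,)
    means: np.ndarray         # (N, 3)
    covariances: np.ndarray   # (N, 3, 3)
    color_space: str = "rgb"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.validate()

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def validate(self, eps: float = 1e-12) -> None:
        if np.any(self.weights < -eps) or np.any(self.weights > 1 + eps):
            raise ValueError("weights must lie in [0, 1]")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError(f"weights sum to {self.weights.sum()}, not 1")
        if self.means.shape != (self.n_components, 3):
            raise ValueError(f"means shape {self.means.shape}")
        if self.covariances.shape != (self.n_components, 3, 3):
            raise ValueError(f"covariances shape {self.covariances.shape}")
        for n, C in enumerate(self.covariances):
            if not np.allclose(C, C.T, atol=1e-10):
                raise NotSPDError(f"covariance {n} not symmetric")
            lo = float(np.linalg.eigvalsh(C)[0])
            if lo <= 0:
                raise NotSPDError(
                    f"covariance {n} not positive-definite "
                    f"(smallest eigenvalue {lo:.3e})"
                )


def _check_spd(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    lo = float(np.linalg.eigvalsh(C)[0])
    if not np.allclose(C, C.T, atol=1e-10) or lo <= 0:
        raise NotSPDError(
            f"matrix not SPD (smallest eigenvalue {lo:.3e})"
        )
    return C


def log_gaussian_pdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray
                     ) -> np.ndarray:
    """Log of the trivariate normal density, vectorized over rows of ``x``."""
    cov = _check_spd(cov)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    L = np.linalg.cholesky(cov)
    diff = x - np.asarray(mean, dtype=float)
    z = np.linalg.solve(L, diff.T)          # (3, n)
    maha = np.sum(z * z, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    d = x.shape[1]
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def gaussian_pdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray):
    """Trivariate normal density N(x | V, C); scalar for a single color."""
    out = np.exp(log_gaussian_pdf(x, mean, cov))
    return float(out[0]) if np.asarray(x).ndim == 1 else out


def _component_logpdfs(x: np.ndarray, model: StainGMM) -> np.ndarray:
    """(n_pixels, N) matrix of log W_n + log N(x | V_n, C_n)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    cols = [np.log(max(w, 1e-300)) + log_gaussian_pdf(x, m, c)
            for w, m, c in zip(model.weights, model.means, model.covariances)]
    return np.stack(cols, axis=1)


def mixture_density(x: np.ndarray, model: StainGMM):
    """P(x) = sum_n W_n N(x | V_n, C_n)."""
    lp = logsumexp(_component_logpdfs(x, model), axis=1)
    out = np.exp(lp)
    return float(out[0]) if np.asarray(x).ndim == 1 else out


def responsibilities(x: np.ndarray, model: StainGMM) -> np.ndarray:
    """Posterior component probabilities for each pixel (rows sum to 1).

    Computed in log space.  Pixels so far in the tails that every component
    density underflows are hard-assigned to the nearest component mean.
    """
    single = np.asarray(x).ndim == 1
    lp = _component_logpdfs(x, model)
    norm = logsumexp(lp, axis=1, keepdims=True)
    resp = np.exp(lp - norm)
    dead = ~np.isfinite(norm[:, 0])
    if np.any(dead):
        logger.warning("hard-assigning %d zero-density pixels to nearest mean",
                       int(dead.sum()))
        xv = np.atleast_2d(np.asarray(x, dtype=float))[dead]
        with np.errstate(over="ignore"):
            d2 = ((xv[:, None, :] - model.means[None]) ** 2).sum(-1)
        resp[dead] = 0.0
        resp[dead, d2.argmin(axis=1)] = 1.0
    return resp[0] if single else resp


def log_likelihood(pixels: np.ndarray, model: StainGMM) -> float:
    """Total data log-likelihood sum_k ln P(x_k), log-sum-exp stabilized."""
    pixels = np.atleast_2d(np.asarray(pixels, dtype=float))
    if len(pixels) == 0:
        raise ValueError("need at least one pixel")
    return float(logsumexp(_component_logpdfs(pixels, model), axis=1).sum())


@dataclass
class EMResult:
    model: StainGMM
    log_likelihood_trace: np.ndarray
    iterations: int
    converged: bool


def _floor_covariance(C: np.ndarray, eps: float) -> np.ndarray:
    """Clip covariance eigenvalues at eps (keeps C SPD under collapse)."""
    C = (C + C.T) / 2.0
    vals, vecs = np.linalg.eigh(C)
    if vals[0] < eps:
        vals = np.maximum(vals, eps)
        C = (vecs * vals) @ vecs.T
    return C


class ColorMixtureEM(BaseEstimator):
    """EM estimator for the pixel-color Gaussian mixture.

    Parameters
    ----------
    n_components : number of color classes (3: nucleus, cytoplasm, background).
    tol : relative log-likelihood change declaring convergence.
    max_iter : EM iteration cap.
    covariance_floor : eigenvalue floor applied to every covariance update.
    covariance_type : "full" or "diag".
    n_init : seeded random restarts tried in addition to the luminance-quantile
        initialization; the run with the best final log-likelihood is kept.
    random_state : seed for the restarts.

    Fitted attributes: ``weights_``, ``means_``, ``covariances_``,
    ``log_likelihood_trace_``, ``n_iter_``, ``converged_``.
    """

    def __init__(self, n_components: int = 3, tol: float = 1e-6,
                 max_iter: int = 200, covariance_floor: float = 1e-6,
                 covariance_type: str = "full", n_init: int = 3,
                 random_state: int | None = 0):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.covariance_floor = covariance_floor
        self.covariance_type = covariance_type
        self.n_init = n_init
        self.random_state = random_state

    # -- initialization -----------------------------------------------------

    def _init_luminance(self, X: np.ndarray) -> tuple[np.ndarray, ...]:
        luma = X @ _LUMA
        order = np.argsort(luma)
        groups = np.array_split(order, self.n_components)
        return self._moments_from_groups(X, groups)

    def _init_random(self, X: np.ndarray, rng: np.random.Generator):
        assign = rng.integers(0, self.n_components, size=len(X))
        groups = [np.where(assign == n)[0] for n in range(self.n_components)]
        return self._moments_from_groups(X, groups)

    def _moments_from_groups(self, X, groups):
        N = self.n_components
        W = np.empty(N)
        V = np.empty((N, 3))
        C = np.empty((N, 3, 3))
        for n, idx in enumerate(groups):
            pts = X[idx] if len(idx) else X
            W[n] = max(len(idx), 1) / len(X)
            V[n] = pts.mean(axis=0)
            C[n] = self._shape_cov(np.cov(pts.T) if len(pts) > 1
                                   else np.eye(3) * self.covariance_floor)
        W /= W.sum()
        return W, V, C

    def _shape_cov(self, C: np.ndarray) -> np.ndarray:
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape != (3, 3):
            C = np.eye(3) * float(C)
        if self.covariance_type == "diag":
            C = np.diag(np.diag(C))
        return _floor_covariance(C, self.covariance_floor)

    # -- EM ------------------------------------------------------------------

    def _run_em(self, X: np.ndarray, W, V, C) -> EMResult:
        trace = []
        converged = False
        for _ in range(self.max_iter):
            model = StainGMM(W, V, C)
            lp = _component_logpdfs(X, model)
            norm = logsumexp(lp, axis=1, keepdims=True)
            trace.append(float(norm.sum()))
            resp = np.exp(lp - norm)

            nk = resp.sum(axis=0)
            if np.any(nk < 1e-10):
                logger.warning("component collapse (n_k ~ 0); re-flooring")
                nk = np.maximum(nk, 1e-10)
            W = nk / nk.sum()
            V = (resp.T @ X) / nk[:, None]
            Cn = []
            for n in range(self.n_components):
                diff = X - V[n]
                cov = (resp[:, n, None] * diff).T @ diff / nk[n]
                Cn.append(self._shape_cov(cov))
            C = np.array(Cn)

            if len(trace) >= 2:
                prev, cur = trace[-2], trace[-1]
                if abs(cur - prev) <= self.tol * (abs(prev) + 1e-12):
                    converged = True
                    break
        final = StainGMM(W, V, C)
        trace.append(log_likelihood(X, final))
        return EMResult(final, np.asarray(trace), len(trace) - 1, converged)

    def fit(self, X: np.ndarray, y=None) -> "ColorMixtureEM":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if len(X) < 10 * self.n_components:
            raise ValueError(
                f"need at least {10 * self.n_components} pixels, got {len(X)}"
            )
        rng = np.random.default_rng(self.random_state)
        best: EMResult | None = None
        inits = [self._init_luminance(X)]
        inits += [self._init_random(X, rng) for _ in range(self.n_init)]
        for W, V, C in inits:
            res = self._run_em(X, W, V, C)
            if best is None or res.log_likelihood_trace[-1] > \
                    best.log_likelihood_trace[-1]:
                best = res
        self.weights_ = best.model.weights
        self.means_ = best.model.means
        self.covariances_ = best.model.covariances
        self.log_likelihood_trace_ = best.log_likelihood_trace
        self.n_iter_ = best.iterations
        self.converged_ = best.converged
        self.em_result_ = best
        return self

    def to_model(self, color_space: str = "rgb") -> StainGMM:
        return StainGMM(self.weights_, self.means_, self.covariances_,
                        color_space)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return responsibilities(X, self.to_model())

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(np.atleast_2d(X)).argmax(axis=1)

    def score(self, X: np.ndarray, y=None) -> float:
        return log_likelihood(X, self.to_model()) / len(np.atleast_2d(X))


def fit_gmm_em(pixels: np.ndarray, n_components: int = 3,
               seed: int | None = 0, tol: float = 1e-6,
               max_iter: int = 200, **kwargs) -> EMResult:
    """Functional wrapper over :class:`ColorMixtureEM`."""
    est = ColorMixtureEM(n_components=n_components, tol=tol,
                         max_iter=max_iter, random_state=seed, **kwargs)
    est.fit(pixels)
    return est.em_result_


# --- component matching and color transfer ----------------------------------


def _luminance_order(model: StainGMM) -> np.ndarray:
    """Component indices sorted by ascending luminance of means.

    Ties broken by green-channel mean, then by component index.
    """
    luma = model.means @ _LUMA
    keys = np.stack([luma, model.means[:, 1],
                     np.arange(model.n_components, dtype=float)])
    return np.lexsort((keys[2], keys[1], keys[0]))


def match_components(source: StainGMM, reference: StainGMM) -> np.ndarray:
    """Pair source components to reference components by luminance rank.

    Returns ``perm`` with ``perm[i]`` the reference component matched to
    source component ``i``.
    """
    if source.n_components != reference.n_components:
        raise ValueError("component counts differ")
    perm = np.empty(source.n_components, dtype=int)
    perm[_luminance_order(source)] = _luminance_order(reference)
    return perm


def _sqrtm_spd(C: np.ndarray, inverse: bool = False) -> np.ndarray:
    vals, vecs = np.linalg.eigh(np.asarray(C, dtype=float))
    if vals[0] <= 0:
        raise NotSPDError(
            f"matrix not SPD (smallest eigenvalue {vals[0]:.3e})"
        )
    r = vals ** (-0.5 if inverse else 0.5)
    return (vecs * r) @ vecs.T


def normalize_colors(image: np.ndarray, source: StainGMM,
                     reference: StainGMM, soft: bool = False,
                     keep_background: bool = False) -> np.ndarray:
    """Map a slide's colors onto the reference mixture, class by class.

    Each pixel is assigned to its argmax-responsibility source component
    (``soft=True`` blends the per-component maps by responsibility) and
    transformed by the matched reference component's whitening-coloring map.
    Output dtype and dimensions equal the input's; values are clipped to the
    valid color range.
    """
    img = np.asarray(image)
    as_uint8 = img.dtype == np.uint8
    X = img.reshape(-1, 3).astype(float) / (255.0 if as_uint8 else 1.0)

    perm = match_components(source, reference)
    resp = responsibilities(X, source)
    maps = []
    for n in range(source.n_components):
        try:
            A = _sqrtm_spd(reference.covariances[perm[n]]) @ \
                _sqrtm_spd(source.covariances[n], inverse=True)
        except NotSPDError as err:
            raise NotSPDError(f"component {n}: {err}") from err
        maps.append((X - source.means[n]) @ A.T + reference.means[perm[n]])

    if soft:
        out = sum(resp[:, n, None] * maps[n] for n in range(len(maps)))
    else:
        hard = resp.argmax(axis=1)
        out = np.empty_like(X)
        for n in range(len(maps)):
            sel = hard == n
            out[sel] = maps[n][sel]

    if keep_background:
        bg_src = int(_luminance_order(source)[-1])
        sel = resp.argmax(axis=1) == bg_src
        out[sel] = X[sel]

    out = np.clip(out, 0.0, 1.0)
    if as_uint8:
        out = np.round(out * 255.0).astype(np.uint8)
    return out.reshape(img.shape)


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Optical density transform of 8-bit RGB (absorbance-like space)."""
    return -np.log10((np.asarray(rgb, dtype=float) + 1.0) / 256.0)


class StainNormalizer(BaseEstimator, TransformerMixin):
    """Normalize slide colors to a reference image's color mixture.

    ``fit`` learns the reference mixture from a reference RGB image;
    ``transform`` fits a fresh source mixture on each input image (one model
    per slide) and maps its pixels onto the reference components.
    """

    def __init__(self, n_components: int = 3, n_init: int = 3,
                 soft: bool = False, keep_background: bool = False,
                 random_state: int | None = 0):
        self.n_components = n_components
        self.n_init = n_init
        self.soft = soft
        self.keep_background = keep_background
        self.random_state = random_state

    def _fit_pixels(self, image: np.ndarray) -> StainGMM:
        X = np.asarray(image).reshape(-1, 3).astype(float)
        if X.max() > 1.0:
            X = X / 255.0
        est = ColorMixtureEM(n_components=self.n_components,
                             n_init=self.n_init,
                             random_state=self.random_state)
        return est.fit(X).to_model()

    def fit(self, reference_image: np.ndarray, y=None) -> "StainNormalizer":
        self.reference_model_ = self._fit_pixels(reference_image)
        return self

    def transform(self, image: np.ndarray) -> np.ndarray:
        source = self._fit_pixels(image)
        return normalize_colors(image, source, self.reference_model_,
                                soft=self.soft,
                                keep_background=self.keep_background)
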