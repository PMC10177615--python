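"""REML mixed-model fitting and per-marker association tests.

The model is  y = W v + SNP_i + Z u + e,  u ~ N(0, K_g Vg),  e ~ N(0, I Ve),
where Z (n × n′) maps individuals to compression groups and K_g (n′ × n′)
is the group kinship.  The covariance of y is V = Z K_g Zᵀ Vg + I Ve.

Fitting profiles the variance ratio λ = Vg/Ve on the spectral decomposition
of G = Z K_g Zᵀ: with G = U diag(s) Uᵀ, rotating by Uᵀ makes V diagonal up
to the scale Ve, so the restricted likelihood is a cheap one-dimensional
function of λ.  Marker tests are generalized least squares under the fitted
covariance structure; in P3D mode the null-model λ is reused for every
marker while the residual scale is re-profiled per marker, so the statistic
reduces exactly to the ordinary F-test when Vg = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import GenotypeMatrix
from .kinship import CompressedKinship, CovariateMatrix

logger = logging.getLogger(__name__)

LAMBDA_GRID = np.logspace(-5, 5, 100)

ASSOC_COLUMNS = ["id", "chrom", "pos", "effect", "se", "stat", "p"]


@dataclass
class VarianceComponents:
    """Additive genetic (Vg) and residual (Ve) variances, trait units²."""

    vg: float
    ve: float

    def __post_init__(self) -> None:
        if self.vg < 0:
            raise ValueError("Vg must be >= 0")
        if self.ve <= 0:
            raise ValueError("Ve must be > 0")


@dataclass
class MixedModelFit:
    components: VarianceComponents
    neg2ll: float
    fixed_effects: np.ndarray
    random_effects: np.ndarray
    residuals: np.ndarray

    @property
    def heritability(self) -> float:
        """Vg / (Vg + Ve) — the fraction of variance assigned to the group term."""
        return self.components.vg / (self.components.vg + self.components.ve)


def _spectral(ck: CompressedKinship) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of G = Z K_g Zᵀ with a PSD guard."""
    g = ck.individual_covariance()
    s, u = np.linalg.eigh((g + g.T) / 2.0)
    if s.min() < -1e-8:
        raise ValueError(
            f"compressed covariance not PSD (min eigenvalue {s.min():.3e})"
        )
    return np.clip(s, 0.0, None), u


def _check_design(w: np.ndarray) -> int:
    p = np.linalg.matrix_rank(w)
    if p < w.shape[1]:
        raise ValueError("covariate design matrix W is rank deficient")
    return p


def _profile_neg2ll(
    lam: float, s: np.ndarray, yt: np.ndarray, wt: np.ndarray, logdet_wtw: float
) -> tuple[float, float, np.ndarray]:
    """−2 REML log-likelihood at ratio λ, with Ve profiled out.

    Returns (neg2ll, ve_hat, beta_hat) in the rotated basis.
    """
    n, p = wt.shape
    h = lam * s + 1.0
    sqw = 1.0 / np.sqrt(h)
    a = wt * sqw[:, None]
    b = yt * sqw
    ata = a.T @ a
    beta = np.linalg.solve(ata, a.T @ b)
    rss = float(np.sum((b - a @ beta) ** 2))
    ve = rss / (n - p)
    sign, logdet_awa = np.linalg.slogdet(ata)
    if sign <= 0 or ve <= 0:
        return np.inf, np.nan, beta
    neg2 = (
        (n - p) * (np.log(2.0 * np.pi * ve) + 1.0)
        + float(np.sum(np.log(h)))
        + logdet_awa
        - logdet_wtw
    )
    return neg2, ve, beta


def fit_null_reml(
    y: np.ndarray, w: CovariateMatrix | np.ndarray, ck: CompressedKinship
) -> MixedModelFit:
    """REML fit of the null (no-marker) mixed model.

    λ = Vg/Ve is profiled over a 100-point log grid on [1e−5, 1e5] and
    refined by bounded scalar minimisation to 1e−8.
    """
    wmat = w.values if isinstance(w, CovariateMatrix) else np.asarray(w, float)
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values; drop them first")
    _check_design(wmat)
    s, u = _spectral(ck)
    yt = u.T @ y
    wt = u.T @ wmat
    _, logdet_wtw = np.linalg.slogdet(wmat.T @ wmat)

    vals = np.array(
        [_profile_neg2ll(l, s, yt, wt, logdet_wtw)[0] for l in LAMBDA_GRID]
    )
    i = int(np.argmin(vals))
    lo = LAMBDA_GRID[max(i - 1, 0)]
    hi = LAMBDA_GRID[min(i + 1, len(LAMBDA_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda l: _profile_neg2ll(l, s, yt, wt, logdet_wtw)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(res.x) if res.fun <= vals[i] else float(LAMBDA_GRID[i])
    neg2, ve, beta_rot = _profile_neg2ll(lam, s, yt, wt, logdet_wtw)
    vg = lam * ve

    # back-transform: BLUPs of group effects and individual residuals
    vinv_diag = 1.0 / (ve * (lam * s + 1.0))
    r = y - wmat @ beta_rot  # beta in original basis equals rotated solution
    vinv_r = u @ (vinv_diag * (u.T @ r))
    u_blup = vg * ck.group_values @ ck.incidence.T @ vinv_r
    resid = r - ck.incidence @ u_blup
    return MixedModelFit(
        components=VarianceComponents(vg=vg, ve=ve),
        neg2ll=float(neg2),
        fixed_effects=beta_rot,
        random_effects=u_blup,
        residuals=resid,
    )


def neg2_restricted_loglik(
    y: np.ndarray,
    w: CovariateMatrix | np.ndarray,
    ck: CompressedKinship,
    vc: VarianceComponents,
) -> float:
    """Exact −2 × REML log-likelihood at the supplied variance components.

    Dense-matrix evaluation of
    (n−p) log 2π + log|V| + log|WᵀV⁻¹W| − log|WᵀW| + yᵀPy,
    consistent with the profiled objective of :func:`fit_null_reml`.
    """
    if vc.ve <= 0:
        raise ValueError("Ve must be > 0")
    wmat = w.values if isinstance(w, CovariateMatrix) else np.asarray(w, float)
    y = np.asarray(y, dtype=float)
    n, p = wmat.shape
    v = vc.vg * ck.individual_covariance() + vc.ve * np.eye(n)
    _, logdet_v = np.linalg.slogdet(v)
    vinv_w = np.linalg.solve(v, wmat)
    vinv_y = np.linalg.solve(v, y)
    wvw = wmat.T @ vinv_w
    _, logdet_wvw = np.linalg.slogdet(wvw)
    _, logdet_wtw = np.linalg.slogdet(wmat.T @ wmat)
    beta = np.linalg.solve(wvw, wmat.T @ vinv_y)
    r = y - wmat @ beta
    ypy = float(r @ np.linalg.solve(v, r))
    return float(
        (n - p) * np.log(2.0 * np.pi) + logdet_v + logdet_wvw - logdet_wtw + ypy
    )


def _gls_marker_test(
    a_w: np.ndarray, b: np.ndarray, xt_scaled: np.ndarray
) -> tuple[float, float, float, float]:
    """Weighted LS of b on [a_w, x]; returns (effect, se, F, p) for x.

    The residual scale is estimated from this model's own fit with
    n − p − 1 degrees of freedom, so λ = 0 reproduces the OLS F-test.
    """
    n, p = a_w.shape
    x = np.column_stack([a_w, xt_scaled])
    xtx = x.T @ x
    # collinearity / zero-variance guard via conditioning of the last pivot
    try:
        c = np.linalg.cholesky(xtx)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan, np.nan
    if c[-1, -1] ** 2 < 1e-10 * max(xtx[-1, -1], 1e-300):
        return np.nan, np.nan, np.nan, np.nan
    beta = np.linalg.solve(xtx, x.T @ b)
    rss = float(np.sum((b - x @ beta) ** 2))
    df = n - p - 1
    if df <= 0:
        return np.nan, np.nan, np.nan, np.nan
    sigma2 = rss / df
    xtx_inv_last = np.linalg.inv(xtx)[-1, -1]
    se = np.sqrt(sigma2 * xtx_inv_last)
    effect = float(beta[-1])
    if se == 0:
        return effect, np.nan, np.nan, np.nan
    f = (effect / se) ** 2
    pval = float(stats.f.sf(f, 1, df))
    return effect, float(se), float(f), pval


def scan_markers(
    y: np.ndarray,
    w: CovariateMatrix | np.ndarray,
    g: GenotypeMatrix,
    ck: CompressedKinship,
    mode: str = "P3D",
    null_fit: MixedModelFit | None = None,
    markers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Test each marker in ``g`` under the compressed mixed model.

    ``P3D`` reuses the null fit's variance ratio for every marker; ``full``
    re-optimises λ per marker.  Markers collinear with W (including
    zero-variance markers) yield a missing p-value and are counted.
    Returns a table with columns id, chrom, pos, effect, se, stat, p.
    """
    if mode not in ("P3D", "full"):
        raise ValueError("mode must be 'P3D' or 'full'")
    wmat = w.values if isinstance(w, CovariateMatrix) else np.asarray(w, float)
    y = np.asarray(y, dtype=float)
    codes = g.codes
    if np.isnan(codes).any():
        raise ValueError("scan requires imputed dosages")
    s, u = _spectral(ck)
    yt = u.T @ y
    wt = u.T @ wmat
    xt_all = u.T @ codes
    _, logdet_wtw = np.linalg.slogdet(wmat.T @ wmat)

    if mode == "P3D":
        if null_fit is None:
            null_fit = fit_null_reml(y, wmat, ck)
        lam = null_fit.components.vg / null_fit.components.ve

    out = np.empty((codes.shape[1], 4))
    for j in range(codes.shape[1]):
        if mode == "full":
            wx = np.column_stack([wmat, codes[:, j]])
            if np.linalg.matrix_rank(wx) < wx.shape[1]:
                out[j] = (np.nan, np.nan, np.nan, np.nan)
                continue
            wxt = u.T @ wx
            _, ld = np.linalg.slogdet(wx.T @ wx)
            grid = [
                _profile_neg2ll(l, s, yt, wxt, ld)[0] for l in LAMBDA_GRID
            ]
            i = int(np.argmin(grid))
            res = optimize.minimize_scalar(
                lambda l: _profile_neg2ll(l, s, yt, wxt, ld)[0],
                bounds=(
                    LAMBDA_GRID[max(i - 1, 0)],
                    LAMBDA_GRID[min(i + 1, len(LAMBDA_GRID) - 1)],
                ),
                method="bounded",
                options={"xatol": 1e-8},
            )
            lam_j = float(res.x) if res.fun <= grid[i] else float(LAMBDA_GRID[i])
        else:
            lam_j = lam
        sqw = 1.0 / np.sqrt(lam_j * s + 1.0)
        out[j] = _gls_marker_test(wt * sqw[:, None], yt * sqw, xt_all[:, j] * sqw)

    n_failed = int(np.isnan(out[:, 3]).sum())
    if n_failed:
        logger.info("scan_markers: %d markers untestable (collinear/constant)", n_failed)
    if markers is not None:
        base = markers[["id", "chrom", "pos"]].reset_index(drop=True)
    else:
        base = pd.DataFrame(
            {
                "id": [f"m{j}" for j in range(codes.shape[1])],
                "chrom": "0",
                "pos": np.arange(codes.shape[1]),
            }
        )
    return pd.concat(
        [base, pd.DataFrame(out, columns=["effect", "se", "stat", "p"])], axis=1
    )
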