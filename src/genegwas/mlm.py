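"""Single-marker mixed linear model scan.

Model per SNP: ``Y = X beta + W v + Z mu + e`` with
``mu ~ N(0, sigma2_g K)`` (``K`` the VanRaden kinship) and
``e ~ N(0, sigma2_e I)``. Variance components are estimated once by
REML on the null model (no SNP) and reused for every marker — the
"population parameters previously determined" (P3D) shortcut — and each
SNP effect is then tested by generalized least squares with a two-sided
t-test. The random effect is fitted at the individual level (``Z = I``);
no compression of individuals into groups is applied, which is stated in
the result metadata.

The REML fit uses the eigendecomposition ``K = U D U'``: rotating the
data by ``U'`` diagonalizes the covariance, reducing REML to a
one-dimensional optimization over the heritability ratio, and the same
rotation turns every per-SNP GLS fit into a cheap weighted OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

from .containers import DegenerateInputError, GenotypeMatrix, logger
from .qc import minor_allele_frequency
from .structure import KinshipMatrix

__all__ = [
    "VarianceComponents",
    "SnpTestResult",
    "kinship_eigendecomposition",
    "fit_variance_components",
    "snp_scan",
    "suggestive_threshold",
]


@dataclass
class VarianceComponents:
    """REML estimates on the null model, reused across the scan (P3D)."""

    sigma2_g: float
    sigma2_e: float
    heritability: float
    log_restricted_likelihood: float
    eigenvalues: np.ndarray = field(repr=False)
    rotation: np.ndarray = field(repr=False)  # U' (n x n)
    boundary: bool = False  # sigma2_g pinned at ~0 -> scan reduces to OLS
    compression: str = "none (individual-level random effect)"


@dataclass
class SnpTestResult:
    """Per-SNP association result of the mixed-model scan."""

    snp_id: str
    chrom: str
    pos_bp: int
    effect: float
    se: float
    t_stat: float
    p_value: float
    maf: float


def _check_kinship(k: KinshipMatrix | np.ndarray) -> np.ndarray:
    values = k.values if isinstance(k, KinshipMatrix) else np.asarray(k, dtype=np.float64)
    if not np.allclose(values, values.T, atol=1e-8):
        raise DegenerateInputError("kinship matrix is not symmetric")
    return (values + values.T) / 2.0


def kinship_eigendecomposition(
    k: KinshipMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose K once for reuse across many REML fits.

    Returns ``(eigenvalues, U)``; negative eigenvalues below ``-1e-6``
    raise, smaller ones are clipped to zero.
    """
    values = _check_kinship(k)
    d, u = np.linalg.eigh(values)
    if d.min() < -1e-6:
        raise DegenerateInputError(
            f"kinship matrix is not PSD (min eigenvalue {d.min():.3g})"
        )
    return np.clip(d, 0.0, None), u


def fit_variance_components(
    y: np.ndarray,
    x: np.ndarray,
    k: KinshipMatrix | np.ndarray | None = None,
    tol: float = 1e-8,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """REML estimation of (sigma2_g, sigma2_e) for a single random effect.

    Parametrized by heritability ``h`` with total variance profiled out:
    ``Var(y) = sigma2 * (h K + (1 - h) I)``. The restricted likelihood is
    maximized over ``h`` in (0, 1) by bounded scalar optimization on the
    rotated data. Eigenvalues of K below ``-1e-6`` raise; small negative
    ones are clipped to zero.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[0] != y.shape[0]:
        x = x.T
    n, q = x.shape
    if np.linalg.matrix_rank(x) < q:
        raise DegenerateInputError("fixed-effect design X is rank deficient")
    if eig is None:
        if k is None:
            raise DegenerateInputError("provide either a kinship matrix or its eigendecomposition")
        eig = kinship_eigendecomposition(k)
    d, u = eig
    ut = u.T
    ys = ut @ y
    xs = ut @ x

    def neg_restricted_ll(h: float) -> float:
        w = h * d + (1.0 - h)  # rotated covariance diagonal
        wi = 1.0 / w
        xtwx = xs.T @ (xs * wi[:, None])
        xtwy = xs.T @ (ys * wi)
        beta = np.linalg.solve(xtwx, xtwy)
        resid = ys - xs @ beta
        rss = float(resid @ (resid * wi))
        sigma2 = rss / (n - q)
        _, logdet_xtwx = np.linalg.slogdet(xtwx)
        ll = -0.5 * (
            (n - q) * np.log(sigma2)
            + np.sum(np.log(w))
            + logdet_xtwx
            + (n - q)
        )
        return -ll

    res = scipy.optimize.minimize_scalar(
        neg_restricted_ll, bounds=(1e-9, 1.0 - 1e-9), method="bounded",
        options={"xatol": tol},
    )
    h = float(res.x)
    w = h * d + (1.0 - h)
    wi = 1.0 / w
    xtwx = xs.T @ (xs * wi[:, None])
    beta = np.linalg.solve(xtwx, xs.T @ (ys * wi))
    resid = ys - xs @ beta
    sigma2 = float(resid @ (resid * wi)) / (n - q)

    boundary = h < 1e-4
    if boundary:
        warnings.warn(
            "sigma2_g estimated at the zero boundary; scan reduces to OLS",
            stacklevel=2,
        )
    logger.info("REML: h2=%.4f sigma2_g=%.4f sigma2_e=%.4f", h, h * sigma2, (1 - h) * sigma2)
    return VarianceComponents(
        sigma2_g=h * sigma2,
        sigma2_e=(1.0 - h) * sigma2,
        heritability=h,
        log_restricted_likelihood=-float(res.fun),
        eigenvalues=d,
        rotation=ut,
        boundary=boundary,
    )


def snp_scan(
    y: np.ndarray,
    x: np.ndarray,
    g: GenotypeMatrix,
    vc: VarianceComponents,
) -> list[SnpTestResult]:
    """GLS scan of every SNP with the P3D variance components.

    Each SNP's dosage column (mean-imputed) is appended to the fixed
    design; the rotated, whitened regression gives the effect estimate,
    its standard error from the per-SNP residual mean square, and a
    two-sided t-test on ``n - rank(X) - 1`` degrees of freedom.
    Monomorphic SNPs are skipped with a warning.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[0] != y.shape[0]:
        x = x.T
    n, q = x.shape
    if g.n_individuals != n:
        raise DegenerateInputError("genotypes and phenotypes have different n")

    h = vc.heritability
    w = h * vc.eigenvalues + (1.0 - h)
    sw = 1.0 / np.sqrt(w)
    ut = vc.rotation
    yw = (ut @ y) * sw
    xw = (ut @ x) * sw[:, None]
    dosage = g.dosages(impute=True)
    gw = (ut @ dosage) * sw[:, None]

    maf = minor_allele_frequency(g)
    df = n - q - 1
    if df < 1:
        raise DegenerateInputError(f"not enough residual degrees of freedom (df={df})")

    # residualize SNP columns and the trait against the whitened X once
    qx, _ = np.linalg.qr(xw)
    y_res = yw - qx @ (qx.T @ yw)
    g_res = gw - qx @ (qx.T @ gw)

    results: list[SnpTestResult] = []
    gg = np.einsum("ij,ij->j", g_res, g_res)
    gy = g_res.T @ y_res
    yy = float(y_res @ y_res)
    for j in range(g.n_snps):
        if g.codes[:, j][g.codes[:, j] >= 0].std() == 0:
            warnings.warn(f"monomorphic SNP {g.snp_ids[j]} skipped", stacklevel=2)
            continue
        vhat = gy[j] / gg[j]
        rss = yy - vhat * gy[j]
        se = float(np.sqrt(max(rss, 0.0) / df / gg[j]))
        if se == 0.0:
            t_stat, p = np.inf, 0.0
        else:
            t_stat = vhat / se
            p = float(2.0 * scipy.stats.t.sf(abs(t_stat), df=df))
        results.append(
            SnpTestResult(
                snp_id=str(g.snp_ids[j]),
                chrom=str(g.chrom[j]),
                pos_bp=int(g.pos_bp[j]),
                effect=float(vhat),
                se=se,
                t_stat=float(t_stat),
                p_value=max(p, np.finfo(float).tiny),
                maf=float(maf[j]),
            )
        )
    return results


def suggestive_threshold(n_snps: int) -> tuple[float, float]:
    """Suggestive (``1/m``) and strict Bonferroni (``0.05/m``) thresholds.

    The suggestive level expects one false positive per genome scan and
    is the customary fallback when the strict level leaves no power.
    """
    if n_snps < 1:
        raise DegenerateInputError("n_snps must be >= 1")
    return 1.0 / n_snps, 0.05 / n_snps
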