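"""Single-marker mixed-model association (SMMA).

Per-SNP fixed-effect tests in ``y = mu*1 + x_j*gamma_j + epsilon`` with
``Var(epsilon) = sigma_g^2 A + sigma_e^2 I``.  Variance components are
estimated once by REML under the null (no SNP) model and then held fixed for
every SNP, so each test is a two-parameter generalized least squares fit in
the eigenbasis of A.  The residual scale is re-estimated per SNP (the
correlation structure stays fixed), which makes the scan reduce exactly to
ordinary least-squares t-statistics with normal p-values when
``sigma_g^2 = 0``.  Used both as a stand-alone association method and as the
stage-1 prescreen for the multi-SNP fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinship import AMatrix
from .panel import PhenotypeVector, SNPPanel


class SMMAError(ValueError):
    pass


@dataclass
class VarianceComponents:
    """REML estimates of the polygenic and residual variances."""

    sigma_g2: float
    sigma_e2: float
    log_likelihood: float
    boundary: bool = False       # delta hit the optimization bounds
    identifiable: bool = True    # False when A ~ c*I (ratio not identified)


@dataclass
class SMMAResult:
    """Per-SNP association table plus the null-model variance components."""

    table: pd.DataFrame  # columns: snp, chrom, pos, beta, se, p, tested
    vc: VarianceComponents

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    @property
    def neg_log10_p(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return -np.log10(self.p_values)


def _phenotype_values(y: PhenotypeVector | np.ndarray, A: AMatrix) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        pos = {iid: k for k, iid in enumerate(y.individual_ids)}
        try:
            return np.array([y.values[pos[i]] for i in A.id_order])
        except KeyError as e:
            raise SMMAError(f"phenotype missing for individual {e.args[0]!r}") from None
    vals = np.asarray(y, dtype=float).ravel()
    if vals.size != A.n:
        raise SMMAError(f"phenotype length {vals.size} != A dimension {A.n}")
    return vals


DELTA_BOUNDS = (1e-5, 1e5)  # delta = sigma_e2 / sigma_g2


def fit_null_reml(y: PhenotypeVector | np.ndarray, A: AMatrix) -> VarianceComponents:
    """REML fit of ``y = mu*1 + g + e``, ``g ~ N(0, sigma_g2 A)``.

    The likelihood is profiled over the variance ratio
    ``delta = sigma_e2/sigma_g2`` using the eigendecomposition of A, and
    maximized by bounded scalar optimization of log(delta) on
    ``[1e-5, 1e5]``.  A boundary solution and the ``A ~ c*I``
    non-identifiable case are flagged, not errors.
    """
    yv = _phenotype_values(y, A)
    n = yv.size
    if n < 3:
        raise SMMAError("need at least 3 individuals for REML")
    if np.ptp(yv) == 0.0:
        raise SMMAError("constant phenotype: variance components undefined")
    d, u = A.eig()
    identifiable = bool(np.ptp(d) > 1e-9 * max(1.0, d.max()))
    yt = u.T @ yv
    ot = u.T @ np.ones(n)

    def neg_restricted_ll(log_delta: float) -> float:
        w = d + np.exp(log_delta)
        s11 = np.sum(ot * ot / w)
        mu = np.sum(ot * yt / w) / s11
        rss = np.sum((yt - mu * ot) ** 2 / w)
        sg2 = rss / (n - 1)
        ll = -0.5 * ((n - 1) * np.log(sg2) + np.sum(np.log(w)) + np.log(s11) + (n - 1))
        if not np.isfinite(ll):
            raise SMMAError("non-finite REML log-likelihood")
        return -ll

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(np.log(DELTA_BOUNDS[0]), np.log(DELTA_BOUNDS[1])),
        method="bounded", options={"xatol": 1e-10})
    log_delta = float(res.x)
    delta = float(np.exp(log_delta))
    boundary = (log_delta < np.log(DELTA_BOUNDS[0]) + 1e-3
                or log_delta > np.log(DELTA_BOUNDS[1]) - 1e-3)
    w = d + delta
    s11 = np.sum(ot * ot / w)
    mu = np.sum(ot * yt / w) / s11
    sg2 = float(np.sum((yt - mu * ot) ** 2 / w) / (n - 1))
    return VarianceComponents(sigma_g2=sg2, sigma_e2=sg2 * delta,
                              log_likelihood=-float(res.fun),
                              boundary=boundary, identifiable=identifiable)


class SMMAScanner:
    """Fixed-variance GLS scan with precomputed rotation (fast re-scans).

    Rotating the design into the eigenbasis of A is done once at
    construction; scanning a new phenotype (e.g. a permutation) costs
    O(n^2 + n p).
    """

    def __init__(self, X: np.ndarray, A: AMatrix, vc: VarianceComponents):
        self.X = np.asarray(X, dtype=float)
        n, p = self.X.shape
        if n != A.n:
            raise SMMAError("genotype rows do not match A")
        d, self.u = A.eig()
        self.w = 1.0 / (vc.sigma_g2 * d + vc.sigma_e2)  # GLS weights in eigenbasis
        if not np.all(np.isfinite(self.w)):
            raise SMMAError("degenerate variance components (zero total variance)")
        self.n = n
        self.tested = np.ptp(self.X, axis=0) > 0  # monomorphic SNPs are not tested
        self.Xt = self.u.T @ self.X
        self.ot = self.u.T @ np.ones(n)
        self.s11 = float(np.sum(self.w * self.ot**2))
        self.s1x = ((self.w * self.ot)[:, None] * self.Xt).sum(axis=0)
        self.sxx = (self.w[:, None] * self.Xt**2).sum(axis=0)

    def scan(self, y_values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (beta, se, p) arrays for one phenotype vector."""
        yt = self.u.T @ np.asarray(y_values, dtype=float)
        s1y = float(np.sum(self.w * self.ot * yt))
        sxy = (self.w[:, None] * self.Xt * yt[:, None]).sum(axis=0)
        syy = float(np.sum(self.w * yt**2))
        det = self.s11 * self.sxx - self.s1x**2
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = (self.s11 * sxy - self.s1x * s1y) / det
            mu = (s1y - self.s1x * beta) / self.s11
            rss = syy - mu * s1y - beta * sxy  # weighted RSS via normal equations
            sigma2 = np.maximum(rss, 0.0) / (self.n - 2)
            se = np.sqrt(sigma2 * self.s11 / det)
            z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        beta = np.where(self.tested, beta, np.nan)
        se = np.where(self.tested, se, np.nan)
        p = np.where(self.tested, p, np.nan)
        return beta, se, p

    def neg_log10_p_stat(self, y_values: np.ndarray) -> np.ndarray:
        """Per-SNP -log10 p statistic (permutation-threshold statistic)."""
        _, _, p = self.scan(y_values)
        with np.errstate(divide="ignore"):
            return -np.log10(p)


def smma_scan(y: PhenotypeVector | np.ndarray, panel: SNPPanel, A: AMatrix,
              vc: VarianceComponents, X: np.ndarray | None = None) -> SMMAResult:
    """Scan every SNP of the panel against the phenotype.

    ``vc`` must come from :func:`fit_null_reml` on the same phenotype/A.  An
    already mean-imputed genotype matrix may be passed as ``X`` to skip
    re-imputation.  Monomorphic SNPs are flagged untested with NaN results.
    """
    from .panel import mean_impute

    yv = _phenotype_values(y, A)
    if X is None:
        X, _ = mean_impute(panel)
    scanner = SMMAScanner(X, A, vc)
    beta, se, p = scanner.scan(yv)
    table = pd.DataFrame({
        "snp": panel.snp_map["name"],
        "chrom": panel.snp_map["chrom"],
        "pos": panel.snp_map["pos"],
        "beta": beta, "se": se, "p": p,
        "tested": scanner.tested,
    })
    return SMMAResult(table=table, vc=vc)


def prescreen(result: SMMAResult, k: int = 500) -> np.ndarray:
    """Indices of the k smallest p-values, ties broken by genome order.

    Untested SNPs are never selected.  If fewer than k SNPs were tested, all
    tested SNPs are returned with a warning.
    """
    if k < 1:
        raise SMMAError("k must be >= 1")
    p = result.p_values.copy()
    p[~result.table["tested"].to_numpy()] = np.inf
    p[np.isnan(p)] = np.inf
    n_tested = int(np.sum(np.isfinite(p)))
    if k > n_tested:
        warnings.warn(f"prescreen k={k} exceeds {n_tested} tested SNPs; returning all",
                      stacklevel=2)
        k = n_tested
    order = np.argsort(p, kind="stable")  # stable: ties keep genome order
    return np.sort(order[:k])
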