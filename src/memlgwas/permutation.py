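"""Genome-wide significance thresholds by phenotype permutation.

The phenotype vector is shuffled across individuals — breaking both the
genotype-phenotype and the pedigree-phenotype links — the association
procedure is rerun on the same SNP subset, and the maximum per-SNP statistic
is recorded.  The threshold is the empirical (1 - alpha) quantile (type-7
interpolation) of the null maxima.  Note the shuffle also destroys the
polygenic covariance structure; this exchangeable null is a documented
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


class PermutationError(RuntimeError):
    pass


@dataclass
class PermutationResult:
    null_maxima: np.ndarray
    threshold: float
    alpha: float
    n_perm: int
    seed: int | None


def permutation_threshold(y_values: np.ndarray,
                          statistic: Callable[[np.ndarray], np.ndarray],
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int | None = None,
                          rng: np.random.Generator | None = None) -> PermutationResult:
    """Empirical family-wise threshold for a per-SNP statistic.

    Parameters
    ----------
    y_values
        Phenotype vector in the individual order the statistic expects.
    statistic
        Maps a phenotype vector to the per-SNP statistic vector (e.g. MEML
        SNP heritabilities, or -log10 p from the SMMA scan).  The SNP subset
        is whatever the callable was built on and is held fixed across
        permutations.
    n_perm, alpha
        Number of phenotype shuffles and the family-wise level.

    A failing permutation is retried with a fresh shuffle at most 3 times.
    Fully reproducible given ``seed`` (or an explicit ``rng``).
    """
    if n_perm < 1:
        raise PermutationError("n_perm must be >= 1")
    if not (0.0 < alpha <= 1.0):
        raise PermutationError("alpha must be in (0, 1]")
    y_values = np.asarray(y_values, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        last_err: Exception | None = None
        for _attempt in range(4):  # 1 try + 3 retries
            perm = rng.permutation(y_values.size)
            try:
                stats_b = np.asarray(statistic(y_values[perm]), dtype=float)
                maxima[b] = np.nanmax(stats_b)
                last_err = None
                break
            except Exception as e:  # noqa: BLE001 - fitter failures are retried
                last_err = e
        if last_err is not None:
            raise PermutationError(
                f"permutation {b} failed after 3 retries: {last_err}") from last_err
    threshold = float(np.quantile(maxima, 1.0 - alpha, method="linear"))
    return PermutationResult(null_maxima=maxima, threshold=threshold,
                             alpha=alpha, n_perm=n_perm, seed=seed)
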