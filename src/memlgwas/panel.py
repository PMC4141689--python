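"""Genotype, phenotype and pedigree containers plus SNP/individual quality control.

Genotypes are additively coded ``1 / 0 / -1`` for ``AA / Aa / aa`` and held in a
dense float matrix with ``NaN`` marking missing calls.  The "A" allele is, by
default, the major allele of each SNP (lexicographically smaller allele on a
tie), so the per-SNP frequency ``p_j`` returned by :func:`allele_freq` is the
major-allele frequency and ``1 - p_j`` the MAF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_CODES = (1.0, 0.0, -1.0)


class PanelError(ValueError):
    """Raised on malformed or degenerate genotype data."""


@dataclass
class SNPPanel:
    """An n x p additively coded genotype matrix with its marker map.

    Parameters
    ----------
    genotypes
        Float array of shape ``(n, p)`` with entries in ``{1, 0, -1}`` and
        ``NaN`` for missing calls.
    snp_map
        DataFrame with columns ``name`` (str), ``chrom`` (int) and ``pos``
        (base pairs or map units, 1-based), one row per genotype column.
        Positions must be non-decreasing within a chromosome.
    individual_ids
        Length-n sequence of individual identifiers.
    """

    genotypes: np.ndarray
    snp_map: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise PanelError("genotype matrix must be 2-D")
        n, p = self.genotypes.shape
        if len(self.snp_map) != p:
            raise PanelError(f"snp_map has {len(self.snp_map)} rows for {p} SNP columns")
        if len(self.individual_ids) != n:
            raise PanelError(f"{len(self.individual_ids)} ids for {n} genotype rows")
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.snp_map = self.snp_map.reset_index(drop=True)
        finite = self.genotypes[np.isfinite(self.genotypes)]
        if finite.size and not np.isin(finite, VALID_CODES).all():
            bad = finite[~np.isin(finite, VALID_CODES)]
            raise PanelError(f"non-missing genotype codes outside {{1,0,-1}}: {bad[:5]}")
        for chrom, grp in self.snp_map.groupby("chrom"):
            if not np.all(np.diff(grp["pos"].to_numpy()) >= 0):
                raise PanelError(f"positions not non-decreasing on chromosome {chrom}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.genotypes)

    def subset(self, individuals: np.ndarray | None = None,
               snps: np.ndarray | None = None) -> "SNPPanel":
        """Return a new panel restricted to the given row/column index arrays."""
        geno = self.genotypes
        ids = np.asarray(self.individual_ids, dtype=object)
        smap = self.snp_map
        if individuals is not None:
            geno = geno[individuals, :]
            ids = ids[individuals]
        if snps is not None:
            geno = geno[:, snps]
            smap = smap.iloc[np.asarray(snps)]
        return SNPPanel(geno.copy(), smap.reset_index(drop=True), list(ids))


@dataclass
class PhenotypeVector:
    """A single continuous trait (one value per individual)."""

    values: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.individual_ids) != self.values.size:
            raise PanelError("phenotype ids and values have different lengths")
        self.individual_ids = [str(i) for i in self.individual_ids]

    def aligned_to(self, panel: SNPPanel) -> tuple["PhenotypeVector", SNPPanel]:
        """Join phenotype and panel on individual id.

        Individuals missing from either side (or with a non-finite trait value)
        are dropped; the number dropped is logged.  Returns the phenotype and
        panel restricted to the common individuals, in panel order.
        """
        pheno = dict(zip(self.individual_ids, self.values))
        keep_rows, vals = [], []
        for i, iid in enumerate(panel.individual_ids):
            v = pheno.get(iid)
            if v is not None and np.isfinite(v):
                keep_rows.append(i)
                vals.append(v)
        dropped = panel.n_individuals - len(keep_rows)
        if dropped:
            logger.info("dropped %d individuals without a phenotype", dropped)
        if not keep_rows:
            raise PanelError("no individuals shared between phenotype and panel")
        sub = panel.subset(individuals=np.asarray(keep_rows))
        return PhenotypeVector(np.asarray(vals), sub.individual_ids), sub


UNKNOWN_PARENT = "0"


@dataclass
class PedigreeTable:
    """Three-column pedigree: (individual, sire, dam), ``"0"`` = unknown parent."""

    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        self.records = [(str(a), str(s), str(d)) for a, s, d in self.records]
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).loc[pd.Series(ids).duplicated()].iloc[0]
            raise PanelError(f"duplicate individual in pedigree: {dup}")

    def topological_order(self) -> list[str]:
        """Parents-before-offspring ordering (Kahn); raises naming a cycle member."""
        parents = {i: {s, d} - {UNKNOWN_PARENT} for i, s, d in self.records}
        known = set(parents)
        indeg = {i: len(ps & known) for i, ps in parents.items()}
        children: dict[str, list[str]] = {i: [] for i in parents}
        for i, ps in parents.items():
            for p in ps & known:
                children[p].append(i)
        order = [i for i, d in indeg.items() if d == 0]
        head = 0
        while head < len(order):
            cur = order[head]
            head += 1
            for c in children[cur]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
        if len(order) != len(parents):
            cyclic = sorted(i for i, d in indeg.items() if d > 0)
            raise PanelError(f"pedigree contains a cycle involving: {cyclic[:5]}")
        return order


@dataclass
class QCReport:
    """Per-stage removal counts from :func:`qc_filter` (stages applied in order)."""

    n_individuals_removed: int = 0
    n_snps_removed_callrate: int = 0
    n_snps_removed_maf: int = 0
    n_snps_removed_hwe: int = 0
    surviving_snp_names: list[str] = field(default_factory=list)


def allele_freq(panel: SNPPanel) -> np.ndarray:
    """Frequency of the "A" (code +1) allele per SNP.

    ``p_j = (2 n_AA + n_Aa) / (2 n_nonmissing)``.  SNPs with no non-missing
    genotypes get ``NaN`` and must be excluded downstream.
    """
    g = panel.genotypes
    nonmiss = np.isfinite(g)
    counts = nonmiss.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        # mean code = 2p - 1  =>  p = (mean + 1) / 2
        mean = np.nansum(g, axis=0) / counts
        p = (mean + 1.0) / 2.0
    p[counts == 0] = np.nan
    if np.any(counts == 0):
        logger.warning("%d SNPs have no non-missing genotypes; frequency undefined",
                       int(np.sum(counts == 0)))
    return p


def genotype_counts(panel: SNPPanel) -> np.ndarray:
    """Per-SNP counts of (AA, Aa, aa) as an integer array of shape (p, 3)."""
    g = panel.genotypes
    return np.stack([
        np.nansum(g == 1.0, axis=0),
        np.nansum(g == 0.0, axis=0),
        np.nansum(g == -1.0, axis=0),
    ], axis=1).astype(int)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square Hardy-Weinberg goodness-of-fit p-value.

    Expected counts are ``(n p^2, 2 n p q, n q^2)`` with ``p`` the A-allele
    frequency.  Monomorphic SNPs return ``p = 1`` by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise PanelError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise PanelError("empty genotype counts")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(panel: SNPPanel, *, ind_missing_max: float = 0.10,
              call_rate_min: float = 0.90, maf_min: float = 0.03,
              hwe_p_min: float = 1e-6) -> tuple[SNPPanel, QCReport]:
    """Quality control: individuals, then call rate, then MAF, then HWE.

    Each stage operates on the data surviving the previous one.  Raises
    :class:`PanelError` if no SNPs survive.
    """
    if panel.n_snps == 0 or panel.n_individuals == 0:
        raise PanelError("empty panel")
    report = QCReport()

    miss_frac = panel.missing_mask.mean(axis=1)
    keep_ind = np.flatnonzero(miss_frac <= ind_missing_max)
    report.n_individuals_removed = panel.n_individuals - keep_ind.size
    cur = panel.subset(individuals=keep_ind) if report.n_individuals_removed else panel

    call_rate = 1.0 - cur.missing_mask.mean(axis=0)
    keep = np.flatnonzero(call_rate >= call_rate_min)
    report.n_snps_removed_callrate = cur.n_snps - keep.size
    cur = cur.subset(snps=keep) if report.n_snps_removed_callrate else cur

    p = allele_freq(cur)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
        keep = np.flatnonzero(~(np.isnan(maf) | (maf < maf_min)))
    report.n_snps_removed_maf = cur.n_snps - keep.size
    cur = cur.subset(snps=keep) if report.n_snps_removed_maf else cur

    counts = genotype_counts(cur)
    hwe_p = np.array([hwe_test(*row) for row in counts])
    keep = np.flatnonzero(hwe_p >= hwe_p_min)
    report.n_snps_removed_hwe = cur.n_snps - keep.size
    cur = cur.subset(snps=keep) if report.n_snps_removed_hwe else cur

    if cur.n_snps == 0:
        raise PanelError("empty panel: all SNPs removed by QC")
    report.surviving_snp_names = list(cur.snp_map["name"])
    return cur, report


def mean_impute(panel: SNPPanel) -> tuple[np.ndarray, np.ndarray]:
    """Replace missing codes by the per-SNP mean ``2 p_j - 1``.

    Returns the complete matrix and the allele frequencies used.  The number of
    imputed calls is logged.  Intended as the last step before model fitting.
    """
    p = allele_freq(panel)
    if np.any(np.isnan(p)):
        raise PanelError("cannot impute SNPs with all genotypes missing")
    x = panel.genotypes.copy()
    miss = ~np.isfinite(x)
    n_miss = int(miss.sum())
    if n_miss:
        fill = np.broadcast_to(2.0 * p - 1.0, x.shape)
        x[miss] = fill[miss]
        logger.info("mean-imputed %d missing genotype calls", n_miss)
    return x, p
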