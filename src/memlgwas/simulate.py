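"""Gene-dropping simulator and power / false-positive-rate evaluation.

The simulated study mirrors a two-generation full-sib design: founder
haplotypes with linkage disequilibrium are created by random mating of a base
population over many historical generations (gene dropping with Haldane
recombination — Poisson crossover counts with mean equal to the chromosome
length in Morgans); generation 1 consists of full-sib families whose parents
are drawn from the founder pool without replacement; generation 2 of full-sib
families whose parents come from distinct generation-1 families.  Phenotypes
are the population mean plus additive QTL effects plus Gaussian noise.

The default genome is 6 chromosomes x 1,000 evenly spaced SNPs, 1 Morgan
each, with generation sizes 50 families x 40 and 20 families x 100 (2,000
individuals per generation).  The default QTL panel (15 major + 28 minor
effects, frozen in ``data/default_qtl.json``) is a synthetic stand-in whose
effects were drawn once so the major QTL jointly explain about 30% of
phenotypic variance at residual variance 1.

A marker at a true QTL position or within +-1 locus of one counts toward
power; any other significant marker is a false positive, with the per
replicate non-QTL locus count ``total SNPs - 3 * (number of QTL)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd

from .kinship import a_matrix
from .meml import MEMLConfig, fit_meml
from .panel import PedigreeTable, PhenotypeVector, SNPPanel, mean_impute
from .permutation import permutation_threshold
from .smma import SMMAScanner, fit_null_reml, prescreen, smma_scan

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


@dataclass
class QTL:
    chrom: int          # 1-based chromosome
    snp_index: int      # 0-based index within the chromosome
    effect: float       # additive effect in trait units


@dataclass
class SimConfig:
    """Full description of one simulated study design."""

    n_chromosomes: int = 6
    snps_per_chromosome: int = 1000
    chromosome_length: float = 1.0        # Morgans
    qtl_spec: list[QTL] | None = None     # None -> default panel from package data
    population_mean: float = 1.0
    residual_variance: float = 1.0
    gen1_families: int = 50
    gen1_family_size: int = 40
    gen2_families: int = 20
    gen2_family_size: int = 100
    base_population_size: int = 100
    historical_generations: int = 100
    founder_allele_freq: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.residual_variance <= 0:
            raise SimulationError("residual_variance must be positive")
        if self.qtl_spec is None:
            self.qtl_spec = default_qtl_spec(self.n_chromosomes, self.snps_per_chromosome)
        self.qtl_spec = [q if isinstance(q, QTL) else QTL(**q) for q in self.qtl_spec]
        L = self.snps_per_chromosome
        for q in self.qtl_spec:
            if not (1 <= q.chrom <= self.n_chromosomes and 0 <= q.snp_index < L):
                raise SimulationError(f"QTL outside the SNP grid: {q}")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome

    def qtl_columns(self) -> np.ndarray:
        """Global (flattened) column index of each QTL."""
        return np.array([(q.chrom - 1) * self.snps_per_chromosome + q.snp_index
                         for q in self.qtl_spec])

    def scaled(self, effect_scale: float) -> "SimConfig":
        """Copy with every QTL effect multiplied by ``effect_scale``."""
        spec = [QTL(q.chrom, q.snp_index, q.effect * effect_scale) for q in self.qtl_spec]
        return replace(self, qtl_spec=spec)


def default_qtl_spec(n_chromosomes: int, snps_per_chromosome: int) -> list[QTL]:
    """Load the frozen default 43-QTL panel, resolved onto the SNP grid."""
    raw = json.loads(resources.files("memlgwas.data").joinpath("default_qtl.json")
                     .read_text())
    spec, used = [], set()
    for q in raw["qtl"]:
        if q["chrom"] > n_chromosomes:
            continue
        idx = int(round(q["pos_frac"] * (snps_per_chromosome - 1)))
        while (q["chrom"], idx) in used:  # grid collision after rounding
            idx += 1
        used.add((q["chrom"], idx))
        spec.append(QTL(int(q["chrom"]), idx, float(q["effect"])))
    return spec


@dataclass
class SimReplicate:
    """One realized population: genotypes, pedigree, phenotypes, truth."""

    panel: SNPPanel
    pedigree: PedigreeTable
    phenotypes: PhenotypeVector | None
    true_qtl: list[QTL]
    seed: int | None
    qtl_columns: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# Meiosis / gene dropping
# ---------------------------------------------------------------------------

def _gamete(haps: np.ndarray, locus_pos: np.ndarray, chrom_starts: np.ndarray,
            length: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a (2, total_loci) parental haplotype pair.

    Crossovers per chromosome: Poisson(length in Morgans), uniform positions
    (Haldane, no interference); starting haplotype random per chromosome.
    """
    out = np.empty(haps.shape[1], dtype=np.uint8)
    for c in range(len(chrom_starts) - 1):
        lo, hi = chrom_starts[c], chrom_starts[c + 1]
        n_xo = rng.poisson(length)
        if n_xo:
            xo = np.sort(rng.uniform(0.0, length, n_xo))
            seg = np.searchsorted(xo, locus_pos[lo:hi], side="right")
        else:
            seg = 0
        phase = (int(rng.integers(2)) + seg) % 2
        out[lo:hi] = np.where(phase == 0, haps[0, lo:hi], haps[1, lo:hi])
    return out


def build_founder_haplotypes(config: SimConfig,
                             rng: np.random.Generator | None = None) -> np.ndarray:
    """LD founder pool: (base_population_size, 2, n_snps) uint8 haplotypes.

    The base population starts from Bernoulli(founder_allele_freq) alleles
    and random-mates for ``historical_generations`` generations; loci drifting
    to fixation are re-polymorphized by flipping one random haplotype (count
    logged).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N, L, C = config.base_population_size, config.snps_per_chromosome, config.n_chromosomes
    total = C * L
    locus_pos = np.tile(np.arange(L) * (config.chromosome_length / L), C)
    chrom_starts = np.arange(C + 1) * L
    haps = (rng.random((N, 2, total)) < config.founder_allele_freq).astype(np.uint8)
    n_flips = 0
    for _gen in range(config.historical_generations):
        new = np.empty_like(haps)
        for i in range(N):
            s, d = rng.choice(N, size=2, replace=False)
            new[i, 0] = _gamete(haps[s], locus_pos, chrom_starts, config.chromosome_length, rng)
            new[i, 1] = _gamete(haps[d], locus_pos, chrom_starts, config.chromosome_length, rng)
        haps = new
        flat = haps.reshape(2 * N, total)
        freq = flat.mean(axis=0)
        fixed = np.flatnonzero((freq == 0.0) | (freq == 1.0))
        for j in fixed:
            k = rng.integers(2 * N)
            flat[k, j] ^= 1
            n_flips += 1
    if n_flips:
        logger.info("re-polymorphized %d fixed locus occurrences during LD buildup", n_flips)
    return haps


def simulate_pedigree_population(config: SimConfig, founder_pool: np.ndarray,
                                 rng: np.random.Generator | None = None,
                                 seed_label: int | None = None) -> SimReplicate:
    """Drop genes through the two-generation full-sib pedigree.

    Generation-1 parents are drawn from the founder pool without replacement
    (one sire + one dam per family); generation-2 parents come from distinct
    generation-1 families, again without replacement.  The returned panel and
    pedigree cover the two offspring generations; founders appear in the
    pedigree with unknown parents.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N = founder_pool.shape[0]
    need = 2 * config.gen1_families
    if N < need:
        raise SimulationError(f"founder pool has {N} individuals; {need} parents required")
    if config.gen2_families * 2 > config.gen1_families:
        raise SimulationError("not enough generation-1 families for distinct gen-2 parents")
    L, C = config.snps_per_chromosome, config.n_chromosomes
    total = C * L
    locus_pos = np.tile(np.arange(L) * (config.chromosome_length / L), C)
    chrom_starts = np.arange(C + 1) * L
    length = config.chromosome_length

    founder_idx = rng.choice(N, size=need, replace=False)
    founder_ids = [f"F{k + 1}" for k in range(need)]
    records: list[tuple[str, str, str]] = [(fid, "0", "0") for fid in founder_ids]

    def breed(sire_h, dam_h):
        return np.stack([_gamete(sire_h, locus_pos, chrom_starts, length, rng),
                         _gamete(dam_h, locus_pos, chrom_starts, length, rng)])

    gen1_haps, gen1_ids, gen1_family = [], [], []
    for f in range(config.gen1_families):
        sire_id, dam_id = founder_ids[2 * f], founder_ids[2 * f + 1]
        sire_h = founder_pool[founder_idx[2 * f]]
        dam_h = founder_pool[founder_idx[2 * f + 1]]
        for k in range(config.gen1_family_size):
            iid = f"G1_{f + 1}_{k + 1}"
            gen1_haps.append(breed(sire_h, dam_h))
            gen1_ids.append(iid)
            gen1_family.append(f)
            records.append((iid, sire_id, dam_id))

    fam_choice = rng.choice(config.gen1_families, size=2 * config.gen2_families,
                            replace=False)
    by_family: dict[int, list[int]] = {}
    for i, f in enumerate(gen1_family):
        by_family.setdefault(f, []).append(i)
    gen2_haps, gen2_ids = [], []
    for f in range(config.gen2_families):
        sf, df = fam_choice[2 * f], fam_choice[2 * f + 1]
        si = int(rng.choice(by_family[sf]))
        di = int(rng.choice(by_family[df]))
        for k in range(config.gen2_family_size):
            iid = f"G2_{f + 1}_{k + 1}"
            gen2_haps.append(breed(gen1_haps[si], gen1_haps[di]))
            gen2_ids.append(iid)
            records.append((iid, gen1_ids[si], gen1_ids[di]))

    all_haps = np.stack(gen1_haps + gen2_haps)
    geno = all_haps.sum(axis=1).astype(float) - 1.0  # allele count - 1 -> {1,0,-1}
    smap = pd.DataFrame({
        "name": [f"c{c + 1}s{j + 1}" for c in range(C) for j in range(L)],
        "chrom": np.repeat(np.arange(1, C + 1), L),
        "pos": np.tile(np.arange(1, L + 1), C) * 1000,
        "cm": np.tile(np.arange(L) * (100.0 * length / L), C),
    })
    panel = SNPPanel(geno, smap, gen1_ids + gen2_ids)
    return SimReplicate(panel=panel, pedigree=PedigreeTable(records), phenotypes=None,
                        true_qtl=list(config.qtl_spec), seed=seed_label,
                        qtl_columns=config.qtl_columns())


def simulate_phenotypes(replicate: SimReplicate, config: SimConfig,
                        rng: np.random.Generator | None = None) -> PhenotypeVector:
    """``y_i = mean + sum_q x_iq beta_q + e_i``, ``e ~ N(0, residual_variance)``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = replicate.panel.genotypes[:, replicate.qtl_columns]
    effects = np.array([q.effect for q in replicate.true_qtl])
    y = (config.population_mean + x @ effects
         + rng.normal(0.0, np.sqrt(config.residual_variance), x.shape[0]))
    return PhenotypeVector(y, replicate.panel.individual_ids)


def simulate_replicate(config: SimConfig, seed: int | None = None) -> SimReplicate:
    """Convenience: founder pool + pedigree drop + phenotypes, one seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pool = build_founder_haplotypes(config, rng)
    rep = simulate_pedigree_population(config, pool, rng, seed_label=seed)
    rep.phenotypes = simulate_phenotypes(rep, config, rng)
    return rep


# ---------------------------------------------------------------------------
# Power / FPR evaluation
# ---------------------------------------------------------------------------

@dataclass
class PowerFPRReport:
    method: str
    n_replicates: int
    detected_qtl_count: int
    total_qtl_count: int
    power: float
    false_positive_count: int
    non_qtl_locus_count: int
    fpr: float


def score_detections(significant: np.ndarray, qtl_columns: np.ndarray,
                     snps_per_chromosome: int) -> tuple[int, int]:
    """Count detected QTL and false positives under the +-1 locus rule.

    A significant marker within one grid position of a true QTL (same
    chromosome) credits that QTL (each QTL at most once); all other
    significant markers are false positives.
    """
    significant = np.asarray(significant, dtype=int)
    detected = np.zeros(len(qtl_columns), dtype=bool)
    fp = 0
    for s in significant:
        hits = np.flatnonzero(
            (np.abs(qtl_columns - s) <= 1)
            & (qtl_columns // snps_per_chromosome == s // snps_per_chromosome))
        if hits.size:
            detected[hits] = True
        else:
            fp += 1
    return int(detected.sum()), fp


def smma_significant(rep: SimReplicate, n_perm: int, alpha: float,
                     seed: int | None, X=None, A_sub=None, vc=None) -> np.ndarray:
    """Genome-wide SMMA with its permuted -log10 p threshold; global indices."""
    y = rep.phenotypes.values
    if X is None:
        X, _ = mean_impute(rep.panel)
    if A_sub is None:
        A_sub = a_matrix(rep.pedigree).submatrix(rep.panel.individual_ids)
    if vc is None:
        vc = fit_null_reml(y, A_sub)
    scanner = SMMAScanner(X, A_sub, vc)
    obs = scanner.neg_log10_p_stat(y)
    perm = permutation_threshold(y, scanner.neg_log10_p_stat, n_perm=n_perm,
                                 alpha=alpha, seed=seed)
    with np.errstate(invalid="ignore"):
        return np.flatnonzero(obs > perm.threshold)


def meml_significant(rep: SimReplicate, n_perm: int, alpha: float, top_k: int,
                     seed: int | None, meml_config: MEMLConfig | None = None,
                     X=None, A_sub=None, vc=None) -> np.ndarray:
    """Two-stage MEML: SMMA prescreen, EM fit, permuted h2 threshold."""
    y = rep.phenotypes.values
    if X is None:
        X, _ = mean_impute(rep.panel)
    if A_sub is None:
        A_sub = a_matrix(rep.pedigree).submatrix(rep.panel.individual_ids)
    if vc is None:
        vc = fit_null_reml(y, A_sub)
    cfg = meml_config or MEMLConfig()
    res = smma_scan(y, rep.panel, A_sub, vc, X=X)
    idx = prescreen(res, k=top_k)
    Xs = X[:, idx]
    freq = (Xs.mean(axis=0) + 1.0) / 2.0

    def h2_stat(yp: np.ndarray) -> np.ndarray:
        return fit_meml(yp, None, A_sub, cfg, X=Xs, snp_freq=freq).heritabilities

    fit = fit_meml(y, None, A_sub, cfg, X=Xs, snp_freq=freq)
    perm = permutation_threshold(y, h2_stat, n_perm=n_perm, alpha=alpha, seed=seed)
    return idx[fit.heritabilities > perm.threshold]


def evaluate_replicates(config: SimConfig, n_replicates: int, seed: int,
                        methods: dict[str, Callable[[SimReplicate, int], np.ndarray]] | None = None,
                        n_perm: int = 1000, alpha: float = 0.05, top_k: int = 500,
                        meml_config: MEMLConfig | None = None) -> dict[str, PowerFPRReport]:
    """Replicated power / false-positive-rate comparison.

    ``methods`` maps a label to a callable ``(replicate, seed) -> global
    indices of significant SNPs``; by default the SMMA and two-stage MEML
    procedures with permutation thresholds are run.  A method failure
    skips the replicate for every method (logged); reports carry the
    effective replicate count.
    """
    if n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
    if methods is None:
        methods = {
            "SMMA": lambda rep, s: smma_significant(rep, n_perm, alpha, s),
            "MEML": lambda rep, s: meml_significant(rep, n_perm, alpha, top_k, s,
                                                    meml_config),
        }
    nq = len(config.qtl_spec)
    non_qtl_per_rep = config.n_snps - 3 * nq
    tally = {m: {"det": 0, "fp": 0, "reps": 0} for m in methods}
    for r, rs in enumerate(rep_seeds):
        rep = simulate_replicate(config, seed=rs)
        try:
            results = {m: fn(rep, rs) for m, fn in methods.items()}
        except Exception:
            logger.exception("replicate %d failed; skipped", r)
            continue
        for m, sig in results.items():
            det, fp = score_detections(sig, rep.qtl_columns, config.snps_per_chromosome)
            tally[m]["det"] += det
            tally[m]["fp"] += fp
            tally[m]["reps"] += 1
    reports = {}
    for m, t in tally.items():
        reps = t["reps"]
        total_qtl = nq * reps
        non_qtl = non_qtl_per_rep * reps
        reports[m] = PowerFPRReport(
            method=m, n_replicates=reps,
            detected_qtl_count=t["det"], total_qtl_count=total_qtl,
            power=t["det"] / total_qtl if total_qtl else float("nan"),
            false_positive_count=t["fp"], non_qtl_locus_count=non_qtl,
            fpr=t["fp"] / non_qtl if non_qtl else float("nan"))
    return reports
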