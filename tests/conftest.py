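"""Shared builders for synthetic test inputs (all generated at test time)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from memlgwas import PedigreeTable, SNPPanel


def make_snp_map(p: int, chrom: int = 1) -> pd.DataFrame:
    return pd.DataFrame({
        "name": [f"snp{j + 1}" for j in range(p)],
        "chrom": chrom,
        "pos": np.arange(1, p + 1) * 1000,
    })


def random_panel(rng: np.random.Generator, n: int, p: int,
                 freq: float | np.ndarray = 0.5,
                 missing_rate: float = 0.0) -> SNPPanel:
    """Panel with HWE genotypes at the given A-allele frequency."""
    fr = np.broadcast_to(np.asarray(freq, dtype=float), (p,))
    a1 = rng.random((n, p)) < fr
    a2 = rng.random((n, p)) < fr
    geno = a1.astype(float) + a2.astype(float) - 1.0
    if missing_rate > 0:
        geno[rng.random((n, p)) < missing_rate] = np.nan
    return SNPPanel(geno, make_snp_map(p), [f"i{k + 1}" for k in range(n)])


def founder_pedigree(n: int) -> PedigreeTable:
    return PedigreeTable([(f"i{k + 1}", "0", "0") for k in range(n)])


def full_sib_pedigree(n_families: int, family_size: int) -> PedigreeTable:
    """Unrelated founder pairs, each with ``family_size`` full-sib offspring.

    Offspring ids are ``i1..iN`` in family blocks so they can double as panel
    individual ids.
    """
    recs = []
    k = 0
    for f in range(n_families):
        s, d = f"s{f + 1}", f"d{f + 1}"
        recs += [(s, "0", "0"), (d, "0", "0")]
        for _ in range(family_size):
            k += 1
            recs.append((f"i{k}", s, d))
    return PedigreeTable(recs)


def nested_pedigree(n_founder_pairs: int = 40, gen1_per_pair: int = 10,
                    gen2_pairs: int = 100, gen2_per_pair: int = 6,
                    seed: int = 0) -> PedigreeTable:
    """Deeper two-generation design (gen-2 parents from distinct gen-1 families)."""
    rng = np.random.default_rng(seed)
    recs, gen1, fam = [], [], []
    for f in range(n_founder_pairs):
        s, d = f"S{f}", f"D{f}"
        recs += [(s, "0", "0"), (d, "0", "0")]
        for k in range(gen1_per_pair):
            iid = f"A{f}_{k}"
            recs.append((iid, s, d))
            gen1.append(iid)
            fam.append(f)
    fam = np.asarray(fam)
    m = 0
    for _ in range(gen2_pairs):
        i, j = rng.choice(len(gen1), 2, replace=False)
        while fam[i] == fam[j]:
            i, j = rng.choice(len(gen1), 2, replace=False)
        for _ in range(gen2_per_pair):
            recs.append((f"B{m}", gen1[i], gen1[j]))
            m += 1
    return PedigreeTable(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240115)
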