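"""Text-format readers and writers: PLINK .ped/.map, phenotype TSV, pedigree CSV.

Only the text PLINK dialect is supported (six leading columns, then two allele
columns per SNP, ``0 0`` = missing).  Alleles are collapsed to the additive
{1, 0, -1} coding with the SNP's major allele playing "A" unless an explicit
per-SNP reference allele is supplied.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelError, PedigreeTable, PhenotypeVector, SNPPanel, UNKNOWN_PARENT


class ParseError(PanelError):
    pass


def read_map(map_path: str | Path) -> pd.DataFrame:
    """Read a 4-column PLINK .map file (chrom, name, genetic distance, bp)."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 4:
                raise ParseError(f"{map_path}: line {lineno}: expected 4 columns, got {len(tok)}")
            rows.append((int(tok[0]), tok[1], float(tok[2]), int(tok[3])))
    return pd.DataFrame(rows, columns=["chrom", "name", "cm", "pos"])


def read_plink_text(ped_path: str | Path, map_path: str | Path,
                    allele_coding: dict[str, str] | None = None) -> SNPPanel:
    """Read a text .ped/.map pair into a :class:`SNPPanel`.

    Parameters
    ----------
    allele_coding
        Optional per-SNP reference-allele rule: maps SNP name to the allele
        symbol to treat as "A" (code +1 when homozygous).  SNPs not listed (or
        when ``None``) use the major allele, with the lexicographically smaller
        symbol on a tie.
    """
    smap = read_map(map_path)
    p = len(smap)
    ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * p:
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * p} fields "
                    f"({p} SNPs), got {len(tok)}")
            ids.append(tok[1])
            alleles = tok[6:]
            for a in alleles:
                if len(a) != 1 or not (a.isalnum()):
                    raise ParseError(f"{ped_path}: line {lineno}: bad allele symbol {a!r}")
            allele_rows.append(alleles)

    n = len(ids)
    geno = np.full((n, p), np.nan)
    arr = np.array(allele_rows, dtype=object).reshape(n, p, 2) if n else np.empty((0, p, 2), object)
    for j in range(p):
        a1 = arr[:, j, 0]
        a2 = arr[:, j, 1]
        called = (a1 != "0") & (a2 != "0")
        counts = Counter(np.concatenate([a1[called], a2[called]]))
        name = smap.loc[j, "name"]
        ref = (allele_coding or {}).get(name)
        if ref is None:
            if not counts:
                continue  # all-missing SNP: leave NaN
            # major allele; lexicographic tie-break
            ref = min(counts, key=lambda a: (-counts[a], a))
        observed = set(counts)
        if len(observed - {ref}) > 1:
            raise ParseError(f"SNP {name}: more than two alleles observed: {sorted(observed)}")
        geno[called, j] = (a1[called] == ref).astype(float) + (a2[called] == ref) - 1.0
    return SNPPanel(geno, smap[["name", "chrom", "pos"]].assign(cm=smap["cm"]), ids)


def write_plink_text(panel: SNPPanel, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a panel as text .ped/.map using symbols A (code allele) and B.

    Round-trips exactly with ``read_plink_text(..., allele_coding={name: "A"})``;
    with the default major-allele rule the code matrix also round-trips
    whenever A is the major allele of every SNP.
    """
    smap = panel.snp_map
    cm = smap["cm"] if "cm" in smap else pd.Series(np.zeros(len(smap)))
    with open(map_path, "w") as fh:
        for (_, row), c in zip(smap.iterrows(), cm):
            fh.write(f"{int(row['chrom'])}\t{row['name']}\t{c:g}\t{int(row['pos'])}\n")
    code_to_pair = {1.0: "A A", 0.0: "A B", -1.0: "B B"}
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(panel.individual_ids):
            fields = [str(iid), str(iid), "0", "0", "0", "-9"]
            for g in panel.genotypes[i]:
                fields.append(code_to_pair.get(g, "0 0") if np.isfinite(g) else "0 0")
            fh.write(" ".join(fields) + "\n")


def read_phenotype_tsv(path: str | Path) -> PhenotypeVector:
    """Read a phenotype TSV with a header and columns (id, value)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: phenotype file needs at least 2 columns (id, value)")
    return PhenotypeVector(df.iloc[:, 1].to_numpy(float), df.iloc[:, 0].astype(str).tolist())


def write_phenotype_tsv(pheno: PhenotypeVector, path: str | Path,
                        trait_name: str = "trait") -> None:
    pd.DataFrame({"id": pheno.individual_ids, trait_name: pheno.values}).to_csv(
        path, sep="\t", index=False)


def read_pedigree_csv(path: str | Path) -> PedigreeTable:
    """Read a pedigree CSV with columns (id, sire, dam); "0" marks unknown."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: pedigree file needs 3 columns (id, sire, dam)")
    recs = [(r[0], r[1] or UNKNOWN_PARENT, r[2] or UNKNOWN_PARENT)
            for r in df.itertuples(index=False)]
    return PedigreeTable(recs)


def write_pedigree_csv(ped: PedigreeTable, path: str | Path) -> None:
    pd.DataFrame(ped.records, columns=["id", "sire", "dam"]).to_csv(path, index=False)


def write_a_matrix(values: np.ndarray, ids: list[str], path: str | Path) -> None:
    """Write a relationship matrix as whitespace-delimited text with an id header."""
    with open(path, "w") as fh:
        fh.write(" ".join(ids) + "\n")
        np.savetxt(fh, values, fmt="%.10g")
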