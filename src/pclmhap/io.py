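"""Readers and writers for genotype matrices, dose tables and reports.

Genotype TSV/CSV: individuals in rows (first column = individual id), SNPs
in columns (header = marker ids), entries 0/1/2 with ``NA``, ``.`` or empty
for missing.  Dose-probability TSV: long format with columns
``individual_id, snp_id, p0, p1, p2``.  VCF: biallelic SNPs only; ``GT``
yields crisp doses (dose = copies of the minor allele), ``GP`` yields dose
triples.  Missing entries route a dataset to the fuzzy path automatically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"NA", "na", ".", "", "nan", "NaN"}


class GenotypeData(NamedTuple):
    genotypes: np.ndarray          # (N, n) float, NaN = missing
    individual_ids: list[str]
    snp_ids: list[str]
    minor_is_alt: Optional[list[bool]]  # VCF only: coding decision per SNP


def read_genotypes(path, fmt: str = "auto", transpose: bool = False) -> GenotypeData:
    """Read a genotype matrix from TSV/CSV or VCF."""
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        return _read_vcf_gt(path)
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown genotype format {fmt!r}")
    sep = "," if fmt == "csv" or path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if transpose:
        df = df.T
    values = df.to_numpy()
    out = np.empty(values.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(values):
        cell = cell.strip()
        if cell in _MISSING_TOKENS:
            out[i, j] = np.nan
        elif cell in ("0", "1", "2"):
            out[i, j] = float(cell)
        else:
            raise ValueError(
                f"non-genotype cell {cell!r} at individual {df.index[i]!r}, "
                f"marker {df.columns[j]!r}"
            )
    if np.isnan(out).any():
        logger.info("missing genotype calls found; dataset will use the fuzzy path")
    return GenotypeData(out, [str(x) for x in df.index], [str(c) for c in df.columns], None)


def _read_vcf_gt(path: Path) -> GenotypeData:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids, minor_is_alt = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multiallelic site %s:%s", var.CHROM, var.POS)
            continue
        doses = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        alt_dose = np.where(doses == 3, 2.0, doses)
        alt_dose[doses == 2] = np.nan
        finite = alt_dose[~np.isnan(alt_dose)]
        alt_freq = finite.mean() / 2.0 if finite.size else 0.0
        flip = alt_freq > 0.5  # code the minor allele; ties keep ALT
        rows.append(2.0 - alt_dose if flip else alt_dose)
        minor_is_alt.append(not flip)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    if not rows:
        raise ValueError(f"no biallelic SNPs found in {path}")
    return GenotypeData(np.column_stack(rows), samples, ids, minor_is_alt)


def read_dose_probs(path):
    """Read a long-format dose-probability TSV into a DoseProbTable."""
    from .variants import DoseProbTable

    df = pd.read_csv(path, sep="\t")
    required = ["individual_id", "snp_id", "p0", "p1", "p2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"dose table is missing columns {missing}")
    if (df[["p0", "p1", "p2"]] < 0).to_numpy().any():
        raise ValueError("negative dose probability in table")
    ind_ids = list(dict.fromkeys(df["individual_id"].astype(str)))
    snp_ids = list(dict.fromkeys(df["snp_id"].astype(str)))
    ind_pos = {v: k for k, v in enumerate(ind_ids)}
    snp_pos = {v: k for k, v in enumerate(snp_ids)}
    probs = np.full((len(ind_ids), len(snp_ids), 3), np.nan)
    for row in df.itertuples(index=False):
        probs[ind_pos[str(row.individual_id)], snp_pos[str(row.snp_id)]] = (
            row.p0, row.p1, row.p2,
        )
    if np.isnan(probs).any():
        raise ValueError("dose table does not cover every individual x SNP cell")
    return DoseProbTable(probs, ind_ids, snp_ids)


def write_dose_probs(table, path) -> None:
    rows = []
    for i, ind in enumerate(table.individual_ids):
        for s, snp in enumerate(table.snp_ids):
            p = table.probs[i, s]
            rows.append((ind, snp, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=["individual_id", "snp_id", "p0", "p1", "p2"]).to_csv(
        path, sep="\t", index=False
    )


def write_genotypes(genotypes, individual_ids, snp_ids, path) -> None:
    g = np.asarray(genotypes, dtype=float)
    df = pd.DataFrame(g, index=individual_ids, columns=snp_ids)
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.to_csv(path, sep="\t", index_label="individual_id")


def haplotype_report(estimator) -> pd.DataFrame:
    """Tabular report of a fitted estimator: one row per haplotype."""
    return pd.DataFrame(
        dict(
            haplotype=estimator.haplotypes_,
            estimate=estimator.haplotype_probs_,
            std_error=estimator.se_,
            prior=estimator.prior_probs_,
        )
    )


def write_haplotype_report(estimator, path, sig_digits: int = 6) -> None:
    df = haplotype_report(estimator)
    for col in ("estimate", "std_error", "prior"):
        df[col] = df[col].map(lambda v: f"{v:.{sig_digits}g}")
    df.to_csv(path, sep="\t", index=False)


def read_haplotype_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"haplotype": str})


def fit_metadata(estimator) -> dict:
    return dict(
        n_snps=int(estimator.n_snps_),
        n_individuals=int(estimator.n_individuals_),
        variant=estimator.variant_,
        lam=float(estimator.lambda_),
        aic=float(estimator.aic_),
        effective_dimension=float(estimator.ed_),
        deviance=float(estimator.deviance_),
        converged=bool(estimator.converged_),
        n_iter=int(estimator.n_iter_),
    )


def write_metadata(meta: dict, path) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
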