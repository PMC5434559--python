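"""Readers, writers and run configuration.

Formats: genotype TSV (header of SNP ids, first column sample id, cells in
{0,1,2,NA}), VCF (biallelic GT converted to ALT-dosage), phenotype TSV
(sample_id, status), 3-column edge-list TSV, coefficient TSV, and a
YAML/JSON run configuration validated by a strict schema (unknown keys
rejected).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeTable",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "write_coefficients",
    "write_fit_metadata",
    "maf_filter",
    "hwe_filter",
    "RunConfig",
    "load_run_config",
]


@dataclass
class GenotypeTable:
    """Samples x SNPs dosage matrix with ids and a missingness mask.

    ``values`` holds imputed dosages in [0, 2]; ``missing`` marks cells
    that were NA in the source and were imputed to the column mean.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray
    missing: np.ndarray = field(default=None)  # bool mask, same shape

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != p:
            raise ValueError("id lengths do not match the value matrix")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != p:
            raise ValueError("duplicate SNP ids")
        if self.missing is None:
            self.missing = np.zeros((n, p), dtype=bool)

    @property
    def missing_fraction(self) -> float:
        return float(self.missing.mean())


def _impute_column_means(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    missing = np.isnan(values)
    if missing.any():
        logger.info("imputing %d missing genotype cells to column means",
                    int(missing.sum()))
        col_mean = np.nanmean(np.where(missing, np.nan, values), axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        values = np.where(missing, col_mean[None, :], values)
    return values, missing


def read_genotypes(path, format: str = "tsv",
                   impute: bool = True) -> GenotypeTable:
    """Read a genotype matrix from TSV or VCF.

    TSV cells must be 0/1/2 or NA; any other cell raises a parse error
    naming the offending row and column.  VCF sites are converted to
    ALT-allele dosage from GT; multiallelic sites are skipped with a
    logged count.  Missing genotypes are imputed to the column mean
    (``impute=False`` keeps NaN, for complete-case filtering downstream).
    """
    if format == "tsv":
        return _read_genotypes_tsv(path, impute)
    if format == "vcf":
        return _read_genotypes_vcf(path, impute)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path, impute: bool) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: genotype TSV needs a sample-id column "
                         "plus at least one SNP column")
    snp_ids = list(df.columns[1:])
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    values = np.empty((len(sample_ids), len(snp_ids)))
    for j, snp in enumerate(snp_ids):
        col = df[snp].to_numpy()
        for i, cell in enumerate(col):
            s = str(cell).strip()
            if s in ("NA", "nan", ""):
                values[i, j] = np.nan
            elif s in ("0", "1", "2"):
                values[i, j] = float(s)
            else:
                raise ValueError(
                    f"{path}: invalid genotype {s!r} at line {i + 2}, "
                    f"column {snp!r} (expected 0/1/2/NA)")
    if impute:
        values, missing = _impute_column_means(values)
    else:
        missing = np.isnan(values)
    return GenotypeTable(sample_ids, snp_ids, values, missing)


def _read_genotypes_vcf(path, impute: bool) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    cols: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        dosage = np.full(len(sample_ids), np.nan)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if alleles:
                dosage[i] = float(sum(1 for a in alleles if a > 0))
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        snp_ids.append(vid)
        cols.append(dosage)
    vcf.close()
    if n_multi:
        logger.info("skipped %d multiallelic site(s)", n_multi)
    if not cols:
        raise ValueError(f"{path}: no biallelic sites found")
    values = np.column_stack(cols)
    if impute:
        values, missing = _impute_column_means(values)
    else:
        missing = np.isnan(values)
    return GenotypeTable(sample_ids, snp_ids, values, missing)


def write_genotypes(table: GenotypeTable, path) -> None:
    vals = table.values.astype(object)
    vals[table.missing] = "NA"
    out = pd.DataFrame(vals, columns=table.snp_ids)
    out = out.map(lambda v: v if v == "NA" else f"{int(round(float(v)))}"
                  if float(v).is_integer() else f"{float(v):g}")
    out.insert(0, "sample_id", table.sample_ids)
    out.to_csv(path, sep="\t", index=False)


def read_phenotype(path, sample_ids: list[str]) -> np.ndarray:
    """Two-column TSV (sample_id, status in {0,1}) aligned to sample_ids."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: phenotype TSV must have exactly two "
                         "columns (sample_id, status)")
    df.columns = ["sample_id", "status"]
    status = {}
    for i, (sid, s) in enumerate(zip(df["sample_id"], df["status"])):
        s = str(s).strip()
        if s not in ("0", "1"):
            raise ValueError(f"{path}: non-binary status {s!r} at line "
                             f"{i + 2}")
        status[str(sid)] = float(s)
    extra = set(status) - set(sample_ids)
    if extra:
        raise ValueError(f"{path}: phenotype sample(s) not in genotypes: "
                         f"{sorted(extra)}")
    missing = [s for s in sample_ids if s not in status]
    if missing:
        raise ValueError(f"{path}: no phenotype for sample(s): {missing}")
    return np.array([status[s] for s in sample_ids])


def write_phenotype(sample_ids, y, path) -> None:
    pd.DataFrame({"sample_id": sample_ids,
                  "status": np.asarray(y).astype(int)}
                 ).to_csv(path, sep="\t", index=False)


def write_coefficients(snp_ids, beta, path) -> None:
    """Coefficient TSV: snp_id, beta, selected flag (exactly nonzero)."""
    beta = np.asarray(beta)
    pd.DataFrame({"snp_id": snp_ids, "beta": beta,
                  "selected": (beta != 0).astype(int)}
                 ).to_csv(path, sep="\t", index=False)


def write_fit_metadata(fit_result, path) -> None:
    meta = {
        "method": fit_result.method,
        "lambda1": fit_result.spec.lambda1,
        "lambda2": fit_result.spec.lambda2,
        "gamma": fit_result.spec.gamma,
        "n_iterations": fit_result.n_iterations,
        "converged": fit_result.converged,
        "objective": fit_result.objective,
        "n_selected": int(len(fit_result.support)),
    }
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")


# ---------------------------------------------------------------------------
# optional genotype QC filters (off by default)
# ---------------------------------------------------------------------------

def _alt_freq(values: np.ndarray) -> np.ndarray:
    return values.mean(axis=0) / 2.0


def maf_filter(table: GenotypeTable, min_maf: float) -> np.ndarray:
    """Boolean keep-mask: minor-allele frequency >= min_maf."""
    p_hat = _alt_freq(table.values)
    maf = np.minimum(p_hat, 1.0 - p_hat)
    return maf >= min_maf


def hwe_filter(table: GenotypeTable, alpha: float = 1e-4) -> np.ndarray:
    """Keep-mask from the 1-df chi-square Hardy-Weinberg test on counts."""
    from scipy.stats import chi2

    keep = np.ones(len(table.snp_ids), dtype=bool)
    rounded = np.rint(table.values)
    for j in range(rounded.shape[1]):
        col = rounded[:, j][~table.missing[:, j]]
        n = col.size
        counts = np.array([(col == k).sum() for k in (0, 1, 2)], dtype=float)
        p_hat = (2 * counts[2] + counts[1]) / (2 * n)
        exp = n * np.array([(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat),
                            p_hat ** 2])
        if np.any(exp == 0):
            continue  # monomorphic: HWE test undefined, left to MAF filter
        stat = float(np.sum((counts - exp) ** 2 / exp))
        keep[j] = chi2.sf(stat, df=1) >= alpha
    return keep


# ---------------------------------------------------------------------------
# run configuration (strict schema; unknown keys rejected)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NetworkSettings(_Strict):
    alpha: float = 5.0
    c: float = 1.96


class PenaltySettings(_Strict):
    gamma: float = 4.5
    n_lambda1: int = 20
    lambda1_min_ratio: float = 0.01
    lambda2_grid: list[float] = [0.0, 0.01, 0.1, 1.0, 10.0]


class ScenarioSettings(_Strict):
    n: int = 500
    p: int = 750
    cluster_size: int = 5
    structure: str = "ar"
    rho: float = 0.5
    effect_cluster_fraction: float = 0.10
    effect_low: float = 0.25
    effect_high: float = 0.75
    data_type: str = "snp"


class BenchmarkSettings(_Strict):
    n_replicates: int = 100
    methods: list[str] = ["network", "mcp", "enet", "lasso"]
    roc: bool = False


class RunConfig(_Strict):
    """Structured, schema-validated configuration for `slslogit benchmark`."""

    seed: int = 0
    output_dir: str = "slslogit_out"
    network: NetworkSettings = NetworkSettings()
    penalty: PenaltySettings = PenaltySettings()
    scenarios: list[ScenarioSettings] = [ScenarioSettings()]
    benchmark: BenchmarkSettings = BenchmarkSettings()


def load_run_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
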