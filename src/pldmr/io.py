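"""File I/O and the cohort-preprocessing (QC) pipeline.

Supported formats
-----------------
* Genotypes: PLINK ``.raw`` dialect (header ``FID IID PAT MAT SEX PHENOTYPE``
  followed by one column per SNP, additive 0/1/2 coding, ``NA`` missing) and
  a plain TSV matrix (``sample_id`` column then one column per variant).
* Phenotypes/covariates: TSV with a ``sample_id`` column and named real
  columns.
* Simulation truth manifests and fit records: JSON.

All floating-point output is written at 17 significant digits so a
write/read round trip is bit-exact.

The QC pipeline mirrors the preprocessing applied to a real cohort, in a
fixed, logged order: missingness filter, Hardy-Weinberg test, covariate
residualization of the phenotypes, instrument selection by one multiple
regression of the exposure on all candidate variants, and finally centering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import GenotypeMatrix, center_columns

__all__ = [
    "RawGenotypes",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "write_truth",
    "write_fit_records",
    "filter_missingness",
    "hwe_test",
    "residualize",
    "select_instruments",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"
PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class ParseError(ValueError):
    """Malformed genotype/phenotype file; the message carries a line number."""


@dataclass
class RawGenotypes:
    """Genotype dosages straight from disk: values may be missing (NaN)."""

    values: np.ndarray  # float array, NaN where missing
    sample_ids: list[str]
    variant_ids: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def missing_rate(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)


@dataclass
class QCReport:
    """Per-variant bookkeeping for every preprocessing decision."""

    n_variants_in: int = 0
    n_dropped_missingness: int = 0
    n_dropped_hwe: int = 0
    n_dropped_selection: int = 0
    variant_decisions: list[dict] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return (
            self.n_variants_in
            - self.n_dropped_missingness
            - self.n_dropped_hwe
            - self.n_dropped_selection
        )

    def to_dict(self) -> dict:
        return {
            "n_variants_in": self.n_variants_in,
            "n_dropped_missingness": self.n_dropped_missingness,
            "n_dropped_hwe": self.n_dropped_hwe,
            "n_dropped_selection": self.n_dropped_selection,
            "n_kept": self.n_kept,
            "variant_decisions": self.variant_decisions,
        }


def _validate_dosages(df: pd.DataFrame, path, header_lines: int) -> np.ndarray:
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_na = df.isna().to_numpy()
    bad = np.isnan(vals) & ~raw_na  # non-numeric token that was not NA
    ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    bad |= ~ok
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: line {i + 1 + header_lines}, column {df.columns[j]!r}: "
            f"entry {df.iloc[i, j]!r} is not one of 0/1/2/NA"
        )
    return vals


def read_genotypes(path, format: str = "plink_raw") -> RawGenotypes:
    """Read a genotype matrix with its missingness mask.

    ``format='plink_raw'`` expects the PLINK ``--recode A`` dialect;
    ``format='tsv'`` a plain table with a ``sample_id`` first column.
    """
    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        missing_meta = [c for c in PLINK_META if c not in df.columns]
        if missing_meta:
            raise ParseError(f"{path}: line 1: missing PLINK .raw columns {missing_meta}")
        snp_cols = [c for c in df.columns if c not in PLINK_META]
        if not snp_cols:
            raise ParseError(f"{path}: line 1: no SNP columns after the PLINK metadata")
        sample_ids = df["IID"].astype(str).tolist()
        vals = _validate_dosages(df[snp_cols], path, header_lines=1)
        return RawGenotypes(vals, sample_ids, snp_cols)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.columns[0] != "sample_id":
            raise ParseError(f"{path}: line 1: first column must be 'sample_id'")
        snp_cols = list(df.columns[1:])
        if not snp_cols:
            raise ParseError(f"{path}: line 1: no variant columns")
        sample_ids = df["sample_id"].astype(str).tolist()
        vals = _validate_dosages(df[snp_cols], path, header_lines=1)
        return RawGenotypes(vals, sample_ids, snp_cols)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(G, path, format: str = "plink_raw") -> None:
    """Write a genotype matrix (GenotypeMatrix or RawGenotypes) to disk."""
    vals = np.asarray(G.values, dtype=float)
    df = pd.DataFrame(vals, columns=G.variant_ids)
    df = df.astype(object).where(~pd.isna(df), other=pd.NA)
    # integer dosages print without a decimal point
    df = df.map(lambda v: int(v) if pd.notna(v) and float(v).is_integer() else v)
    if format == "plink_raw":
        meta = pd.DataFrame({
            "FID": G.sample_ids, "IID": G.sample_ids,
            "PAT": 0, "MAT": 0, "SEX": 0, "PHENOTYPE": -9,
        })
        out = pd.concat([meta, df], axis=1)
        out.to_csv(path, sep=" ", index=False, na_rep="NA")
    elif format == "tsv":
        df.insert(0, "sample_id", G.sample_ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def read_phenotypes(path) -> pd.DataFrame:
    """TSV table with a ``sample_id`` column and named phenotype/covariate columns."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: line 1: missing 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_fit_records(fits, path, format: str = "json") -> None:
    """Serialize MRFit records to JSON (list of objects) or TSV (one row each)."""
    records = [f.to_record() for f in fits]
    if format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
    elif format == "tsv":
        pd.DataFrame(records).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    else:
        raise ValueError(f"unknown fit-record format {format!r}")


# ---------------------------------------------------------------------------
# QC pipeline
# ---------------------------------------------------------------------------

def filter_missingness(
    raw: RawGenotypes,
    max_missing: float = 0.20,
    report: QCReport | None = None,
) -> tuple[RawGenotypes, QCReport]:
    """Drop variants with missing-rate above threshold; mean-impute the rest.

    Variants with a proportion of missing calls strictly greater than
    ``max_missing`` (default 20%) are removed; surviving columns have their
    remaining missing entries replaced by the column mean of the observed
    dosages, and the imputation is flagged in the report.
    """
    if not (0 <= max_missing <= 1):
        raise ValueError("max_missing must lie in [0, 1]")
    report = report or QCReport(n_variants_in=raw.m)
    rates = raw.missing_rate()
    keep = rates <= max_missing
    if not keep.any():
        raise ValueError("all variants exceed the missingness threshold")
    for j, vid in enumerate(raw.variant_ids):
        report.variant_decisions.append({
            "id": vid,
            "missing_rate": float(rates[j]),
            "hwe_p": None,
            "selection_p": None,
            "kept": bool(keep[j]),
            "imputed": bool(keep[j] and 0 < rates[j]),
        })
    report.n_dropped_missingness = int((~keep).sum())
    vals = raw.values[:, keep].copy()
    mask = np.isnan(vals)
    if mask.any():
        col_means = np.nanmean(vals, axis=0)
        vals[mask] = np.take(col_means, np.where(mask)[1])
        logger.info("mean-imputed %d missing genotype calls", int(mask.sum()))
    kept_ids = [v for v, k in zip(raw.variant_ids, keep) if k]
    return RawGenotypes(vals, raw.sample_ids, kept_ids), report


def hwe_test(dosages: np.ndarray) -> float:
    """Chi-square (1 df) goodness-of-fit test of Hardy-Weinberg equilibrium.

    Observed genotype counts (0, 1, 2 copies of the minor allele) are
    compared with the HWE expectation computed from the sample allele
    frequency.  Monomorphic input returns p = 1 by convention.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no non-missing genotypes")
    if not np.isin(d, (0.0, 1.0, 2.0)).all():
        raise ValueError("dosages must be 0/1/2")
    n = d.size
    obs = np.array([(d == 0).sum(), (d == 1).sum(), (d == 2).sum()], dtype=float)
    p = d.sum() / (2 * n)  # allele frequency of the counted allele
    if p == 0.0 or p == 1.0:
        return 1.0
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def residualize(
    y: np.ndarray,
    covariates: np.ndarray | None,
    transform: str = "none",
) -> np.ndarray:
    """Residuals of y (optionally log-transformed) on [1, covariates].

    The returned residuals are orthogonal to the intercept and every
    covariate column; with no covariates this is plain centering.
    """
    y = np.asarray(y, dtype=float).ravel()
    if transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive values")
        y = np.log(y)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    n = y.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design matrix (with intercept) is rank deficient")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def select_instruments(
    G: GenotypeMatrix,
    exposure: np.ndarray,
    p_threshold: float = 5e-8,
    positive_only: bool = True,
    report: QCReport | None = None,
) -> tuple[list[str], QCReport]:
    """Instrument selection by one multiple regression of exposure on G.

    All candidate variants enter a single multiple regression of the
    (centered) exposure on the centered genotype matrix; variants are kept
    when their coefficient p-value is below ``p_threshold`` and, with
    ``positive_only``, when the coefficient is positive.
    """
    import statsmodels.api as sm

    if G.n <= G.m:
        raise ValueError(
            f"multiple-regression selection needs n > m candidates "
            f"(n={G.n}, m={G.m}); pre-screen the variant set first"
        )
    Gc = G.center()
    x = np.asarray(exposure, dtype=float).ravel()
    x = x - x.mean()
    model = sm.OLS(x, Gc.values).fit()
    report = report or QCReport(n_variants_in=G.m)
    kept = []
    by_id = {d["id"]: d for d in report.variant_decisions}
    for j, vid in enumerate(Gc.variant_ids):
        coef = float(model.params[j])
        pval = float(model.pvalues[j])
        ok = pval < p_threshold and (coef > 0 or not positive_only)
        if ok:
            kept.append(vid)
        dec = by_id.get(vid)
        if dec is None:
            dec = {"id": vid, "missing_rate": None, "hwe_p": None,
                   "selection_p": pval, "kept": ok}
            report.variant_decisions.append(dec)
        else:
            dec["selection_p"] = pval
            dec["kept"] = bool(dec.get("kept", True)) and ok
    report.n_dropped_selection = G.m - len(kept)
    return kept, report


def preprocess(
    raw: RawGenotypes,
    pheno: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: list[str] | None = None,
    max_missing: float = 0.20,
    hwe_threshold: float = 1e-6,
    p_threshold: float = 5e-8,
    positive_only: bool = True,
    transform_exposure: str = "none",
    transform_outcome: str = "none",
):
    """The full QC pipeline in its fixed order.

    missingness filter -> HWE test -> covariate residualization ->
    instrument selection -> centering.  Returns a centered
    :class:`~pldmr.model_core.GenotypeMatrix`, a centered
    :class:`~pldmr.model_core.PhenotypePair` and the :class:`QCReport`.

    The phenotype table is joined 1:1 to the genotype samples on
    ``sample_id``; any mismatch is fatal.  Sample order follows the genotype
    file.
    """
    from .model_core import PhenotypePair

    pheno = pheno.set_index("sample_id")
    missing_samples = [s for s in raw.sample_ids if s not in pheno.index]
    if missing_samples:
        raise ValueError(f"samples absent from phenotype table: {missing_samples[:5]}")
    pheno = pheno.loc[raw.sample_ids]

    report = QCReport(n_variants_in=raw.m)
    logger.info("QC stage 1/5: missingness filter (> %.0f%%)", 100 * max_missing)
    filtered, report = filter_missingness(raw, max_missing, report)

    logger.info("QC stage 2/5: Hardy-Weinberg test (p < %g)", hwe_threshold)
    by_id = {d["id"]: d for d in report.variant_decisions}
    raw_cols = {v: raw.values[:, j] for j, v in enumerate(raw.variant_ids)}
    hwe_keep = []
    for vid in filtered.variant_ids:
        p = hwe_test(raw_cols[vid])  # pre-imputation dosages
        by_id[vid]["hwe_p"] = p
        ok = p >= hwe_threshold
        hwe_keep.append(ok)
        if not ok:
            by_id[vid]["kept"] = False
    hwe_keep = np.asarray(hwe_keep)
    report.n_dropped_hwe = int((~hwe_keep).sum())
    if not hwe_keep.any():
        raise ValueError("all variants fail the Hardy-Weinberg filter")
    filtered = RawGenotypes(
        filtered.values[:, hwe_keep],
        filtered.sample_ids,
        [v for v, k in zip(filtered.variant_ids, hwe_keep) if k],
    )

    logger.info("QC stage 3/5: covariate residualization")
    cov = pheno[covariates].to_numpy(dtype=float) if covariates else None
    x = residualize(pheno[exposure].to_numpy(dtype=float), cov, transform_exposure)
    y = residualize(pheno[outcome].to_numpy(dtype=float), cov, transform_outcome)

    logger.info("QC stage 4/5: instrument selection (p < %g)", p_threshold)
    G_cand = GenotypeMatrix(
        filtered.values, sample_ids=list(filtered.sample_ids),
        variant_ids=list(filtered.variant_ids), centered=False,
    )
    kept_ids, report = select_instruments(G_cand, x, p_threshold, positive_only, report)
    if not kept_ids:
        raise ValueError("no variants survive instrument selection")
    keep = np.isin(np.asarray(G_cand.variant_ids), kept_ids)

    logger.info("QC stage 5/5: centering (%d variants kept)", len(kept_ids))
    G = GenotypeMatrix(
        G_cand.values[:, keep], sample_ids=list(filtered.sample_ids),
        variant_ids=kept_ids, centered=False,
    ).center()
    P = PhenotypePair(x, y).center()
    return G, P, report
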