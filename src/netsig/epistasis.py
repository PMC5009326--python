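"""Two-cohort APOE x SNP interaction scan on Alzheimer's age-at-onset.

Per cohort: genotype/sample QC, classical-MDS stratification covariates
from allele-sharing distances, and an ordinary-least-squares model per
SNP

    AAO ~ 1 + APOE4count + dosage + APOE4count*dosage + MDS1..k

whose interaction-term p-value is the test of epistasis.  The two
cohorts are combined by a fixed-effects, sample-size-weighted Z
meta-analysis with per-study genomic control; SNPs discordant in
direction between studies are dropped, survivors are mapped to genes
by physical position and FDR-adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCohort",
    "QCReport",
    "GeneBoundaries",
    "qc",
    "mds_covariates",
    "interaction_scan",
    "meta_analyze",
    "direction_filter",
    "map_snps_to_genes",
    "fdr_qvalues",
    "p_from_z",
    "z_from_p",
    "ld_r2_dprime",
]

#: Median of the chi-square(1) distribution; denominator of lambda_GC.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.45493642...


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeCohort:
    """Dosage matrix + SNP metadata + phenotype table for one study.

    ``dosage`` is a sample x SNP DataFrame with entries {0, 1, 2} or
    NaN for missing calls.  ``snp_meta`` is indexed by SNP id with
    columns ``chrom`` (str), ``pos`` (1-based int), ``a1``, ``a2``.
    ``pheno`` is indexed by sample id with columns ``aao`` (years) and
    ``apoe4`` (epsilon-4 allele count in {0, 1, 2}) plus optional
    covariates.
    """

    dosage: pd.DataFrame
    snp_meta: pd.DataFrame
    pheno: pd.DataFrame
    name: str = "cohort"

    def __post_init__(self) -> None:
        if self.dosage.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.dosage.columns.duplicated().any():
            raise ValueError("duplicate SNP ids")
        if not set(self.dosage.columns) <= set(self.snp_meta.index):
            raise ValueError("SNPs in dosage missing from snp_meta")
        if not set(self.dosage.index) <= set(self.pheno.index):
            raise ValueError("samples in dosage missing from pheno")
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid dosage {vals[bad[0], bad[1]]!r} for sample "
                f"{self.dosage.index[bad[0]]!r}, SNP {self.dosage.columns[bad[1]]!r}"
            )
        if (self.snp_meta.loc[list(self.dosage.columns), "pos"] <= 0).any():
            raise ValueError("SNP positions must be positive 1-based integers")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]


@dataclass
class QCReport:
    """Counts of SNPs/samples removed by each quality-control rule."""

    n_samples_in: int
    n_snps_in: int
    samples_removed_call_rate: list[str]
    snps_removed_non_autosome: list[str]
    snps_removed_call_rate: list[str]
    snps_removed_maf: list[str]
    rule_order: list[str] = field(default_factory=list)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - len(self.samples_removed_call_rate)

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - (
            len(self.snps_removed_non_autosome)
            + len(self.snps_removed_call_rate)
            + len(self.snps_removed_maf)
        )


@dataclass(frozen=True)
class GeneBoundaries:
    """1-based inclusive genomic interval of a gene."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start {self.start} > end {self.end}")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


def qc(
    cohort: GenotypeCohort,
    snp_call: float = 0.95,
    maf: float = 0.05,
    sample_call: float = 0.95,
    autosomes_only: bool = True,
) -> tuple[GenotypeCohort, QCReport]:
    """Standard GWAS quality control.

    Samples with call rate below ``sample_call`` are removed first;
    SNP filters (non-autosome, call rate below ``snp_call``, minor
    allele frequency below ``maf``) are then applied on the retained
    samples, in that order.
    """
    d = cohort.dosage
    n_samples_in, n_snps_in = d.shape

    sample_cr = 1.0 - d.isna().mean(axis=1)
    bad_samples = sorted(d.index[sample_cr < sample_call])
    d = d.drop(index=bad_samples)

    meta = cohort.snp_meta
    if autosomes_only:
        chrom = meta.loc[list(d.columns), "chrom"].astype(str)
        non_auto = sorted(c for c in d.columns if chrom[c] not in _AUTOSOMES)
    else:
        non_auto = []
    d = d.drop(columns=non_auto)

    snp_cr = 1.0 - d.isna().mean(axis=0)
    low_call = sorted(d.columns[snp_cr < snp_call])
    d = d.drop(columns=low_call)

    freq = d.mean(axis=0) / 2.0  # allele frequency of a2 on retained samples
    minor = np.minimum(freq, 1.0 - freq)
    low_maf = sorted(d.columns[minor < maf])
    d = d.drop(columns=low_maf)

    report = QCReport(
        n_samples_in=n_samples_in,
        n_snps_in=n_snps_in,
        samples_removed_call_rate=bad_samples,
        snps_removed_non_autosome=non_auto,
        snps_removed_call_rate=low_call,
        snps_removed_maf=low_maf,
        rule_order=[
            "sample call rate", "non-autosome", "SNP call rate", "MAF",
        ],
    )
    logger.info(
        "%s QC: %d/%d samples, %d/%d SNPs retained",
        cohort.name, report.n_samples_out, n_samples_in,
        report.n_snps_out, n_snps_in,
    )
    filtered = GenotypeCohort(
        dosage=d,
        snp_meta=cohort.snp_meta.loc[list(d.columns)],
        pheno=cohort.pheno.loc[list(d.index)],
        name=cohort.name,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# MDS stratification covariates
# ---------------------------------------------------------------------------

def _ibs_distance(dosage: np.ndarray) -> np.ndarray:
    """Pairwise 1 - IBS allele-sharing distance.

    IBS between two samples is the mean over co-observed SNPs of
    (2 - |d_i - d_j|)/2.  Computed with one-hot matrix products so the
    cost is a handful of (n x m)(m x n) multiplications even with
    missing calls.
    """
    n = dosage.shape[0]
    levels = [0.0, 1.0, 2.0]
    onehots = [np.where(np.isnan(dosage), 0.0, dosage == lv).astype(float) for lv in levels]
    observed = (~np.isnan(dosage)).astype(float)
    co_observed = observed @ observed.T
    absdiff = np.zeros((n, n))
    for gi, Xi in zip(levels, onehots):
        for gj, Xj in zip(levels, onehots):
            if gi != gj:
                absdiff += abs(gi - gj) * (Xi @ Xj.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = absdiff / (2.0 * co_observed)
    dist[co_observed == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    return dist


def mds_covariates(cohort: GenotypeCohort, n_axes: int = 3) -> pd.DataFrame:
    """Classical metric MDS (principal coordinates) of 1 - IBS.

    Returns the top ``n_axes`` coordinates per sample as columns
    ``MDS1..MDSk``.  The sign of each axis is fixed so its
    largest-magnitude loading is positive, making the output
    deterministic and invariant (up to row permutation) to sample
    order.
    """
    dosage = cohort.dosage.to_numpy(dtype=float)
    dist = _ibs_distance(dosage)
    if np.isnan(dist).any():
        logger.warning("sample pairs with no co-observed SNPs; distances imputed to max")
        dist = np.where(np.isnan(dist), np.nanmax(dist), dist)
    missing_overlap = np.isnan(dosage).mean()
    if missing_overlap > 0.2:
        logger.warning("high missingness (%.1f%%); MDS may be unstable", 100 * missing_overlap)

    n = dist.shape[0]
    d2 = dist**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1][:n_axes]
    coords = np.zeros((n, n_axes))
    for a, i in enumerate(order):
        lam = max(evals[i], 0.0)
        v = evecs[:, i] * np.sqrt(lam)
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v = -v
        coords[:, a] = v
    return pd.DataFrame(
        coords, index=cohort.dosage.index,
        columns=[f"MDS{i + 1}" for i in range(n_axes)],
    )


def mds_outliers(coords: pd.DataFrame, sd_threshold: float = 6.0) -> list[str]:
    """Samples beyond ``sd_threshold`` SDs on any MDS axis."""
    z = (coords - coords.mean()) / coords.std(ddof=1)
    mask = (z.abs() > sd_threshold).any(axis=1)
    return sorted(coords.index[mask])


# ---------------------------------------------------------------------------
# Per-SNP interaction regression
# ---------------------------------------------------------------------------

def interaction_scan(
    cohort: GenotypeCohort,
    covariates: pd.DataFrame | None = None,
    min_complete: int = 10,
) -> pd.DataFrame:
    """OLS epistasis scan: AAO ~ APOE4 + SNP + APOE4*SNP (+ covariates).

    Per SNP, samples with a missing call are dropped (complete-case)
    and the interaction coefficient, its standard error, t statistic
    and two-sided p from the t distribution with residual degrees of
    freedom are reported.  SNPs with a collinear design (monomorphic
    after QC, or fewer than ``min_complete`` complete cases) are
    flagged NA rather than dropped.

    Returns a DataFrame indexed by SNP id with columns
    ``beta_int, se, t, p, n_used, direction``.
    """
    samples = cohort.dosage.index
    aao = cohort.pheno.loc[samples, "aao"].to_numpy(dtype=float)
    apoe = cohort.pheno.loc[samples, "apoe4"].to_numpy(dtype=float)
    if covariates is not None:
        cov = covariates.loc[samples].to_numpy(dtype=float)
    else:
        cov = np.empty((len(samples), 0))

    rows = []
    dosage = cohort.dosage.to_numpy(dtype=float)
    for j, snp in enumerate(cohort.dosage.columns):
        g = dosage[:, j]
        keep = ~np.isnan(g)
        n_used = int(keep.sum())
        if n_used < min_complete:
            rows.append((snp, np.nan, np.nan, np.nan, np.nan, n_used, 0))
            continue
        gk = g[keep]
        X = np.column_stack(
            [np.ones(n_used), apoe[keep], gk, apoe[keep] * gk, cov[keep]]
        )
        y = aao[keep]
        df_resid = n_used - X.shape[1]
        if df_resid < 1 or np.linalg.matrix_rank(X) < X.shape[1]:
            rows.append((snp, np.nan, np.nan, np.nan, np.nan, n_used, 0))
            continue
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ (X.T @ y)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / df_resid
        se = float(np.sqrt(sigma2 * xtx_inv[3, 3]))
        b = float(beta[3])
        if se == 0:
            rows.append((snp, b, np.nan, np.nan, np.nan, n_used, int(np.sign(b))))
            continue
        t = b / se
        p = 2.0 * float(stats.t.sf(abs(t), df_resid))
        rows.append((snp, b, se, t, max(p, np.finfo(float).tiny), n_used,
                     int(np.sign(b)) if b != 0 else 0))
    out = pd.DataFrame(
        rows, columns=["snp", "beta_int", "se", "t", "p", "n_used", "direction"]
    ).set_index("snp")
    n_na = int(out["p"].isna().sum())
    if n_na:
        logger.warning("%d SNPs flagged NA (collinear or too few complete cases)", n_na)
    return out


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------

def p_from_z(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided normal p-value: p = 2 * Phi(-|z|)."""
    out = 2.0 * stats.norm.sf(np.abs(z))
    return float(out) if np.isscalar(z) else out


def z_from_p(p: float | np.ndarray, sign: float | np.ndarray = 1.0):
    """Signed Z from a two-sided p: z = sign * Phi^-1(1 - p/2)."""
    out = np.sign(sign) * stats.norm.isf(np.asarray(p) / 2.0)
    return float(out) if np.isscalar(p) else out


def genomic_inflation(z: np.ndarray) -> float:
    """lambda_GC = median(z^2) / median of chi-square(1)."""
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def _harmonize(meta1: pd.DataFrame, meta2: pd.DataFrame, snps: list[str]) -> tuple[list[str], pd.Series]:
    """Match allele orientation between cohorts.

    Returns the harmonizable SNPs and a +-1 flip factor applied to the
    second study's effect direction (A1/A2 swapped => flip).  SNPs with
    incompatible alleles are dropped with a warning.
    """
    keep, flip = [], {}
    for s in snps:
        a1a, a2a = meta1.loc[s, "a1"], meta1.loc[s, "a2"]
        a1b, a2b = meta2.loc[s, "a1"], meta2.loc[s, "a2"]
        if (a1a, a2a) == (a1b, a2b):
            keep.append(s)
            flip[s] = 1.0
        elif (a1a, a2a) == (a2b, a1b):
            keep.append(s)
            flip[s] = -1.0
        else:
            logger.warning("SNP %s dropped: alleles %s/%s vs %s/%s", s, a1a, a2a, a1b, a2b)
    return keep, pd.Series(flip)


def meta_analyze(
    results1: pd.DataFrame,
    results2: pd.DataFrame,
    n1: int,
    n2: int,
    genomic_control: bool = True,
    snp_meta1: pd.DataFrame | None = None,
    snp_meta2: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fixed-effects, sample-size-weighted Z meta-analysis.

    Per study, z_i = sign(beta_i) * Phi^-1(1 - p_i/2); with genomic
    control each study's z is divided by sqrt(lambda_i) where
    lambda_i = median(z^2)/0.4549, floored at 1.  The combined
    statistic is z = (w1 z1 + w2 z2) / sqrt(w1^2 + w2^2) with
    w_i = sqrt(N_i), p = 2 Phi(-|z|).  Only SNPs present (and non-NA)
    in both studies are combined; when SNP metadata is supplied the
    allele orientation of study 2 is harmonized by strand-free A1/A2
    matching.  The ``direction`` string concatenates the per-study
    signs, e.g. "++" or "+-".
    """
    common = [s for s in results1.index if s in set(results2.index)]
    if not common:
        raise ValueError("no SNPs in common between the two studies")
    r1 = results1.loc[common]
    r2 = results2.loc[common]
    valid = r1["p"].notna() & r2["p"].notna()
    common = [s for s, v in zip(common, valid) if v]
    r1, r2 = r1.loc[common], r2.loc[common]

    if snp_meta1 is not None and snp_meta2 is not None:
        common, flip = _harmonize(snp_meta1, snp_meta2, common)
        r1, r2 = r1.loc[common], r2.loc[common]
    else:
        flip = pd.Series(1.0, index=common)

    z1 = z_from_p(r1["p"].to_numpy(), np.sign(r1["beta_int"].to_numpy()))
    z2 = z_from_p(r2["p"].to_numpy(), np.sign(r2["beta_int"].to_numpy()))
    z2 = z2 * flip.loc[common].to_numpy()

    lam1 = lam2 = 1.0
    if genomic_control:
        lam1 = max(genomic_inflation(z1), 1.0)
        lam2 = max(genomic_inflation(z2), 1.0)
        z1 = z1 / np.sqrt(lam1)
        z2 = z2 / np.sqrt(lam2)
        logger.info("genomic inflation: lambda1=%.3f lambda2=%.3f", lam1, lam2)

    w1, w2 = np.sqrt(n1), np.sqrt(n2)
    z_meta = (w1 * z1 + w2 * z2) / np.sqrt(w1**2 + w2**2)
    p_meta = p_from_z(z_meta)

    def sign_char(x: float) -> str:
        return "+" if x > 0 else ("-" if x < 0 else "0")

    direction = [sign_char(a) + sign_char(b) for a, b in zip(z1, z2)]
    out = pd.DataFrame(
        {
            "z_meta": z_meta,
            "p_meta": p_meta,
            "direction": direction,
            "z1": z1,
            "z2": z2,
            "n_total": int(n1 + n2),
            "lambda1": lam1,
            "lambda2": lam2,
        },
        index=pd.Index(common, name="snp"),
    )
    return out


def direction_filter(meta: pd.DataFrame) -> pd.DataFrame:
    """Keep SNPs whose per-study effect directions agree."""
    if meta.empty:
        return meta
    same = meta["direction"].isin(["++", "--"])
    logger.info("direction filter: %d/%d SNPs concordant", int(same.sum()), len(meta))
    return meta[same]


# ---------------------------------------------------------------------------
# SNP -> gene mapping and FDR
# ---------------------------------------------------------------------------

def map_snps_to_genes(
    snp_meta: pd.DataFrame, boundaries: list[GeneBoundaries]
) -> dict[str, list[str]]:
    """Map SNPs to genes whose [start, end] interval contains them.

    Intervals are 1-based inclusive on the same chromosome; overlapping
    genes yield multiple assignments.  SNPs mapping nowhere are absent
    from the result.
    """
    by_chrom: dict[str, list[GeneBoundaries]] = {}
    for g in boundaries:
        by_chrom.setdefault(str(g.chrom), []).append(g)
    out: dict[str, list[str]] = {}
    for snp, row in snp_meta.iterrows():
        pos = int(row["pos"])
        genes = [
            g.gene
            for g in by_chrom.get(str(row["chrom"]), [])
            if g.start <= pos <= g.end
        ]
        if genes:
            out[str(snp)] = sorted(genes)
    multi = {s: g for s, g in out.items() if len(g) > 1}
    if multi:
        logger.info("%d SNPs map to multiple overlapping genes", len(multi))
    return out


def fdr_qvalues(
    pvalues, method: str = "bh", threshold: float = 0.05
) -> pd.DataFrame:
    """FDR-adjusted q-values with a significance flag.

    ``method="bh"`` is plain Benjamini-Hochberg; ``method="storey"``
    scales BH by an estimated null proportion
    pi0 = min(1, 2 * mean(p > 0.5)).
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    q = multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        pi0 = min(1.0, 2.0 * float(np.mean(p > 0.5)))
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError("method must be 'bh' or 'storey'")
    return pd.DataFrame({"p": p, "q": q, "significant": q < threshold})


# ---------------------------------------------------------------------------
# LD summaries for reporting correlated SNP pairs
# ---------------------------------------------------------------------------

def ld_r2_dprime(
    dos_a: np.ndarray, dos_b: np.ndarray, max_iter: int = 200, tol: float = 1e-10
) -> tuple[float, float]:
    """r^2 and D' between two SNPs from unphased dosages.

    Haplotype frequencies are estimated by the standard two-locus EM on
    the 3x3 genotype table (phase is ambiguous only for the double
    heterozygote).  Returns (r2, dprime).
    """
    a = np.asarray(dos_a, dtype=float)
    b = np.asarray(dos_b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 complete observations")
    pa = a.mean() / 2.0
    pb = b.mean() / 2.0
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic SNP")
    # x = freq of the a1-b1 haplotype; double heterozygotes are the only
    # phase-ambiguous genotype
    n_dh = int(np.sum((a == 1) & (b == 1)))
    known_11 = float(
        2 * np.sum((a == 2) & (b == 2))
        + np.sum((a == 2) & (b == 1))
        + np.sum((a == 1) & (b == 2))
    )
    total_hap = 2.0 * n
    x = pa * pb  # start at linkage equilibrium
    for _ in range(max_iter):
        # P(coupling | double het)
        num = x * (1 - pa - pb + x)
        den = num + (pa - x) * (pb - x)
        frac = num / den if den > 0 else 0.5
        x_new = (known_11 + n_dh * frac) / total_hap
        if abs(x_new - x) < tol:
            x = x_new
            break
        x = x_new
    d = x - pa * pb
    r2 = d**2 / (pa * (1 - pa) * pb * (1 - pb))
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    return float(r2), float(min(dprime, 1.0))
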