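"""Negative-binomial differential expression with a fold-change-threshold null.

The model is the standard RNA-seq count model: counts K_ij for feature i in
sample j are negative binomial with mean s_j * q_ij and dispersion alpha_i,
where s_j is a per-sample size factor and the variance is mu + alpha * mu^2.
Each contrast compares one mutant genotype against the wild-type reference
with a Wald test on the log2 fold change.  mRNA contrasts test the composite
null |LFC| <= 1 (a feature must at least double or halve to count as
differentially expressed); miRNA contrasts test the point null LFC = 0 and
are restricted to a single sequencing batch, because each batch contains the
wild type plus only one mutant genotype.

Multiple testing is controlled with Benjamini-Hochberg at an adjusted-p
cutoff of 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "ContrastSpec",
    "DEResult",
    "DispersionEstimates",
    "ContrastError",
    "estimate_size_factors",
    "estimate_dispersions",
    "wald_contrast",
    "adjust_bh",
    "run_contrast",
    "contrasts_from_yaml",
]

#: floor (in normalized counts) applied to group means when forming log ratios,
#: so that features observed in only one group get a large but finite LFC.
PSEUDO_MEAN_FLOOR = 0.5

#: floor on the final per-feature dispersion; keeps standard errors finite.
MIN_DISPERSION = 1e-8

#: default adjusted-p cutoff for calling differential expression.
DEFAULT_ALPHA = 0.1


class ContrastError(ValueError):
    """A contrast that cannot be formed from the available samples."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene-level counts (features x samples) with per-sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, one row per feature, one column per
        sample.  Feature and sample identifiers must be unique.
    sample_meta
        DataFrame indexed by sample id with columns ``genotype``, ``assay``
        and ``batch``, aligned to the columns of ``counts``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integral")
        missing = [c for c in ("genotype", "assay", "batch") if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta missing columns: {missing}")
        if list(self.sample_meta.index) != list(self.counts.columns):
            self.sample_meta = self.sample_meta.reindex(self.counts.columns)
            if self.sample_meta["genotype"].isna().any():
                raise ValueError("every sample must have a genotype in sample_meta")

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, mask: pd.Series) -> "CountMatrix":
        keep = self.sample_meta.index[mask]
        return CountMatrix(self.counts[keep], self.sample_meta.loc[keep])

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, counts_path, samples_path) -> None:
        """Write counts (first column ``feature``) and the sample sheet."""
        self.counts.rename_axis("feature").to_csv(counts_path, sep="\t")
        self.sample_meta.rename_axis("sample").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(counts, meta)


@dataclass(frozen=True)
class ContrastSpec:
    """One mutant-vs-reference comparison and how to call significance.

    ``lfc_threshold`` is the composite-null threshold theta: the null
    hypothesis is |LFC| <= theta, so p-values are 1 for any feature whose
    estimated |LFC| does not exceed theta.
    """

    test_genotype: str
    ref_genotype: str = "WT"
    assay: str = "mRNA"
    lfc_threshold: float = 1.0
    alpha: float = DEFAULT_ALPHA
    batch_restrict: str | None = None

    def __post_init__(self) -> None:
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.test_genotype == self.ref_genotype:
            raise ValueError("test and reference genotypes must differ")

    @property
    def name(self) -> str:
        return f"{self.test_genotype}-vs-{self.ref_genotype}"

    @classmethod
    def mrna(cls, test_genotype: str, ref_genotype: str = "WT", **kw) -> "ContrastSpec":
        """mRNA convention: theta = 1, no batch restriction."""
        return cls(test_genotype, ref_genotype, assay="mRNA", lfc_threshold=1.0, **kw)

    @classmethod
    def mirna(
        cls, test_genotype: str, ref_genotype: str = "WT", batch_restrict: str | None = None, **kw
    ) -> "ContrastSpec":
        """miRNA convention: theta = 0, optionally restricted to one batch."""
        return cls(
            test_genotype,
            ref_genotype,
            assay="miRNA",
            lfc_threshold=0.0,
            batch_restrict=batch_restrict,
            **kw,
        )


@dataclass
class DispersionEstimates:
    """Per-feature NB dispersions: genewise, trended and the blend used in testing."""

    genewise: pd.Series
    trended: pd.Series
    final: pd.Series
    trend_coefficients: tuple[float, float] = (0.0, 0.0)  # (a, b) in a/mu + b


@dataclass
class DEResult:
    """Per-feature statistics for one contrast.

    ``table`` columns: base_mean, lfc, se, stat, pvalue, padj, is_de
    (plus lfc_shrunk when shrinkage was requested).  Features with all-zero
    counts in the used samples carry NaN p-values and are never flagged.
    """

    table: pd.DataFrame
    spec: ContrastSpec

    @property
    def de_features(self) -> list[str]:
        return list(self.table.index[self.table["is_de"]])

    def to_tsv(self, path) -> None:
        self.table.rename_axis("feature").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, spec: ContrastSpec) -> "DEResult":
        table = pd.read_csv(path, sep="\t", index_col=0)
        table["is_de"] = table["is_de"].astype(bool)
        return cls(table, spec)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over features (restricted to
    features with a positive geometric mean across samples) of
    count_ij / geometric_mean_i.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    values = mat.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_values = np.log(values)
    usable = np.all(values > 0, axis=1)
    if not usable.any():
        raise ValueError(
            "no feature has positive counts in every sample; median-of-ratios is "
            "undefined (consider a pseudo-reference fallback on filtered features)"
        )
    log_geomean = log_values[usable].mean(axis=1)
    log_ratios = log_values[usable] - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=mat.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


def estimate_dispersions(
    counts: CountMatrix,
    size_factors: pd.Series,
    trend_weight: float = 0.5,
) -> DispersionEstimates:
    """Method-of-moments NB dispersions with a mean-dispersion trend.

    Genewise dispersions come from the pooled within-genotype variance of
    normalized counts; the Poisson component accounts for the size factors
    (Var(K/s) = mu/s at dispersion zero).  A hyperbolic trend a/mu + b is fit
    by non-negative least squares, and the final dispersion is a fixed-weight
    blend of the genewise estimate and the trend.
    """
    if not 0.0 <= trend_weight <= 1.0:
        raise ValueError("trend_weight must be in [0, 1]")
    norm = counts.counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    groups = counts.sample_meta["genotype"]
    group_sizes = groups.value_counts()
    if (group_sizes < 2).any():
        bad = list(group_sizes.index[group_sizes < 2])
        raise ValueError(f"need >= 2 replicates per genotype; too few in: {bad}")

    # pooled within-group variance (removes genotype means, so planted DE does
    # not inflate the estimate) and overall mean of normalized counts
    n_total = norm.shape[1]
    ss = np.zeros(norm.shape[0])
    df = 0
    for g in group_sizes.index:
        cols = (groups == g).to_numpy()
        sub = norm[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += cols.sum() - 1
    pooled_var = ss / df
    mean_norm = norm.mean(axis=1)

    # E[pooled_var] = mu * mean(1/s) + alpha * mu^2 under the NB model
    inv_s_mean = float(np.mean(1.0 / size_factors.to_numpy()))
    with np.errstate(divide="ignore", invalid="ignore"):
        genewise = (pooled_var - mean_norm * inv_s_mean) / mean_norm**2
    genewise = np.where(mean_norm > 0, np.maximum(genewise, 0.0), 0.0)
    genewise = np.nan_to_num(genewise, nan=0.0, posinf=0.0)

    a, b = _fit_dispersion_trend(mean_norm, genewise)
    with np.errstate(divide="ignore"):
        trended = np.where(mean_norm > 0, a / np.maximum(mean_norm, 1e-12) + b, b)
    final = np.maximum((1 - trend_weight) * genewise + trend_weight * trended, MIN_DISPERSION)

    idx = counts.counts.index
    return DispersionEstimates(
        genewise=pd.Series(genewise, index=idx, name="genewise"),
        trended=pd.Series(trended, index=idx, name="trended"),
        final=pd.Series(final, index=idx, name="final"),
        trend_coefficients=(a, b),
    )


def _fit_dispersion_trend(mean_norm: np.ndarray, genewise: np.ndarray) -> tuple[float, float]:
    """Fit genewise ~ a/mu + b with a, b >= 0 (non-negative least squares)."""
    use = mean_norm > 1.0
    if use.sum() < 10:
        use = mean_norm > 0
    if use.sum() == 0:
        return 0.0, 0.0
    x = 1.0 / mean_norm[use]
    y = genewise[use]
    # trim the most extreme genewise values so outliers do not drive the trend
    if y.size >= 20:
        cap = np.quantile(y, 0.95)
        y = np.minimum(y, cap)
    design = np.column_stack([x, np.ones_like(x)])
    from scipy.optimize import nnls

    coef, _ = nnls(design, y)
    return float(coef[0]), float(coef[1])


# ---------------------------------------------------------------------------
# Wald test under the composite null |LFC| <= theta
# ---------------------------------------------------------------------------


def _select_contrast_samples(counts: CountMatrix, spec: ContrastSpec) -> CountMatrix:
    meta = counts.sample_meta
    mask = meta["genotype"].isin([spec.test_genotype, spec.ref_genotype])
    if spec.batch_restrict is not None:
        mask &= meta["batch"].astype(str) == str(spec.batch_restrict)
    sub = counts.subset_samples(mask)
    geno = sub.sample_meta["genotype"]
    for g in (spec.test_genotype, spec.ref_genotype):
        if (geno == g).sum() == 0:
            where = f" in batch {spec.batch_restrict!r}" if spec.batch_restrict else ""
            raise ContrastError(f"genotype {g!r} has no samples{where}")
    # refuse contrasts fully confounded with batch: the two genotypes must
    # co-occur in at least one batch (e.g. KO vs KI across independent batches
    # cannot be separated from the batch effect)
    batches_test = set(sub.sample_meta.loc[geno == spec.test_genotype, "batch"])
    batches_ref = set(sub.sample_meta.loc[geno == spec.ref_genotype, "batch"])
    if not batches_test & batches_ref:
        raise ContrastError(
            f"contrast {spec.name} is confounded with batch: {spec.test_genotype} is in "
            f"batches {sorted(map(str, batches_test))} and {spec.ref_genotype} in "
            f"{sorted(map(str, batches_ref))}, with no batch in common"
        )
    return sub


def wald_contrast(
    counts: CountMatrix,
    spec: ContrastSpec,
    size_factors: pd.Series,
    dispersions: DispersionEstimates,
) -> DEResult:
    """Two-group NB Wald test of |LFC| > theta on normalized counts.

    Group means are estimated on normalized counts with a pseudo-mean floor of
    0.5 when forming the log ratio; the standard error comes from the NB
    variance at the final dispersion.  The statistic is
    max(0, |lfc| - theta) / se, with two-sided normal p-values, so every
    feature inside the null band |lfc| <= theta gets p = 1 exactly.
    """
    sub = _select_contrast_samples(counts, spec)
    sf = size_factors.loc[sub.samples].to_numpy()
    norm = sub.counts.to_numpy(dtype=float) / sf[None, :]
    geno = sub.sample_meta["genotype"]
    is_test = (geno == spec.test_genotype).to_numpy()
    is_ref = (geno == spec.ref_genotype).to_numpy()
    n_t, n_r = int(is_test.sum()), int(is_ref.sum())

    mu_t = norm[:, is_test].mean(axis=1)
    mu_r = norm[:, is_ref].mean(axis=1)
    base_mean = norm.mean(axis=1)

    ft = np.maximum(mu_t, PSEUDO_MEAN_FLOOR)
    fr = np.maximum(mu_r, PSEUDO_MEAN_FLOOR)
    lfc = np.log2(ft / fr)

    alpha = dispersions.final.to_numpy()
    # Var(mean of K_j/s_j) = mu * sum(1/s_j)/n^2 + alpha * mu^2 / n; delta
    # method on the natural log, then convert to log2
    inv_s_t = float((1.0 / sf[is_test]).sum())
    inv_s_r = float((1.0 / sf[is_ref]).sum())
    var_ln_t = inv_s_t / (n_t**2 * ft) + alpha / n_t
    var_ln_r = inv_s_r / (n_r**2 * fr) + alpha / n_r
    se = np.sqrt(var_ln_t + var_ln_r) / math.log(2)

    stat = np.maximum(0.0, np.abs(lfc) - spec.lfc_threshold) / se
    pvalue = np.minimum(1.0, 2.0 * sps.norm.sf(stat))

    untested = sub.counts.to_numpy().sum(axis=1) == 0
    lfc[untested] = 0.0
    se[untested] = np.nan
    stat[untested] = np.nan
    pvalue[untested] = np.nan

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "lfc": lfc,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": np.nan,
            "is_de": False,
        },
        index=sub.counts.index,
    )
    return DEResult(table, spec)


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN in, NaN out.

    Undefined (NaN) entries are excluded from the number of tests m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    defined = ~np.isnan(p)
    if defined.any():
        if (p[defined] < 0).any() or (p[defined] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[defined] = multipletests(p[defined], method="fdr_bh")[1]
    return out


def _shrink_lfc(lfc: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Normal-prior shrinkage of LFCs toward zero (reporting aid only).

    The prior variance tau^2 is estimated by moment matching:
    Var(lfc) ~= tau^2 + mean(se^2).
    """
    ok = np.isfinite(lfc) & np.isfinite(se)
    if ok.sum() < 3:
        return lfc.copy()
    tau2 = max(0.0, float(np.var(lfc[ok])) - float(np.mean(se[ok] ** 2)))
    shrunk = lfc.copy()
    shrunk[ok] = lfc[ok] * tau2 / (tau2 + se[ok] ** 2)
    return shrunk


def run_contrast(counts: CountMatrix, spec: ContrastSpec, shrink: bool = False) -> DEResult:
    """Full pipeline for one contrast: size factors -> dispersions -> Wald -> BH.

    Size factors and dispersions are estimated on the samples the contrast
    uses (after any batch restriction), so each miRNA batch is analyzed
    independently.  Features are flagged ``is_de`` when padj < spec.alpha;
    sign-classification downstream uses the unshrunk LFC.
    """
    sub = _select_contrast_samples(counts, spec)
    size_factors = estimate_size_factors(sub)
    dispersions = estimate_dispersions(sub, size_factors)
    result = wald_contrast(sub, spec, size_factors, dispersions)
    result.table["padj"] = adjust_bh(result.table["pvalue"])
    result.table["is_de"] = result.table["padj"] < spec.alpha
    result.table["is_de"] = result.table["is_de"].fillna(False).astype(bool)
    if shrink:
        result.table["lfc_shrunk"] = _shrink_lfc(
            result.table["lfc"].to_numpy(), result.table["se"].to_numpy()
        )
    return result


def contrasts_from_yaml(path) -> list[ContrastSpec]:
    """Read contrast definitions from a YAML file.

    Schema: a top-level ``contrasts`` list of mappings with keys
    test_genotype, ref_genotype (default WT), assay (default mRNA),
    lfc_threshold (default 1 for mRNA, 0 for miRNA), alpha (default 0.1)
    and batch_restrict (optional).
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = []
    for entry in doc["contrasts"]:
        entry = dict(entry)
        assay = entry.setdefault("assay", "mRNA")
        entry.setdefault("lfc_threshold", 1.0 if assay == "mRNA" else 0.0)
        specs.append(ContrastSpec(**entry))
    return specs
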