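"""Mixed-model genome-wide association with permutation calibration.

The phenotype y is modelled as y = mu + g + e with a polygenic term
g ~ N(0, sigma_g^2 K) over a genotype-derived kinship matrix K and
residual e ~ N(0, sigma_e^2 I).  Variance components are estimated by
REML through the spectral decomposition of K and a one-dimensional
search over the variance ratio delta = sigma_e^2 / sigma_g^2
(the fast single-kinship formulation).  Each marker is then tested as
a fixed effect in the rotated (decorrelated) model with delta held at
its null estimate; the likelihood-ratio statistic is chi-square with
one degree of freedom under the null.

Calibration utilities: the genomic inflation factor lambda (median
observed statistic over the null chi-square(1) median) and a
permutation-based family-wise threshold (the 5% quantile of the
genome-wide minimum p-value over phenotype permutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm, pearsonr, rankdata

#: Conventional null median of the 1-df chi-square distribution used for
#: the genomic inflation factor; the exactly computed value is
#: chi2.ppf(0.5, 1) = 0.45494, rounded in the GWAS literature to 0.456.
CHI2_1DF_NULL_MEDIAN = 0.456


def chi2_median(df: int = 1) -> float:
    """Exact median of the chi-square distribution with ``df`` degrees."""
    return float(chi2.ppf(0.5, df))


# ---------------------------------------------------------------------------
# phenotypes


def normalize_phenotypes(
    raw: pd.DataFrame, control: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ratio-normalize growth phenotypes to the control condition.

    ``raw`` is long-format with columns isolate, condition, replicate,
    value.  Each measurement is divided by the matching replicate's
    control-condition value; replicates are aggregated by median.
    Returns (isolate x condition table of median ratios, per-condition
    mean pairwise replicate Pearson correlation).  Isolates with a
    missing or zero control value come out missing (NaN).
    """
    wide = raw.pivot_table(
        index=["isolate", "replicate"], columns="condition", values="value",
        aggfunc="first",
    )
    if control not in wide.columns:
        raise ValueError(f"control condition {control!r} absent from table")
    ctrl = wide[control].replace(0, np.nan)
    ratios = wide.drop(columns=control).div(ctrl, axis=0)
    table = ratios.groupby(level="isolate").median()

    cors = {}
    for cond in ratios.columns:
        mat = ratios[cond].unstack("replicate")
        reps = mat.columns
        vals = []
        for i, a in enumerate(reps):
            for b in reps[i + 1 :]:
                pair = mat[[a, b]].dropna()
                if len(pair) >= 3 and pair[a].std() > 0 and pair[b].std() > 0:
                    vals.append(pearsonr(pair[a], pair[b])[0])
        cors[cond] = float(np.mean(vals)) if vals else float("nan")
    return table, pd.DataFrame({"replicate_correlation": cors})


def quantile_normalize(values: np.ndarray | pd.Series) -> np.ndarray:
    """Map values to standard-normal scores by rank.

    Rank r of n (ties averaged) maps to Phi^{-1}((r - 0.5) / n);
    missing values stay missing.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.ptp(x[ok]) == 0:
        raise ValueError("all values identical; quantile normalization degenerate")
    r = rankdata(x[ok], method="average")
    out[ok] = norm.ppf((r - 0.5) / n)
    return out


# ---------------------------------------------------------------------------
# markers and kinship


def cnv_classes(copy_number: pd.DataFrame) -> pd.DataFrame:
    """Encode copy numbers as 0 (absent, < 0.5), 1 (0.5-1 copy) or
    2 (more than one copy)."""
    x = copy_number.to_numpy(dtype=float)
    cls = np.where(x < 0.5, 0, np.where(x <= 1.0, 1, 2))
    return pd.DataFrame(cls, index=copy_number.index, columns=copy_number.columns)


def build_marker_matrix(
    snp_dosage: pd.DataFrame | None = None,
    cnv: pd.DataFrame | None = None,
    maf_min: float = 0.05,
    min_called: int | None = None,
) -> pd.DataFrame:
    """Assemble the isolates x markers association matrix.

    SNPs enter as alt-allele counts 0/1/2 and CNVs as the 0/1/2 class
    coding of :func:`cnv_classes`.  Markers with minor-allele frequency
    at or below ``maf_min`` (SNPs: alt frequency; CNVs: frequency of
    the rarer pooled class) or called in fewer than ``min_called``
    isolates are excluded.
    """
    parts = []
    if snp_dosage is not None:
        parts.append(snp_dosage)
    if cnv is not None:
        parts.append(cnv_classes(cnv))
    if not parts:
        raise ValueError("no marker source given")
    markers = pd.concat(parts, axis=1)
    x = markers.to_numpy(dtype=float)
    called = np.isfinite(x).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(x, axis=0) / (2 * called)
    maf = np.minimum(p, 1 - p)
    keep = maf > maf_min
    if min_called is not None:
        keep &= called >= min_called
    out = markers.loc[:, keep]
    if out.shape[1] == 0:
        raise ValueError("no markers survive the MAF/missingness filters")
    return out


def kinship(markers: pd.DataFrame) -> pd.DataFrame:
    """Realized-relationship matrix K = Z Z^T / m.

    Each marker column is centred by twice its allele frequency and
    scaled by sqrt(2 p (1 - p)); monomorphic markers are excluded.
    Missing genotypes are mean-imputed before standardization.
    K is symmetric and positive semi-definite.
    """
    x = markers.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least two markers")
    mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mean[None, :], x)
    p = mean / 2
    scale = np.sqrt(2 * p * (1 - p))
    ok = scale > 0
    z = (x[:, ok] - 2 * p[ok]) / scale[ok]
    k = z @ z.T / ok.sum()
    return pd.DataFrame(k, index=markers.index, columns=markers.index)


# ---------------------------------------------------------------------------
# variance components / association


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    log_likelihood: float
    delta: float  # sigma_e2 / sigma_g2
    unidentifiable: bool = False


@dataclass
class NullModel:
    components: VarianceComponents
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    y_rot: np.ndarray


@dataclass
class AssociationResult:
    table: pd.DataFrame  # marker, statistic, p, effect
    lambda_gc: float
    skipped_markers: list[str]


def _reml_neg_loglik(
    log_delta: float, s: np.ndarray, y_rot: np.ndarray, x_rot: np.ndarray
) -> float:
    delta = np.exp(log_delta)
    d = s + delta
    w = 1.0 / d
    xtwx = x_rot.T @ (w[:, None] * x_rot)
    xtwy = x_rot.T @ (w * y_rot)
    beta = np.linalg.solve(xtwx, xtwy)
    r = y_rot - x_rot @ beta
    n, p = x_rot.shape
    rss = float(r @ (w * r))
    sigma_g2 = rss / (n - p)
    _, logdet_xtwx = np.linalg.slogdet(xtwx)
    _, logdet_xtx = np.linalg.slogdet(x_rot.T @ x_rot)
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma_g2)
        + np.sum(np.log(d))
        + logdet_xtwx
        - logdet_xtx
        + (n - p)
    )
    return -ll


def fit_null_lmm(
    y: np.ndarray,
    K: np.ndarray | pd.DataFrame,
    covariates: np.ndarray | None = None,
) -> NullModel:
    """REML fit of the null model y = mu (+ covariates) + g + e.

    The spectral decomposition K = U S U^T reduces the model to
    independent observations with variances sigma_g2 (s_i + delta); the
    restricted likelihood is maximized over delta on a log grid
    followed by bounded refinement.  When K is numerically proportional
    to the identity the two variance components are unidentifiable and
    the result is flagged.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    s, u = np.linalg.eigh((K + K.T) / 2)
    if s.min() < -1e-6 * max(s.max(), 1):
        raise ValueError("kinship matrix is not positive semi-definite")
    s = np.clip(s, 0, None)
    y_rot = u.T @ y
    ones = np.ones((len(y), 1))
    x = ones if covariates is None else np.column_stack([ones, covariates])
    x_rot = u.T @ x

    grid = np.linspace(-8, 8, 33)
    vals = [_reml_neg_loglik(g, s, y_rot, x_rot) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(s, y_rot, x_rot), method="bounded"
    )
    delta = float(np.exp(res.x))
    d = s + delta
    w = 1.0 / d
    xtwx = x_rot.T @ (w[:, None] * x_rot)
    beta = np.linalg.solve(xtwx, x_rot.T @ (w * y_rot))
    r = y_rot - x_rot @ beta
    n, p = x_rot.shape
    sigma_g2 = float(r @ (w * r)) / (n - p)
    sigma_e2 = delta * sigma_g2
    h2 = sigma_g2 / (sigma_g2 + sigma_e2)
    unident = bool(np.ptp(s) < 1e-9 * max(s.max(), 1))
    comps = VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        h2=float(h2),
        log_likelihood=float(-res.fun),
        delta=delta,
        unidentifiable=unident,
    )
    return NullModel(components=comps, eigenvalues=s, eigenvectors=u, y_rot=y_rot)


def _marker_scan(
    null: NullModel, x_rot_markers: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-marker LRT in the rotated model at the null delta.

    Returns (statistic, p, effect) arrays; constant markers get NaN.
    """
    s = null.eigenvalues
    w = 1.0 / (s + null.components.delta)
    y = null.y_rot
    ones_rot = null.eigenvectors.sum(axis=0)  # U^T 1
    a11 = float(ones_rot @ (w * ones_rot))
    b1 = float(ones_rot @ (w * y))
    ywy = float(y @ (w * y))
    rss0 = ywy - b1**2 / a11

    xw = x_rot_markers * w[:, None]
    a12 = ones_rot @ xw
    a22 = np.einsum("ij,ij->j", x_rot_markers, xw)
    b2 = y @ xw
    det = a11 * a22 - a12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta2 = (a11 * b2 - a12 * b1) / det
        beta1 = (b1 - a12 * beta2) / a11
        rss1 = ywy - (beta1 * b1 + beta2 * b2)
        n = len(y)
        stat = n * np.log(rss0 / rss1)
    bad = ~np.isfinite(stat) | (det <= 1e-12 * np.maximum(a11 * a22, 1e-300))
    stat = np.where(bad, np.nan, np.maximum(stat, 0))
    p = chi2.sf(stat, df=1)
    return stat, p, np.where(bad, np.nan, beta2)


def associate(
    y: np.ndarray,
    markers: pd.DataFrame,
    K: np.ndarray | pd.DataFrame,
    null: NullModel | None = None,
) -> AssociationResult:
    """Per-marker mixed-model association.

    Fixed-effect test of each (mean-imputed) marker in the rotated
    model, re-using the null-model delta; statistic ~ chi2(1) under the
    null.  Constant markers are skipped and listed.
    """
    if null is None:
        null = fit_null_lmm(y, K)
    x = markers.to_numpy(dtype=float)
    mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mean[None, :], x)
    constant = x.std(axis=0) == 0
    x_rot = null.eigenvectors.T @ x
    stat, p, eff = _marker_scan(null, x_rot)
    stat[constant] = np.nan
    p[constant] = np.nan
    table = pd.DataFrame(
        {
            "marker": markers.columns,
            "statistic": stat,
            "p": p,
            "effect": eff,
        }
    )
    ok = np.isfinite(stat)
    lam = genomic_inflation(p[ok]) if ok.sum() >= 20 else float("nan")
    skipped = markers.columns[constant].tolist()
    return AssociationResult(table=table, lambda_gc=lam, skipped_markers=skipped)


def genomic_inflation(p_values: np.ndarray) -> float:
    """lambda = median chi-square-equivalent statistic / 0.456."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 20:
        raise ValueError("need at least 20 p-values")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / CHI2_1DF_NULL_MEDIAN)


def permutation_threshold(
    y: np.ndarray,
    markers: pd.DataFrame,
    K: np.ndarray | pd.DataFrame,
    n_perm: int = 100,
    fwer: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise significance threshold from phenotype permutations.

    The phenotype vector is permuted across isolates ``n_perm`` times
    (genotypes and kinship fixed); each permutation records the
    genome-wide minimum p-value, and the threshold is the
    ``fwer``-quantile of those minima taken literally as the
    (fwer * n_perm)-th lowest value (the 5th lowest of 100 by default).
    Deterministic for a fixed seed.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives an unstable quantile")
    rng = np.random.default_rng(seed)
    K = np.asarray(K, dtype=float)
    x = markers.to_numpy(dtype=float)
    mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mean[None, :], x)
    s, u = np.linalg.eigh((K + K.T) / 2)
    s = np.clip(s, 0, None)
    x_rot = u.T @ x
    minima = []
    for _ in range(n_perm):
        perm = rng.permutation(len(y))
        null = _fit_rotated(np.asarray(y)[perm], s, u)
        _, p, _ = _marker_scan(null, x_rot)
        minima.append(np.nanmin(p))
    return fwer_quantile(minima, fwer)


def fwer_quantile(minima: list[float] | np.ndarray, fwer: float = 0.05) -> float:
    """The k-th lowest of the permutation minima, k = fwer * n_perm
    (the 5th lowest of 100 at the default 5% level)."""
    minima = sorted(float(m) for m in minima)
    k = max(int(fwer * len(minima)), 1)
    return minima[k - 1]


def _fit_rotated(y: np.ndarray, s: np.ndarray, u: np.ndarray) -> NullModel:
    """Null REML fit re-using a precomputed eigendecomposition."""
    y_rot = u.T @ y
    x_rot = u.T @ np.ones((len(y), 1))
    grid = np.linspace(-8, 8, 17)
    vals = [_reml_neg_loglik(g, s, y_rot, x_rot) for g in grid]
    i = int(np.argmin(vals))
    res = minimize_scalar(
        _reml_neg_loglik,
        bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
        args=(s, y_rot, x_rot),
        method="bounded",
        options={"xatol": 1e-3},
    )
    delta = float(np.exp(res.x))
    comps = VarianceComponents(
        sigma_g2=float("nan"),
        sigma_e2=float("nan"),
        h2=float("nan"),
        log_likelihood=float(-res.fun),
        delta=delta,
    )
    return NullModel(components=comps, eigenvalues=s, eigenvectors=u, y_rot=y_rot)


def variance_explained(
    y: np.ndarray,
    selected: pd.DataFrame,
    background: pd.DataFrame,
) -> float:
    """Phenotypic variance fraction attributable to selected markers.

    Refits the variance components with the selected markers included
    in the similarity matrix and reports the increase in the genetic
    variance fraction over the background-only null model.
    """
    if selected.shape[1] < 1:
        raise ValueError("need at least one selected marker")
    if (selected.nunique() <= 1).any():
        raise ValueError("selected marker is constant")
    h2_base = fit_null_lmm(y, kinship(background)).components.h2
    combined = pd.concat([background, selected], axis=1)
    h2_full = fit_null_lmm(y, kinship(combined)).components.h2
    return float(max(h2_full - h2_base, 0.0))
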