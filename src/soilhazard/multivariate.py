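"""Multivariate structure of the metal data: correlation, PCA, clustering.

Workflow mirrors standard geochemical practice: z-score the
concentration matrix, screen with the Kaiser-Meyer-Olkin measure (> 0.5
deemed adequate) and Bartlett's sphericity test, run PCA on the
correlation matrix keeping components with eigenvalue > 1, and partition
samples into contamination zones with agglomerative hierarchical
clustering (Ward linkage on Euclidean distance by default).  Cluster
contrasts are summarized per metal with one-way ANOVA and two-group
significance letters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .io import SampleSet, ValidationError

__all__ = [
    "PcaResult",
    "ClusterReport",
    "zscore",
    "pearson_matrix",
    "kmo",
    "bartlett_sphericity",
    "explained_variance_pct",
    "pca",
    "hcluster",
    "cluster_summary",
]


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, SampleSet):
        return data.matrix(), data.metals
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    return arr, [f"v{j}" for j in range(arr.shape[1])]


def zscore(data) -> np.ndarray:
    """Column-wise standardization to mean 0, sd 1 (ddof=1)."""
    x, names = _as_matrix(data)
    sd = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(
            f"zero-variance column(s): {[names[j] for j in zero]}"
        )
    return (x - x.mean(axis=0)) / sd


def pearson_matrix(data) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix with two-sided t-test p-values.

    p-values use t = r * sqrt((n-2)/(1-r^2)) with n-2 df and are not
    corrected for multiple testing (matching the usual star-table
    convention in survey reports).
    """
    x, _ = _as_matrix(data)
    n, p = x.shape
    if n < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pvals = np.where(np.isfinite(t), pvals, 0.0)
    np.fill_diagonal(pvals, 0.0)
    return r, pvals


def kmo(r_matrix: np.ndarray, ridge: float = 0.0) -> float:
    """Overall Kaiser-Meyer-Olkin sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q
    are the anti-image partial correlations obtained from the inverse
    correlation matrix.  Values above 0.5 are conventionally deemed
    adequate for PCA.
    """
    r = np.asarray(r_matrix, dtype=float)
    try:
        inv = np.linalg.inv(r + ridge * np.eye(len(r)))
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "correlation matrix is singular; retry with ridge=1e-8"
        ) from exc
    d = np.sqrt(np.diag(inv))
    q = -inv / np.outer(d, d)
    off = ~np.eye(len(r), dtype=bool)
    r2 = np.sum(r[off] ** 2)
    q2 = np.sum(q[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(r_matrix: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R) with p(p-1)/2 df.
    """
    r = np.asarray(r_matrix, dtype=float)
    p = len(r)
    if n <= p:
        raise ValidationError("Bartlett's test requires n > p")
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValidationError("correlation matrix determinant must be positive")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


@dataclass
class PcaResult:
    """Eigenstructure of the correlation matrix plus adequacy statistics.

    ``loadings`` (p x k) are eigenvectors scaled by sqrt(eigenvalue) for
    the k components with eigenvalue > 1; ``scores`` (n x k) are the
    z-scored data projected on those eigenvectors.
    """

    eigenvalues: np.ndarray
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame
    scores: np.ndarray = field(repr=False)
    kmo: float = np.nan
    bartlett_chi2: float = np.nan
    bartlett_df: int = 0
    bartlett_p: float = np.nan

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def explained_variance_pct(eigenvalues, p: int | None = None) -> np.ndarray:
    """Percent of total variance per component: 100 * lambda / p.

    For correlation-matrix PCA the total variance equals the number of
    variables p (the trace), so the denominator is p rather than the
    eigenvalue sum when p is given.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    total = float(p) if p is not None else float(lam.sum())
    return 100.0 * lam / total


def pca(data, eigen_threshold: float = 1.0) -> PcaResult:
    """PCA on the correlation matrix of (implicitly z-scored) data.

    Components with eigenvalue above ``eigen_threshold`` are retained;
    each component's sign is fixed so its largest-magnitude loading is
    positive.  KMO and Bartlett statistics are attached for adequacy
    screening.
    """
    x, names = _as_matrix(data)
    n, p = x.shape
    if not np.all(np.isfinite(x)):
        raise ValidationError("PCA input contains non-finite values")
    if n <= p:
        raise ValidationError("PCA requires more samples than variables")
    z = zscore(x)
    r = np.corrcoef(z, rowvar=False)
    w, v = np.linalg.eigh(r)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w = np.clip(w, 0.0, None)
    keep = np.flatnonzero(w > eigen_threshold)
    vecs = v[:, keep].copy()
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
    loadings = pd.DataFrame(
        vecs * np.sqrt(w[keep]),
        index=names,
        columns=[f"F{i + 1}" for i in range(len(keep))],
    )
    pct = explained_variance_pct(w, p)
    return PcaResult(
        eigenvalues=w,
        variance_pct=pct,
        cumulative_pct=np.cumsum(pct),
        loadings=loadings,
        scores=z @ vecs,
        kmo=kmo(r),
        bartlett_chi2=bartlett_sphericity(r, n)[0],
        bartlett_df=bartlett_sphericity(r, n)[1],
        bartlett_p=bartlett_sphericity(r, n)[2],
    )


def hcluster(
    data,
    k: int = 2,
    method: str = "ward",
    anchor: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of samples into k zones.

    Ward linkage on Euclidean distance over z-scored columns by default.
    Labels are 1..k, renumbered so cluster 1 has the largest mean of
    ``anchor`` (default: the Fe column when present, else the first
    column) — mirroring the convention that zone 1 is the
    high-concentration zone.  Returns (labels, linkage merge table).
    """
    x, names = _as_matrix(data)
    n = len(x)
    if k > n:
        raise ValidationError(f"cannot form {k} clusters from {n} samples")
    if anchor is None:
        j = names.index("Fe") if "Fe" in names else 0
        anchor = x[:, j]
    z = zscore(x)
    merges = scipy_linkage(z, method=method)
    labels = fcluster(merges, t=k, criterion="maxclust")
    anchor = np.asarray(anchor, dtype=float)
    means = {lab: anchor[labels == lab].mean() for lab in np.unique(labels)}
    ranked = sorted(means, key=means.get, reverse=True)
    remap = {old: new + 1 for new, old in enumerate(ranked)}
    return np.array([remap[lab] for lab in labels]), merges


@dataclass
class ClusterReport:
    """Per-cluster descriptive statistics with per-metal ANOVA contrasts.

    ``stats`` is long-format (cluster, metal, n, min, max, mean, sd,
    skewness, kurtosis); ``anova`` has one row per metal (F, p, and the
    two-group significance letters per cluster — different letters mean
    the cluster means differ at p < 0.05).
    """

    labels: np.ndarray
    stats: pd.DataFrame
    anova: pd.DataFrame

    @property
    def cluster_sizes(self) -> dict[int, int]:
        labs, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))


def cluster_summary(samples: SampleSet, labels) -> ClusterReport:
    """Descriptive statistics and one-way ANOVA per metal across clusters."""
    labels = np.asarray(labels)
    if len(labels) != samples.n:
        raise ValidationError("labels must cover all samples")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 clusters to contrast")
    rows = []
    for lab in uniq:
        mask = labels == lab
        if mask.sum() == 1:
            warnings.warn(
                f"cluster {lab} is a singleton; sd/skewness/kurtosis undefined",
                stacklevel=2,
            )
        for metal in samples.metals:
            v = samples.values(metal)[mask]
            single = len(v) < 2
            rows.append(
                {
                    "cluster": lab,
                    "metal": metal,
                    "n": len(v),
                    "min": v.min(),
                    "max": v.max(),
                    "mean": v.mean(),
                    "sd": np.nan if single else v.std(ddof=1),
                    "skewness": np.nan if len(v) < 3 else stats.skew(v, bias=False),
                    "kurtosis": np.nan if len(v) < 4 else stats.kurtosis(v, bias=False),
                }
            )
    anova_rows = []
    two_group = len(uniq) == 2
    for metal in samples.metals:
        groups = [samples.values(metal)[labels == lab] for lab in uniq]
        if np.ptp(np.concatenate(groups)) == 0:
            f_stat, p_val = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, p_val = stats.f_oneway(*groups)
            if not np.isfinite(f_stat):
                f_stat, p_val = 0.0, 1.0
        row = {"metal": metal, "F": float(f_stat), "p": float(p_val)}
        if two_group:
            means = [g.mean() for g in groups]
            if p_val < 0.05:
                letters = ["a", "b"] if means[0] >= means[1] else ["b", "a"]
            else:
                letters = ["a", "a"]
            for lab, letter in zip(uniq, letters):
                row[f"letter_C{lab}"] = letter
        anova_rows.append(row)
    return ClusterReport(labels, pd.DataFrame(rows), pd.DataFrame(anova_rows))
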