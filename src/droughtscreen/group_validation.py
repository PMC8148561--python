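"""Multivariate validation of tolerance groupings.

Given the genotype x score matrix (per-trait, per-season membership scores)
and the tolerance classes, this module checks that the grouping is supported
by independent multivariate structure: Euclidean hierarchical clustering
(Ward or UPGMA), principal coordinates analysis, a Mantel permutation test
between distance matrices, canonical discriminant functions (eigenvectors of
W^-1 B), Box's M homogeneity test with an LDA/QDA resubstitution classifier
at equal priors, and one-way MANOVA (Wilks' lambda with Rao's F
approximation) with per-trait group means and pairwise contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "DiscriminantModel",
    "ManovaResult",
    "euclidean_distances",
    "hierarchical_cluster",
    "cophenetic_distances",
    "pcoa",
    "mantel_test",
    "canonical_discriminant",
    "box_m",
    "box_m_and_classify",
    "manova",
]


# ---------------------------------------------------------------------------
# distances, clustering, ordination
# ---------------------------------------------------------------------------

def euclidean_distances(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance matrix between rows."""
    x = scores.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("missing or non-finite values in score matrix")
    d = squareform(pdist(x, metric="euclidean"))
    return pd.DataFrame(d, index=scores.index, columns=scores.index)


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray  # scipy merge history: (pair, height, size)
    labels: list[str]
    method: str
    assignments: pd.Series | None = None  # cut at k groups

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(
    distances: pd.DataFrame, method: str = "ward", k: int | None = None
) -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    ``method`` is 'ward' (minimum within-cluster variance increase) or
    'upgma' (unweighted average linkage). If ``k`` is given the tree is cut
    into exactly k groups.
    """
    scipy_method = {"ward": "ward", "upgma": "average"}.get(method)
    if scipy_method is None:
        raise ValueError("linkage must be 'ward' or 'upgma'")
    condensed = squareform(distances.to_numpy(dtype=float), checks=True)
    z = hierarchy.linkage(condensed, method=scipy_method)
    dend = Dendrogram(
        linkage_matrix=z, labels=list(distances.index), method=method
    )
    if k is not None:
        if not 1 <= k <= len(dend.labels):
            raise ValueError("k must be between 1 and the number of items")
        dend.assignments = dend.cut(k)
    return dend


def cophenetic_distances(dend: Dendrogram) -> pd.DataFrame:
    d = squareform(hierarchy.cophenet(dend.linkage_matrix))
    return pd.DataFrame(d, index=dend.labels, columns=dend.labels)


def pcoa(distances: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (principal coordinates analysis).

    Double-centers -D^2/2, eigendecomposes, and returns coordinates on the
    positive-eigenvalue axes (eigenvectors scaled by sqrt(eigenvalue)) plus
    the percentage of variation explained by each retained axis.
    """
    d = distances.to_numpy(dtype=float)
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if np.all(d == 0):
        raise ValueError("all distances are zero")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = w > 1e-10 * w.max()
    w_pos, v_pos = w[keep], v[:, keep]
    coords = v_pos * np.sqrt(w_pos)
    explained = 100.0 * w_pos / w[w > 0].sum()
    cols = [f"PCoA{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=distances.index, columns=cols), explained


def mantel_test(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel permutation test between two distance matrices.

    Pearson r over the upper off-diagonal triangles; the p-value permutes the
    row/column labels of the second matrix, p = (#{r_perm >= r_obs} + 1) /
    (n_perm + 1) for the one-sided 'greater' alternative ('two-sided' uses
    |r_perm| >= |r_obs|).
    """
    if not d1.index.equals(d2.index):
        d2 = d2.loc[d1.index, d1.index]
    a = d1.to_numpy(dtype=float)
    b = d2.to_numpy(dtype=float)
    n = a.shape[0]
    if n < 4:
        raise ValueError("need at least 4 items for a Mantel test")
    iu = np.triu_indices(n, k=1)
    va, vb = a[iu], b[iu]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant off-diagonal distances")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    za = (va - va.mean()) / va.std()
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = b[np.ix_(perm, perm)][iu]
        r_perm = float(np.mean(za * (vp - vp.mean()) / vp.std()))
        if alternative == "greater":
            count += r_perm >= r_obs
        else:
            count += abs(r_perm) >= abs(r_obs)
    p = (count + 1) / (n_perm + 1)
    return r_obs, float(p)


# ---------------------------------------------------------------------------
# discriminant analysis, Box's M, MANOVA
# ---------------------------------------------------------------------------

def _sscp(scores: pd.DataFrame, groups: pd.Series):
    """Within- and between-group SSCP matrices and group summaries."""
    x = scores.to_numpy(dtype=float)
    g = pd.Series(groups, index=scores.index)
    grand = x.mean(axis=0)
    w = np.zeros((x.shape[1], x.shape[1]))
    b = np.zeros_like(w)
    means, sizes = {}, {}
    for label, idx in g.groupby(g).groups.items():
        xi = scores.loc[idx].to_numpy(dtype=float)
        mu = xi.mean(axis=0)
        resid = xi - mu
        w += resid.T @ resid
        diff = (mu - grand)[:, None]
        b += len(xi) * (diff @ diff.T)
        means[label], sizes[label] = mu, len(xi)
    return w, b, means, sizes


@dataclass
class DiscriminantModel:
    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    loadings: pd.DataFrame  # trait x canonical function coefficients
    group_means_canonical: pd.DataFrame  # group x function centroids
    box_m: float | None = None
    box_m_df: float | None = None
    box_m_p: float | None = None
    classifier: str | None = None
    resubstitution_error_pct: float | None = None
    predictions: pd.Series | None = None
    flags: list[str] = field(default_factory=list)


def canonical_discriminant(
    scores: pd.DataFrame, groups: pd.Series, regularize: float = 0.0
) -> DiscriminantModel:
    """Canonical discriminant functions: eigenvectors of W^-1 B.

    At most min(groups - 1, traits) functions carry nonzero eigenvalues;
    explained percentages are over the retained functions. A singular
    within-group SSCP raises unless ``regularize`` adds a ridge (flagged).
    """
    groups = pd.Series(groups, index=scores.index)
    sizes = groups.value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups, each with >= 2 members")
    w, b, means, _ = _sscp(scores, groups)
    flags = []
    if regularize > 0:
        w = w + regularize * np.eye(w.shape[0])
        flags.append(f"within-SSCP ridge {regularize:g}")
    try:
        evals, evecs = linalg.eigh(b, w)
    except linalg.LinAlgError as err:
        raise ValueError(
            "within-group SSCP is singular; pass regularize > 0"
        ) from err
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    n_fn = min(len(sizes) - 1, scores.shape[1])
    evals, evecs = evals[:n_fn], evecs[:, :n_fn]
    # deterministic sign: largest |coefficient| positive
    for kk in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, kk]))
        if evecs[i, kk] < 0:
            evecs[:, kk] = -evecs[:, kk]
    total = evals.sum()
    explained = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    fn_names = [f"Can{i + 1}" for i in range(n_fn)]
    loadings = pd.DataFrame(evecs, index=scores.columns, columns=fn_names)
    centroids = pd.DataFrame(
        {lab: mu @ evecs for lab, mu in means.items()}, index=fn_names
    ).T
    return DiscriminantModel(
        eigenvalues=evals,
        explained_pct=explained,
        loadings=loadings,
        group_means_canonical=centroids,
        flags=flags,
    )


def box_m(scores: pd.DataFrame, groups: pd.Series) -> tuple[float, float, float]:
    """Box's M test of covariance homogeneity, chi-squared approximation.

    Returns (statistic, df, p). Group sizes must exceed the trait count so
    per-group covariances are nonsingular.
    """
    groups = pd.Series(groups, index=scores.index)
    p = scores.shape[1]
    labels = groups.unique()
    g = len(labels)
    n_total = len(scores)
    pooled = np.zeros((p, p))
    logdets, ns = [], []
    for lab in labels:
        xi = scores.loc[groups == lab].to_numpy(dtype=float)
        ni = len(xi)
        if ni <= p:
            raise ValueError(
                f"group {lab!r} has {ni} members <= {p} traits; "
                "covariance singular for Box's M"
            )
        si = np.cov(xi, rowvar=False)
        sign, logdet = np.linalg.slogdet(si)
        if sign <= 0:
            raise ValueError(f"degenerate covariance in group {lab!r}")
        pooled += (ni - 1) * si
        logdets.append(logdet)
        ns.append(ni)
    pooled /= n_total - g
    sign, logdet_pooled = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise ValueError("degenerate pooled covariance")
    m_stat = (n_total - g) * logdet_pooled - sum(
        (ni - 1) * ld for ni, ld in zip(ns, logdets)
    )
    c = (sum(1 / (ni - 1) for ni in ns) - 1 / (n_total - g)) * (
        2 * p**2 + 3 * p - 1
    ) / (6 * (p + 1) * (g - 1))
    chi2 = m_stat * (1 - c)
    df = p * (p + 1) * (g - 1) / 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), float(df), pval


def _gaussian_classify(
    scores: pd.DataFrame, means: dict, covs: dict
) -> pd.Series:
    """Argmax of per-group Gaussian log-densities at equal priors."""
    labels = list(means)
    x = scores.to_numpy(dtype=float)
    ll = np.empty((len(x), len(labels)))
    for j, lab in enumerate(labels):
        cov = covs[lab]
        sign, logdet = np.linalg.slogdet(cov)
        inv = np.linalg.inv(cov)
        diff = x - means[lab]
        ll[:, j] = -0.5 * (logdet + np.einsum("ij,jk,ik->i", diff, inv, diff))
    best = np.asarray(labels, dtype=object)[np.argmax(ll, axis=1)]
    return pd.Series(best, index=scores.index, name="predicted")


def box_m_and_classify(
    scores: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    allow_pooled_fallback: bool = True,
) -> DiscriminantModel:
    """Box's M-guided discriminant classification with equal priors.

    If Box's M rejects covariance homogeneity at ``alpha``, a quadratic
    (per-group covariance) classifier is used; otherwise a linear (pooled
    covariance) one. Groups too small for a stable per-group covariance fall
    back to the pooled estimate (flagged). Reports the resubstitution error.
    """
    groups = pd.Series(groups, index=scores.index)
    model = canonical_discriminant(scores, groups)
    p = scores.shape[1]
    w, _, means, sizes = _sscp(scores, groups)
    pooled = w / (len(scores) - len(sizes))
    try:
        m_stat, m_df, m_p = box_m(scores, groups)
        classifier = "qda" if m_p < alpha else "lda"
    except ValueError as err:
        if not allow_pooled_fallback:
            raise
        logger.warning("Box's M unavailable (%s); using pooled LDA", err)
        m_stat = m_df = m_p = None
        classifier = "lda"
        model.flags.append("box-m-unavailable")

    covs = {}
    for lab, mu in means.items():
        if classifier == "qda" and sizes[lab] > p:
            xi = scores.loc[groups == lab].to_numpy(dtype=float)
            covs[lab] = np.cov(xi, rowvar=False)
        else:
            if classifier == "qda":
                model.flags.append(f"pooled covariance fallback for group {lab!r}")
                logger.warning(
                    "group %r too small for per-group covariance; pooled used", lab
                )
            covs[lab] = pooled
    predictions = _gaussian_classify(scores, means, covs)
    error_pct = 100.0 * float((predictions != groups).mean())

    model.box_m, model.box_m_df, model.box_m_p = m_stat, m_df, m_p
    model.classifier = classifier
    model.resubstitution_error_pct = error_pct
    model.predictions = predictions
    return model


@dataclass
class ManovaResult:
    wilks_lambda: float
    f_stat: float
    df: tuple[float, float]
    p_value: float
    ls_means: pd.DataFrame  # group x trait means
    pairwise: pd.DataFrame  # per trait, group pair, diff, p, significant


def manova(
    scores: pd.DataFrame, groups: pd.Series, alpha: float = 0.05
) -> ManovaResult:
    """One-way MANOVA: Wilks' lambda with Rao's F approximation.

    Also reports per-trait group (LS) means and unadjusted pairwise
    mean-difference t tests using the pooled within-group variance.
    """
    groups = pd.Series(groups, index=scores.index)
    p = scores.shape[1]
    g = groups.nunique()
    n = len(scores)
    if n - g < p:
        raise ValueError("residual df smaller than trait count")
    w, b, means, sizes = _sscp(scores, groups)
    sign_t, logdet_t = np.linalg.slogdet(w + b)
    if sign_t <= 0:
        raise ValueError("total SSCP is singular")
    sign_w, logdet_w = np.linalg.slogdet(w)
    lam = float(np.exp(logdet_w - logdet_t)) if sign_w > 0 else 0.0

    vh, ve = g - 1, n - g
    m = ve + vh - (p + vh + 1) / 2
    denom = p**2 + vh**2 - 5
    t = np.sqrt((p**2 * vh**2 - 4) / denom) if denom > 0 else 1.0
    df1 = p * vh
    df2 = m * t - p * vh / 2 + 1
    lam_t = lam ** (1 / t) if lam > 0 else 0.0
    f_stat = (1 - lam_t) / lam_t * df2 / df1 if lam_t > 0 else np.inf
    p_value = float(stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0

    ls_means = pd.DataFrame(means).T
    ls_means.columns = scores.columns
    ls_means.index.name = "group"

    mse = np.diag(w) / ve
    rows = []
    labels = list(means)
    for trait_i, trait in enumerate(scores.columns):
        for a in range(len(labels)):
            for bdx in range(a + 1, len(labels)):
                la, lb = labels[a], labels[bdx]
                diff = means[la][trait_i] - means[lb][trait_i]
                se = np.sqrt(mse[trait_i] * (1 / sizes[la] + 1 / sizes[lb]))
                tt = diff / se if se > 0 else np.inf
                pv = 2 * stats.t.sf(abs(tt), ve)
                rows.append(
                    {
                        "trait": trait,
                        "group_a": la,
                        "group_b": lb,
                        "difference": diff,
                        "p_value": pv,
                        "significant": pv < alpha,
                    }
                )
    return ManovaResult(
        wilks_lambda=lam,
        f_stat=float(f_stat),
        df=(float(df1), float(df2)),
        p_value=p_value,
        ls_means=ls_means,
        pairwise=pd.DataFrame(rows),
    )
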