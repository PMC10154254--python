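"""Relatedness pruning and ancestry assignment.

Reproduces the sample-selection stage of a cohort GWAS follow-up: a
robust pairwise kinship matrix is estimated from a panel of common,
LD-pruned biallelic markers; a maximal set of mutually unrelated samples
is retained (greedy, deterministic); and continental ancestry is assigned
by projecting study genotypes onto principal components fitted to a
labelled reference panel and classifying with a Gaussian
shared-covariance (linear discriminant) model on the leading PCs.

Kinship uses the heterozygote-concordance (between-family, "robust")
estimator: for a pair (i, j) over their jointly observed markers,

    phi_ij = (N_het,het - 2 * N_opposing_hom) / (N_het(i) + N_het(j))

which is 0.5 for duplicates, ~0.25 for full sibs, ~0 for unrelated pairs,
and needs no allele-frequency estimates, making it robust to population
structure. PCA uses Patterson scaling: each marker centred by 2*p_hat and
scaled by sqrt(2*p_hat*(1-p_hat)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import DimensionError, InputError, ProjectionError
from .genotype_io import GenotypeMatrix

KINSHIP_THRESHOLD_3RD_DEGREE = 0.0442  # midpoint cut between 3rd degree and unrelated

UNASSIGNED = "unassigned"


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    phi: np.ndarray  # symmetric, diagonal unused

    def pairs_above(self, threshold: float) -> list[tuple[str, str, float]]:
        out = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.phi[i, j] > threshold:
                    out.append((self.sample_ids[i], self.sample_ids[j], float(self.phi[i, j])))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((self.sample_ids[i], self.sample_ids[j], self.phi[i, j]))
        return pd.DataFrame(rows, columns=["id1", "id2", "phi"])


@dataclass
class PcaModel:
    """Frequency-scaled PCA of a reference panel, reusable for projection."""

    marker_ids: list[str]
    center: np.ndarray  # 2 * p_hat per marker
    scale: np.ndarray  # sqrt(2 p (1-p)) per marker
    loadings: np.ndarray  # markers x K
    reference_scores: np.ndarray  # reference samples x K
    explained_variance_ratio: np.ndarray


@dataclass
class AncestryAssignment:
    sample_id: str
    pcs: np.ndarray
    label: str
    posterior: float


def select_pca_markers(
    matrix: GenotypeMatrix,
    n_target: tuple[int, int] = (30_000, 100_000),
    maf_min: float = 0.05,
    r2_prune: float = 0.2,
    window: int = 50,
    step: int = 25,
) -> np.ndarray:
    """Indices of common markers surviving sliding-window LD pruning.

    Markers below ``maf_min`` are dropped; within each window of
    ``window`` markers (advanced by ``step``) any marker whose dosage r²
    with an already-kept earlier marker exceeds ``r2_prune`` is dropped.
    If more than ``n_target[1]`` survive, the list is thinned evenly; if
    fewer than ``n_target[0]`` survive a warning is emitted and the
    survivors are returned.
    """
    d = matrix.dosages
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    candidate = np.flatnonzero(~np.isnan(maf) & (maf >= maf_min))

    keep_flag = np.ones(len(candidate), dtype=bool)
    filled = d[:, candidate]
    col_mean = np.where(np.isnan(p[candidate]), 0.0, 2 * p[candidate])
    filled = np.where(np.isnan(filled), col_mean, filled)
    m = len(candidate)
    start = 0
    while start < m:
        stop = min(start + window, m)
        idx = np.arange(start, stop)
        live = idx[keep_flag[idx]]
        if len(live) > 1:
            block = filled[:, live]
            sd = block.std(axis=0)
            ok = sd > 0
            corr = np.zeros((len(live), len(live)))
            if ok.sum() > 1:
                sub = np.corrcoef(block[:, ok], rowvar=False)
                corr[np.ix_(ok, ok)] = sub
            r2 = corr**2
            for a in range(len(live)):
                if not keep_flag[live[a]]:
                    continue
                for b in range(a + 1, len(live)):
                    if keep_flag[live[b]] and r2[a, b] > r2_prune:
                        keep_flag[live[b]] = False
        if stop == m:
            break
        start += step

    kept = candidate[keep_flag]
    lo, hi = n_target
    if len(kept) > hi:
        kept = kept[np.linspace(0, len(kept) - 1, hi).astype(int)]
    elif len(kept) < lo:
        warnings.warn(
            f"only {len(kept)} markers survive pruning (target >= {lo})",
            stacklevel=2,
        )
    return kept


def estimate_kinship(matrix: GenotypeMatrix) -> KinshipMatrix:
    """Pairwise robust kinship from identity-state counts.

    Missing genotypes are pairwise-deleted. Runs as a handful of matrix
    products, so scales to thousands of samples at 10^4-10^5 markers.
    """
    if matrix.n_samples < 2:
        raise InputError("kinship needs at least 2 samples")
    if matrix.n_variants < 1000:
        warnings.warn(
            f"kinship on {matrix.n_variants} markers; >= 1000 recommended",
            stacklevel=2,
        )
    d = matrix.dosages
    obs = (~np.isnan(d)).astype(float)
    het = (d == 1).astype(float)
    hom_ref = (d == 0).astype(float)
    hom_alt = (d == 2).astype(float)

    n_het_het = het @ het.T
    n_opp = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    # heterozygote counts of each member over the pair's shared markers
    het_i = het @ obs.T
    denom = het_i + het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_het_het - 2.0 * n_opp) / denom
    phi[denom == 0] = 0.0
    np.fill_diagonal(phi, 0.5)
    return KinshipMatrix(sample_ids=list(matrix.sample_ids), phi=phi)


def maximal_unrelated_set(
    kinship: KinshipMatrix,
    threshold: float = KINSHIP_THRESHOLD_3RD_DEGREE,
    missingness: dict[str, float] | None = None,
) -> list[str]:
    """Greedy maximal independent set in the above-threshold relatedness graph.

    Iteratively drops the sample with the most above-threshold partners;
    ties are broken toward higher missingness, then lexicographically
    larger id, so the result is deterministic. The returned set is
    verified to contain no related pair.
    """
    if threshold <= 0:
        raise InputError("kinship threshold must be > 0")
    ids = kinship.sample_ids
    n = len(ids)
    adj = kinship.phi > threshold
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    miss = missingness or {}
    deg = adj.sum(axis=1)  # updated incrementally as samples are dropped
    while True:
        worst = int(deg[alive].max(initial=0)) if alive.any() else 0
        if worst == 0:
            break
        cand = np.flatnonzero(alive & (deg == worst))
        drop = max(cand, key=lambda i: (miss.get(ids[i], 0.0), ids[i]))
        alive[drop] = False
        deg[adj[drop]] -= 1
        deg[drop] = 0
    kept = [ids[i] for i in np.flatnonzero(alive)]
    # invariant: no retained pair is related above threshold
    sub = adj[np.ix_(alive, alive)]
    assert not sub.any(), "greedy pruning left a related pair"
    return kept


def _standardise(
    dosages: np.ndarray, center: np.ndarray, scale: np.ndarray
) -> np.ndarray:
    z = (dosages - center) / scale
    return np.where(np.isnan(z), 0.0, z)  # mean-impute missing after centring


def fit_reference_pca(reference: GenotypeMatrix, k: int = 10) -> PcaModel:
    """Centred, frequency-scaled PCA of a reference panel.

    Monomorphic markers are excluded (their scale is zero). Raises
    DimensionError when ``k`` exceeds the data's rank.
    """
    d = reference.dosages
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0
    poly = ~np.isnan(p) & (p > 0) & (p < 1)
    d = d[:, poly]
    p = p[poly]
    center = 2.0 * p
    scale = np.sqrt(2.0 * p * (1.0 - p))
    z = _standardise(d, center, scale)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if len(s) else 0
    if k > rank:
        raise DimensionError(f"requested {k} PCs but rank is {rank}")
    var = s**2
    return PcaModel(
        marker_ids=[reference.variants.loc[i, "id"] for i in np.flatnonzero(poly)],
        center=center,
        scale=scale,
        loadings=vt[:k].T,
        reference_scores=u[:, :k] * s[:k],
        explained_variance_ratio=var[:k] / var.sum(),
    )


def project_onto_pca(
    model: PcaModel, study: GenotypeMatrix, min_overlap: float = 0.8
) -> np.ndarray:
    """Project study samples onto reference loadings (no shrinkage correction)."""
    study_ids = {v: i for i, v in enumerate(study.variants["id"])}
    present = [m in study_ids for m in model.marker_ids]
    overlap = np.mean(present) if model.marker_ids else 0.0
    if overlap < min_overlap:
        raise ProjectionError(
            f"marker overlap {overlap:.2%} below minimum {min_overlap:.0%}"
        )
    cols = [study_ids.get(m) for m in model.marker_ids]
    d = np.full((study.n_samples, len(model.marker_ids)), np.nan)
    for k, c in enumerate(cols):
        if c is not None:
            d[:, k] = study.dosages[:, c]
    z = _standardise(d, model.center, model.scale)
    return z @ model.loadings


def project_and_classify(
    pca_model: PcaModel,
    study: GenotypeMatrix,
    reference_labels: list[str],
    confidence_floor: float = 0.9,
    min_overlap: float = 0.8,
    typicality_floor: float = 1e-6,
) -> list[AncestryAssignment]:
    """Assign an ancestry label to each study sample.

    A linear discriminant (Gaussian class-conditional, shared covariance)
    model is fitted to the reference samples' PC scores and labels; each
    projected study sample receives the argmax-posterior label. A sample
    is ``unassigned`` when the maximum posterior falls below
    ``confidence_floor`` or when it is atypical of every class: posteriors
    are relative, so a point far from all centroids (an admixed or
    unrepresented ancestry) can still saturate one class's posterior. The
    typicality test compares the Mahalanobis distance to the predicted
    class mean (under the pooled within-class covariance) against the
    chi-squared(K) tail; samples below ``typicality_floor`` are
    unassigned.
    """
    if len(reference_labels) != pca_model.reference_scores.shape[0]:
        raise InputError("one reference label required per reference sample")
    if study.n_samples == 0:
        return []
    scores = project_onto_pca(pca_model, study, min_overlap=min_overlap)
    ref_scores = pca_model.reference_scores
    labels_arr = np.asarray(reference_labels)
    clf = LinearDiscriminantAnalysis()
    clf.fit(ref_scores, reference_labels)
    post = clf.predict_proba(scores)
    best = post.argmax(axis=1)

    classes = [str(c) for c in clf.classes_]
    means = {c: ref_scores[labels_arr == c].mean(axis=0) for c in classes}
    resid = np.vstack([ref_scores[labels_arr == c] - means[c] for c in classes])
    pooled_cov = np.cov(resid, rowvar=False)
    pooled_icov = np.linalg.pinv(np.atleast_2d(pooled_cov))
    k = scores.shape[1]

    out = []
    for i, sid in enumerate(study.sample_ids):
        p = float(post[i, best[i]])
        label = classes[best[i]]
        delta = scores[i] - means[label]
        d2 = float(delta @ pooled_icov @ delta)
        typical = stats.chi2.sf(d2, df=k) >= typicality_floor
        if p < confidence_floor or not typical:
            label = UNASSIGNED
        out.append(
            AncestryAssignment(sample_id=sid, pcs=scores[i], label=label, posterior=p)
        )
    return out
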