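"""Three-pronged DDI / non-DDI classification of a test sample.

A test profile is judged by three independent analyses over the biomarker
genes:

* **PA** — posterior probability from the shrunken-centroid discriminant,
  positive when P(DDI) exceeds a cutoff (0.9 by default);
* **2DC** — the sample is appended to the reference profiles, the joint set
  is clustered (Euclidean distance, average linkage) and cut into two
  clusters; the call is the majority reference class of the sample's cluster;
* **PCA** — the sample is projected onto the first principal component of
  the reference profiles, which separates the two classes; the call depends
  on which side of the midpoint between the class mean scores it falls.

The overall rule is deliberately sensitivity-first: a chemical is called
DDI if ANY one analysis is positive; non-DDI only when none is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .core_data import ExpressionMatrix, TernaryCall
from .errors import AlignmentError, DegenerateModelError, ValidationError
from .nsc import CLASSES, DDI, NONDDI, NSCModel, _normalize_labels, surviving_features

__all__ = [
    "ClassificationReport",
    "classify_pa",
    "hclust_average",
    "classify_2dc",
    "classify_pca",
    "overall_call",
    "classify_sample",
]


@dataclass
class ClassificationReport:
    """Per-sample outcome of the three analyses plus the overall call."""

    sample_id: str
    pa_posterior: float
    pa_call: TernaryCall
    c2dc_call: TernaryCall
    c2dc_cluster_composition: dict[str, int]
    pca_score: float
    pca_call: TernaryCall
    overall_call: TernaryCall

    def to_row(self) -> dict[str, object]:
        return {
            "sample": self.sample_id,
            "pa_posterior": self.pa_posterior,
            "pa": str(self.pa_call),
            "2dc": str(self.c2dc_call),
            "pca": str(self.pca_call),
            "overall": str(self.overall_call),
        }


def _as_vector(sample: Union[pd.Series, np.ndarray], gene_ids: Sequence[str]) -> np.ndarray:
    """Align a sample to ``gene_ids``; Series are reindexed, arrays must match."""
    if isinstance(sample, pd.Series):
        missing = [g for g in gene_ids if g not in sample.index]
        if missing:
            raise AlignmentError(f"sample lacks gene(s): {', '.join(missing[:10])}")
        return sample.reindex(gene_ids).to_numpy(dtype=float)
    arr = np.asarray(sample, dtype=float).ravel()
    if arr.shape != (len(gene_ids),):
        raise AlignmentError(f"sample has {arr.size} values for {len(gene_ids)} genes")
    return arr


def classify_pa(
    model: NSCModel,
    sample: Union[pd.Series, np.ndarray],
    cutoff: float = 0.9,
) -> tuple[float, TernaryCall]:
    """Posterior probability of DDI and the corresponding ternary call.

    The discriminant per class is computed over the surviving genes,

        delta_k(x) = sum_j (x_j - xbar'_kj)^2 / (s_j + s0)^2 - 2 log pi_k,

    and posteriors follow as exp(-delta_k/2) normalized across classes
    (evaluated with a log-sum-exp shift for numerical stability). The call
    is positive when P(DDI) > cutoff, negative when P(DDI) < 1 - cutoff,
    marginal in between.
    """
    if not 0.5 < cutoff < 1:
        raise ValidationError("cutoff must be in (0.5, 1)")
    alive = np.any(model.shrunken_diff != 0.0, axis=0)
    if not alive.any():
        raise DegenerateModelError("no surviving genes at this shrinkage; cannot classify")
    genes = [g for g, a in zip(model.gene_ids, alive) if a]
    x = _as_vector(sample, genes) if isinstance(sample, pd.Series) else _as_vector(sample, model.gene_ids)[alive]
    centroids = model.shrunken_centroids()[:, alive]
    scale = (model.pooled_sd[alive] + model.sd_offset) ** 2
    disc = np.array(
        [((x - centroids[k]) ** 2 / scale).sum() - 2.0 * np.log(model.priors[k]) for k in range(2)]
    )
    logp = -0.5 * disc
    logp -= logp.max()  # stable normalization
    p = np.exp(logp)
    p /= p.sum()
    p_ddi = float(p[model.classes.index(DDI)])
    if p_ddi > cutoff:
        call = TernaryCall.POS
    elif p_ddi < 1.0 - cutoff:
        call = TernaryCall.NEG
    else:
        call = TernaryCall.MARGINAL
    return p_ddi, call


def hclust_average(d: np.ndarray) -> np.ndarray:
    """Agglomerative clustering of a symmetric distance matrix under
    unweighted average linkage.

    Returns the merge list in scipy linkage form: row ``[i, j, height, size]``
    merges clusters ``i`` and ``j`` (leaves are 0..n-1, new clusters n, n+1,
    ...). Heights are non-decreasing.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValidationError("distance matrix diagonal must be zero")
    if np.any(d < 0):
        raise ValidationError("distances must be non-negative")
    return linkage(squareform(d, checks=False), method="average")


def classify_2dc(
    reference: ExpressionMatrix,
    labels: Sequence[str],
    sample: Union[pd.Series, np.ndarray],
    sample_id: str = "test",
) -> tuple[TernaryCall, dict[str, int]]:
    """Two-cluster call: append the sample to the reference set, cluster with
    Euclidean average linkage, cut into two clusters, and call by the
    majority reference class of the sample's cluster.

    Marginal on an exact class tie or when the sample clusters alone.
    """
    lab = _normalize_labels(labels, reference.n_samples)
    if len(set(lab)) < 2:
        raise ValidationError("reference must contain both classes")
    x = _as_vector(sample, reference.gene_ids)
    profiles = np.column_stack([reference.values, x]).T  # (n+1) x J, sample last
    Z = hclust_average(squareform(pdist(profiles), checks=False))
    assign = fcluster(Z, t=2, criterion="maxclust")
    mine = assign[-1]
    in_cluster = np.flatnonzero(assign[:-1] == mine)
    composition = {
        DDI: int((lab[in_cluster] == DDI).sum()),
        NONDDI: int((lab[in_cluster] == NONDDI).sum()),
    }
    if composition[DDI] > composition[NONDDI]:
        call = TernaryCall.POS
    elif composition[DDI] < composition[NONDDI]:
        call = TernaryCall.NEG
    else:  # tie, or no reference samples share the cluster
        call = TernaryCall.MARGINAL
    return call, composition


def classify_pca(
    reference: ExpressionMatrix,
    labels: Sequence[str],
    sample: Union[pd.Series, np.ndarray],
    margin_frac: float = 0.10,
) -> tuple[float, TernaryCall]:
    """First-principal-component call.

    PCA is fitted on the gene-centered reference profiles; PC1 is oriented so
    the DDI reference mean score is positive. The boundary is the midpoint of
    the class mean scores, with a marginal zone of half-width
    ``margin_frac * |mean_DDI - mean_nonDDI|``.
    """
    if not 0 <= margin_frac < 0.5:
        raise ValidationError("margin_frac must be in [0, 0.5)")
    lab = _normalize_labels(labels, reference.n_samples)
    for c in CLASSES:
        if (lab == c).sum() < 3:
            raise ValidationError(f"reference needs >=3 samples in class {c} for PCA")
    X = reference.values.T  # samples x genes
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise DegenerateModelError("reference profiles have zero variance")
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(X).ravel()  # centered internally by the fit
    mean_ddi = scores[lab == DDI].mean()
    mean_non = scores[lab == NONDDI].mean()
    if mean_ddi < mean_non:  # orient PC1 so DDI scores positive
        scores, mean_ddi, mean_non = -scores, -mean_ddi, -mean_non
        pca.components_ = -pca.components_
    x = _as_vector(sample, reference.gene_ids)
    score = float(pca.transform(x[None, :])[0, 0])
    boundary = 0.5 * (mean_ddi + mean_non)
    eps = margin_frac * abs(mean_ddi - mean_non)
    if score > boundary + eps:
        call = TernaryCall.POS
    elif score < boundary - eps:
        call = TernaryCall.NEG
    else:
        call = TernaryCall.MARGINAL
    return score, call


def overall_call(pa: TernaryCall, c2dc: TernaryCall, pca: TernaryCall) -> TernaryCall:
    """Combine the three per-method calls.

    Positive if any method is positive; negative only when all three are
    negative; marginal otherwise (some method marginal, none positive).
    """
    calls = (pa, c2dc, pca)
    if TernaryCall.POS in calls:
        return TernaryCall.POS
    if all(c is TernaryCall.NEG for c in calls):
        return TernaryCall.NEG
    return TernaryCall.MARGINAL


def classify_sample(
    model: NSCModel,
    reference: ExpressionMatrix,
    labels: Sequence[str],
    sample: Union[pd.Series, np.ndarray],
    sample_id: str = "test",
    cutoff: float = 0.9,
    margin_frac: float = 0.10,
) -> ClassificationReport:
    """Run all three analyses on one sample and combine them.

    Distances and projections use the model's surviving genes only, so the
    ensemble sees exactly the feature set the shrinkage retained.
    """
    genes = surviving_features(model)
    if not genes:
        raise DegenerateModelError("no surviving genes at this shrinkage; cannot classify")
    ref = reference.subset_genes(genes)
    if isinstance(sample, pd.Series):
        vec = sample
    else:
        vec = pd.Series(_as_vector(sample, model.gene_ids), index=model.gene_ids)
    vec = vec.reindex(genes)
    if vec.isna().any():
        raise AlignmentError("sample lacks surviving panel genes")
    posterior, pa = classify_pa(model, vec, cutoff=cutoff)
    c2dc, composition = classify_2dc(ref, labels, vec, sample_id=sample_id)
    score, pca_c = classify_pca(ref, labels, vec, margin_frac=margin_frac)
    return ClassificationReport(
        sample_id=sample_id,
        pa_posterior=posterior,
        pa_call=pa,
        c2dc_call=c2dc,
        c2dc_cluster_composition=composition,
        pca_score=score,
        pca_call=pca_c,
        overall_call=overall_call(pa, c2dc, pca_c),
    )
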