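"""Signature discovery: responsive-gene filtering and the nearest shrunken
centroid (NSC) classifier.

The NSC model standardizes each class centroid by the pooled within-class
standard deviation (plus a stabilizing offset ``s0``) and soft-thresholds the
standardized class-vs-overall difference toward zero by a shrinkage
parameter ``delta``:

    d_kj  = (xbar_kj - xbar_j) / (m_k * (s_j + s0))
    d'_kj = sign(d_kj) * max(|d_kj| - delta, 0)

Genes whose difference survives for at least one class form the biomarker
panel; ``delta`` controls panel size. The classifier is strictly two-class
(DNA-damage-inducing vs not).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ExpressionMatrix
from .errors import (
    FoldError,
    InsufficientReplicatesError,
    PairingError,
    TrainingError,
    ValidationError,
)

__all__ = [
    "DDI",
    "NONDDI",
    "CLASSES",
    "FilterCriteria",
    "NSCModel",
    "filter_responsive_genes",
    "compute_log2_ratios",
    "train_nsc",
    "surviving_features",
    "shrinkage_path",
    "cross_validate",
    "CVResult",
]

DDI = "DDI"
NONDDI = "NONDDI"
CLASSES = (DDI, NONDDI)


@dataclass
class FilterCriteria:
    """Thresholds for the responsive-gene pre-filter.

    A gene qualifies in a treatment condition when a two-sample Welch t-test
    between treated and control replicates gives p < ``p_threshold`` AND the
    linear fold change is at least ``fc_threshold`` in either direction; it is
    retained when it qualifies in at least ``min_conditions`` conditions.
    """

    p_threshold: float = 0.01
    fc_threshold: float = 1.7
    min_conditions: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValidationError("p_threshold must be in (0, 1)")
        if self.fc_threshold < 1:
            raise ValidationError("fc_threshold must be >= 1")
        if self.min_conditions < 1:
            raise ValidationError("min_conditions must be >= 1")


def filter_responsive_genes(
    replicated_profiles: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    criteria: FilterCriteria = FilterCriteria(),
) -> list[str]:
    """Select genes significantly perturbed in enough treatment conditions.

    Parameters
    ----------
    replicated_profiles
        Mapping of condition name to ``(treated, control)`` gene x replicate
        DataFrames of log2-scale expression; all conditions must share the
        gene index, each arm needs >= 2 replicates.
    criteria
        Significance / fold-change / condition-count thresholds.

    Returns genes (input order preserved) qualifying in at least
    ``criteria.min_conditions`` conditions.
    """
    if not replicated_profiles:
        raise ValidationError("no treatment conditions supplied")
    gene_order: Optional[pd.Index] = None
    counts: Optional[np.ndarray] = None
    for cond, (treated, control) in replicated_profiles.items():
        if treated.shape[1] < 2 or control.shape[1] < 2:
            raise InsufficientReplicatesError(
                f"condition {cond!r} needs >=2 replicates per arm for the t-test"
            )
        if gene_order is None:
            gene_order = treated.index
            counts = np.zeros(len(gene_order), dtype=int)
        if not treated.index.equals(gene_order) or not control.index.equals(gene_order):
            raise ValidationError(f"condition {cond!r} gene index differs from the first condition")
        t_arr = treated.to_numpy(dtype=float)
        c_arr = control.to_numpy(dtype=float)
        # Welch's t-test on log2 values, unadjusted p
        _, p = stats.ttest_ind(t_arr, c_arr, axis=1, equal_var=False)
        fc = 2.0 ** (t_arr.mean(axis=1) - c_arr.mean(axis=1))
        big = (fc >= criteria.fc_threshold) | (fc <= 1.0 / criteria.fc_threshold)
        counts += ((p < criteria.p_threshold) & big).astype(int)
    assert gene_order is not None and counts is not None
    return [g for g, c in zip(gene_order, counts) if c >= criteria.min_conditions]


def compute_log2_ratios(
    treated: ExpressionMatrix,
    control: ExpressionMatrix,
    pairing: Mapping[str, str],
) -> ExpressionMatrix:
    """log2(treated/control) per gene for each treated sample and its paired
    control; inputs are linear-scale intensities (all strictly positive)."""
    if treated.gene_ids != control.gene_ids:
        raise ValidationError("treated and control matrices must share gene ids and order")
    unpaired = [s for s in treated.sample_ids if s not in pairing]
    if unpaired:
        raise PairingError(f"treated sample(s) without a control pairing: {', '.join(unpaired)}")
    bad_ref = [c for c in pairing.values() if c not in control.sample_ids]
    if bad_ref:
        raise PairingError(f"pairing references unknown control sample(s): {', '.join(bad_ref)}")
    if np.any(treated.values <= 0) or np.any(control.values <= 0):
        raise ValidationError("intensities must be strictly positive to form ratios")
    cols = []
    for s in treated.sample_ids:
        t = treated.values[:, treated.sample_ids.index(s)]
        c = control.values[:, control.sample_ids.index(pairing[s])]
        cols.append(np.log2(t / c))
    return ExpressionMatrix(
        treated.gene_ids, treated.sample_ids, np.column_stack(cols), treated.samples_meta
    )


@dataclass
class NSCModel:
    """A trained two-class nearest shrunken centroid model.

    All per-gene arrays are aligned with ``gene_ids``; per-class arrays are
    ordered as ``classes`` = (DDI, NONDDI).
    """

    classes: tuple[str, str]
    gene_ids: list[str]
    overall_centroid: np.ndarray       # xbar_j
    class_centroids: np.ndarray        # (2, J) xbar_kj
    pooled_sd: np.ndarray              # s_j
    sd_offset: float                   # s0
    m_k: np.ndarray                    # (2,) class normalizers
    delta: float
    shrunken_diff: np.ndarray          # (2, J) d'_kj
    priors: np.ndarray                 # (2,) pi_k
    n_per_class: np.ndarray            # (2,)
    n_total: int
    m_variant: str = "plus"            # "plus": sqrt(1/n_k + 1/n); "minus": sqrt(1/n_k - 1/n)

    @property
    def raw_diff(self) -> np.ndarray:
        """Unshrunken standardized differences d_kj (recomputed)."""
        denom = self.m_k[:, None] * (self.pooled_sd + self.sd_offset)[None, :]
        return (self.class_centroids - self.overall_centroid[None, :]) / denom

    def shrunken_centroids(self) -> np.ndarray:
        """xbar'_kj = xbar_j + m_k (s_j + s0) d'_kj, shape (2, J)."""
        return (
            self.overall_centroid[None, :]
            + self.m_k[:, None] * (self.pooled_sd + self.sd_offset)[None, :] * self.shrunken_diff
        )

    def validate(self) -> None:
        J = len(self.gene_ids)
        if self.class_centroids.shape != (2, J) or self.shrunken_diff.shape != (2, J):
            raise ValidationError("per-class arrays must have shape (2, n_genes)")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValidationError("priors must sum to 1")
        if np.any(self.pooled_sd < 0):
            raise ValidationError("pooled SDs must be non-negative")
        if np.any(self.pooled_sd > 0) and not self.sd_offset > 0:
            raise ValidationError("sd_offset must be positive when any gene varies")

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format": "tgxddi-nsc-model",
            "format_version": 1,
            "classes": list(self.classes),
            "gene_ids": self.gene_ids,
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "sd_offset": self.sd_offset,
            "m_k": self.m_k.tolist(),
            "delta": self.delta,
            "shrunken_diff": self.shrunken_diff.tolist(),
            "priors": self.priors.tolist(),
            "n_per_class": self.n_per_class.tolist(),
            "n_total": self.n_total,
            "m_variant": self.m_variant,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NSCModel":
        doc = json.loads(text)
        if doc.get("format") != "tgxddi-nsc-model":
            raise ValidationError("not an NSC model document")
        model = cls(
            classes=tuple(doc["classes"]),
            gene_ids=list(doc["gene_ids"]),
            overall_centroid=np.array(doc["overall_centroid"], dtype=float),
            class_centroids=np.array(doc["class_centroids"], dtype=float),
            pooled_sd=np.array(doc["pooled_sd"], dtype=float),
            sd_offset=float(doc["sd_offset"]),
            m_k=np.array(doc["m_k"], dtype=float),
            delta=float(doc["delta"]),
            shrunken_diff=np.array(doc["shrunken_diff"], dtype=float),
            priors=np.array(doc["priors"], dtype=float),
            n_per_class=np.array(doc["n_per_class"], dtype=int),
            n_total=int(doc["n_total"]),
            m_variant=doc.get("m_variant", "plus"),
        )
        model.validate()
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "NSCModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _normalize_labels(labels: Sequence[str], n_samples: int) -> np.ndarray:
    if len(labels) != n_samples:
        raise ValidationError(f"{len(labels)} labels for {n_samples} samples")
    lab = np.array([str(l).strip().upper().replace("-", "") for l in labels])
    lab[lab == "NON"] = NONDDI
    bad = sorted(set(lab) - set(CLASSES))
    if bad:
        raise ValidationError(f"unknown class label(s): {', '.join(bad)}; expected DDI / NONDDI")
    return lab


def train_nsc(
    m: ExpressionMatrix,
    labels: Sequence[str],
    delta: float,
    priors: Union[Literal["proportional", "uniform"], Sequence[float]] = "proportional",
    m_variant: Literal["plus", "minus"] = "plus",
) -> NSCModel:
    """Train the two-class NSC model at shrinkage threshold ``delta``.

    ``m_variant`` selects the class normalizer: ``"plus"`` uses
    ``m_k = sqrt(1/n_k + 1/n)`` (default), ``"minus"`` the
    ``sqrt(1/n_k - 1/n)`` variant.
    """
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    lab = _normalize_labels(labels, m.n_samples)
    X = m.values  # J x n
    n = m.n_samples
    masks = [lab == k for k in CLASSES]
    n_k = np.array([mask.sum() for mask in masks])
    for k, nk in zip(CLASSES, n_k):
        if nk < 2:
            raise TrainingError(f"class {k} has {nk} sample(s); need >= 2")

    class_centroids = np.stack([X[:, mask].mean(axis=1) for mask in masks])  # 2 x J
    overall_centroid = X.mean(axis=1)
    ss_within = sum(
        ((X[:, mask] - cc[:, None]) ** 2).sum(axis=1)
        for mask, cc in zip(masks, class_centroids)
    )
    pooled_sd = np.sqrt(ss_within / (n - len(CLASSES)))
    s0 = float(np.median(pooled_sd))
    if s0 <= 0:
        raise TrainingError("all genes are constant within classes; cannot standardize")

    if m_variant == "plus":
        m_k = np.sqrt(1.0 / n_k + 1.0 / n)
    elif m_variant == "minus":
        m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    else:
        raise ValidationError(f"unknown m_variant {m_variant!r}")

    d = (class_centroids - overall_centroid[None, :]) / (m_k[:, None] * (pooled_sd + s0)[None, :])
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)

    if isinstance(priors, str):
        if priors == "proportional":
            pi = n_k / n
        elif priors == "uniform":
            pi = np.full(2, 0.5)
        else:
            raise ValidationError(f"unknown priors mode {priors!r}")
    else:
        pi = np.asarray(priors, dtype=float)
        if pi.shape != (2,) or np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0):
            raise ValidationError("explicit priors must be two positive numbers summing to 1")

    model = NSCModel(
        classes=CLASSES,
        gene_ids=list(m.gene_ids),
        overall_centroid=overall_centroid,
        class_centroids=class_centroids,
        pooled_sd=pooled_sd,
        sd_offset=s0,
        m_k=m_k,
        delta=float(delta),
        shrunken_diff=d_shrunk,
        priors=pi,
        n_per_class=n_k,
        n_total=n,
        m_variant=m_variant,
    )
    model.validate()
    return model


def surviving_features(model: NSCModel) -> list[str]:
    """Genes whose shrunken difference is nonzero for at least one class."""
    alive = np.any(model.shrunken_diff != 0.0, axis=0)
    return [g for g, a in zip(model.gene_ids, alive) if a]


def shrinkage_path(
    m: ExpressionMatrix,
    labels: Sequence[str],
    deltas: Sequence[float],
    k: int = 10,
    seed: int = 0,
    priors: Union[str, Sequence[float]] = "proportional",
) -> pd.DataFrame:
    """Surviving-gene count and k-fold CV accuracy along a shrinkage grid.

    Returns a DataFrame with columns ``delta``, ``n_surviving``,
    ``cv_accuracy``, ordered by delta.
    """
    ds = sorted(float(d) for d in deltas)
    if not ds:
        raise ValidationError("deltas grid is empty")
    if any(d < 0 for d in ds):
        raise ValidationError("deltas must be non-negative")
    rows = []
    for d in ds:
        model = train_nsc(m, labels, d, priors=priors)
        cv = cross_validate(m, labels, d, k=k, seed=seed, priors=priors)
        rows.append({"delta": d, "n_surviving": len(surviving_features(model)),
                     "cv_accuracy": cv.accuracy})
    return pd.DataFrame(rows)


@dataclass
class CVResult:
    """Cross-validation outcome: overall accuracy plus per-fold assignments."""

    accuracy: float
    folds: list[list[str]]                      # sample ids per fold
    predictions: dict[str, str]                 # sample id -> predicted class
    truths: dict[str, str]


def _predict_classes(model: NSCModel, X: np.ndarray) -> list[str]:
    """Argmin-discriminant class per column of X (aligned to model genes)."""
    centroids = model.shrunken_centroids()
    scale = (model.pooled_sd + model.sd_offset) ** 2
    out = []
    for j in range(X.shape[1]):
        x = X[:, j]
        disc = [
            float(((x - centroids[k]) ** 2 / scale).sum() - 2.0 * np.log(model.priors[k]))
            for k in range(2)
        ]
        out.append(model.classes[int(np.argmin(disc))])
    return out


def stratified_folds(
    labels: Sequence[str], k: int, seed: int
) -> list[list[int]]:
    """Seeded stratified folds: per class, shuffle then chunk; remainder
    samples go to the earliest folds."""
    lab = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in sorted(set(lab)):
        idx = np.flatnonzero(lab == cls)
        idx = idx[rng.permutation(len(idx))]
        base, rem = divmod(len(idx), k)
        start = 0
        for f in range(k):
            size = base + (1 if f < rem else 0)
            folds[f].extend(int(i) for i in idx[start : start + size])
            start += size
    return folds


def cross_validate(
    m: ExpressionMatrix,
    labels: Sequence[str],
    delta: float,
    k: int = 10,
    seed: int = 0,
    priors: Union[str, Sequence[float]] = "proportional",
) -> CVResult:
    """Stratified k-fold cross-validation of the NSC classifier.

    Identical seeds yield identical folds and accuracy. Raises
    :class:`FoldError` if any fold would leave fewer than two training
    samples in either class.
    """
    lab = _normalize_labels(labels, m.n_samples)
    folds_idx = stratified_folds(lab, k, seed)
    n_k = {c: int((lab == c).sum()) for c in CLASSES}
    for f, fold in enumerate(folds_idx):
        held = lab[fold] if fold else np.array([])
        for c in CLASSES:
            left = n_k[c] - int((held == c).sum()) if len(held) else n_k[c]
            if left < 2:
                raise FoldError(
                    f"fold {f} leaves {left} training sample(s) in class {c}; use smaller k"
                )
    predictions: dict[str, str] = {}
    truths: dict[str, str] = {}
    for fold in folds_idx:
        if not fold:
            continue
        train_mask = np.ones(m.n_samples, dtype=bool)
        train_mask[fold] = False
        train_m = ExpressionMatrix(
            m.gene_ids, [m.sample_ids[i] for i in np.flatnonzero(train_mask)],
            m.values[:, train_mask],
        )
        model = train_nsc(train_m, lab[train_mask], delta, priors=priors)
        preds = _predict_classes(model, m.values[:, fold])
        for i, pred in zip(fold, preds):
            sid = m.sample_ids[i]
            predictions[sid] = pred
            truths[sid] = str(lab[i])
    correct = sum(predictions[s] == truths[s] for s in predictions)
    return CVResult(
        accuracy=correct / len(predictions),
        folds=[[m.sample_ids[i] for i in fold] for fold in folds_idx],
        predictions=predictions,
        truths=truths,
    )
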