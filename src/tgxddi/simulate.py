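"""Synthetic data with known ground truth.

Real training data for the DNA-damage biomarker (microarray profiles of TK6
cells under 28 reference agents) is not redistributable, so the toolkit
ships a generator that emulates its statistical shape: two classes of
log2-ratio profiles where a planted subset of genes separates the classes,
plus Hill-shaped per-gene dose-response series for the potency workflow.
Noise is Gaussian on the log2 scale (log-normal on the linear scale), the
standard microarray error model. Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .bmd import DoseResponseSeries
from .core_data import ExpressionMatrix, SampleMeta
from .errors import ValidationError
from .nsc import DDI, NONDDI

__all__ = [
    "SimulationSpec",
    "simulate_reference_set",
    "simulate_test_samples",
    "simulate_dose_series",
]


@dataclass
class SimulationSpec:
    """Parameters of the two-class reference-set generator.

    ``effect`` is the mean log2-ratio shift of informative genes in DDI
    samples (half shifted up, half down); ``sigma`` the per-observation
    noise SD in log2 units.
    """

    n_ddi: int = 11
    n_nonddi: int = 17
    n_genes: int = 500
    n_informative: int = 20
    effect: float = 2.0
    sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ddi < 2 or self.n_nonddi < 2:
            raise ValidationError("need at least 2 samples per class")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValidationError("n_informative must be in [0, n_genes]")
        if not self.sigma > 0:
            raise ValidationError("sigma must be positive")


def simulate_reference_set(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, list[str], list[str]]:
    """Draw a two-class log2-ratio reference matrix with planted signal.

    Returns ``(matrix, labels, informative_gene_ids)``. Non-informative
    genes are Normal(0, sigma) in both classes; informative genes receive an
    additional +effect (first half) or -effect (second half) in DDI samples.
    Identical seeds produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(1, spec.n_genes + 1)]
    info_idx = np.sort(rng.choice(spec.n_genes, size=spec.n_informative, replace=False))
    n = spec.n_ddi + spec.n_nonddi
    values = rng.normal(0.0, spec.sigma, size=(spec.n_genes, n))
    half = spec.n_informative // 2
    shift = np.zeros(spec.n_informative)
    shift[:half] = spec.effect
    shift[half:] = -spec.effect
    values[info_idx, : spec.n_ddi] += shift[:, None]
    sample_ids = [f"DDI{i:02d}" for i in range(1, spec.n_ddi + 1)] + [
        f"NON{i:02d}" for i in range(1, spec.n_nonddi + 1)
    ]
    labels = [DDI] * spec.n_ddi + [NONDDI] * spec.n_nonddi
    meta = {s: SampleMeta(agent=s, class_label=c) for s, c in zip(sample_ids, labels)}
    m = ExpressionMatrix(genes, sample_ids, values, samples_meta=meta)
    return m, labels, [genes[i] for i in info_idx]


def simulate_test_samples(
    spec: SimulationSpec,
    informative: Sequence[str],
    gene_ids: Sequence[str],
    n_ddi: int,
    n_nonddi: int,
    seed: int,
) -> tuple[ExpressionMatrix, list[str]]:
    """Fresh draws from the same generating distribution as the reference.

    Used to evaluate classifiers on samples never seen during training.
    """
    rng = np.random.default_rng(seed)
    genes = list(gene_ids)
    info_pos = [genes.index(g) for g in informative]
    n = n_ddi + n_nonddi
    values = rng.normal(0.0, spec.sigma, size=(len(genes), n))
    half = len(info_pos) // 2
    shift = np.zeros(len(info_pos))
    shift[:half] = spec.effect
    shift[half:] = -spec.effect
    values[np.asarray(info_pos, dtype=int), :n_ddi] += shift[:, None]
    sample_ids = [f"tDDI{i:03d}" for i in range(1, n_ddi + 1)] + [
        f"tNON{i:03d}" for i in range(1, n_nonddi + 1)
    ]
    labels = [DDI] * n_ddi + [NONDDI] * n_nonddi
    return ExpressionMatrix(genes, sample_ids, values), labels


def simulate_dose_series(
    true_params: Mapping[str, tuple[float, float, float, float]],
    doses: Sequence[float],
    reps: int = 3,
    sigma: float = 0.05,
    seed: int = 0,
) -> list[DoseResponseSeries]:
    """Hill-shaped dose-response series with multiplicative log-normal noise.

    ``true_params`` maps gene id to Hill parameters ``(a, b, k, n)`` on the
    linear expression scale (f(d) = a + b d^n / (k^n + d^n)). Responses are
    f(d) * exp(Normal(0, sigma)) converted to log2 ratios.
    """
    d = [float(x) for x in doses]
    if any(not (b > a) for a, b in zip(d, d[1:])):
        raise ValidationError("doses must be strictly increasing")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for gene, (a, b, k, n) in true_params.items():
        if k <= 0:
            raise ValidationError(f"gene {gene}: Hill k must be positive")
        if a <= 0:
            raise ValidationError(f"gene {gene}: baseline a must be positive")
        responses = []
        for dose in d:
            f = a + b * (dose**n / (k**n + dose**n) if dose > 0 else 0.0)
            lin = f * np.exp(rng.normal(0.0, sigma, size=reps))
            responses.append(list(np.log2(lin)))
        out.append(DoseResponseSeries(gene_id=gene, doses=d, responses=responses))
    return out
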