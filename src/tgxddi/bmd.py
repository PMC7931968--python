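"""Concentration pre-screen and benchmark-dose (BMD) potency estimation.

The pre-screen mirrors the dose-setting step used before profiling: the
transcriptional response of three stress genes (GADD45A, ATF3, CDKN1A) is
measured over candidate concentrations, and the lowest concentration giving
a robust fold increase in at least one of them is carried forward.

Potency is estimated gene-by-gene: each dose-response series (log2 ratios,
converted to the linear expression scale where the control is 1) is fitted
with a small model family (Hill, exponential), the benchmark dose is the
concentration at which the fitted curve departs from its baseline by the
benchmark response (10% by default), and the panel potency is the median of
the per-gene BMDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .errors import FittingError, PotencyUndefinedError, ValidationError

__all__ = [
    "STRESS_GENES",
    "DoseResponseSeries",
    "ModelFit",
    "BMDResult",
    "select_screen_dose",
    "fit_dose_response",
    "compute_bmd",
    "panel_potency",
]

STRESS_GENES = ("GADD45A", "ATF3", "CDKN1A")


@dataclass
class DoseResponseSeries:
    """Replicated log2-ratio responses of one gene over increasing doses."""

    gene_id: str
    doses: list[float]
    responses: list[list[float]]  # log2 ratios, one list of replicates per dose
    unit: str = "uM"

    def __post_init__(self) -> None:
        d = [float(x) for x in self.doses]
        if any(x < 0 for x in d):
            raise ValidationError("doses must be non-negative")
        if any(not (b > a) for a, b in zip(d, d[1:])):
            raise ValidationError("doses must be strictly increasing")
        if len(self.responses) != len(d):
            raise ValidationError("one replicate list per dose required")
        if any(len(r) < 1 for r in self.responses):
            raise ValidationError("each dose needs at least one replicate")
        self.doses = d

    def flatten_linear(self) -> tuple[np.ndarray, np.ndarray]:
        """(dose, linear response) pairs, replicates expanded; control == 1."""
        ds, ys = [], []
        for d, reps in zip(self.doses, self.responses):
            for r in reps:
                ds.append(d)
                ys.append(2.0 ** float(r))
        return np.array(ds), np.array(ys)


def select_screen_dose(
    panel_fc: pd.DataFrame, threshold: float = 1.5
) -> Optional[float]:
    """Lowest dose at which any stress gene shows a fold change >= threshold.

    ``panel_fc`` is a dose-indexed DataFrame of linear fold changes with one
    column per stress gene (GADD45A, ATF3, CDKN1A). Returns ``None`` when no
    dose qualifies.
    """
    cols = {c.strip().upper() for c in panel_fc.columns}
    missing = [g for g in STRESS_GENES if g not in cols]
    if missing:
        raise ValidationError(f"pre-screen table lacks stress gene(s): {', '.join(missing)}")
    fc = panel_fc.copy()
    fc.columns = [c.strip().upper() for c in fc.columns]
    fc = fc[list(STRESS_GENES)]
    qualifying = fc.index[(fc >= threshold).any(axis=1)]
    if len(qualifying) == 0:
        return None
    return float(min(qualifying))


def _hill(params: np.ndarray, d: np.ndarray) -> np.ndarray:
    a, b, k, n = params
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(d > 0, d**n / (k**n + d**n), 0.0)
    return a + b * frac


def _expo(params: np.ndarray, d: np.ndarray) -> np.ndarray:
    a, c = params
    return a * np.exp(c * d)


_HILL_N_MAX = 18.0  # cap on the Hill coefficient; avoids step-function fits


@dataclass
class ModelFit:
    """One fitted dose-response model on the linear expression scale."""

    model_name: str            # "hill" or "exponential"
    params: np.ndarray
    rss: float
    aic: float
    converged: bool
    n_obs: int

    def predict(self, d: np.ndarray | float) -> np.ndarray | float:
        darr = np.asarray(d, dtype=float)
        out = _hill(self.params, darr) if self.model_name == "hill" else _expo(self.params, darr)
        return float(out) if np.isscalar(d) else out


@dataclass
class BMDResult:
    """Per-gene benchmark dose."""

    gene_id: str
    model_name: str
    params: np.ndarray
    bmd: Optional[float]
    bmr: float
    converged: bool
    fit_quality: float          # AIC of the selected model
    status: str                 # "ok" | "above-range" | "non-responsive" | "no-fit"


def _aic(rss: float, n: int, p: int) -> float:
    rss = max(rss, 1e-300)
    return n * float(np.log(rss / n)) + 2 * p


def _fit_one(model: str, d: np.ndarray, y: np.ndarray, seed: int) -> ModelFit:
    rng = np.random.default_rng(seed)
    dmax = d.max()
    dpos = d[d > 0]
    y0 = float(np.median(y[d == d.min()])) if (d == d.min()).any() else float(y.mean())
    span = float(y.max() - y.min())

    if model == "hill":
        resid = lambda p: _hill(p, d) - y
        lo = np.array([1e-8, -100.0, max(dpos.min() / 100.0, 1e-9) if dpos.size else 1e-9, 1.0])
        hi = np.array([100.0, 100.0, dmax * 100.0, _HILL_N_MAX])
        starts = []
        for _ in range(5):
            starts.append(
                np.array(
                    [
                        max(y0, 1e-6),
                        span * rng.uniform(0.5, 1.5) * (1 if y[-1] >= y[0] else -1),
                        float(rng.uniform(dpos.min(), dmax)) if dpos.size else 1.0,
                        float(rng.uniform(1.0, 4.0)),
                    ]
                )
            )
        p_len = 4
    elif model == "exponential":
        resid = lambda p: _expo(p, d) - y
        lo = np.array([1e-8, -50.0 / max(dmax, 1e-9)])
        hi = np.array([100.0, 50.0 / max(dmax, 1e-9)])
        slope0 = np.log(max(y[-1], 1e-6) / max(y0, 1e-6)) / max(dmax, 1e-9)
        starts = [np.array([max(y0, 1e-6), slope0 * f]) for f in (1.0, 0.5, 2.0, -1.0, 0.0)]
        p_len = 2
    else:
        raise ValidationError(f"unknown model {model!r}")

    best: Optional[ModelFit] = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), max_nfev=2000)
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        fit = ModelFit(model, sol.x, rss, _aic(rss, len(y), p_len), bool(sol.success), len(y))
        if best is None or fit.rss < best.rss:
            best = fit
    if best is None:
        return ModelFit(model, np.full(p_len, np.nan), np.inf, np.inf, False, len(y))
    return best


def fit_dose_response(
    series: DoseResponseSeries,
    family: Sequence[str] = ("hill", "exponential"),
    seed: int = 0,
) -> dict[str, ModelFit]:
    """Least-squares fits of each model in ``family`` on the linear scale.

    Multi-start (5 seeded starts per model); the returned mapping carries one
    :class:`ModelFit` per model plus the AIC-best under key ``"best"``.
    Non-convergence is reported on the fit, not raised.
    """
    if len(set(series.doses)) < 3:
        raise FittingError(f"gene {series.gene_id}: need >=3 distinct doses to fit")
    d, y = series.flatten_linear()
    if not np.all(np.isfinite(y)):
        raise FittingError(f"gene {series.gene_id}: non-finite responses")
    fits = {m: _fit_one(m, d, y, seed) for m in family}
    converged = {m: f for m, f in fits.items() if f.converged}
    pool = converged or fits
    fits["best"] = min(pool.values(), key=lambda f: f.aic)
    return fits


def compute_bmd(fit: ModelFit, bmr: float = 0.10, d_max: Optional[float] = None) -> BMDResult:
    """Benchmark dose of a fitted curve: the smallest d in [0, d_max] with
    |f(d) - f(0)| = bmr * |f(0)|, found by monotone root bracketing.

    When the curve never departs by the benchmark response within range the
    result is flagged ``above-range`` (bmd None).
    """
    if not 0 < bmr < 1:
        raise ValidationError("bmr must be in (0, 1)")
    if d_max is None:
        d_max = 10.0 ** np.ceil(np.log10(max(fit.params[2] if fit.model_name == "hill" else 1.0, 1.0))) * 100
    f0 = float(fit.predict(0.0))
    if f0 == 0:
        raise ValidationError("baseline f(0) = 0; benchmark response undefined")
    target = bmr * abs(f0)
    g = lambda d: abs(float(fit.predict(d)) - f0) - target
    # scan a log-spaced grid for the first bracket
    grid = np.concatenate([[0.0], np.logspace(np.log10(d_max) - 9, np.log10(d_max), 400)])
    bmd: Optional[float] = None
    for a, b in zip(grid, grid[1:]):
        ga, gb = g(a), g(b)
        if ga == 0:
            bmd = float(a)
            break
        if ga < 0 <= gb:
            bmd = float(brentq(g, a, b, xtol=1e-12, rtol=1e-12))
            break
    status = "ok" if bmd is not None and bmd > 0 else "above-range"
    if bmd is not None and bmd == 0:
        status = "ok"
    return BMDResult(
        gene_id="",
        model_name=fit.model_name,
        params=fit.params,
        bmd=bmd,
        bmr=bmr,
        converged=fit.converged,
        fit_quality=fit.aic,
        status=status,
    )


def panel_potency(
    series_set: Iterable[DoseResponseSeries],
    bmr: float = 0.10,
    family: Sequence[str] = ("hill", "exponential"),
    seed: int = 0,
    amplitude_floor: float = 0.02,
) -> tuple[float, pd.DataFrame]:
    """Median benchmark dose over a gene panel, plus a per-gene status table.

    Genes whose fitted curve moves less than ``amplitude_floor`` (linear
    fraction of baseline) across the tested range are flagged
    ``non-responsive``; only in-range, converged BMDs enter the median.
    """
    rows = []
    usable = []
    for series in series_set:
        d_max = max(series.doses)
        try:
            fits = fit_dose_response(series, family=family, seed=seed)
        except FittingError as exc:
            rows.append({"gene": series.gene_id, "status": "no-fit", "bmd": np.nan,
                         "model": "", "note": str(exc)})
            continue
        best = fits["best"]
        dgrid = np.linspace(0, d_max, 200)
        curve = np.asarray(best.predict(dgrid))
        f0 = float(best.predict(0.0))
        if not best.converged:
            rows.append({"gene": series.gene_id, "status": "no-fit", "bmd": np.nan,
                         "model": best.model_name, "note": "did not converge"})
            continue
        if np.max(np.abs(curve - f0)) < amplitude_floor * abs(f0):
            rows.append({"gene": series.gene_id, "status": "non-responsive", "bmd": np.nan,
                         "model": best.model_name, "note": ""})
            continue
        res = compute_bmd(best, bmr=bmr, d_max=d_max)
        res.gene_id = series.gene_id
        if res.status == "ok" and res.bmd is not None and res.bmd <= d_max:
            usable.append(res.bmd)
            rows.append({"gene": series.gene_id, "status": "converged", "bmd": res.bmd,
                         "model": best.model_name, "note": ""})
        else:
            rows.append({"gene": series.gene_id, "status": "above-range", "bmd": np.nan,
                         "model": best.model_name, "note": ""})
    table = pd.DataFrame(rows, columns=["gene", "status", "bmd", "model", "note"])
    if not usable:
        raise PotencyUndefinedError("no gene yielded a converged, in-range benchmark dose")
    return float(np.median(usable)), table
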