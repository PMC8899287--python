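"""Information-criterion comparison of candidate gating schemes.

For least-squares fits the criterion is computed from the pooled SSE:

    AIC  = 2(k + 1) + n ln(SSE) - n ln(n)
    dAIC = 2k + n ln(SSE)

where ``k`` counts the fitted parameters (the +1 is the implicit error
variance), and ``n`` the total number of fitted data points.  The two forms
differ only by the model-independent constant ``2 - n ln(n)``, so they rank
models identically.  Relative support is summarised by Akaike weights,
``w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2)``, computed stably by
subtracting the minimum before exponentiation; ``w_i`` estimates the
probability that model i is the best of the candidate set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fitting import FitDataset, FitResult, GatingModelFitter, objective
from .schemes import scheme_catalogue

__all__ = [
    "aic",
    "delta_aic",
    "akaike_weights",
    "weight_ratio",
    "validation_sse",
    "ModelComparison",
    "ComparisonError",
    "compare_models",
    "SchemeSelector",
]


class ComparisonError(ValueError):
    """Candidate fits are not comparable (e.g. different data counts)."""


def _check_sse_n(n: int, sse_value: float) -> None:
    if n <= 0:
        raise ValueError("n must be > 0")
    if sse_value <= 0:
        raise ValueError("SSE must be > 0 for the log-likelihood surrogate")


def aic(k: int, n: int, sse_value: float) -> float:
    """Akaike information criterion for a least-squares fit."""
    _check_sse_n(n, sse_value)
    return 2.0 * (k + 1) + n * math.log(sse_value) - n * math.log(n)


def delta_aic(k: int, n: int, sse_value: float) -> float:
    """AIC without the model-independent constant: 2k + n ln(SSE)."""
    _check_sse_n(n, sse_value)
    return 2.0 * k + n * math.log(sse_value)


def akaike_weights(delta_aics) -> np.ndarray:
    """Akaike weights of a candidate set from its dAIC (or AIC) values."""
    d = np.asarray(delta_aics, dtype=float)
    if d.size == 0:
        raise ValueError("empty candidate list")
    if not np.all(np.isfinite(d)):
        raise ValueError("dAIC values must be finite")
    rel = d - d.min()
    w = np.exp(-rel / 2.0)
    return w / w.sum()


def weight_ratio(delta_aics, i: int, j: int) -> float:
    """Evidence ratio w_i / w_j = exp((dAIC_j - dAIC_i) / 2)."""
    d = np.asarray(delta_aics, dtype=float)
    return float(np.exp((d[j] - d[i]) / 2.0))


def validation_sse(
    result: FitResult, dataset: FitDataset, **solver_kwargs
) -> float:
    """SSE of a fitted model on held-out data, without refitting."""
    return objective(result.params, result.scheme_label, dataset, **solver_kwargs)


@dataclass
class ModelComparison:
    """Comparison table across candidate schemes, sorted by AIC."""

    table: pd.DataFrame
    best_label: str
    significant: bool

    def weight_of(self, label: str) -> float:
        return float(self.table.set_index("model").loc[label, "weight"])

    def ratio(self, label_i: str, label_j: str) -> float:
        t = self.table.set_index("model")
        return float(
            np.exp((t.loc[label_j, "delta_aic"] - t.loc[label_i, "delta_aic"]) / 2.0)
        )

    def write(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)


def compare_models(
    fit_results: list[FitResult],
    validation_datasets: list[FitDataset] | None = None,
    **solver_kwargs,
) -> ModelComparison:
    """Rank fitted candidate schemes by AIC and Akaike weight.

    All fits must share the same data count ``n``.  When validation
    datasets are given, each fitted model is additionally simulated on the
    held-out protocols and its validation SSE reported (no refitting).
    Ties in AIC are broken lexicographically by label; the best-vs-second
    comparison is flagged significant when the dAIC difference exceeds 2.
    """
    if not fit_results:
        raise ComparisonError("no fits to compare")
    ns = {r.n_points for r in fit_results}
    if len(ns) != 1:
        raise ComparisonError(f"inconsistent data counts across fits: {sorted(ns)}")
    rows = []
    for r in fit_results:
        rows.append(
            {
                "model": r.scheme_label,
                "k": r.k_params,
                "n": r.n_points,
                "sse": r.sse,
                "aic": aic(r.k_params, r.n_points, r.sse),
                "delta_aic": delta_aic(r.k_params, r.n_points, r.sse),
            }
        )
    table = pd.DataFrame(rows)
    table["weight"] = akaike_weights(table["delta_aic"].to_numpy())
    if validation_datasets:
        vals = []
        for r in fit_results:
            total = 0.0
            for ds in validation_datasets:
                total += validation_sse(r, ds, **solver_kwargs)
            vals.append(total)
        table["validation_sse"] = vals
    table = table.sort_values(["aic", "model"]).reset_index(drop=True)
    best = table.iloc[0]["model"]
    significant = (
        len(table) > 1
        and abs(table.iloc[1]["delta_aic"] - table.iloc[0]["delta_aic"]) > 2.0
    )
    return ModelComparison(table=table, best_label=str(best), significant=significant)


class SchemeSelector(BaseEstimator):
    """Fit every candidate scheme to a dataset and rank them by AIC.

    Parameters mirror :class:`GatingModelFitter`; ``schemes`` defaults to
    the full ten-model catalogue.

    Attributes
    ----------
    results_ : dict[str, FitResult]
    comparison_ : ModelComparison
    best_scheme_ : str
    """

    def __init__(
        self,
        schemes: list[str] | None = None,
        n_restarts: int = 10,
        random_state: int = 0,
        bounds: dict | None = None,
        p_leak: float = 0.0,
        max_nfev: int = 120,
        solver_method: str = "LSODA",
        rtol: float = 1e-7,
        atol: float = 1e-9,
        vj_modulation=None,
    ):
        self.schemes = schemes
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.bounds = bounds
        self.p_leak = p_leak
        self.max_nfev = max_nfev
        self.solver_method = solver_method
        self.rtol = rtol
        self.atol = atol
        self.vj_modulation = vj_modulation

    def fit(self, X: FitDataset, y=None, validation: list[FitDataset] | None = None):
        labels = self.schemes if self.schemes is not None else sorted(scheme_catalogue())
        self.results_ = {}
        for label in labels:
            fitter = GatingModelFitter(
                scheme=label,
                bounds=self.bounds,
                n_restarts=self.n_restarts,
                random_state=self.random_state,
                p_leak=self.p_leak,
                max_nfev=self.max_nfev,
                solver_method=self.solver_method,
                rtol=self.rtol,
                atol=self.atol,
                vj_modulation=self.vj_modulation,
            )
            fitter.fit(X)
            self.results_[label] = fitter.result_
        from .pair import VjModulation

        self.comparison_ = compare_models(
            list(self.results_.values()),
            validation_datasets=validation,
            method=self.solver_method,
            rtol=self.rtol,
            atol=self.atol,
            mod=self.vj_modulation if self.vj_modulation is not None else VjModulation(),
        )
        self.best_scheme_ = self.comparison_.best_label
        return self
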