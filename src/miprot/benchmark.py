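"""Confusion-matrix indicators, imputation-error diagnostics and the
multiple-imputation-vs-baseline benchmark runner.

``run_benchmark`` sweeps (design, missing proportion, imputation method,
dataset index): each synthetic dataset is amputed (or generated with mixed
MCAR+MNAR missingness), both workflow arms run on the *same* incomplete
matrix with the same engine, and decisions are scored against the ground
truth.  Datasets on which an arm declares zero positives are flagged
pathological: they are excluded from that arm's metric means but always
counted and reported.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .impute import ImputationEnsemble
from .simulate import (
    DESIGN_DEFAULTS,
    DESIGNS,
    GroundTruth,
    MnarMcarSpec,
    ampute,
)
from .workflow import PooledModeratedTTest, SingleImputationModeratedTTest

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMetrics",
    "ImputationErrorSet",
    "BenchmarkReport",
    "confusion_metrics",
    "count_pathological",
    "imputation_errors",
    "run_benchmark",
    "METRIC_NAMES",
]

METRIC_NAMES = ("sensitivity", "specificity", "precision", "f_score", "mcc")


@dataclass
class ConfusionMetrics:
    """Standard confusion-matrix indicators; undefined ratios are NaN."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    mcc: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f_score": self.f_score,
            "mcc": self.mcc,
        }


def _ratio(num, den):
    return float(num) / den if den > 0 else float("nan")


def confusion_metrics(decisions, truth) -> ConfusionMetrics:
    """Score boolean calls against truth labels (or a GroundTruth)."""
    if isinstance(truth, GroundTruth):
        truth = truth.is_de
    decisions = np.asarray(decisions, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if decisions.shape != truth.shape:
        raise ValueError("decision and truth vectors differ in length")
    tp = int((decisions & truth).sum())
    fp = int((decisions & ~truth).sum())
    tn = int((~decisions & ~truth).sum())
    fn = int((~decisions & truth).sum())
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    if np.isnan(prec) or np.isnan(sens) or prec + sens == 0:
        f = float("nan") if (np.isnan(prec) or np.isnan(sens)) else 0.0
    else:
        f = 2.0 * prec * sens / (prec + sens)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else float("nan")
    return ConfusionMetrics(tp, fp, tn, fn, sens, spec, prec, f, float(mcc))


def count_pathological(results: list, alpha: float = 0.05) -> int:
    """Datasets whose decision vector has zero positives at ``alpha``.

    ``results`` may hold result DataFrames (with a ``p_adjusted`` column)
    or plain boolean decision vectors.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n = 0
    for res in results:
        if isinstance(res, pd.DataFrame):
            calls = res["p_adjusted"].to_numpy() <= alpha
        else:
            calls = np.asarray(res, dtype=bool)
        if not calls.any():
            n += 1
    return n


@dataclass
class ImputationErrorSet:
    """Imputation errors on masked cells: per-draw and draw-averaged."""

    per_draw: np.ndarray  # (D, M)
    averaged: np.ndarray  # (M,)


def imputation_errors(ensemble: ImputationEnsemble, truth) -> ImputationErrorSet:
    """Errors (imputed - true) for every masked cell and draw.

    The draw-averaged errors correspond to the values actually used after
    combining the D draws by their mean.
    """
    complete = truth.complete if isinstance(truth, GroundTruth) else np.asarray(truth)
    if complete.shape != ensemble.source.values.shape:
        raise ValueError("truth matrix shape does not match the ensemble")
    if np.isnan(complete).any():
        raise ValueError("truth matrix must be complete")
    mask = ensemble.source_mask
    per_draw = ensemble.data[:, mask] - complete[mask]
    return ImputationErrorSet(per_draw=per_draw, averaged=per_draw.mean(axis=0))


# ---------------------------------------------------------------------------
# Benchmark runner
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    """Sweep results: per-dataset rows, aggregate means +/- sd, pathology."""

    per_dataset: pd.DataFrame
    aggregate: pd.DataFrame
    pathological: pd.DataFrame

    @classmethod
    def from_rows(cls, rows: pd.DataFrame) -> "BenchmarkReport":
        agg_rows = []
        path_rows = []
        for (method, prop), grp in rows.groupby(["method", "proportion"], sort=True):
            entry = {"method": method, "proportion": prop, "n_datasets": len(grp)}
            for arm in ("mi", "baseline"):
                n_path = int(grp[f"{arm}_pathological"].sum())
                path_rows.append(
                    {
                        "method": method,
                        "proportion": prop,
                        "arm": arm,
                        "n_pathological": n_path,
                    }
                )
                ok = ~grp[f"{arm}_pathological"]
                for m in METRIC_NAMES:
                    vals = grp.loc[ok, f"{arm}_{m}"]
                    entry[f"{arm}_{m}_mean"] = vals.mean()
                    entry[f"{arm}_{m}_sd"] = vals.std()
            ok_both = ~(grp["mi_pathological"] | grp["baseline_pathological"])
            for m in METRIC_NAMES:
                diff = grp.loc[ok_both, f"mi_{m}"] - grp.loc[ok_both, f"baseline_{m}"]
                entry[f"diff_{m}_mean"] = diff.mean()
                entry[f"diff_{m}_sd"] = diff.std()
            agg_rows.append(entry)
        return cls(
            per_dataset=rows,
            aggregate=pd.DataFrame(agg_rows),
            pathological=pd.DataFrame(path_rows),
        )


def _generate(design: str, proportion: float, seed: int, overrides: dict):
    """One incomplete dataset plus truth for a named design."""
    if design not in DESIGNS:
        raise ValueError(f"unknown design: {design!r}")
    spec_cls, fn = DESIGNS[design]
    kwargs = dict(DESIGN_DEFAULTS.get(design, {}))
    kwargs.update(overrides)
    if spec_cls is MnarMcarSpec:
        spec = spec_cls(missing_proportion=proportion, seed=seed, **kwargs)
        table, truth = fn(spec)
        return table, truth
    spec = spec_cls(seed=seed, **kwargs)
    complete, truth = fn(spec)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2**20,)))
    amputed = ampute(complete, proportion, mechanism="uniform", seed=rng.integers(2**31))
    return amputed, truth


def run_benchmark(
    design: str,
    methods=("mle",),
    proportions=(0.01, 0.05, 0.10, 0.15, 0.20, 0.25),
    n_datasets: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    design_overrides: dict | None = None,
    engine_params: dict | None = None,
) -> BenchmarkReport:
    """Run both workflow arms over a simulation sweep and score them.

    Dataset ``i`` uses seed ``seed + i`` for generation/amputation and for
    both arms, so the two arms always see the same incomplete matrix.  A
    failure on one dataset is logged and skipped without aborting the sweep.
    """
    overrides = design_overrides or {}
    rows = []
    for method in methods:
        for prop in proportions:
            for i in range(n_datasets):
                ds_seed = seed + i
                try:
                    table, truth = _generate(design, prop, ds_seed, overrides)
                    row = {
                        "design": design,
                        "method": method,
                        "proportion": prop,
                        "dataset": i,
                        "missing": table.missing_proportion,
                    }
                    for arm, cls in (
                        ("mi", PooledModeratedTTest),
                        ("baseline", SingleImputationModeratedTTest),
                    ):
                        est = cls(
                            method=method,
                            alpha=alpha,
                            random_state=ds_seed,
                            engine_params=engine_params,
                        )
                        calls = est.fit_predict(table)
                        cm = confusion_metrics(calls, truth)
                        row.update({f"{arm}_{k}": v for k, v in cm.as_dict().items()})
                        row[f"{arm}_pathological"] = not calls.any()
                    rows.append(row)
                except Exception:  # pragma: no cover - isolation guard
                    logger.exception(
                        "dataset failed: design=%s method=%s prop=%s i=%d",
                        design,
                        method,
                        prop,
                        i,
                    )
    return BenchmarkReport.from_rows(pd.DataFrame(rows))
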