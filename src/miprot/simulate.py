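"""Synthetic quantification datasets with known differential-expression truth.

Four generators emulate the benchmark conditions used throughout the
package's evaluation:

* ``simulate_mar_design1`` — fixed-effect one-way ANOVA with widely
  separated groups (200 analytes, 10 differentially expressed at group
  means 100 vs 200, unit noise).
* ``simulate_mar_design2`` — random hierarchical ANOVA (1000 analytes, 200
  DE; analyte effect and group effect both N(1.5, 0.5), noise sd 0.5); the
  analyte effect is drawn once per row.
* ``simulate_mar_design3`` — same distributions, but the analyte and group
  effects are redrawn independently per cell (random-effects variant).
* ``simulate_mcar_mnar`` — Gaussian log2 intensities (means 12.5/25, sd 2)
  with a mixed MCAR + intensity-dependent left-censoring (MNAR) missingness
  mechanism.

``ampute`` masks cells of a complete table at an exact target proportion.
All generators are reproducible: the same spec and seed give bit-identical
output.  Each dataset index uses its own RNG stream derived from the master
seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .quant import QuantTable

__all__ = [
    "MarDesign1Spec",
    "MarDesign2Spec",
    "MarDesign3Spec",
    "MnarMcarSpec",
    "GroundTruth",
    "simulate_mar_design1",
    "simulate_mar_design2",
    "simulate_mar_design3",
    "simulate_mcar_mnar",
    "ampute",
    "AMPUTATION_PROPORTIONS",
    "make_dataset",
    "DESIGNS",
]

#: The missing-value proportions used throughout the benchmark sweeps.
AMPUTATION_PROPORTIONS = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass
class GroundTruth:
    """True DE labels plus the complete (pre-amputation) matrix."""

    is_de: np.ndarray
    complete: np.ndarray

    def __post_init__(self) -> None:
        self.is_de = np.asarray(self.is_de, dtype=bool)
        self.complete = np.asarray(self.complete, dtype=float)
        if np.isnan(self.complete).any():
            raise ValueError("ground-truth matrix must be complete")


def _check_common(n_analytes, n_de, sd):
    if n_de > n_analytes:
        raise ValueError("DE count exceeds number of analytes")
    if sd < 0:
        raise ValueError("standard deviation must be >= 0")


@dataclass
class MarDesign1Spec:
    """Fixed-effect one-way ANOVA design with scarcely overlapping groups."""

    n_analytes: int = 200
    n_de: int = 10
    samples_per_condition: tuple[int, int] = (5, 5)
    baseline_mean: float = 100.0
    de_shift: float = 100.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        _check_common(self.n_analytes, self.n_de, self.noise_sd)


@dataclass
class MarDesign2Spec:
    """Random hierarchical ANOVA design: y = P_p + G_pk + eps."""

    n_analytes: int = 1000
    n_de: int = 200
    samples_per_condition: tuple[int, int] = (10, 10)
    analyte_mean: float = 1.5
    analyte_sd: float = 0.5
    group_mean: float = 1.5
    group_sd: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        _check_common(self.n_analytes, self.n_de, self.noise_sd)


@dataclass
class MarDesign3Spec(MarDesign2Spec):
    """As design 2, but analyte/group effects are redrawn per cell."""


@dataclass
class MnarMcarSpec:
    """Gaussian log-intensities with mixed MCAR + left-censoring missingness."""

    n_analytes: int = 1000
    n_de: int = 200
    samples_per_condition: tuple[int, int] = (10, 10)
    mean_condition1: float = 12.5
    mean_condition2: float = 25.0
    sd: float = 2.0
    missing_proportion: float = 0.0
    mnar_weight: float = 0.5
    mnar_quantile: float = 0.10
    mnar_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        _check_common(self.n_analytes, self.n_de, self.sd)
        if not 0 <= self.missing_proportion < 1:
            raise ValueError("missing proportion must be in [0, 1)")
        if not 0 <= self.mnar_weight <= 1:
            raise ValueError("mnar_weight must be in [0, 1]")


def _make_table(values, samples_per_condition) -> QuantTable:
    P = values.shape[0]
    n1, n2 = samples_per_condition
    sample_ids = [f"A{i + 1}" for i in range(n1)] + [f"B{i + 1}" for i in range(n2)]
    condition_of = {s: s[0] for s in sample_ids}
    ids = [f"analyte_{i + 1}" for i in range(P)]
    return QuantTable(values, ids, sample_ids, condition_of)


def _truth(values, n_de, n_analytes) -> GroundTruth:
    is_de = np.zeros(n_analytes, dtype=bool)
    is_de[:n_de] = True
    return GroundTruth(is_de=is_de, complete=values.copy())


def simulate_mar_design1(spec: MarDesign1Spec, rng=None):
    """First design: DE rows at condition means (mu, mu + delta), rest at mu."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n1, n2 = spec.samples_per_condition
    P, N = spec.n_analytes, n1 + n2
    means = np.full((P, N), spec.baseline_mean)
    means[: spec.n_de, n1:] += spec.de_shift
    values = means + rng.normal(0.0, spec.noise_sd, size=(P, N))
    return _make_table(values, spec.samples_per_condition), _truth(values, spec.n_de, P)


def simulate_mar_design2(spec: MarDesign2Spec, rng=None):
    """Second design: one analyte effect per row, one group effect per DE row."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n1, n2 = spec.samples_per_condition
    P, N = spec.n_analytes, n1 + n2
    P_p = rng.normal(spec.analyte_mean, spec.analyte_sd, size=P)
    G_pk = np.zeros(P)
    G_pk[: spec.n_de] = rng.normal(spec.group_mean, spec.group_sd, size=spec.n_de)
    means = np.tile(P_p[:, None], (1, N))
    means[:, n1:] += G_pk[:, None]
    values = means + rng.normal(0.0, spec.noise_sd, size=(P, N))
    return _make_table(values, spec.samples_per_condition), _truth(values, spec.n_de, P)


def simulate_mar_design3(spec: MarDesign3Spec, rng=None):
    """Third design: analyte and group effects redrawn independently per cell."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n1, n2 = spec.samples_per_condition
    P, N = spec.n_analytes, n1 + n2
    values = rng.normal(spec.analyte_mean, spec.analyte_sd, size=(P, N))
    g = np.zeros((P, n2))
    g[: spec.n_de] = rng.normal(spec.group_mean, spec.group_sd, size=(spec.n_de, n2))
    values[:, n1:] += g
    values += rng.normal(0.0, spec.noise_sd, size=(P, N))
    return _make_table(values, spec.samples_per_condition), _truth(values, spec.n_de, P)


def simulate_mcar_mnar(spec: MnarMcarSpec, rng=None):
    """Gaussian log-intensities, then mixed MCAR + left-censoring missingness.

    The complete matrix has DE rows at means (m1, m2) and null rows at m1 in
    both conditions, common sd.  A fraction ``mnar_weight`` of the masked
    cells is sampled without replacement with logistic left-censoring
    weights centred at the ``mnar_quantile`` quantile of the complete
    matrix; the remainder is uniform.  The total masked count is exact.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n1, n2 = spec.samples_per_condition
    P, N = spec.n_analytes, n1 + n2
    means = np.full((P, N), spec.mean_condition1)
    means[: spec.n_de, n1:] = spec.mean_condition2
    values = means + rng.normal(0.0, spec.sd, size=(P, N))
    truth = _truth(values, spec.n_de, P)
    table = _make_table(values, spec.samples_per_condition)
    if spec.missing_proportion > 0:
        total = int(round(spec.missing_proportion * P * N))
        n_mnar = int(round(spec.mnar_weight * total))
        flat = values.ravel()
        masked = np.zeros(flat.size, dtype=bool)
        if n_mnar > 0:
            centre = np.quantile(flat, spec.mnar_quantile)
            with np.errstate(over="ignore"):
                w = 1.0 / (1.0 + np.exp((flat - centre) / spec.mnar_scale))
            w /= w.sum()
            idx = rng.choice(flat.size, size=n_mnar, replace=False, p=w)
            masked[idx] = True
        n_mcar = total - n_mnar
        if n_mcar > 0:
            remaining = np.flatnonzero(~masked)
            idx = rng.choice(remaining, size=n_mcar, replace=False)
            masked[idx] = True
        out = values.copy()
        out.ravel()[masked] = np.nan
        table = replace(table, values=out)
    return table, truth


# ---------------------------------------------------------------------------
# Amputation
# ---------------------------------------------------------------------------

def ampute(
    table: QuantTable,
    proportion: float,
    mechanism: str = "uniform",
    seed: int | None = None,
    protect_conditions: bool = False,
    max_retries: int = 100,
) -> QuantTable:
    """Mask cells of a complete table at the target proportion.

    ``uniform`` masks exactly ``round(proportion * P * N)`` cells chosen
    uniformly without replacement.  ``covariate_mar`` masks each cell with a
    probability that is a logistic function of the mean of the *other*
    condition's values in the same row (missingness depends only on observed
    data, i.e. MAR), calibrated so the expected proportion matches the
    target.  With ``protect_conditions`` a masking that empties a whole
    row-by-condition block is resampled, then raised after bounded retries.
    """
    if table.mask.any():
        raise ValueError("ampute requires a complete table")
    if not 0 <= proportion < 1:
        raise ValueError("proportion must be in [0, 1)")
    if proportion == 0:
        return replace(table, values=table.values.copy())
    rng = np.random.default_rng(seed)
    P, N = table.values.shape
    cond_cols = [table.condition_columns(c) for c in table.conditions]

    for _ in range(max_retries):
        if mechanism == "uniform":
            n_mask = int(round(proportion * P * N))
            idx = rng.choice(P * N, size=n_mask, replace=False)
            masked = np.zeros(P * N, dtype=bool)
            masked[idx] = True
            masked = masked.reshape(P, N)
        elif mechanism == "covariate_mar":
            masked = _covariate_mar_mask(table.values, cond_cols, proportion, rng)
        else:
            raise ValueError(f"unknown mechanism: {mechanism!r}")
        if protect_conditions:
            ok = all(
                (~masked[:, cols]).any(axis=1).all() for cols in cond_cols
            )
            if not ok:
                continue
        out = table.values.copy()
        out[masked] = np.nan
        return replace(table, values=out)
    raise RuntimeError(
        f"could not find a masking keeping every row observed in every "
        f"condition after {max_retries} retries (proportion={proportion})"
    )


def _covariate_mar_mask(values, cond_cols, proportion, rng):
    """Cellwise logistic masking driven by the other condition's row mean."""
    P, N = values.shape
    driver = np.empty_like(values)
    for i, cols in enumerate(cond_cols):
        other = np.concatenate([c for j, c in enumerate(cond_cols) if j != i])
        driver[:, cols] = values[:, other].mean(axis=1, keepdims=True)
    z = (driver - driver.mean()) / (driver.std() + 1e-12)
    # calibrate the intercept so the mean masking probability hits the target
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        prob = 1.0 / (1.0 + np.exp(z - mid))
        if prob.mean() > proportion:
            hi = mid
        else:
            lo = mid
    prob = 1.0 / (1.0 + np.exp(z - 0.5 * (lo + hi)))
    return rng.random(size=(P, N)) < prob


# ---------------------------------------------------------------------------
# Dataset streams
# ---------------------------------------------------------------------------

DESIGNS = {
    "mar1": (MarDesign1Spec, simulate_mar_design1),
    "mar2": (MarDesign2Spec, simulate_mar_design2),
    "mar3": (MarDesign3Spec, simulate_mar_design3),
    "mnar1": (MnarMcarSpec, simulate_mcar_mnar),
    "mnar2": (
        MnarMcarSpec,
        simulate_mcar_mnar,
    ),
}

#: Overrides applied to the base spec for named designs.
DESIGN_DEFAULTS = {
    "mnar2": {"n_analytes": 10000, "n_de": 500},
}


def make_dataset(design: str, index: int, master_seed: int, **overrides):
    """Generate dataset ``index`` of a named design, on its own RNG stream.

    The stream is derived from ``(master_seed, index)`` via a spawned
    ``SeedSequence`` so each dataset is independently reproducible.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design: {design!r}")
    spec_cls, fn = DESIGNS[design]
    kwargs = dict(DESIGN_DEFAULTS.get(design, {}))
    kwargs.update(overrides)
    spec = spec_cls(**kwargs)
    rng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))
    return fn(spec, rng=rng)
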