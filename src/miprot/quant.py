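"""Core containers and I/O for wide quantification tables.

A quantification table is an analytes x samples matrix of log2 intensities
with missing cells (encoded as NaN internally), a condition label per sample
column and, optionally, a peptide -> protein map.  Everything downstream
(imputation, pooling, testing, aggregation) operates on these containers.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "QuantTable",
    "ExperimentDesign",
    "PeptideProteinMap",
    "load_quant_table",
    "write_quant_table",
    "write_results",
    "filter_min_observed",
    "filter_shared_peptides",
    "quantile_normalize",
]


@dataclass
class QuantTable:
    """Analytes x samples matrix of log2 intensities with missing cells.

    Parameters
    ----------
    values : ndarray of shape (P, N)
        log2 intensities; missing cells are NaN.
    analyte_ids : list of str
        P unique analyte (peptide or protein) identifiers.
    sample_ids : list of str
        N unique sample identifiers.
    condition_of : dict
        Maps every sample id to a condition label.
    """

    values: np.ndarray
    analyte_ids: list[str]
    sample_ids: list[str]
    condition_of: dict[str, str]
    log2_scale: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.analyte_ids = list(self.analyte_ids)
        self.sample_ids = list(self.sample_ids)
        P, N = self.values.shape
        if len(self.analyte_ids) != P or len(self.sample_ids) != N:
            raise ValueError("id lists do not match matrix shape")
        if len(set(self.analyte_ids)) != P:
            raise ValueError("duplicate analyte ids")
        if len(set(self.sample_ids)) != N:
            raise ValueError("duplicate sample ids")
        missing = set(self.sample_ids) - set(self.condition_of)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values).any():
                raise ValueError("values must be finite or NaN")

    # -- basic geometry -------------------------------------------------
    @property
    def n_analytes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean missing mask (True = missing)."""
        return np.isnan(self.values)

    @property
    def missing_proportion(self) -> float:
        return float(self.mask.mean())

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance among samples."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def condition_labels(self) -> np.ndarray:
        """Condition label per sample column, aligned with ``sample_ids``."""
        return np.array([self.condition_of[s] for s in self.sample_ids])

    def condition_columns(self, condition: str) -> np.ndarray:
        """Column indices belonging to one condition."""
        labels = self.condition_labels()
        return np.flatnonzero(labels == condition)

    def design(self) -> "ExperimentDesign":
        return ExperimentDesign.from_table(self)

    def subset_rows(self, index: np.ndarray) -> "QuantTable":
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[index].copy(),
            analyte_ids=[self.analyte_ids[i] for i in index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.analyte_ids, columns=self.sample_ids)


@dataclass
class ExperimentDesign:
    """Cell-means design: one indicator column per condition.

    X is N x K with orthogonal indicator columns, so X'X = diag(n_k).
    """

    X: np.ndarray
    conditions: list[str]
    n_k: np.ndarray

    @classmethod
    def from_table(cls, table: QuantTable) -> "ExperimentDesign":
        conditions = table.conditions
        if len(conditions) < 2:
            raise ValueError("need at least two conditions")
        labels = table.condition_labels()
        X = np.column_stack([(labels == c).astype(float) for c in conditions])
        return cls(X=X, conditions=conditions, n_k=X.sum(axis=0).astype(int))

    @classmethod
    def from_labels(cls, labels) -> "ExperimentDesign":
        labels = np.asarray(labels)
        seen: dict = {}
        for l in labels:
            seen.setdefault(l, None)
        conditions = list(seen)
        X = np.column_stack([(labels == c).astype(float) for c in conditions])
        return cls(X=X, conditions=[str(c) for c in conditions], n_k=X.sum(axis=0).astype(int))

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def K(self) -> int:
        return self.X.shape[1]

    def pairwise_contrasts(self) -> list[tuple[str, np.ndarray]]:
        """All pairwise condition-difference contrasts e_l - e_k (l > k)."""
        out = []
        for k in range(self.K):
            for l in range(k + 1, self.K):
                c = np.zeros(self.K)
                c[k], c[l] = -1.0, 1.0
                out.append((f"{self.conditions[l]}-{self.conditions[k]}", c))
        return out


@dataclass
class PeptideProteinMap:
    """Maps each peptide id to the set of protein accessions it matches."""

    mapping: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = {k: frozenset(v) for k, v in self.mapping.items()}

    def proteins_of(self, peptide: str) -> frozenset[str]:
        return self.mapping[peptide]

    def is_unique(self, peptide: str) -> bool:
        return len(self.mapping[peptide]) == 1

    def covers(self, peptides) -> list[str]:
        """Return the peptides *not* covered by the map."""
        return [p for p in peptides if p not in self.mapping]

    @classmethod
    def from_tsv(cls, path) -> "PeptideProteinMap":
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
        mapping: dict[str, set[str]] = {}
        for pep, prot in zip(df.iloc[:, 0], df.iloc[:, 1]):
            mapping.setdefault(pep, set()).add(prot)
        return cls({k: frozenset(v) for k, v in mapping.items()})


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------

def _read_design_config(design_config) -> dict[str, list[str]]:
    if isinstance(design_config, dict):
        cfg = design_config
    else:
        with open(design_config) as fh:
            text = fh.read()
        cfg = yaml.safe_load(text)
    conditions = cfg.get("conditions", cfg)
    if not isinstance(conditions, dict) or len(conditions) < 2:
        raise ValueError("design config must name at least two conditions")
    return {str(k): list(v) for k, v in conditions.items()}


def load_quant_table(path, design_config, dialect: str = "generic_tsv"):
    """Read a wide quantification table.

    Parameters
    ----------
    path : str or Path
        TSV/CSV file.  ``generic_tsv``: first column analyte id, remaining
        columns samples, values already log2, empty/NA cells missing.
        ``maxquant_peptides``: a MaxQuant ``peptides.txt`` export; intensity
        columns are ``Intensity <sample>``, zeros mean missing, values are
        log2-transformed on load and the peptide->protein map is read from
        the protein-mapping column.
    design_config : dict or path
        ``{"conditions": {label: [sample, ...], ...}}`` (YAML/JSON file or
        in-memory dict).

    Returns
    -------
    QuantTable, or (QuantTable, PeptideProteinMap) for the MaxQuant dialect.
    """
    conditions = _read_design_config(design_config)
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)

    if dialect == "generic_tsv":
        id_col = df.columns[0]
        analyte_ids = df[id_col].tolist()
        sample_cols = {s for cols in conditions.values() for s in cols}
        unknown = sample_cols - set(df.columns)
        if unknown:
            raise ValueError(f"design config names unknown columns: {sorted(unknown)}")
        ordered_samples = [c for c in df.columns[1:] if c in sample_cols]
        values = _parse_numeric(df, ordered_samples)
        condition_of = {s: lab for lab, cols in conditions.items() for s in cols}
        table = QuantTable(values, analyte_ids, ordered_samples, condition_of)
        return table

    if dialect == "maxquant_peptides":
        for flag in ("Reverse", "Potential contaminant"):
            if flag in df.columns:
                bad = df[flag].fillna("") == "+"
                if bad.any():
                    logger.info("dropping %d rows flagged %r", int(bad.sum()), flag)
                    df = df.loc[~bad]
        id_col = "Sequence" if "Sequence" in df.columns else df.columns[0]
        analyte_ids = df[id_col].tolist()
        if len(set(analyte_ids)) != len(analyte_ids):
            raise ValueError("duplicate analyte ids in peptides table")
        sample_names = {s for cols in conditions.values() for s in cols}
        col_of = {}
        for s in sample_names:
            col = f"Intensity {s}"
            if col not in df.columns:
                raise ValueError(f"design config names unknown sample column: {s!r}")
            col_of[s] = col
        ordered_samples = [
            c.removeprefix("Intensity ")
            for c in df.columns
            if c.startswith("Intensity ") and c.removeprefix("Intensity ") in sample_names
        ]
        raw = _parse_numeric(df, [col_of[s] for s in ordered_samples])
        raw[raw == 0] = np.nan  # zero intensity means "not quantified"
        with np.errstate(invalid="ignore"):
            values = np.log2(raw)
        condition_of = {s: lab for lab, cols in conditions.items() for s in cols}
        table = QuantTable(values, analyte_ids, ordered_samples, condition_of)
        prot_col = next(
            (c for c in ("Proteins", "Leading razor protein") if c in df.columns), None
        )
        if prot_col is None:
            return table
        mapping = {
            pep: frozenset(str(ps).split(";"))
            for pep, ps in zip(analyte_ids, df[prot_col].fillna(""))
        }
        return table, PeptideProteinMap(mapping)

    raise ValueError(f"unknown dialect: {dialect!r}")


def _parse_numeric(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    out = np.empty((len(df), len(cols)))
    for j, c in enumerate(cols):
        parsed = pd.to_numeric(df[c], errors="coerce")
        bad = parsed.isna() & df[c].notna() & (df[c].str.strip() != "") & (
            ~df[c].str.strip().str.upper().isin(["NA", "NAN"])
        )
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric cell at row {i}, column {c!r}: {df[c].iloc[i]!r}")
        out[:, j] = parsed.to_numpy(dtype=float)
    return out


def write_quant_table(table: QuantTable, path) -> None:
    """Write the generic wide TSV (empty field = missing)."""
    df = table.to_frame()
    df.index.name = "analyte_id"
    df.to_csv(path, sep="\t", na_rep="")


def write_design_config(table: QuantTable, path) -> None:
    cfg = {"conditions": {}}
    for s in table.sample_ids:
        cfg["conditions"].setdefault(table.condition_of[s], []).append(s)
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=1)


def write_results(results: pd.DataFrame, path) -> None:
    """Write a differential-analysis result table as TSV."""
    results.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def filter_min_observed(table: QuantTable, min_per_condition: int) -> QuantTable:
    """Keep rows with >= ``min_per_condition`` observed cells in *every* condition.

    This is the usual pre-filter for label-free data (e.g. "at least 1 out
    of 3 quantified values in each condition").  Row order is preserved.
    """
    if min_per_condition < 0:
        raise ValueError("min_per_condition must be >= 0")
    observed = ~table.mask
    keep = np.ones(table.n_analytes, dtype=bool)
    for cond in table.conditions:
        cols = table.condition_columns(cond)
        if min_per_condition > len(cols):
            raise ValueError(
                f"min_per_condition={min_per_condition} exceeds size of condition {cond!r}"
            )
        keep &= observed[:, cols].sum(axis=1) >= min_per_condition
    return table.subset_rows(np.flatnonzero(keep))


def filter_shared_peptides(table: QuantTable, pep_map: PeptideProteinMap) -> QuantTable:
    """Retain only peptides mapping to exactly one protein."""
    absent = pep_map.covers(table.analyte_ids)
    if absent:
        raise ValueError(f"analytes absent from peptide->protein map: {absent}")
    keep = [i for i, a in enumerate(table.analyte_ids) if pep_map.is_unique(a)]
    return table.subset_rows(np.array(keep, dtype=int))


def quantile_normalize(table: QuantTable) -> QuantTable:
    """Quantile-normalize sample columns to a shared reference distribution.

    The reference is the mean of the column-wise order statistics.  Missing
    cells are excluded from ranking and stay missing; ties receive the mean
    of their target quantiles.  On complete data every column's sorted
    vector afterwards equals the reference exactly.
    """
    X = table.values
    P, N = X.shape
    n_obs = (~np.isnan(X)).sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(f"column {table.sample_ids[j]!r} has no observed values")

    # Reference quantile curve on a common grid (mean across columns of each
    # column's empirical quantile function).
    G = int(n_obs.max())
    grid = np.linspace(0.0, 1.0, G) if G > 1 else np.array([0.5])
    curves = np.empty((N, G))
    for j in range(N):
        col = np.sort(X[~np.isnan(X[:, j]), j])
        if len(col) == 1:
            curves[j] = col[0]
        else:
            p = np.linspace(0.0, 1.0, len(col))
            curves[j] = np.interp(grid, p, col)
    reference = curves.mean(axis=0)

    out = X.copy()
    for j in range(N):
        obs = ~np.isnan(X[:, j])
        col = X[obs, j]
        n = len(col)
        # average ranks for ties -> average target quantiles
        ranks = pd.Series(col).rank(method="average").to_numpy() - 1.0
        p = ranks / (n - 1) if n > 1 else np.full(n, 0.5)
        out[obs, j] = np.interp(p, grid, reference) if G > 1 else reference[0]
    return replace(table, values=out)
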