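"""Peptide-to-protein roll-up inside each imputed dataset.

Aggregation happens after imputation (so the protein matrices are
complete) and on the raw intensity scale: within every draw, a protein's
intensity is log2 of the sum of its unique peptides' raw-scale
(2**log2-value) intensities.  Shared peptides must have been filtered out
beforehand.  The protein-level ensemble is then pooled and tested exactly
like a peptide-level one.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .impute import ImputationEnsemble, multi_impute
from .moderate import adjust_bh, estimate_prior, moderate_variance, moderated_t
from .pool import fit_per_imputation, rubin_combine
from .quant import (
    ExperimentDesign,
    PeptideProteinMap,
    QuantTable,
    filter_shared_peptides,
    quantile_normalize,
)

logger = logging.getLogger(__name__)

__all__ = ["ProteinEnsemble", "aggregate_ensemble", "run_protein_workflow"]


@dataclass
class ProteinEnsemble:
    """D completed protein-level matrices with roll-up provenance."""

    data: np.ndarray  # (D, G, N)
    protein_ids: list[str]
    sample_ids: list[str]
    condition_of: dict[str, str]
    peptide_counts: dict[str, int]
    method: str

    @property
    def n_draws(self) -> int:
        return self.data.shape[0]

    def design(self) -> ExperimentDesign:
        labels = [self.condition_of[s] for s in self.sample_ids]
        return ExperimentDesign.from_labels(labels)


def aggregate_ensemble(
    ensemble: ImputationEnsemble, pep_map: PeptideProteinMap
) -> ProteinEnsemble:
    """Sum unique peptides' raw-scale intensities per protein, per draw.

    Every ensemble row must map to exactly one protein (run
    ``filter_shared_peptides`` upstream); a shared peptide raises.
    """
    table = ensemble.source
    absent = pep_map.covers(table.analyte_ids)
    if absent:
        raise ValueError(f"peptides absent from the map: {absent}")
    shared = [a for a in table.analyte_ids if not pep_map.is_unique(a)]
    if shared:
        raise ValueError(
            f"shared peptides must be filtered out before aggregation: {shared}"
        )
    groups: dict[str, list[int]] = {}
    for i, pep in enumerate(table.analyte_ids):
        (protein,) = pep_map.proteins_of(pep)
        groups.setdefault(protein, []).append(i)
    proteins = list(groups)
    D, _, N = ensemble.data.shape
    out = np.empty((D, len(proteins), N))
    raw = np.exp2(ensemble.data)
    for g, protein in enumerate(proteins):
        out[:, g, :] = np.log2(raw[:, groups[protein], :].sum(axis=1))
    counts = {p: len(groups[p]) for p in proteins}
    return ProteinEnsemble(
        data=out,
        protein_ids=proteins,
        sample_ids=table.sample_ids,
        condition_of=dict(table.condition_of),
        peptide_counts=counts,
        method=ensemble.method,
    )


def run_protein_workflow(
    table: QuantTable,
    pep_map: PeptideProteinMap,
    method: str = "mle",
    D: int | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
    normalize: bool = True,
    **engine_params,
) -> pd.DataFrame:
    """Protein-level pipeline: filter, normalise, impute, aggregate, test.

    Steps: drop shared peptides, quantile-normalise the log2 peptide table,
    multiply-impute at peptide level, roll up each draw to proteins on the
    raw scale (log2 re-applied inside aggregation), pool the protein-level
    fits with Rubin's rules, project, moderate and BH-test.
    """
    peptides = filter_shared_peptides(table, pep_map)
    if normalize:
        peptides = quantile_normalize(peptides)
    ensemble = multi_impute(peptides, method=method, D=D, seed=seed, **engine_params)
    proteins = aggregate_ensemble(ensemble, pep_map)
    design = proteins.design()
    pooled = rubin_combine(fit_per_imputation(proteins.data, design))
    prior = estimate_prior(pooled.s2, pooled.dof)
    s2_mod = moderate_variance(pooled.s2, prior, pooled.dof)
    frames = []
    for name, c in design.pairwise_contrasts():
        res = moderated_t(pooled, s2_mod, c, design, prior)
        res.insert(0, "contrast", name)
        res.insert(0, "analyte_id", proteins.protein_ids)
        res["n_peptides"] = [proteins.peptide_counts[p] for p in proteins.protein_ids]
        res["p_adjusted"] = adjust_bh(res["p_value"].to_numpy())
        res["significant"] = res["p_adjusted"] <= alpha
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
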