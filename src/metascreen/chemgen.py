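"""Chemical-genetic validation: does a drug's effect require its target?

If a hit drug really acts through its predicted target, a deletion mutant
of that target should respond less: fewer metabolites should change on
treatment, and individual marker metabolites should respond more weakly.
Counts use a per-metabolite two-sided equal-variance (Student's) t-test of
drug replicates against same-genotype vehicle controls, unadjusted.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .screen_io import ScreenTable, ScreenError

__all__ = [
    "DiffCount",
    "diff_count",
    "genotype_dependence",
    "metabolite_response_contrast",
]


@dataclasses.dataclass
class DiffCount:
    genotype: str
    drug: str
    n_significant: int
    tested_metabolites: int
    alpha: float


def _group_rows(table: ScreenTable, genotype: str, treatment_class: str,
                treatment_id: str | None = None):
    meta = table.meta
    mask = (meta["genotype"] == genotype) & (meta["treatment_class"] == treatment_class)
    if treatment_id is not None:
        mask &= meta["treatment_id"] == treatment_id
    return meta.index[mask]


def diff_count(
    table: ScreenTable, genotype: str, drug: str, alpha: float = 0.05
) -> DiffCount:
    """Metabolites changing significantly under the drug within a genotype."""
    drug_idx = _group_rows(table, genotype, "drug", drug)
    veh_idx = _group_rows(table, genotype, "vehicle_control")
    if len(drug_idx) < 2:
        raise ScreenError(f"need >= 2 drug replicates for {genotype}/{drug}")
    if len(veh_idx) < 2:
        raise ScreenError(f"missing vehicle replicates for genotype {genotype}")
    a = table.intensities.loc[drug_idx].to_numpy(dtype=float)
    b = table.intensities.loc[veh_idx].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=True, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    tested = int(np.isfinite(p).sum())
    return DiffCount(
        genotype=genotype,
        drug=drug,
        n_significant=int(np.sum(p < alpha)),
        tested_metabolites=tested,
        alpha=alpha,
    )


def genotype_dependence(wt: DiffCount, mutant: DiffCount) -> dict:
    """Is the wild-type response broader than the mutant's?

    ``ratio`` uses add-one smoothing so a zero wild-type count stays finite.
    """
    if wt.drug != mutant.drug or wt.alpha != mutant.alpha:
        raise ValueError("counts must refer to the same drug and alpha")
    return {
        "impaired": wt.n_significant > mutant.n_significant,
        "ratio": (mutant.n_significant + 1) / (wt.n_significant + 1),
    }


def metabolite_response_contrast(
    table: ScreenTable,
    metabolite: str,
    drug: str,
    genotype_a: str,
    genotype_b: str,
) -> dict:
    """Compare one metabolite's drug response between two genotypes.

    The response of each replicate is its ratio to the mean of the same
    genotype's vehicle controls; the two genotypes' responses are compared
    with a two-sided equal-variance t-test.
    """
    if metabolite not in table.intensities.columns:
        raise ScreenError(f"metabolite {metabolite!r} not in table")
    folds = {}
    responses = {}
    for genotype in (genotype_a, genotype_b):
        drug_idx = _group_rows(table, genotype, "drug", drug)
        veh_idx = _group_rows(table, genotype, "vehicle_control")
        if len(drug_idx) < 2 or len(veh_idx) < 2:
            raise ScreenError(
                f"genotype {genotype}: need drug and vehicle replicates"
            )
        veh_mean = float(table.intensities.loc[veh_idx, metabolite].mean())
        if not np.isfinite(veh_mean) or veh_mean <= 0:
            raise ScreenError(f"genotype {genotype}: vehicle mean <= 0 or missing")
        resp = table.intensities.loc[drug_idx, metabolite].to_numpy(dtype=float) / veh_mean
        responses[genotype] = resp
        folds[genotype] = float(np.nanmean(resp))
    t = stats.ttest_ind(
        responses[genotype_a], responses[genotype_b], equal_var=True,
        nan_policy="omit",
    )
    return {
        "fold_a": folds[genotype_a],
        "fold_b": folds[genotype_b],
        "p": float(t.pvalue),
    }
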