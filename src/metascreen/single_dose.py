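"""Single-inducer-concentration matching and recall of known interactions.

When overexpression is measured at one inducer concentration only, a drug
is compared directly with the induced or uninduced profile of each gene.
Expected signs follow pharmacology: against the *induced* state an agonist
should look similar (positive similarity) and an antagonist dissimilar
(negative); against the *uninduced* (loss-of-function-like) state the
expectation flips.  Known interactions are recalled by ranking every drug
per gene, pooling rank percentiles across genes, and sweeping a threshold
to trace a ROC curve; AUC equals the Mann-Whitney statistic
U / (n_pos * n_neg) with ties counted one half.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .match import MatchError, matrix_of_similarities
from .normalize import ProfileMatrix
from .screen_io import ScreenTable, ScreenError

__all__ = [
    "KnownInteraction",
    "RocResult",
    "signed_score",
    "rank_drugs_per_gene",
    "rankings_from_profiles",
    "pooled_roc",
    "count_significant_metabolites",
    "tabulate_top20",
]


@dataclasses.dataclass(frozen=True)
class KnownInteraction:
    gene: str
    drug: str
    mode: str  # "agonist" | "antagonist"


@dataclasses.dataclass
class RocResult:
    points: np.ndarray  # (fpr, tpr) pairs from (0,0) to (1,1)
    auc: float
    n_pos: int
    n_neg: int


def signed_score(similarity: float, mode: str, induction_state: str) -> float:
    """Similarity signed by the expected direction for the given mode.

    Induced state: agonists keep the sign, antagonists flip it.  Uninduced
    state: the conventions swap (an antagonist mimics loss of function, so
    a positive similarity to the uninduced profile is expected).
    """
    if mode not in ("agonist", "antagonist"):
        raise ValueError(f"unknown mode {mode!r}")
    if induction_state not in ("induced", "uninduced"):
        raise ValueError(f"unknown induction state {induction_state!r}")
    flip = (mode == "antagonist") == (induction_state == "induced")
    return -similarity if flip else similarity


def rank_drugs_per_gene(
    oe_profile: pd.Series,
    drug_profiles: ProfileMatrix,
    metric: str = "spearman",
    min_overlap: int = 20,
) -> list[tuple[str, float]]:
    """Drugs ranked by similarity to one overexpression profile,
    descending, ties broken alphabetically."""
    drugs = drug_profiles.of_class("drug")
    if drugs.empty:
        raise MatchError("no drug profiles to rank")
    sims = matrix_of_similarities(
        drugs, oe_profile.to_frame().T, metric, min_overlap
    ).iloc[:, 0]
    pairs = [(key[1], float(v)) for key, v in sims.items()]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def rankings_from_profiles(
    oe_profiles: ProfileMatrix,
    drug_profiles: ProfileMatrix,
    state: str = "induced",
    metric: str = "spearman",
    min_overlap: int = 20,
) -> dict[str, list[tuple[str, float]]]:
    """Per-gene drug rankings against the induced (max dose) or uninduced
    (dose 0) overexpression profile."""
    oe = oe_profiles.of_class("overexpression")
    rankings: dict[str, list[tuple[str, float]]] = {}
    for gene, grp in oe.groupby(level="treatment_id", sort=True):
        doses = grp.index.get_level_values("dose")
        target = doses.max() if state == "induced" else doses.min()
        row = grp[doses == target].iloc[0]
        rankings[gene] = rank_drugs_per_gene(
            row, drug_profiles, metric, min_overlap
        )
    return rankings


def pooled_roc(
    known: Sequence[KnownInteraction],
    rankings: Mapping[str, Sequence[tuple[str, float]]],
    state: str = "induced",
) -> RocResult:
    """ROC for recovering known interactions from pooled per-gene ranks.

    Positives are scored by :func:`signed_score` under their annotated
    mode; unlabeled drugs are scored under the mode most favorable to them
    (their absolute similarity), which makes the reported AUC conservative.
    Each drug contributes its rank percentile (rank - 0.5) / n within its
    gene so genes with different library sizes pool on a common scale.
    """
    if not known:
        raise ValueError("no known interactions supplied")
    missing = sorted({k.gene for k in known} - set(rankings))
    if missing:
        raise ScreenError(f"no ranking available for gene(s): {missing}")
    pos_by_gene: dict[str, dict[str, str]] = {}
    for k in known:
        pos_by_gene.setdefault(k.gene, {})[k.drug] = k.mode
    percentiles: list[float] = []
    labels: list[int] = []
    for gene, positives in pos_by_gene.items():
        entries = rankings[gene]
        scores = np.empty(len(entries))
        lab = np.zeros(len(entries), dtype=int)
        for i, (drug, sim) in enumerate(entries):
            if drug in positives:
                scores[i] = signed_score(sim, positives[drug], state)
                lab[i] = 1
            else:
                scores[i] = abs(sim)
        # high score -> low (good) percentile
        ranks = stats.rankdata(-scores, method="average")
        pct = (ranks - 0.5) / len(entries)
        percentiles.extend(pct)
        labels.extend(lab)
    labels_arr = np.asarray(labels)
    pct_arr = np.asarray(percentiles)
    n_pos = int(labels_arr.sum())
    n_neg = int(len(labels_arr) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positives and negatives for a ROC")
    # AUC by the rank (Mann-Whitney) formula with half-tie counting
    r = stats.rankdata(-pct_arr, method="average")  # lower percentile = better
    u = r[labels_arr == 1].sum() - n_pos * (n_pos + 1) / 2
    auc = float(u / (n_pos * n_neg))
    fpr, tpr, _ = roc_curve(labels_arr, -pct_arr)
    return RocResult(points=np.column_stack([fpr, tpr]), auc=auc,
                     n_pos=n_pos, n_neg=n_neg)


def count_significant_metabolites(
    table: ScreenTable,
    drug: str,
    alpha: float = 0.05,
    ions: Sequence[str] | None = None,
) -> int:
    """Number of metabolites changed by the drug versus same-plate vehicle.

    Two-sided equal-variance t-test per metabolite on replicate z-scored
    samples; p-values are unadjusted.
    """
    meta = table.meta
    drug_idx = meta.index[
        (meta["treatment_class"] == "drug") & (meta["treatment_id"] == drug)
    ]
    if len(drug_idx) < 2:
        raise ScreenError(f"need >= 2 replicates of drug {drug!r}")
    plates = meta.loc[drug_idx, "plate_id"].unique()
    veh_idx = meta.index[
        (meta["treatment_class"] == "vehicle_control")
        & meta["plate_id"].isin(plates)
    ]
    if len(veh_idx) < 2:
        raise ScreenError(f"need >= 2 vehicle controls on plates of {drug!r}")
    cols = list(ions) if ions is not None else table.ion_ids
    a = table.intensities.loc[drug_idx, cols].to_numpy(dtype=float)
    b = table.intensities.loc[veh_idx, cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=True, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    return int(np.sum(p < alpha))


def tabulate_top20(
    rankings: Mapping[str, Sequence[tuple[str, float]]],
    eligible_drugs: set[str] | None = None,
    top_n: int = 20,
) -> tuple[dict[str, int], dict[int, int]]:
    """Count, per drug, the genes for which it ranks in the top ``top_n``
    by absolute similarity; also return the histogram of counts.

    Drugs never appearing in any top list are reported with count 0.
    """
    counts: dict[str, int] = {}
    all_drugs: set[str] = set()
    for gene, entries in rankings.items():
        if eligible_drugs is not None:
            entries = [(d, s) for d, s in entries if d in eligible_drugs]
        all_drugs.update(d for d, _ in entries)
        if len(entries) < top_n:
            warnings.warn(
                f"gene {gene}: only {len(entries)} eligible drugs (< {top_n})"
            )
        top = sorted(entries, key=lambda p: (-abs(p[1]), p[0]))[:top_n]
        for drug, _ in top:
            counts[drug] = counts.get(drug, 0) + 1
    for drug in all_drugs:
        counts.setdefault(drug, 0)
    histogram: dict[int, int] = {}
    for c in counts.values():
        histogram[c] = histogram.get(c, 0) + 1
    return counts, histogram
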