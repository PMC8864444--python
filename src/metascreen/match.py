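"""Similarity between drug and overexpression metabolome profiles.

Supports Spearman correlation (rank Pearson with mean ranks for ties, the
primary metric), Pearson correlation, and cosine similarity.  Missing ions
are handled pairwise-complete: an ion absent in either profile is dropped
from that comparison.  Dose-response series collect one similarity per
inducer dose (including dose 0, the uninduced state) for every
(gene, drug, timepoint) combination.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import ProfileMatrix

__all__ = [
    "MatchError",
    "DoseResponseCurve",
    "similarity",
    "matrix_of_similarities",
    "build_dose_response",
]

METRICS = ("spearman", "pearson", "cosine")


class MatchError(ValueError):
    pass


@dataclasses.dataclass
class DoseResponseCurve:
    """Similarity of one drug to one gene's overexpression series."""

    gene: str
    drug: str
    timepoint: float
    doses: np.ndarray          # ascending, nM; includes 0 (uninduced)
    similarities: np.ndarray   # one per dose, in [-1, 1]
    metric: str
    n_common_ions: int
    unfittable: bool = False

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.similarities = np.asarray(self.similarities, dtype=float)
        if len(self.doses) != len(self.similarities):
            raise MatchError("doses and similarities must have equal length")
        if np.any(np.diff(self.doses) <= 0):
            raise MatchError("doses must be strictly ascending")

    @property
    def max_abs_similarity(self) -> float:
        return float(np.nanmax(np.abs(self.similarities)))


def similarity(
    a: pd.Series, b: pd.Series, metric: str = "spearman", min_overlap: int = 20
) -> float:
    """Similarity of two profiles on their common, pairwise-complete ions."""
    if metric not in METRICS:
        raise MatchError(f"unknown metric {metric!r}")
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(joined) < min_overlap:
        raise MatchError(
            f"only {len(joined)} common ions; min_overlap={min_overlap}"
        )
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if metric == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            warnings.warn("zero-norm vector in cosine similarity")
            return float("nan")
        return float(x @ y / (nx * ny))
    if metric == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance vector in correlation")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _prepare(matrix: np.ndarray, metric: str) -> np.ndarray:
    """Row-wise transform so that similarity = transformed @ transformed.T."""
    x = matrix.astype(float)
    if metric == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
    if metric in ("spearman", "pearson"):
        x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance profiles give NaN similarities")
    with np.errstate(invalid="ignore", divide="ignore"):
        x = x / norms
    x[zero] = np.nan
    return x


def matrix_of_similarities(
    drug_profiles: ProfileMatrix | pd.DataFrame,
    oe_profiles: ProfileMatrix | pd.DataFrame,
    metric: str = "spearman",
    min_overlap: int = 20,
) -> pd.DataFrame:
    """Full drug x overexpression-condition similarity matrix.

    Ions missing anywhere are dropped so every entry is computed on the same
    complete ion set (condition-averaged profiles are complete by
    construction).
    """
    if metric not in METRICS:
        raise MatchError(f"unknown metric {metric!r}")
    d = drug_profiles.values if isinstance(drug_profiles, ProfileMatrix) else drug_profiles
    o = oe_profiles.values if isinstance(oe_profiles, ProfileMatrix) else oe_profiles
    common = d.columns.intersection(o.columns)
    d = d[common].dropna(axis=1)
    o = o[common].dropna(axis=1)
    common = d.columns.intersection(o.columns)
    if len(common) < min_overlap:
        raise MatchError(
            f"only {len(common)} complete common ions; min_overlap={min_overlap}"
        )
    dm = _prepare(d[common].to_numpy(), metric)
    om = _prepare(o[common].to_numpy(), metric)
    return pd.DataFrame(dm @ om.T, index=d.index, columns=o.index)


def build_dose_response(
    drug_profiles: ProfileMatrix,
    oe_profiles: ProfileMatrix,
    metric: str = "spearman",
    min_overlap: int = 20,
) -> list[DoseResponseCurve]:
    """One similarity-vs-dose curve per (gene, drug, timepoint).

    Genes with fewer than 4 distinct doses yield curves flagged unfittable.
    """
    drugs = drug_profiles.of_class("drug")
    oe = oe_profiles.of_class("overexpression")
    sims = matrix_of_similarities(drugs, oe, metric, min_overlap)
    n_ions = len(
        drugs.columns.intersection(oe.columns)
    )
    curves: list[DoseResponseCurve] = []
    oe_index = oe.index.to_frame(index=False)
    for (gene, timepoint), grp in oe_index.groupby(["treatment_id", "timepoint"]):
        grp = grp.sort_values("dose")
        doses = grp["dose"].to_numpy(dtype=float)
        cols = [
            ("overexpression", gene, dose, timepoint) for dose in doses
        ]
        unfittable = len(np.unique(doses)) < 4
        block = sims[cols]
        for drug_key, row in block.iterrows():
            curves.append(
                DoseResponseCurve(
                    gene=gene,
                    drug=drug_key[1],
                    timepoint=float(timepoint),
                    doses=doses,
                    similarities=row.to_numpy(dtype=float),
                    metric=metric,
                    n_common_ions=n_ions,
                    unfittable=unfittable,
                )
            )
    return curves


def curves_to_frame(curves: Sequence[DoseResponseCurve]) -> pd.DataFrame:
    """Long-format table of curves (one row per dose point)."""
    records = []
    for c in curves:
        for d, s in zip(c.doses, c.similarities):
            records.append(
                (c.gene, c.drug, c.timepoint, d, s, c.metric, c.n_common_ions,
                 c.unfittable)
            )
    return pd.DataFrame(
        records,
        columns=["gene", "drug", "timepoint", "dose", "similarity", "metric",
                 "n_common_ions", "unfittable"],
    )


def curves_from_frame(df: pd.DataFrame) -> list[DoseResponseCurve]:
    curves = []
    for (gene, drug, tp), grp in df.groupby(["gene", "drug", "timepoint"], sort=True):
        grp = grp.sort_values("dose")
        curves.append(
            DoseResponseCurve(
                gene=gene,
                drug=drug,
                timepoint=float(tp),
                doses=grp["dose"].to_numpy(),
                similarities=grp["similarity"].to_numpy(),
                metric=grp["metric"].iloc[0],
                n_common_ions=int(grp["n_common_ions"].iloc[0]),
                unfittable=bool(grp["unfittable"].iloc[0]),
            )
        )
    return curves
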