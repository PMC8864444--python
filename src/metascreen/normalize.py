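"""Preprocessing chain: raw ion intensities to condition-averaged z-profiles.

Stages run in a fixed order mirroring how flow-injection screens are
cleaned in practice:

1. drop ions missing in more than half the samples;
2. remove OD600 / total-ion-current outlier samples (robust MAD gate, per
   plate);
3. drop ions known to be drug-derived artifacts;
4. subtract the per-batch LOWESS trend of each ion over injection order,
   then align batch medians to the global median;
5. regress each ion on OD600 and remove the biomass component;
6. z-score per ion, either against all samples of the same 96-well plate
   ("plate" scheme, used for chemical screens) or against the plate's
   estradiol-treated wild-type controls ("control" scheme, used for
   overexpression dose series);
7. optionally restrict to ions annotated to organism compounds and average
   replicate z-scores per condition.

Corrections operate on the raw intensity scale by subtraction; standard
deviations use the n-1 (sample) convention throughout.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import PipelineConfig
from .screen_io import ScreenTable, ScreenError, organism_ions

__all__ = [
    "NormalizationReport",
    "ProfileMatrix",
    "drop_sparse_ions",
    "filter_outlier_samples",
    "remove_drug_artifact_ions",
    "correct_injection_drift",
    "correct_biomass",
    "zscore_plate",
    "zscore_vs_control",
    "restrict_and_average",
    "log2_fold_changes",
    "normalize_screen",
]

CONDITION_KEYS = ["treatment_class", "treatment_id", "dose", "timepoint"]

_MAD_SCALE = 1.4826  # consistent with a normal sd


@dataclasses.dataclass
class NormalizationReport:
    samples_removed: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    ions_removed: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    drift_before: dict = dataclasses.field(default_factory=dict)
    drift_after: dict = dataclasses.field(default_factory=dict)
    od_slopes: dict = dataclasses.field(default_factory=dict)
    messages: list[str] = dataclasses.field(default_factory=list)

    def extend(self, other: "NormalizationReport") -> None:
        self.samples_removed += other.samples_removed
        self.ions_removed += other.ions_removed
        self.drift_before.update(other.drift_before)
        self.drift_after.update(other.drift_after)
        self.od_slopes.update(other.od_slopes)
        self.messages += other.messages

    def to_dict(self) -> dict:
        return {
            "samples_removed": self.samples_removed,
            "ions_removed": self.ions_removed,
            "drift_before": self.drift_before,
            "drift_after": self.drift_after,
            "od_slopes": self.od_slopes,
            "messages": self.messages,
        }


@dataclasses.dataclass
class ProfileMatrix:
    """Condition-averaged z-scored profiles.

    ``values`` is indexed by the condition key (treatment_class,
    treatment_id, dose, timepoint) with ions as columns; ``n_replicates``
    is aligned to the rows.
    """

    values: pd.DataFrame
    n_replicates: pd.Series

    @property
    def ion_ids(self) -> list[str]:
        return list(self.values.columns)

    def profile(self, treatment_class: str, treatment_id: str,
                dose: float | None = None, timepoint: float | None = None) -> pd.Series:
        """Single condition profile; dose/timepoint may be omitted when unique."""
        df = self.values.xs(treatment_class, level="treatment_class", drop_level=False)
        df = df.xs(treatment_id, level="treatment_id", drop_level=False)
        if dose is not None:
            df = df[df.index.get_level_values("dose") == dose]
        if timepoint is not None:
            df = df[df.index.get_level_values("timepoint") == timepoint]
        if len(df) != 1:
            raise KeyError(
                f"condition ({treatment_class}, {treatment_id}, {dose}, {timepoint}) "
                f"matches {len(df)} rows"
            )
        return df.iloc[0]

    def of_class(self, treatment_class: str) -> pd.DataFrame:
        return self.values.xs(
            treatment_class, level="treatment_class", drop_level=False
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.values.reset_index()
        out.insert(4, "n_replicates", self.n_replicates.to_numpy())
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProfileMatrix":
        df = df.copy()
        nrep = df.pop("n_replicates")
        df = df.set_index(CONDITION_KEYS)
        nrep.index = df.index
        return cls(values=df, n_replicates=nrep.astype(int))


def _robust_z(x: pd.Series) -> pd.Series:
    med = x.median()
    mad = (x - med).abs().median() * _MAD_SCALE
    if mad == 0:
        return pd.Series(0.0, index=x.index)
    return (x - med) / mad


def drop_sparse_ions(
    table: ScreenTable, max_missing_fraction: float = 0.5
) -> tuple[ScreenTable, NormalizationReport]:
    """Drop ions missing in more than ``max_missing_fraction`` of samples."""
    report = NormalizationReport()
    frac = table.intensities.isna().mean(axis=0)
    bad = frac.index[frac > max_missing_fraction]
    report.ions_removed += [(ion, "unannotated") for ion in bad]
    if len(bad):
        report.messages.append(f"dropped {len(bad)} mostly-missing ions")
    return ScreenTable(table.intensities.drop(columns=bad), table.meta.copy()), report


def filter_outlier_samples(
    table: ScreenTable, mad_multiplier: float = 4.0
) -> tuple[ScreenTable, NormalizationReport]:
    """Remove samples whose OD600 or total ion current deviates from the
    plate median by more than ``mad_multiplier`` scaled MADs."""
    if table.n_samples == 0:
        raise ScreenError("empty screen table")
    report = NormalizationReport()
    tic = table.intensities.sum(axis=1, skipna=True)
    keep = pd.Series(True, index=table.meta.index)
    for plate, idx in table.meta.groupby("plate_id").groups.items():
        if len(idx) < 4:
            report.messages.append(
                f"plate {plate}: fewer than 4 samples, outlier filter skipped"
            )
            continue
        z_od = _robust_z(table.meta.loc[idx, "od600"])
        z_tic = _robust_z(tic.loc[idx])
        for sid in idx:
            if abs(z_od[sid]) > mad_multiplier:
                keep[sid] = False
                report.samples_removed.append((sid, "od600_outlier"))
            elif abs(z_tic[sid]) > mad_multiplier:
                keep[sid] = False
                report.samples_removed.append((sid, "tic_outlier"))
    return table.subset(keep), report


def remove_drug_artifact_ions(
    table: ScreenTable, drug_ion_list: Iterable[str]
) -> tuple[ScreenTable, NormalizationReport]:
    """Drop ions that are actually drug-derived (misannotated as metabolites)."""
    report = NormalizationReport()
    drug_ions = list(drug_ion_list)
    present = [i for i in drug_ions if i in table.intensities.columns]
    absent = [i for i in drug_ions if i not in table.intensities.columns]
    if absent:
        warnings.warn(f"drug artifact ions not in table: {absent}")
        report.messages.append(f"artifact ions absent from table: {absent}")
    report.ions_removed += [(ion, "drug_artifact") for ion in present]
    return ScreenTable(table.intensities.drop(columns=present), table.meta.copy()), report


def _abs_spearman_vs_injection(values: pd.DataFrame, inj: pd.Series) -> float:
    """Mean |Spearman(ion, injection order)|, complete rows only, vectorized."""
    ok = values.notna().all(axis=1)
    if ok.sum() < 3:
        return float("nan")
    ranks = values.loc[ok].rank(axis=0).to_numpy()
    r_inj = inj.loc[ok].rank().to_numpy()
    ranks = ranks - ranks.mean(axis=0)
    r_inj = r_inj - r_inj.mean()
    denom = np.sqrt((ranks**2).sum(axis=0) * (r_inj**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        cors = np.abs((ranks * r_inj[:, None]).sum(axis=0) / denom)
    cors = cors[np.isfinite(cors)]
    return float(np.mean(cors)) if cors.size else float("nan")


def correct_injection_drift(
    table: ScreenTable,
    lowess_fraction: float = 0.3,
    lowess_iterations: int = 2,
    log_scale: bool = False,
) -> tuple[ScreenTable, NormalizationReport]:
    """Subtract each ion's per-batch LOWESS trend over injection order, then
    re-center batch medians to the ion's global median."""
    report = NormalizationReport()
    values = table.intensities.copy()
    if log_scale:
        values = np.log(values)
    inj = table.meta["injection_index"].astype(float)
    batches = table.meta["batch_id"]
    min_pts = max(5, int(np.ceil(2.0 / lowess_fraction)))
    detrended = values.copy()
    for batch, idx in table.meta.groupby("batch_id").groups.items():
        sub = values.loc[idx]
        x = inj.loc[idx]
        report.drift_before[batch] = _abs_spearman_vs_injection(sub, x)
        if len(idx) < min_pts:
            # too few points for a stable local fit: median subtraction only
            report.messages.append(
                f"batch {batch}: {len(idx)} samples < {min_pts}, "
                "median subtraction fallback"
            )
            detrended.loc[idx] = sub - sub.median(axis=0)
            continue
        order = x.sort_values().index
        xs = x.loc[order].to_numpy()
        block = sub.loc[order].to_numpy(dtype=float)
        out_block = np.full_like(block, np.nan)
        for c in range(block.shape[1]):
            y = block[:, c]
            ok = np.isfinite(y)
            if ok.sum() < min_pts:
                med = np.nanmedian(y) if ok.any() else 0.0
                out_block[:, c] = y - med
                continue
            trend = lowess(
                y[ok], xs[ok], frac=lowess_fraction, it=lowess_iterations,
                return_sorted=False,
            )
            out_block[ok, c] = y[ok] - trend
        detrended.loc[order] = out_block
        report.drift_after[batch] = _abs_spearman_vs_injection(
            detrended.loc[idx], x
        )
    # batch median alignment: every batch median moves to the global median
    global_med = values.median(axis=0, skipna=True)
    out = detrended.copy()
    for batch, idx in table.meta.groupby("batch_id").groups.items():
        batch_med = detrended.loc[idx].median(axis=0, skipna=True)
        out.loc[idx] = detrended.loc[idx] - batch_med + global_med
    if log_scale:
        out = np.exp(out)
    return ScreenTable(out, table.meta.copy()), report


def correct_biomass(
    table: ScreenTable, log_scale: bool = False
) -> tuple[ScreenTable, NormalizationReport]:
    """Remove each ion's OLS-fitted OD600 component (residuals + grand mean)."""
    if table.n_samples < 2:
        raise ScreenError("insufficient data for OD600 regression")
    report = NormalizationReport()
    od = table.meta["od600"].to_numpy(dtype=float)
    if np.ptp(od) == 0:
        warnings.warn("constant OD600: biomass correction skipped")
        report.messages.append("constant OD600: biomass correction is a no-op")
        return table.copy(), report
    values = table.intensities.copy()
    if log_scale:
        values = np.log(values)
    X = values.to_numpy(dtype=float)
    mask = np.isfinite(X)
    od_col = od[:, None]
    # per-ion OLS slope with pairwise-complete samples
    n = mask.sum(axis=0).astype(float)
    od_mean = np.where(n > 0, (od_col * mask).sum(axis=0) / np.maximum(n, 1), 0.0)
    Xz = np.where(mask, X, 0.0)
    x_mean = np.where(n > 0, Xz.sum(axis=0) / np.maximum(n, 1), 0.0)
    dod = (od_col - od_mean) * mask
    dx = (X - x_mean) * mask
    dx = np.where(mask, dx, 0.0)
    denom = (dod**2).sum(axis=0)
    slope = np.where(denom > 0, (dod * dx).sum(axis=0) / np.maximum(denom, 1e-300), 0.0)
    fitted_dev = (od_col - od_mean) * slope
    out = np.where(mask, X - fitted_dev, np.nan)
    result = pd.DataFrame(out, index=values.index, columns=values.columns)
    if log_scale:
        result = np.exp(result)
    report.od_slopes = dict(zip(values.columns, slope))
    return ScreenTable(result, table.meta.copy()), report


def _zscore(values: pd.DataFrame, mu: pd.Series, sigma: pd.Series,
            report: NormalizationReport, plate: str) -> pd.DataFrame:
    z = (values - mu) / sigma
    zero_var = sigma.index[(sigma == 0) | sigma.isna()]
    for ion in zero_var:
        z[ion] = np.nan
        report.ions_removed.append((ion, "zero_variance"))
    return z


def zscore_plate(table: ScreenTable) -> tuple[ScreenTable, NormalizationReport]:
    """z = (x - mu) / sigma per ion per plate, over all samples of the plate."""
    report = NormalizationReport()
    out = table.intensities.copy()
    for plate, idx in table.meta.groupby("plate_id").groups.items():
        if len(idx) < 2:
            raise ScreenError(f"plate {plate} has a single sample; cannot z-score")
        sub = table.intensities.loc[idx]
        out.loc[idx] = _zscore(sub, sub.mean(axis=0), sub.std(axis=0, ddof=1),
                               report, plate)
    return ScreenTable(out, table.meta.copy()), report


def zscore_vs_control(
    table: ScreenTable, control_class: str = "wt_control"
) -> tuple[ScreenTable, NormalizationReport]:
    """z per ion per plate using that plate's control samples' mean and sd."""
    report = NormalizationReport()
    out = table.intensities.copy()
    for plate, idx in table.meta.groupby("plate_id").groups.items():
        ctrl = idx[table.meta.loc[idx, "treatment_class"] == control_class]
        if len(ctrl) < 3:
            raise ScreenError(
                f"plate {plate} has {len(ctrl)} {control_class} samples (< 3)"
            )
        sub = table.intensities.loc[ctrl]
        out.loc[idx] = _zscore(
            table.intensities.loc[idx], sub.mean(axis=0), sub.std(axis=0, ddof=1),
            report, plate,
        )
    return ScreenTable(out, table.meta.copy()), report


def restrict_and_average(
    table: ScreenTable,
    annotations: pd.DataFrame | None = None,
    restrict: bool = True,
) -> ProfileMatrix:
    """Average replicate z-scores per condition, optionally restricted to
    ions annotated to organism compounds.

    Ions left missing in any condition after averaging are dropped globally
    so profiles are complete.
    """
    values = table.intensities
    if restrict:
        if annotations is None:
            raise ScreenError("restrict=True requires an annotation table")
        keep = [i for i in organism_ions(annotations) if i in values.columns]
        values = values[keep]
    grouped = values.join(table.meta[CONDITION_KEYS]).groupby(CONDITION_KEYS, sort=True)
    means = grouped.mean()
    counts = grouped.size()
    empty = counts.index[counts == 0]
    if len(empty):
        warnings.warn(f"conditions with no replicates dropped: {list(empty)}")
    incomplete = means.columns[means.isna().any(axis=0)]
    means = means.drop(columns=incomplete)
    return ProfileMatrix(values=means, n_replicates=counts.astype(int))


def log2_fold_changes(
    table: ScreenTable, reference_class: str = "vehicle_control"
) -> ProfileMatrix:
    """Per condition per ion, log2(mean treated / mean reference), with the
    reference taken from ``reference_class`` samples on the same plates."""
    meta = table.meta
    out_rows = {}
    counts = {}
    for key, idx in meta.groupby(CONDITION_KEYS, sort=True).groups.items():
        if key[0] == reference_class:
            continue
        plates = meta.loc[idx, "plate_id"].unique()
        ref_idx = meta.index[
            (meta["treatment_class"] == reference_class)
            & meta["plate_id"].isin(plates)
        ]
        if len(ref_idx) == 0:
            warnings.warn(f"no {reference_class} reference for condition {key}")
            continue
        treated_mean = table.intensities.loc[idx].mean(axis=0)
        ref_mean = table.intensities.loc[ref_idx].mean(axis=0)
        valid = (ref_mean > 0) & treated_mean.notna() & (treated_mean > 0)
        lfc = pd.Series(np.nan, index=table.intensities.columns)
        lfc[valid] = np.log2(treated_mean[valid] / ref_mean[valid])
        out_rows[key] = lfc
        counts[key] = len(idx)
    values = pd.DataFrame(out_rows).T
    values.index = pd.MultiIndex.from_tuples(values.index, names=CONDITION_KEYS)
    nrep = pd.Series(counts)
    nrep.index = values.index
    return ProfileMatrix(values=values, n_replicates=nrep.astype(int))


def normalize_screen(
    table: ScreenTable,
    annotations: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    scheme: str | None = None,
    drug_ion_list: Iterable[str] = (),
    restrict: bool = True,
) -> tuple[ProfileMatrix, NormalizationReport]:
    """Run the full preprocessing chain in its fixed order and return
    condition-averaged profiles plus a merged report."""
    cfg = config or PipelineConfig()
    scheme = scheme or cfg.zscore_scheme
    report = NormalizationReport()
    table, rep = drop_sparse_ions(table, cfg.max_missing_fraction)
    report.extend(rep)
    table, rep = filter_outlier_samples(table, cfg.mad_multiplier)
    report.extend(rep)
    table, rep = remove_drug_artifact_ions(table, drug_ion_list)
    report.extend(rep)
    table, rep = correct_injection_drift(
        table, cfg.lowess_fraction, cfg.lowess_iterations, cfg.log_scale_corrections
    )
    report.extend(rep)
    table, rep = correct_biomass(table, cfg.log_scale_corrections)
    report.extend(rep)
    if scheme == "plate":
        table, rep = zscore_plate(table)
    elif scheme == "control":
        table, rep = zscore_vs_control(table)
    else:
        raise ScreenError(f"unknown z-score scheme {scheme!r}")
    report.extend(rep)
    profiles = restrict_and_average(table, annotations, restrict=restrict)
    return profiles, report
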