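"""Pipeline configuration with documented defaults.

Every tunable of the pipeline lives here.  Defaults follow the published
analysis where the analysis states a value (top-10% fit-quality gate,
10,000 structural permutations, 1,000 cluster-label shuffles, 15 clusters,
alpha 0.05) and otherwise use the package's own documented choices
(LOWESS fraction, MAD multiplier, minimum ion overlap).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Bad configuration file: unknown key or wrong type."""


@dataclasses.dataclass
class PipelineConfig:
    # normalization
    lowess_fraction: float = 0.3        # LOWESS span over injection order, per batch
    lowess_iterations: int = 2          # robustifying iterations
    mad_multiplier: float = 4.0         # OD600 / TIC outlier gate, in scaled MADs
    max_missing_fraction: float = 0.5   # ions missing in more samples are dropped
    log_scale_corrections: bool = False  # drift/OD correction on log intensities
    zscore_scheme: str = "plate"        # "plate" or "control"
    # profile matching
    similarity_metric: str = "spearman"  # spearman | pearson | cosine
    min_overlap: int = 20               # minimum common ions per comparison
    # hit calling
    fit_quality_percentile: float = 0.10  # top fraction of per-gene fit qualities
    # evaluation
    alpha: float = 0.05                 # per-metabolite significance level
    min_sig_metabolites: int = 5        # eligibility gate for top-20 tabulation
    # chemistry
    chem_permutations: int = 10000      # random quintuple draws
    mcs_atom_limit: int = 60
    mcs_time_budget: float = 5.0        # seconds per molecule pair
    # clustering / enrichment
    n_clusters: int = 15
    enrich_permutations: int = 1000     # cluster-label shuffles
    # reproducibility
    seed: int = 0

    @classmethod
    def from_dict(cls, values: dict) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(values) - set(fields)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        kwargs = {}
        for key, val in values.items():
            ftype = fields[key].type
            expected = {"float": (int, float), "int": (int,), "bool": (bool,), "str": (str,)}[
                ftype if isinstance(ftype, str) else ftype.__name__
            ]
            if isinstance(val, bool) and bool not in expected:
                raise ConfigError(f"key {key!r}: expected {ftype}, got bool")
            if not isinstance(val, expected):
                raise ConfigError(
                    f"key {key!r}: expected {ftype}, got {type(val).__name__}"
                )
            kwargs[key] = val
        return cls(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML configuration; unspecified keys take defaults.

    An empty or absent file yields all defaults.  Unknown keys and type
    mismatches raise :class:`ConfigError` naming the offending key.
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping of key: value pairs")
    return PipelineConfig.from_dict(data)
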