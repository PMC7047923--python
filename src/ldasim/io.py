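"""Serialization: TSV tables, config files, run manifests.

TSV is the canonical tabular format: header row, tab-delimited, full float
precision, not-available values written as "NA". Configs are YAML or JSON
mappings mirroring the design field names. Every CLI run writes a JSON
manifest (config snapshot, seed, package version, output paths, per-block
sampling modes) sufficient to reproduce the run byte-identically.

BIOM export of the community matrix is available when the ``biom`` package
is importable; TSV output never depends on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariance import CovarianceSpec
from .sampling import TruncationSpec
from .simulate import CommunityDataset, SimulatedDataset, SimulationDesign
from .trends import TrendSpec

__all__ = [
    "design_to_dict",
    "design_from_dict",
    "load_config",
    "write_long_tsv",
    "read_long_tsv",
    "write_community_tsv",
    "write_biom",
    "RunManifest",
]

_NA = "NA"


def design_to_dict(design: SimulationDesign) -> dict:
    d = {
        "n_control": design.n_control,
        "n_treat": design.n_treat,
        "control_mean": design.control_mean,
        "covariance": design.covariance.to_dict(),
        "trend": design.trend.to_dict(),
        "num_timepoints": design.num_timepoints,
        "t_interval": list(design.t_interval),
        "asynch_time": design.asynch_time,
        "missing_pct": design.missing_pct,
        "missing_per_subject": design.missing_per_subject,
        "miss_val": _NA if _is_na(design.miss_val) else design.miss_val,
        "truncation": design.truncation.to_dict(),
        "seed": design.seed,
    }
    return d


def _is_na(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or v == _NA


def design_from_dict(d: dict) -> SimulationDesign:
    miss_val = d.get("miss_val", 0.0)
    return SimulationDesign(
        n_control=int(d["n_control"]),
        n_treat=int(d["n_treat"]),
        control_mean=float(d.get("control_mean", 0.0)),
        covariance=CovarianceSpec.from_dict(d["covariance"]),
        trend=TrendSpec.from_dict(d.get("trend", {"form": "none"})),
        num_timepoints=int(d.get("num_timepoints", 5)),
        t_interval=tuple(float(x) for x in d.get("t_interval", (0.0, 10.0))),
        asynch_time=bool(d.get("asynch_time", False)),
        missing_pct=float(d.get("missing_pct", 0.0)),
        missing_per_subject=int(d.get("missing_per_subject", 0)),
        miss_val=float("nan") if _is_na(miss_val) else float(miss_val),
        truncation=TruncationSpec.from_dict(d.get("truncation", {})),
        seed=int(d.get("seed", 0)),
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config mapping (by extension; YAML reads JSON too)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    return data


def write_long_tsv(dataset: SimulatedDataset, path: str | Path) -> None:
    """Write the long-format records (Y, ID, time, group, Y_obs)."""
    dataset.records.to_csv(path, sep="\t", index=False, na_rep=_NA, float_format="%.17g")


def read_long_tsv(path: str | Path) -> pd.DataFrame:
    """Read a long-format TSV back; "NA" round-trips to NaN."""
    return pd.read_csv(
        path, sep="\t", na_values=[_NA], keep_default_na=False,
        dtype={"group": str},
    )


def write_miss_tsv(dataset: SimulatedDataset, path: str | Path) -> None:
    dataset.miss_data.to_csv(path, sep="\t", index=False, na_rep=_NA)


def write_community_tsv(
    community: CommunityDataset, features_path: str | Path, meta_path: str | Path
) -> None:
    """Write the feature table (rows features, columns samples) and the
    sample metadata (ID, time, group, Sample_ID)."""
    community.abundance.to_csv(
        features_path, sep="\t", na_rep=_NA, float_format="%.17g", index_label="feature"
    )
    community.sample_meta.to_csv(meta_path, sep="\t", index=False, na_rep=_NA)


def write_biom(community: CommunityDataset, path: str | Path) -> bool:
    """Write the community matrix as BIOM if the biom package is present.

    Returns True on success, False when biom is unavailable (TSV output is
    the canonical format and never depends on it).
    """
    try:
        import biom  # noqa: F401
        from biom.table import Table
        from biom.util import biom_open
    except ImportError:
        return False
    table = Table(
        community.abundance.to_numpy(),
        observation_ids=list(community.abundance.index),
        sample_ids=list(community.abundance.columns),
    )
    with biom_open(str(path), "w") as fh:
        table.to_hdf5(fh, generated_by="ldasim")
    return True


@dataclass
class RunManifest:
    """Provenance for one CLI run: enough to reproduce it exactly."""

    command: str
    seed: int
    config: dict
    outputs: list[str] = field(default_factory=list)
    sampling_modes: list[str] = field(default_factory=list)
    version: str = ""

    def write(self, path: str | Path) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")
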