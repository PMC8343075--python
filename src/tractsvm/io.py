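"""File formats: long-format profile CSV, streamline-bundle JSON lines,
YAML run configuration.

The profile CSV is the canonical interchange format: one row per
(subject, tract, property, node) with columns
``subject_id, group, tract_id, property, node, value``. Subjects missing
any node of any (tract, property) pair present in the file are dropped
with a logged warning — the along-tract pipeline needs complete grids.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort
from .profiling import StreamlineBundle
from .tracts import GROUPS, PROPERTIES, check_property, check_tract

logger = logging.getLogger("tractsvm")

PROFILE_COLUMNS = ["subject_id", "group", "tract_id", "property", "node", "value"]

__all__ = [
    "RunConfig",
    "read_profiles",
    "write_profiles",
    "read_bundle",
    "write_bundle",
    "read_config",
    "write_config",
]


@dataclass
class RunConfig:
    """Pipeline parameters, serialized into every output for provenance."""

    target_k: int = 10
    svm_c: float = 1.0
    alpha: float = 0.05
    auc_floor: float = 0.6
    n_perm: int = 1000
    fdr_q: float = 0.05
    freq_threshold: float = 0.5
    corr_threshold: float = 0.9
    use_cbr: bool = True
    test_all_nodes: bool = False  # FDR family: candidates only (default) or all nodes
    include_all_properties: bool = True  # add the concatenated "ALL" screens
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_k < 1:
            raise ValueError("target_k must be >= 1")
        for name in ("alpha", "auc_floor", "fdr_q", "freq_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_config(path: str | Path) -> RunConfig:
    return RunConfig(**yaml.safe_load(Path(path).read_text()))


def write_profiles(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to the long-format profile CSV."""
    cohort.to_long().to_csv(path, index=False)


def read_profiles(path: str | Path, n_nodes: int | None = None) -> Cohort:
    """Read and validate a long-format profile CSV into a :class:`Cohort`.

    Node indices must lie in 1..n_nodes (inferred as the maximum node when
    not given); duplicated (subject, tract, property, node) rows are an
    error; subjects with incomplete grids are dropped with a warning.
    """
    df = pd.read_csv(path)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    for tract in df["tract_id"].unique():
        check_tract(tract)
    for prop in df["property"].unique():
        check_property(prop)
    bad_groups = set(df["group"].unique()) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels {sorted(bad_groups)}")
    if n_nodes is None:
        n_nodes = int(df["node"].max())
    if (df["node"] < 1).any() or (df["node"] > n_nodes).any():
        raise ValueError(f"node indices outside 1..{n_nodes}")
    dup = df.duplicated(subset=["subject_id", "tract_id", "property", "node"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate profile row for subject {row['subject_id']!r}, "
            f"({row['tract_id']}, {row['property']}, node {int(row['node'])})"
        )
    group_per_subject = df.groupby("subject_id")["group"].nunique()
    if (group_per_subject > 1).any():
        raise ValueError("conflicting group labels for a subject")

    pairs = sorted(set(zip(df["tract_id"], df["property"])))
    counts = df.groupby("subject_id").size()
    expected = len(pairs) * n_nodes
    complete = counts[counts == expected].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        logger.warning(
            "dropping %d subject(s) with incomplete profiles: %s",
            len(dropped), ", ".join(map(str, dropped)),
        )
        df = df[df["subject_id"].isin(complete)]
    if df.empty:
        raise ValueError("no subject has a complete profile grid")

    subjects = sorted(df["subject_id"].unique())
    sub_index = {s: i for i, s in enumerate(subjects)}
    groups = np.empty(len(subjects), dtype=object)
    for s, g in df.drop_duplicates("subject_id")[["subject_id", "group"]].values:
        groups[sub_index[s]] = g
    data = {}
    for (tract, prop), block in df.groupby(["tract_id", "property"]):
        arr = np.full((len(subjects), n_nodes), np.nan)
        rows = block["subject_id"].map(sub_index).to_numpy()
        cols = block["node"].to_numpy(dtype=int) - 1
        arr[rows, cols] = block["value"].to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError(f"incomplete grid for ({tract}, {prop}) after filtering")
        data[(tract, prop)] = arr
    return Cohort(subjects=subjects, groups=groups, data=data, n_nodes=n_nodes)


BUNDLE_FORMAT = "tractsvm-bundle-v1"


def write_bundle(bundle: StreamlineBundle, path: str | Path) -> None:
    """Write a bundle as JSON lines: a header line, then one fiber per line."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"format": BUNDLE_FORMAT, "tract_id": bundle.tract_id}) + "\n")
        for pts, vals in zip(bundle.fibers, bundle.values):
            fh.write(json.dumps({"points": pts.tolist(), "values": vals.tolist()}) + "\n")


def read_bundle(path: str | Path) -> StreamlineBundle:
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("format") != BUNDLE_FORMAT:
            raise ValueError(f"not a {BUNDLE_FORMAT} file: {path}")
        fibers, values = [], []
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            fibers.append(np.asarray(rec["points"], dtype=float))
            values.append(np.asarray(rec["values"], dtype=float))
    return StreamlineBundle(fibers, values, tract_id=header.get("tract_id"))
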