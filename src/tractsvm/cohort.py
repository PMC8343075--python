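"""The labelled cohort of tract profiles — the unit of analysis.

A :class:`Cohort` holds, for every subject, one ``n_nodes``-long profile per
(tract, property) pair, plus the conversion label (``"C"`` converter /
``"NC"`` non-converter) and optional demographics. Internally profiles are
stored as dense ``(n_subjects, n_nodes)`` arrays keyed by (tract, property),
which is the layout every downstream stage consumes; the long-format CSV
representation lives in :mod:`tractsvm.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracts import GROUPS, check_property, check_tract

#: Sentinel property name meaning "all four properties concatenated".
ALL_PROPERTIES = "ALL"


@dataclass
class TractProfile:
    """One subject's along-tract profile of one diffusion property."""

    subject_id: str
    tract_id: str
    property: str
    values: np.ndarray  # length n_nodes, node 1 first

    def __post_init__(self) -> None:
        check_tract(self.tract_id)
        check_property(self.property)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be a 1-D vector")


@dataclass
class Cohort:
    """Labelled collection of tract profiles.

    Parameters
    ----------
    subjects
        Subject identifiers, in row order of the data arrays.
    groups
        Array of ``"C"``/``"NC"`` labels aligned with ``subjects``.
    data
        Mapping ``(tract_id, property) -> (n_subjects, n_nodes)`` array.
    n_nodes
        Number of nodes per profile (100 in the standard protocol).
    demographics
        Optional per-subject covariates (age, sex, MMSE ...), indexed by
        subject id. Independent of the profiles unless explicitly coupled.
    """

    subjects: list[str]
    groups: np.ndarray
    data: dict[tuple[str, str], np.ndarray]
    n_nodes: int = 100
    demographics: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype=object)
        if len(self.groups) != len(self.subjects):
            raise ValueError("groups and subjects must align")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        for (tract, prop), arr in self.data.items():
            check_tract(tract)
            check_property(prop)
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (len(self.subjects), self.n_nodes):
                raise ValueError(
                    f"profile array for ({tract}, {prop}) has shape {arr.shape}, "
                    f"expected {(len(self.subjects), self.n_nodes)}"
                )
            self.data[(tract, prop)] = arr

    # -- basic introspection -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def tracts(self) -> list[str]:
        return sorted({t for t, _ in self.data})

    @property
    def properties(self) -> list[str]:
        return sorted({p for _, p in self.data})

    def pairs(self) -> list[tuple[str, str]]:
        """All (tract, property) pairs present, in a stable order."""
        return sorted(self.data)

    def labels(self) -> np.ndarray:
        """Binary labels with converters (C) coded 1."""
        return (self.groups == "C").astype(int)

    @property
    def n_converters(self) -> int:
        return int((self.groups == "C").sum())

    # -- feature-matrix assembly --------------------------------------------

    def feature_matrix(
        self, tract_id: str, property: str
    ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str, int]]]:
        """Subjects × features matrix for one tract.

        ``property`` may be one of FA/MD/RD/AxD or :data:`ALL_PROPERTIES`, in
        which case the four 100-node property vectors are concatenated into
        one 400-feature row per subject (FA, MD, RD, AxD order).

        Returns ``(X, y, feature_names)`` where ``y`` codes C as 1 and each
        feature name is a ``(tract_id, property, node)`` triple with 1-based
        node indices.
        """
        check_tract(tract_id)
        if property == ALL_PROPERTIES:
            props = [p for p in ("FA", "MD", "RD", "AxD") if (tract_id, p) in self.data]
            if not props:
                raise KeyError(f"no profiles stored for tract {tract_id!r}")
        else:
            check_property(property)
            if (tract_id, property) not in self.data:
                raise KeyError(f"no profiles stored for ({tract_id!r}, {property!r})")
            props = [property]
        blocks = [self.data[(tract_id, p)] for p in props]
        X = np.hstack(blocks)
        names = [
            (tract_id, p, node)
            for p in props
            for node in range(1, self.n_nodes + 1)
        ]
        return X, self.labels(), names

    def region_feature_matrix(
        self, regions: list[tuple[str, str, list[int]]]
    ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str, int]]]:
        """Assemble features restricted to node regions across tracts/properties.

        ``regions`` is a list of ``(tract_id, property, nodes)`` with 1-based
        node lists; columns follow the given order.
        """
        cols = []
        names: list[tuple[str, str, int]] = []
        for tract, prop, nodes in regions:
            arr = self.data[(check_tract(tract), check_property(prop))]
            for node in nodes:
                if not 1 <= node <= self.n_nodes:
                    raise ValueError(f"node {node} outside 1..{self.n_nodes}")
                cols.append(arr[:, node - 1])
                names.append((tract, prop, node))
        if not cols:
            raise ValueError("empty region set")
        return np.column_stack(cols), self.labels(), names

    # -- long-format conversion ---------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Long-format table: subject_id, group, tract_id, property, node, value."""
        frames = []
        nodes = np.arange(1, self.n_nodes + 1)
        for (tract, prop), arr in sorted(self.data.items()):
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": np.repeat(self.subjects, self.n_nodes),
                        "group": np.repeat(self.groups, self.n_nodes),
                        "tract_id": tract,
                        "property": prop,
                        "node": np.tile(nodes, self.n_subjects),
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)
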