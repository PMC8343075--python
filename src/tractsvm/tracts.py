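"""Canonical tract and diffusion-property registries.

The 20 major white-matter tracts routinely delineated by automated fiber
quantification, and the four tensor-derived diffusion properties measured
along them. Tract identifiers are snake_case and stable; they are the only
tract names accepted anywhere in the package.
"""

from __future__ import annotations

#: The 20 canonical AFQ tracts (left/right pairs plus the two callosal forceps).
CANONICAL_TRACTS: tuple[str, ...] = (
    "left_thalamic_radiation",
    "right_thalamic_radiation",
    "left_corticospinal",
    "right_corticospinal",
    "left_cingulum_cingulate",
    "right_cingulum_cingulate",
    "left_cingulum_hippocampus",
    "right_cingulum_hippocampus",
    "callosum_forceps_major",
    "callosum_forceps_minor",
    "left_ifof",
    "right_ifof",
    "left_ilf",
    "right_ilf",
    "left_slf",
    "right_slf",
    "left_uncinate",
    "right_uncinate",
    "left_arcuate",
    "right_arcuate",
)

#: Diffusion properties: fractional anisotropy (dimensionless), mean/radial/axial
#: diffusivity (10^-3 mm^2/s).
PROPERTIES: tuple[str, ...] = ("FA", "MD", "RD", "AxD")

#: Number of equidistant nodes a tract profile is sampled at.
N_NODES_DEFAULT: int = 100

#: Group labels: converters (C) and non-converters (NC); C is the positive class.
GROUPS: tuple[str, str] = ("C", "NC")


def check_tract(tract_id: str) -> str:
    """Validate a tract identifier, returning it unchanged."""
    if tract_id not in CANONICAL_TRACTS:
        raise ValueError(
            f"unknown tract {tract_id!r}; expected one of the 20 canonical "
            f"tract ids, e.g. {CANONICAL_TRACTS[0]!r}"
        )
    return tract_id


def check_property(prop: str) -> str:
    """Validate a diffusion-property name, returning it unchanged."""
    if prop not in PROPERTIES:
        raise ValueError(f"unknown diffusion property {prop!r}; expected one of {PROPERTIES}")
    return prop
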