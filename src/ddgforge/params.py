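"""Versioned force-field parameter resolution.

All tunable constants ship in ``data/parameters.yaml`` as a v1 baseline plus
the incremental changes introduced by later force-field revisions.  A
:class:`ForceField` is the fully resolved parameter set for one version tag.

Version tags, in calibration order::

    v1 < v2 < v3 < v4 < v2-4 < v5 < v6 < v7 < v8 < v9 < v10

``v2-4`` is the integration point of the first three changes; every later
version includes all earlier ones.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

VERSIONS = ["v1", "v2", "v3", "v4", "v2-4", "v5", "v6", "v7", "v8", "v9", "v10"]

#: angle names of the H-bond geometry boundary table
HBOND_ANGLE_KEYS = (
    "maxFreeProtDon",
    "minFreeProtDon",
    "optMaxFreeProtDon",
    "optMinFreeProtDon",
    "maxProtFreeAcc",
    "minProtFreeAcc",
    "optMaxProtFreeAcc",
    "optMinProtFreeAcc",
    "optDihed",
)


def version_index(version: str) -> int:
    """Ordinal of a version tag; raises ``ValueError`` for unknown tags."""
    try:
        return VERSIONS.index(version)
    except ValueError:
        raise ValueError(
            f"unknown force-field version {version!r}; expected one of {VERSIONS}"
        ) from None


def version_at_least(version: str, other: str) -> bool:
    return version_index(version) >= version_index(other)


@dataclass
class HBondGeometryTable:
    """Per-class H-bond angle boundaries (degrees).

    ``classes`` maps a class name (``ALL-ALL`` for the v1 single-column table,
    ``BB-BB``/``BB-SC``/``SC-SC`` for the v8 table) to a dict with the nine
    boundary entries of :data:`HBOND_ANGLE_KEYS`.
    """

    classes: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for name, tbl in self.classes.items():
            missing = set(HBOND_ANGLE_KEYS) - set(tbl)
            if missing:
                raise ValueError(f"geometry table {name} missing {sorted(missing)}")
            for angle in ("FreeProtDon", "ProtFreeAcc"):
                lo = tbl[f"min{angle}"]
                olo = tbl[f"optMin{angle}"]
                ohi = tbl[f"optMax{angle}"]
                hi = tbl[f"max{angle}"]
                if not lo <= olo <= ohi <= hi:
                    raise ValueError(
                        f"geometry table {name}/{angle}: require "
                        f"min <= optMin <= optMax <= max, got {lo},{olo},{ohi},{hi}"
                    )

    def for_class(self, klass: str) -> dict[str, float]:
        """Boundaries for an interaction class, falling back to ALL-ALL."""
        if klass in self.classes:
            return self.classes[klass]
        return self.classes["ALL-ALL"]


@dataclass
class ForceField:
    """Fully resolved parameter set for one force-field version."""

    version: str
    raw: dict[str, Any] = field(repr=False)

    # --- resolved feature switches -------------------------------------
    salt_bridge_factor: float = 1.0      # v2+
    dipole_distance_power: int = 1       # v3+: 2
    ncap_multipliers: dict[str, float] = field(default_factory=dict)
    met_entropy: float = 0.0051          # v5+: Lys value
    pipi_enabled: bool = False           # v6+
    ph_all_residues: bool = False        # v6+: corrected pKas beyond His/Cys
    trp_apolar_shift: float = 0.0        # v7+
    hbond_geometry: HBondGeometryTable | None = None
    ring_volume_factor: float = 1.0      # v9+
    min_buried_extra: float = 0.0        # v10
    pro_min_buried_v10: bool = False     # v10

    @property
    def hbond(self) -> dict[str, Any]:
        return self.raw["hbond"]

    @property
    def electrostatics(self) -> dict[str, Any]:
        return self.raw["electrostatics"]

    @property
    def pipi(self) -> dict[str, Any]:
        return self.raw["pipi"]

    @property
    def solvation(self) -> dict[str, Any]:
        return self.raw["solvation"]

    @property
    def volumes(self) -> dict[str, Any]:
        return self.raw["volumes"]

    @property
    def entropy_table(self) -> dict[str, float]:
        table = dict(self.raw["entropy"]["table"])
        table["MET"] = self.met_entropy
        return table

    @property
    def clash(self) -> dict[str, float]:
        return self.raw["clash"]


def load_raw_parameters(path: str | None = None) -> dict[str, Any]:
    """Load the shipped (or a user-supplied) YAML parameter file."""
    if path is None:
        text = (
            resources.files("ddgforge").joinpath("data/parameters.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def get_params(version: str = "v10", path: str | None = None) -> ForceField:
    """Resolve the concrete parameter set for ``version``.

    Each revision's change is applied cumulatively on top of the v1 baseline.
    """
    raw = copy.deepcopy(load_raw_parameters(path))
    ff = ForceField(version=version, raw=raw)
    v = version_index(version)  # validates the tag

    if version_at_least(version, "v2"):
        ff.salt_bridge_factor = raw["hbond"]["salt_bridge_factor"]
    if version_at_least(version, "v3"):
        ff.dipole_distance_power = 2
    if version_at_least(version, "v4"):
        ff.ncap_multipliers = dict(raw["hbond"]["ncap_multipliers"])
    if version_at_least(version, "v5"):
        ff.met_entropy = raw["entropy"]["met_v5"]
    if version_at_least(version, "v6"):
        ff.pipi_enabled = True
        ff.ph_all_residues = True
    if version_at_least(version, "v7"):
        ff.trp_apolar_shift = raw["solvation"]["trp_apolar_shift"]
    if version_at_least(version, "v8"):
        ff.hbond_geometry = HBondGeometryTable(classes=raw["hbond"]["geometry"]["v8"])
    else:
        ff.hbond_geometry = HBondGeometryTable(classes=raw["hbond"]["geometry"]["v1"])
    if version_at_least(version, "v9"):
        ff.ring_volume_factor = raw["volumes"]["ring_volume_factor"]
    if version_at_least(version, "v10"):
        ff.min_buried_extra = raw["volumes"]["v10_min_buried_increment"]
        ff.pro_min_buried_v10 = True
    del v
    return ff
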