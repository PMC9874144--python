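"""Region sets defining the amyloid and tau PET outcome blocks.

SUVR tables are wide (subjects x regions) with columns named by
hemisphere-qualified Desikan-Killiany labels: ``ctx-lh-<label>`` /
``ctx-rh-<label>`` for cortical regions, ``lh-<label>`` / ``rh-<label>`` for
subcortical structures (here only the amygdala).  Region membership ships as
editable YAML config; the defaults give 19 bilateral amyloid regions (38
columns, the families of a global-amyloid composite) and 7 bilateral
early-Braak tau regions (14 columns, hippocampus excluded for off-target
binding).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["RegionSet", "default_region_set", "validate_suvr_table", "RegionError"]

HEMIS = ("lh", "rh")
TRACERS = ("abeta", "tau")


class RegionError(ValueError):
    """Unknown tracer or invalid SUVR table."""


@dataclass(frozen=True)
class RegionSet:
    """An ordered, bilateral set of PET regions for one tracer.

    ``cortical`` and ``subcortical`` hold unlateralised Desikan-Killiany
    labels; :attr:`columns` expands them to the hemisphere-qualified column
    names, lh before rh for each label.
    """

    name: str
    tracer: str
    cortical: tuple[str, ...]
    subcortical: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tracer not in TRACERS:
            raise RegionError(f"unknown tracer {self.tracer!r}; expected one of {TRACERS}")
        labels = list(self.cortical) + list(self.subcortical)
        if len(labels) != len(set(labels)):
            raise RegionError("duplicate region labels in set")
        if self.tracer == "tau" and "hippocampus" in labels:
            raise RegionError("tau region sets must not include the hippocampus")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.cortical) + tuple(self.subcortical)

    @property
    def columns(self) -> tuple[str, ...]:
        cols: list[str] = []
        for lab in self.cortical:
            cols += [f"ctx-{h}-{lab}" for h in HEMIS]
        for lab in self.subcortical:
            cols += [f"{h}-{lab}" for h in HEMIS]
        return tuple(cols)

    def __len__(self) -> int:
        return len(self.columns)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "RegionSet":
        return cls(
            name=raw["name"],
            tracer=raw["tracer"],
            cortical=tuple(raw.get("cortical") or ()),
            subcortical=tuple(raw.get("subcortical") or ()),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "tracer": self.tracer,
            "cortical": list(self.cortical),
            "subcortical": list(self.subcortical),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def default_region_set(tracer: str) -> RegionSet:
    """Shipped region set for ``tracer`` ('abeta' -> 38 columns, 'tau' -> 14)."""
    if tracer not in TRACERS:
        raise RegionError(f"unknown tracer {tracer!r}; expected one of {TRACERS}")
    ref = resources.files("mindpls.data") / f"regions_{tracer}.yaml"
    with ref.open() as fh:
        return RegionSet._from_mapping(yaml.safe_load(fh))


def validate_suvr_table(table: pd.DataFrame, regions: RegionSet) -> pd.DataFrame:
    """Check and reorder a wide SUVR table against a region set.

    Columns are reordered to the region-set order; extra columns are dropped
    with a warning.  All SUVR values must be positive and finite.
    """
    want = list(regions.columns)
    absent = [c for c in want if c not in table.columns]
    if absent:
        raise RegionError(f"SUVR table missing region column(s): {absent}")
    extra = [c for c in table.columns if c not in want]
    if extra:
        warnings.warn(f"dropping {len(extra)} extra SUVR column(s): {extra}", stacklevel=2)
    out = table[want].astype(float)
    vals = out.to_numpy()
    if not np.isfinite(vals).all():
        raise RegionError("SUVR table contains non-finite values")
    if (vals <= 0).any():
        bad = out.columns[(vals <= 0).any(axis=0)]
        raise RegionError(f"nonpositive SUVR values in column(s): {list(bad)}")
    return out
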