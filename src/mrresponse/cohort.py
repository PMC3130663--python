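"""Longitudinal cohort containers.

One :class:`AnimalRecord` holds a single xenograft's tumor volume, serum PSA,
ROI-mean ADC and ROI-mean K^trans at the three imaging days (0, 1, 9) plus the
day-30 endpoint volume.  A :class:`Cohort` is the full four-group experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Canonical treatment-arm labels: untreated control, radiotherapy only,
#: androgen deprivation only, and the combination.
GROUPS = ("control", "rt", "adt", "adt_rt")

#: Canonical biomarker order used everywhere downstream.
BIOMARKERS = ("adc", "ktrans", "volume", "psa")

#: Imaging days relative to treatment start.
DAYS = (0, 1, 9)


@dataclass
class AnimalRecord:
    """One animal's longitudinal measurements.

    ``volume`` is in mm^3, ``psa`` in ng/ml, ``adc`` in mm^2/s and ``ktrans``
    in 1/s; each maps imaging day -> value.  ``v30`` is the day-30 endpoint
    tumor volume in mm^3.
    """

    id: str
    group: str
    volume: dict[int, float]
    psa: dict[int, float]
    adc: dict[int, float]
    ktrans: dict[int, float]
    v30: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for animal {self.id}")
        for name in BIOMARKERS:
            traj = getattr(self, _FIELD_BY_BIOMARKER[name])
            missing = [d for d in DAYS if d not in traj]
            if missing:
                raise ValueError(
                    f"animal {self.id}: {name} missing days {missing}"
                )
        if not self.v30 > 0:
            raise ValueError(f"animal {self.id}: V30 must be positive, got {self.v30}")

    def trajectory(self, biomarker: str) -> dict[int, float]:
        return getattr(self, _FIELD_BY_BIOMARKER[biomarker])


_FIELD_BY_BIOMARKER = {"adc": "adc", "ktrans": "ktrans", "volume": "volume", "psa": "psa"}

_CSV_PREFIX = {"volume": "V", "psa": "PSA", "adc": "ADC", "ktrans": "Ktrans"}


@dataclass
class Cohort:
    """A simulated (or measured) experiment: list of animals plus provenance."""

    animals: list[AnimalRecord]
    config_snapshot: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [a.id for a in self.animals]
        if len(set(ids)) != len(ids):
            raise ValueError("animal ids are not unique")

    def __len__(self) -> int:
        return len(self.animals)

    def groups(self) -> list[str]:
        return [a.group for a in self.animals]

    def subset(self, group: str) -> list[AnimalRecord]:
        return [a for a in self.animals if a.group == group]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for a in self.animals:
            row: dict[str, object] = {"id": a.id, "group": a.group}
            for name in BIOMARKERS:
                traj = a.trajectory(name)
                for d in DAYS:
                    row[f"{_CSV_PREFIX[name]}_d{d}"] = traj[d]
            row["V_30"] = a.v30
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write one row per animal; a JSON sidecar records config and seed."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {"config": self.config_snapshot, "seed": self.seed}
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        df = pd.read_csv(path)
        animals = []
        for _, row in df.iterrows():
            kwargs = {}
            for name in BIOMARKERS:
                kwargs[_FIELD_BY_BIOMARKER[name]] = {
                    d: float(row[f"{_CSV_PREFIX[name]}_d{d}"]) for d in DAYS
                }
            animals.append(
                AnimalRecord(
                    id=str(row["id"]), group=str(row["group"]), v30=float(row["V_30"]), **kwargs
                )
            )
        meta_path = path.with_suffix(".json")
        config, seed = {}, None
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            config, seed = meta.get("config", {}), meta.get("seed")
        return cls(animals=animals, config_snapshot=config, seed=seed)
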