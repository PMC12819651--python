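"""Coregulator binding-plate container, well-label arithmetic and I/O.

A plate records fluorescence intensities for the binding of a nuclear
receptor (here, the glucocorticoid-receptor ligand-binding domain) to an
array of immobilized coregulator peptide motifs, under a set of conditions:

* ``Apo`` — the unstimulated receptor, the normalization reference;
* a stimulus control (typically ``cortisol``);
* up to 96 sequential plant fractions, named by their well label
  (``A1`` ... ``H12``); the fractionation order makes the well sequence a
  chemical gradient, so wells are mapped to 1-based row-major indices
  (``A1``->1 ... ``A12``->12, ``B1``->13, ... ``H12``->96);
* optional spiked conditions written ``<stimulus>+<motif>``, in which a
  soluble coregulator motif competes with the immobilized ones.

Files are long-format CSV (columns ``plant_id, motif, condition, well,
replicate, value``) or an equivalent JSON object.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlateError",
    "APO",
    "well_to_index",
    "index_to_well",
    "is_well_label",
    "BindingPlate",
    "load_plate",
    "write_plate",
]

#: Condition name of the unstimulated reference.
APO = "Apo"

_ROWS = "ABCDEFGH"
_WELL_RE = re.compile(r"^([A-H])(1[0-2]|[1-9])$")


class PlateError(ValueError):
    """Raised for malformed plate files or invariant violations."""


def is_well_label(label: str) -> bool:
    return bool(_WELL_RE.match(str(label)))


def well_to_index(label: str) -> int:
    """Map a 96-well label to its 1-based row-major sequential index.

    ``A1`` -> 1, ``A12`` -> 12, ``B12`` -> 24, ``C4`` -> 28, ``D6`` -> 42,
    ``H12`` -> 96.
    """
    m = _WELL_RE.match(str(label))
    if not m:
        raise PlateError(f"unknown well label {label!r}")
    row, col = m.groups()
    return _ROWS.index(row) * 12 + int(col)


def index_to_well(index: int) -> str:
    """Inverse of :func:`well_to_index` on 1..96."""
    if not 1 <= int(index) <= 96:
        raise PlateError(f"well index {index} outside 1..96")
    i = int(index) - 1
    return f"{_ROWS[i // 12]}{i % 12 + 1}"


def split_spiked(condition: str) -> tuple[str, str] | None:
    """Return (base stimulus, spiked motif) for a ``base+motif`` condition."""
    if "+" in condition:
        base, motif = condition.split("+", 1)
        return base, motif
    return None


class BindingPlate:
    """Motif x condition x replicate fluorescence matrix for one plant.

    Parameters
    ----------
    plant_id
        Identifier of the plant / extract the fraction series derives from.
    data
        Long-format frame with columns ``motif, condition, well, replicate,
        value``.  ``well`` is empty except for fraction conditions, whose
        condition name equals their well label.
    """

    REQUIRED = ("motif", "condition", "well", "replicate", "value")

    def __init__(self, plant_id: str, data: pd.DataFrame):
        missing = set(self.REQUIRED) - set(data.columns)
        if missing:
            raise PlateError(f"plate data missing columns {sorted(missing)}")
        df = data.loc[:, list(self.REQUIRED)].copy()
        df["motif"] = df["motif"].astype(str)
        df["condition"] = df["condition"].astype(str)
        df["well"] = df["well"].fillna("").astype(str)
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)
        if (df["value"] < 0).any():
            bad = df.loc[df["value"] < 0].iloc[0]
            raise PlateError(
                f"negative fluorescence for motif {bad['motif']!r}, "
                f"condition {bad['condition']!r}"
            )
        if APO not in set(df["condition"]):
            raise PlateError(f"plate {plant_id!r} lacks an {APO} condition")
        for w in df.loc[df["well"] != "", "well"].unique():
            well_to_index(w)  # raises on unknown labels
        self.plant_id = str(plant_id)
        self.data = df.reset_index(drop=True)
        self.motifs: tuple[str, ...] = tuple(dict.fromkeys(df["motif"]))
        self.conditions: tuple[str, ...] = tuple(dict.fromkeys(df["condition"]))
        self._matrix_cache: dict[str, pd.DataFrame] = {}
        self._mean_cache: pd.DataFrame | None = None

    # -- condition taxonomy -------------------------------------------------
    @property
    def fraction_conditions(self) -> tuple[str, ...]:
        """Fraction conditions in sequential (row-major well) order."""
        fracs = [c for c in self.conditions if is_well_label(c)]
        return tuple(sorted(fracs, key=well_to_index))

    @property
    def spiked_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if split_spiked(c) is not None)

    @property
    def stimulus_conditions(self) -> tuple[str, ...]:
        """Non-Apo, non-fraction, non-spiked conditions (e.g. cortisol)."""
        return tuple(
            c
            for c in self.conditions
            if c != APO and not is_well_label(c) and split_spiked(c) is None
        )

    def fraction_indices(self) -> dict[str, int]:
        return {c: well_to_index(c) for c in self.fraction_conditions}

    # -- value access -------------------------------------------------------
    def values(self, motif: str, condition: str) -> np.ndarray:
        """Replicate values for one (motif, condition) cell, replicate order."""
        sel = self.data[
            (self.data["motif"] == motif) & (self.data["condition"] == condition)
        ].sort_values("replicate")
        if sel.empty:
            raise PlateError(f"no values for motif {motif!r}, condition {condition!r}")
        return sel["value"].to_numpy()

    def value_matrix(self, condition: str) -> pd.DataFrame:
        """Motif x replicate matrix for one condition (motif plate order)."""
        if condition not in self._matrix_cache:
            sel = self.data[self.data["condition"] == condition]
            mat = sel.pivot_table(
                index="motif", columns="replicate", values="value", aggfunc="first"
            )
            self._matrix_cache[condition] = mat.reindex(
                [m for m in self.motifs if m in mat.index]
            )
        return self._matrix_cache[condition]

    def mean_table(self) -> pd.DataFrame:
        """Motif x condition matrix of replicate means (cached)."""
        if self._mean_cache is None:
            self._mean_cache = self.data.pivot_table(
                index="motif", columns="condition", values="value", aggfunc="mean"
            ).reindex(list(self.motifs))
        return self._mean_cache

    def n_replicates(self, condition: str) -> int:
        return int(
            self.data.loc[self.data["condition"] == condition, "replicate"].nunique()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BindingPlate):
            return NotImplemented
        a = self.data.sort_values(list(self.REQUIRED[:4])).reset_index(drop=True)
        b = other.data.sort_values(list(self.REQUIRED[:4])).reset_index(drop=True)
        return self.plant_id == other.plant_id and a.equals(b)

    def __repr__(self) -> str:
        return (
            f"<BindingPlate {self.plant_id!r}: {len(self.motifs)} motifs, "
            f"{len(self.conditions)} conditions>"
        )


def load_plate(path: str | Path) -> BindingPlate:
    """Load a plate from long-format CSV or the equivalent JSON object."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        try:
            plant_id = obj["plant_id"]
            df = pd.DataFrame(obj["data"])
        except (KeyError, TypeError) as exc:
            raise PlateError(f"{path}: malformed plate JSON ({exc})") from exc
    elif path.suffix.lower() == ".csv":
        df = pd.read_csv(path, keep_default_na=False, na_values=[])
        if "plant_id" not in df.columns or df.empty:
            raise PlateError(f"{path}: missing plant_id column or empty file")
        ids = df["plant_id"].astype(str).unique()
        if len(ids) != 1:
            raise PlateError(f"{path}: expected a single plant_id, got {list(ids)}")
        plant_id = ids[0]
        df = df.drop(columns=["plant_id"])
    else:
        raise PlateError(f"unsupported plate format {path.suffix!r}")
    try:
        return BindingPlate(plant_id, df)
    except PlateError as exc:
        raise PlateError(f"{path}: {exc}") from exc


def write_plate(plate: BindingPlate, path: str | Path) -> Path:
    """Write a plate to CSV or JSON; the output round-trips via load_plate."""
    path = Path(path)
    df = plate.data.sort_values(["condition", "motif", "replicate"]).reset_index(
        drop=True
    )
    if path.suffix.lower() == ".json":
        payload = {
            "plant_id": plate.plant_id,
            "data": {c: df[c].tolist() for c in df.columns},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)
    elif path.suffix.lower() == ".csv":
        out = df.copy()
        out.insert(0, "plant_id", plate.plant_id)
        out.to_csv(path, index=False)
    else:
        raise PlateError(f"unsupported plate format {path.suffix!r}")
    return path
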