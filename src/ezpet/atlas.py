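"""Integer label atlases for anatomical localization.

An atlas pairs an integer label volume with a lookup table assigning each
region a name, a side (L / R / midline) and a sublobar class (mesial
temporal MT, lateral temporal LT, frontal F, parietal P, occipital O,
insular I, or "other" for non-cortical structures), plus a cortical flag.
Cluster localization votes over these labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import Volume, read_volume

__all__ = ["LabelAtlas", "load_atlas", "SIDES", "SUBLOBAR_CLASSES"]

SIDES = ("L", "R", "midline")
SUBLOBAR_CLASSES = ("MT", "LT", "F", "P", "O", "I", "other")

_TABLE_COLUMNS = ["id", "name", "side", "sublobar", "cortical"]


@dataclass
class LabelAtlas:
    """An integer label volume plus its region table.

    Invariant: every nonzero label present in the volume appears in the
    table exactly once; label 0 is background and never tabulated.
    """

    labels: Volume
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.issubdtype(self.labels.data.dtype, np.integer):
            raise ValueError("atlas label volume must have an integer dtype")
        missing = [c for c in _TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"atlas table is missing columns {missing}")
        ids = self.table["id"].to_numpy()
        if (ids == 0).any():
            raise ValueError("label 0 is reserved for background")
        dup = self.table["id"][self.table["id"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate label ids in atlas table: {dup}")
        bad_side = set(self.table["side"]) - set(SIDES)
        if bad_side:
            raise ValueError(f"unknown side values: {sorted(bad_side)}")
        bad_sub = set(self.table["sublobar"]) - set(SUBLOBAR_CLASSES)
        if bad_sub:
            raise ValueError(f"unknown sublobar classes: {sorted(bad_sub)}")
        present = np.unique(self.labels.data)
        present = present[present != 0]
        untabulated = sorted(set(present.tolist()) - set(ids.tolist()))
        if untabulated:
            raise ValueError(f"labels present in volume but absent from table: {untabulated}")
        self._rows = {int(r.id): r for r in self.table.itertuples(index=False)}

    def side(self, label: int) -> str:
        return self._rows[int(label)].side

    def sublobar(self, label: int) -> str:
        return self._rows[int(label)].sublobar

    def is_cortical(self, label: int) -> bool:
        if label == 0:
            return False
        return bool(self._rows[int(label)].cortical)

    def name(self, label: int) -> str:
        return self._rows[int(label)].name

    @property
    def cortical_ids(self) -> list[int]:
        return [int(i) for i in self.table.loc[self.table["cortical"].astype(bool), "id"]]


def load_atlas(volume_path, table_path) -> LabelAtlas:
    """Load a label atlas from a NIfTI label image and a TSV region table.

    The table must carry columns (id, name, side, sublobar, cortical);
    ``cortical`` is parsed as 0/1 or true/false.
    """
    vol = read_volume(volume_path)
    data = vol.data
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError("atlas label volume holds non-integer values")
        data = rounded.astype(np.int32)
        vol = Volume(data, vol.affine)
    table = pd.read_csv(table_path, sep="\t", dtype={"name": str, "side": str, "sublobar": str})
    if "cortical" in table.columns and table["cortical"].dtype == object:
        table["cortical"] = (
            table["cortical"].str.strip().str.lower().map({"true": 1, "false": 0}).fillna(table["cortical"])
        )
    table["cortical"] = table["cortical"].astype(int).astype(bool)
    return LabelAtlas(vol, table)
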