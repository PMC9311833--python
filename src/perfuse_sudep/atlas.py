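"""The 74-structure brain atlas catalogue.

The perfusion quantification operates on 74 cortical and subcortical grey-matter
structures (Oishi-style whole-brain parcellation).  Each structure carries a
laterality (left / right / midline), a partner relation pairing left and right
homologues (midline structures partner themselves), and a cortical/subcortical
class used for the N/N_subc cluster summaries.

Because the seizure onset side differs between patients, cross-patient analyses
re-key paired structures to an ipsilateral/contralateral frame
(:func:`relabel_ipsilateral`).  This is a pure permutation of the ROI table —
activity values are never altered.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "StructureDef",
    "AtlasSpec",
    "load_atlas_spec",
    "default_atlas",
    "relabel_ipsilateral",
]

HEMISPHERES = ("left", "right", "midline")
CLASSES = ("cortical", "subcortical")


class AtlasError(ValueError):
    """Malformed or inconsistent atlas catalogue."""


@dataclass(frozen=True)
class StructureDef:
    """One atlas structure: integer label, name, laterality, partner and class."""

    id: int
    name: str
    hemisphere: str
    partner_id: int
    klass: str


@dataclass(frozen=True)
class AtlasSpec:
    """Validated catalogue of the 74 atlas structures."""

    structures: tuple[StructureDef, ...]
    _by_id: dict = field(default_factory=dict, repr=False, compare=False)
    _by_name: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_id", {s.id: s for s in self.structures})
        object.__setattr__(self, "_by_name", {s.name: s for s in self.structures})
        self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        n = len(self.structures)
        if n != 74:
            raise AtlasError(f"atlas must define exactly 74 structures, got {n}")
        if len(self._by_id) != n:
            raise AtlasError("duplicate structure ids in atlas")
        if len(self._by_name) != n:
            raise AtlasError("duplicate structure names in atlas")
        for s in self.structures:
            if s.id < 1:
                raise AtlasError(f"structure {s.name!r}: id must be >= 1")
            if s.hemisphere not in HEMISPHERES:
                raise AtlasError(f"structure {s.name!r}: bad hemisphere {s.hemisphere!r}")
            if s.klass not in CLASSES:
                raise AtlasError(f"structure {s.name!r}: bad class {s.klass!r}")
            partner = self._by_id.get(s.partner_id)
            if partner is None:
                raise AtlasError(f"structure {s.name!r}: partner id {s.partner_id} unknown")
            if partner.partner_id != s.id:
                raise AtlasError(
                    f"partner relation is not an involution at {s.name!r} "
                    f"(partner {partner.name!r} points back to id {partner.partner_id})"
                )
            if s.hemisphere == "midline":
                if s.partner_id != s.id:
                    raise AtlasError(f"midline structure {s.name!r} must partner itself")
            else:
                if s.partner_id == s.id:
                    raise AtlasError(f"lateral structure {s.name!r} cannot partner itself")
                expected = "right" if s.hemisphere == "left" else "left"
                if partner.hemisphere != expected:
                    raise AtlasError(
                        f"structure {s.name!r}: partner {partner.name!r} is in "
                        f"{partner.hemisphere!r}, expected {expected!r}"
                    )

    # -- lookups ----------------------------------------------------------
    @property
    def n_structures(self) -> int:
        return len(self.structures)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.structures]

    @property
    def ids(self) -> list[int]:
        return [s.id for s in self.structures]

    def by_id(self, sid: int) -> StructureDef:
        return self._by_id[sid]

    def by_name(self, name: str) -> StructureDef:
        return self._by_name[name]

    def partner(self, name: str) -> StructureDef:
        return self._by_id[self._by_name[name].partner_id]

    def base_name(self, name: str) -> str:
        """Structure name without the _L/_R (or _ipsi/_contra) suffix."""
        for suffix in ("_L", "_R", "_ipsi", "_contra"):
            if name.endswith(suffix):
                return name[: -len(suffix)]
        return name

    def klass_of(self, name: str) -> str:
        """Cortical/subcortical class; accepts canonical, ipsi/contra or midline names."""
        if name in self._by_name:
            return self._by_name[name].klass
        base = self.base_name(name)
        for cand in (f"{base}_L", f"{base}_R", base):
            if cand in self._by_name:
                return self._by_name[cand].klass
        raise KeyError(f"unknown structure name {name!r}")

    def is_subcortical(self, name: str) -> bool:
        return self.klass_of(name) == "subcortical"

    def resolve_side(self, name: str, onset_side: str) -> str:
        """Map an ipsi/contra-suffixed name to its canonical L/R name."""
        if onset_side not in ("left", "right"):
            raise ValueError(f"unknown onset side {onset_side!r}")
        if name in self._by_name:
            return name
        base = self.base_name(name)
        if name.endswith("_ipsi"):
            side = "L" if onset_side == "left" else "R"
        elif name.endswith("_contra"):
            side = "R" if onset_side == "left" else "L"
        else:
            raise KeyError(f"unknown structure name {name!r}")
        canonical = f"{base}_{side}"
        if canonical not in self._by_name:
            raise KeyError(f"unknown structure name {name!r}")
        return canonical

    def ipsicontra_name(self, name: str, onset_side: str) -> str:
        """Canonical L/R name -> ipsi/contra name given the seizure onset side."""
        if onset_side not in ("left", "right"):
            raise ValueError(f"unknown onset side {onset_side!r}")
        s = self._by_name[name]
        if s.hemisphere == "midline":
            return name
        same = (s.hemisphere == onset_side)
        return f"{self.base_name(name)}_{'ipsi' if same else 'contra'}"


def load_atlas_spec(path: str | Path | None = None) -> AtlasSpec:
    """Load and validate an atlas catalogue TSV (``id name hemisphere partner_id class``).

    With no argument, loads the bundled 74-structure default catalogue.
    """
    if path is None:
        ref = resources.files("perfuse_sudep").joinpath("data/atlas74.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    required = {"id", "name", "hemisphere", "partner_id", "class"}
    if not rows or not required.issubset(rows[0].keys()):
        raise AtlasError(f"atlas catalogue must have columns {sorted(required)}")
    structures = []
    for i, row in enumerate(rows, start=2):
        try:
            structures.append(
                StructureDef(
                    id=int(row["id"]),
                    name=row["name"].strip(),
                    hemisphere=row["hemisphere"].strip(),
                    partner_id=int(row["partner_id"]),
                    klass=row["class"].strip(),
                )
            )
        except (KeyError, ValueError) as exc:
            raise AtlasError(f"atlas catalogue line {i}: {exc}") from exc
    return AtlasSpec(structures=tuple(structures))


def default_atlas() -> AtlasSpec:
    """The bundled 74-structure catalogue."""
    return load_atlas_spec(None)


def relabel_ipsilateral(
    table: pd.DataFrame, onset_side: str, atlas: AtlasSpec
) -> pd.DataFrame:
    """Re-key a per-structure table from L/R to ipsi/contra naming.

    ``table`` is indexed by canonical structure name and must cover all 74
    structures.  When onset is left, left-hemisphere structures become ipsi;
    when right, right-hemisphere structures become ipsi.  Midline structures
    keep their names.  Values are permuted, never altered.  Idempotent in the
    sense that the resulting ipsi/contra keys no longer depend on side.
    """
    if onset_side not in ("left", "right"):
        raise ValueError(f"unknown onset side {onset_side!r}")
    missing = set(atlas.names) - set(table.index)
    extra = set(table.index) - set(atlas.names)
    if extra:
        # already relabeled tables pass through unchanged (idempotence)
        if all(n.endswith(("_ipsi", "_contra")) or n in atlas.names for n in table.index):
            return table.copy()
        raise KeyError(f"table contains unknown structures: {sorted(extra)[:5]}")
    if missing:
        raise KeyError(f"table must cover all 74 structures; missing {sorted(missing)[:5]}")
    renamed = table.rename(index=lambda n: atlas.ipsicontra_name(n, onset_side))
    return renamed.sort_index()
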