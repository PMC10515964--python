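"""Hierarchical developmental ontology, ID remapping and annotation volumes.

Regions form a tree (prosomeric-style nomenclature: neuromeres subdivided
into floor/basal/alar/roof plates, and so on).  Each region carries a 16-bit
label (``id16``) used in annotation volumes, optionally the original 32-bit
label of a legacy atlas it derives from, a name, acronym, color and depth.

Label-number scheme
-------------------
* ids below 18000: pre-existing atlas labels, kept verbatim;
* 18000-19999: reserved for newly added structures (the allocator refuses to
  exceed the range);
* 20000-29999: legacy 32-bit ids that do not fit in 16 bits, remapped by
  taking the last four decimal digits and prefixing a 2, i.e.
  ``20000 + id32 % 10000``.  Collisions raise rather than silently renumber.

An annotation volume labels every brain voxel with exactly one region id;
the validator checks mutual exclusivity (trivially true for a single label
image), exhaustiveness against a brain mask, and label membership in the
ontology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .volume import ImageVolume

__all__ = [
    "Region",
    "Ontology",
    "AnnotationVolume",
    "OntologyError",
    "CollisionError",
    "load_ontology",
    "remap_id32_to_16",
    "build_remap_table",
    "NewIdAllocator",
    "validate_annotation",
    "ValidationReport",
    "aggregate_to_level",
    "crosstab_labels",
]

NEW_ID_RANGE = (18000, 19999)
REMAP_RANGE = (20000, 29999)
ID16_MAX = 65535


class OntologyError(ValueError):
    pass


class CollisionError(OntologyError):
    pass


@dataclass
class Region:
    id16: int
    name: str
    acronym: str
    parent: int | None  # parent id16, None for root
    color: str = "#808080"
    id32: int | None = None
    level: int = 0


class Ontology:
    """Region tree keyed by 16-bit id."""

    def __init__(self, regions: Iterable[Region]):
        self.regions: dict[int, Region] = {}
        errors: list[str] = []
        for r in regions:
            if r.id16 in self.regions:
                errors.append(f"duplicate id16 {r.id16}")
            if not (0 <= r.id16 <= ID16_MAX):
                errors.append(f"id16 {r.id16} outside 16-bit range")
            self.regions[r.id16] = r
        self.children: dict[int, list[int]] = {i: [] for i in self.regions}
        roots: list[int] = []
        for r in self.regions.values():
            if r.parent is None:
                roots.append(r.id16)
            elif r.parent not in self.regions:
                errors.append(f"orphan region {r.id16} ({r.acronym}): "
                              f"parent {r.parent} not in ontology")
            else:
                self.children[r.parent].append(r.id16)
        if not roots and self.regions:
            errors.append("no root region")
        self.roots = roots
        # level assignment + cycle detection by walking parent chains
        for r in self.regions.values():
            seen = {r.id16}
            depth = 0
            cur = r
            while cur.parent is not None and cur.parent in self.regions:
                if cur.parent in seen:
                    errors.append(f"cycle in parent links at region {r.id16}")
                    depth = -1
                    break
                seen.add(cur.parent)
                cur = self.regions[cur.parent]
                depth += 1
            if depth >= 0:
                r.level = depth
        if errors:
            raise OntologyError("; ".join(sorted(set(errors))))

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, id16: int) -> bool:
        return int(id16) in self.regions

    def __getitem__(self, id16: int) -> Region:
        return self.regions[int(id16)]

    def ancestor_at_level(self, id16: int, level: int) -> int | None:
        """The ancestor of a region at the given depth (itself if shallower)."""
        r = self.regions[int(id16)]
        if r.level <= level:
            return r.id16
        while r.level > level and r.parent is not None:
            r = self.regions[r.parent]
        return r.id16 if r.level == level else None

    def leaves(self) -> list[int]:
        return [i for i, ch in self.children.items() if not ch]

    def descendants(self, id16: int) -> list[int]:
        out = []
        stack = list(self.children[int(id16)])
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.children[i])
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id16": r.id16, "id32": r.id32, "name": r.name,
             "acronym": r.acronym,
             "parent_id16": r.parent, "color_hex": r.color, "level": r.level}
            for r in self.regions.values()
        ]
        return pd.DataFrame(rows).sort_values("id16").reset_index(drop=True)


def load_ontology(source) -> Ontology:
    """Build an ontology from a CSV/JSON path, DataFrame or row iterable.

    Expected columns/keys: id16 (or id), name, acronym, parent_id16 (or
    parent; empty/NaN for the root), optional color_hex, id32.
    """
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.suffix.lower() == ".json":
            rows = json.loads(p.read_text())
            df = pd.DataFrame(rows)
        else:
            df = pd.read_csv(p)
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.DataFrame(list(source))
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("id16") or cols.get("id")
    parent_col = cols.get("parent_id16") or cols.get("parent")
    if id_col is None or parent_col is None:
        raise OntologyError("ontology table needs id and parent columns")
    regions = []
    for _, row in df.iterrows():
        parent = row[parent_col]
        parent = None if pd.isna(parent) else int(parent)
        id32 = row[cols["id32"]] if "id32" in cols else None
        id32 = None if id32 is None or pd.isna(id32) else int(id32)
        regions.append(Region(
            id16=int(row[id_col]),
            name=str(row[cols.get("name", id_col)]),
            acronym=str(row[cols.get("acronym", id_col)]),
            parent=parent,
            color=str(row[cols["color_hex"]]) if "color_hex" in cols else "#808080",
            id32=id32,
        ))
    return Ontology(regions)


# ---------------------------------------------------------------------------
# ID remapping
# ---------------------------------------------------------------------------

def remap_id32_to_16(id32: int) -> int:
    """16-bit label for a legacy 32-bit id.

    Identity on [0, 65535]; otherwise the last four decimal digits prefixed
    with a 2 (20000 + id32 mod 10000), landing in [20000, 29999].
    """
    id32 = int(id32)
    if id32 < 0:
        raise ValueError(f"id32 must be nonnegative, got {id32}")
    if id32 <= ID16_MAX:
        return id32
    return REMAP_RANGE[0] + id32 % 10000


def build_remap_table(id32s: Sequence[int]) -> dict[int, int]:
    """Remap a set of 32-bit ids, raising on any 16-bit collision."""
    table: dict[int, int] = {}
    owners: dict[int, int] = {}
    for i in id32s:
        m = remap_id32_to_16(i)
        if m in owners and owners[m] != int(i):
            raise CollisionError(
                f"ids {owners[m]} and {int(i)} both map to 16-bit label {m}")
        owners[m] = int(i)
        table[int(i)] = m
    return table


class NewIdAllocator:
    """Hands out ids for newly added structures from the 18000-19999 block."""

    def __init__(self, taken: Iterable[int] = ()):  # existing ids to avoid
        self._taken = set(int(i) for i in taken)
        self._next = NEW_ID_RANGE[0]

    def allocate(self) -> int:
        while self._next in self._taken:
            self._next += 1
        if self._next > NEW_ID_RANGE[1]:
            raise OntologyError("new-structure id block 18000-19999 exhausted")
        out = self._next
        self._next += 1
        return out


# ---------------------------------------------------------------------------
# annotation volumes
# ---------------------------------------------------------------------------

@dataclass
class AnnotationVolume:
    """Integer label volume aligned to a template, with its ontology."""

    labels: ImageVolume
    ontology: Ontology

    def __post_init__(self) -> None:
        if not np.issubdtype(self.labels.data.dtype, np.integer):
            raise ValueError("annotation volume must have an integer dtype")

    @property
    def data(self) -> np.ndarray:
        return self.labels.data

    def region_volumes(self) -> pd.Series:
        ids, counts = np.unique(self.data[self.data != 0], return_counts=True)
        return pd.Series(counts, index=ids, name="voxels")


@dataclass
class ValidationReport:
    """Findings of :func:`validate_annotation`; pass iff all lists empty."""

    unlabeled_in_mask: np.ndarray      # (n, 3) voxel indices labeled 0 inside mask
    unknown_labels: list[int]          # labels absent from the ontology
    labels_outside_mask: list[int]     # labels occurring outside the brain mask

    @property
    def passed(self) -> bool:
        return (len(self.unlabeled_in_mask) == 0 and not self.unknown_labels
                and not self.labels_outside_mask)

    def summary(self) -> str:
        return (f"exhaustiveness violations: {len(self.unlabeled_in_mask)}; "
                f"unknown labels: {self.unknown_labels}; "
                f"labels outside mask: {self.labels_outside_mask}")


def validate_annotation(annot: AnnotationVolume, brain_mask: ImageVolume) -> ValidationReport:
    """Check exhaustiveness, label membership and mask containment."""
    if annot.labels.shape != brain_mask.shape:
        raise ValueError("annotation and mask grids differ")
    lab = annot.data
    mask = brain_mask.data.astype(bool)
    unlabeled = np.argwhere(mask & (lab == 0))
    present = np.unique(lab[lab != 0])
    unknown = sorted(int(i) for i in present if int(i) not in annot.ontology)
    outside = sorted(int(i) for i in np.unique(lab[~mask]) if i != 0)
    return ValidationReport(unlabeled_in_mask=unlabeled,
                            unknown_labels=unknown,
                            labels_outside_mask=outside)


def aggregate_to_level(annot: AnnotationVolume, level: int) -> AnnotationVolume:
    """Replace each voxel's label by its ancestor at the target depth.

    Labels already at or above the target depth are kept; a label whose root
    is shallower than the requested depth is kept as-is.  Total labeled voxel
    count is conserved.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    lut: dict[int, int] = {0: 0}
    for i in np.unique(annot.data):
        i = int(i)
        if i == 0:
            continue
        if i not in annot.ontology:
            lut[i] = i
            continue
        anc = annot.ontology.ancestor_at_level(i, level)
        lut[i] = anc if anc is not None else i
    keys = np.array(sorted(lut))
    vals = np.array([lut[k] for k in keys])
    idx = np.searchsorted(keys, annot.data)
    out = vals[idx].astype(annot.data.dtype)
    return AnnotationVolume(annot.labels.copy(data=out), annot.ontology)


def crosstab_labels(annot_a: AnnotationVolume, annot_b: AnnotationVolume) -> pd.DataFrame:
    """Voxel-count contingency table between two aligned annotations.

    Cell (a, b) counts voxels labeled ``a`` in A and ``b`` in B; marginals
    therefore equal the region volumes exactly.  Use
    :func:`crosstab_to_long` for a Sankey-ready long format (weights are raw
    counts; the figure renderer applies any log scaling).
    """
    if annot_a.labels.shape != annot_b.labels.shape:
        raise ValueError("annotations must share one grid")
    a = annot_a.data.ravel()
    b = annot_b.data.ravel()
    return pd.crosstab(pd.Series(a, name="label_a"), pd.Series(b, name="label_b"))


def crosstab_to_long(table: pd.DataFrame) -> pd.DataFrame:
    long = table.stack().rename("voxels").reset_index()
    return long[long["voxels"] > 0].reset_index(drop=True)
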