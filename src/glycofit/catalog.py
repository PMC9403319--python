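"""Glycan annotations and cross-array-version catalog merging.

A printed array identifies each glycan by a chart number; the catalog
maps that number to a condensed-IUPAC structure string plus two
coarse-grained labels used throughout the graphics:

* ``linkage_class`` — the LacNAc linkage type (Type 1 = Gal(b1-3)GlcNAc,
  Type 2 = Gal(b1-4)GlcNAc), shown as the middle ring of the nested
  affinity charts;
* ``structure_group`` — the terminal-motif family (N-glycan, blood-group
  antigen, sialylated, other) that partitions glycans into the three
  ring charts and the heatmap row blocks.

Different array print versions number the same structures differently;
:func:`merge_catalogs` intersects two versions on structure text and
renumbers the shared glycans into a single merged list, recording the
old→new numbering for both versions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import TextIO

import pandas as pd

__all__ = [
    "LinkageClass",
    "StructureGroup",
    "GlycanAnnotation",
    "GlycanCatalog",
    "RenumberMap",
    "CatalogError",
    "classify_group",
    "infer_linkage",
    "merge_catalogs",
    "read_catalog",
    "write_catalog",
]


class CatalogError(ValueError):
    pass


class LinkageClass(str, Enum):
    TYPE1_LACNAC = "Type1_LacNAc"
    TYPE2_LACNAC = "Type2_LacNAc"
    OTHER = "other"
    UNKNOWN = "unknown"


class StructureGroup(str, Enum):
    N_GLYCAN = "N_glycan"
    BLOOD_GROUP_ANTIGEN = "blood_group_antigen"
    SIALIC_ACID = "sialic_acid"
    OTHER = "other"


#: Fixed display order for group-blocked figures (heatmap rows, rings).
GROUP_ORDER = (
    StructureGroup.N_GLYCAN,
    StructureGroup.BLOOD_GROUP_ANTIGEN,
    StructureGroup.SIALIC_ACID,
    StructureGroup.OTHER,
)


@dataclass(frozen=True)
class GlycanAnnotation:
    chart_number: int
    structure: str
    linkage_class: LinkageClass = LinkageClass.UNKNOWN
    structure_group: StructureGroup | None = None
    terminal_motif: str = ""


@dataclass
class GlycanCatalog:
    version_label: str
    annotations: dict[int, GlycanAnnotation]

    def __post_init__(self) -> None:
        if not self.annotations:
            raise CatalogError("catalog must not be empty")
        for n, ann in self.annotations.items():
            if n != ann.chart_number:
                raise CatalogError(
                    f"catalog key {n} disagrees with chart_number {ann.chart_number}"
                )

    def get(self, chart_number: int | str) -> GlycanAnnotation:
        n = int(chart_number)
        try:
            return self.annotations[n]
        except KeyError:
            raise CatalogError(
                f"glycan {n} is not annotated in catalog {self.version_label!r}"
            ) from None

    def __contains__(self, chart_number: int | str) -> bool:
        return int(chart_number) in self.annotations

    def __len__(self) -> int:
        return len(self.annotations)

    def resolved(self) -> "GlycanCatalog":
        """Return a copy with missing groups/linkages filled by the motif rules."""
        out = {}
        for n, ann in self.annotations.items():
            group = ann.structure_group or classify_group(ann)
            link = (
                ann.linkage_class
                if ann.linkage_class is not LinkageClass.UNKNOWN
                else infer_linkage(ann.structure)
            )
            out[n] = replace(ann, structure_group=group, linkage_class=link)
        return GlycanCatalog(self.version_label, out)


@dataclass
class RenumberMap:
    """(version_label, old chart number) → merged chart number."""

    pairs: dict[tuple[str, int], int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"version": v, "old_number": old, "merged_number": new}
            for (v, old), new in sorted(self.pairs.items())
        ]
        return pd.DataFrame(rows, columns=["version", "old_number", "merged_number"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# motif rules

# Ordered, first match wins.  The precedence sialylated > fucosylated
# blood-group > N-glycan core makes the three figure groups disjoint for
# structures carrying several motifs (e.g. sialyl-Lewis x counts as
# sialic_acid).
_SIALYL = re.compile(r"Neu5(?:Ac|Gc)\(a2-[3689]\)")
_FUCOSYL = re.compile(r"Fuc\(a1-[234]\)")
_NGLYCAN_CORE = re.compile(r"Man\(b1-4\)GlcNAc\(b1-4\)GlcNAc")

_TYPE1 = "Gal(b1-3)GlcNAc"
_TYPE2 = "Gal(b1-4)GlcNAc"


def classify_group(annotation: GlycanAnnotation) -> StructureGroup:
    """Structure group of a glycan; assigned from the structure text when unset.

    Rules, in order of precedence: a sialylated terminal (Neu5Ac/Neu5Gc in
    a2-3/6/8 linkage) → sialic_acid; a fucosylated Lewis/ABH motif
    (Fuc a1-2/3/4) → blood_group_antigen; the chitobiose–mannose N-glycan
    core → N_glycan; anything else → other.  Deterministic and total.
    """
    if annotation.structure_group is not None:
        return annotation.structure_group
    s = " ".join(annotation.structure.split())
    if not s:
        raise CatalogError(
            f"glycan {annotation.chart_number}: structure text is empty"
        )
    if _SIALYL.search(s):
        return StructureGroup.SIALIC_ACID
    if _FUCOSYL.search(s):
        return StructureGroup.BLOOD_GROUP_ANTIGEN
    if _NGLYCAN_CORE.search(s):
        return StructureGroup.N_GLYCAN
    return StructureGroup.OTHER


def infer_linkage(structure: str) -> LinkageClass:
    """LacNAc linkage class from the structure text.

    In condensed IUPAC the non-reducing (terminal) end is written first,
    so when both linkage types occur the earliest occurrence — the one
    closest to the terminal epitope — decides; a tie cannot occur.
    """
    i1 = structure.find(_TYPE1)
    i2 = structure.find(_TYPE2)
    if i1 < 0 and i2 < 0:
        return LinkageClass.OTHER
    if i2 < 0 or (0 <= i1 < i2):
        return LinkageClass.TYPE1_LACNAC
    return LinkageClass.TYPE2_LACNAC


# ---------------------------------------------------------------------------
# merging

def _norm(structure: str) -> str:
    return " ".join(structure.split())


def merge_catalogs(
    a: GlycanCatalog, b: GlycanCatalog
) -> tuple[GlycanCatalog, RenumberMap]:
    """Intersect two catalog versions on structure text and renumber.

    The merged catalog contains exactly the structures present in *both*
    inputs (glycans printed on only one array version are dropped),
    renumbered consecutively from 1 in ascending order of ``a``'s chart
    numbers.  Structure matching is exact text equality after whitespace
    normalisation.

    Raises :class:`CatalogError` if either catalog maps two chart numbers
    to the same structure string (the merge would be ambiguous).
    """
    by_structure: dict[str, dict[str, int]] = {}
    for cat in (a, b):
        seen: dict[str, int] = {}
        for n, ann in cat.annotations.items():
            key = _norm(ann.structure)
            if key in seen:
                raise CatalogError(
                    f"catalog {cat.version_label!r}: duplicate structure "
                    f"{ann.structure!r} at chart numbers {seen[key]} and {n}"
                )
            seen[key] = n
        by_structure[cat.version_label] = seen

    a_map = by_structure[a.version_label]
    b_map = by_structure[b.version_label]
    shared = sorted(set(a_map) & set(b_map), key=lambda s: a_map[s])

    merged_anns: dict[int, GlycanAnnotation] = {}
    pairs: dict[tuple[str, int], int] = {}
    for new, key in enumerate(shared, start=1):
        ann = a.annotations[a_map[key]]
        merged_anns[new] = replace(ann, chart_number=new)
        pairs[(a.version_label, a_map[key])] = new
        pairs[(b.version_label, b_map[key])] = new

    merged = GlycanCatalog(
        version_label=f"{a.version_label}+{b.version_label}",
        annotations=merged_anns,
    )
    return merged, RenumberMap(pairs)


# ---------------------------------------------------------------------------
# CSV interface

_CSV_COLUMNS = ["chart_number", "structure", "linkage_class", "structure_group", "terminal_motif"]


def read_catalog(path: str | Path | TextIO, version_label: str | None = None) -> GlycanCatalog:
    """Read a catalog from a CSV/TSV table.

    Required columns: ``chart_number``, ``structure``.  Optional:
    ``linkage_class``, ``structure_group``, ``terminal_motif`` — when
    absent they stay unset and are filled on demand by the motif rules
    (see :meth:`GlycanCatalog.resolved`).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"chart_number": int})
    for col in ("chart_number", "structure"):
        if col not in df.columns:
            raise CatalogError(f"catalog table is missing required column {col!r}")
    anns: dict[int, GlycanAnnotation] = {}
    for rec in df.to_dict("records"):
        n = int(rec["chart_number"])
        if n in anns:
            raise CatalogError(f"duplicate chart_number {n} in catalog table")
        link = rec.get("linkage_class")
        group = rec.get("structure_group")
        anns[n] = GlycanAnnotation(
            chart_number=n,
            structure=str(rec["structure"]),
            linkage_class=LinkageClass(link) if isinstance(link, str) and link else LinkageClass.UNKNOWN,
            structure_group=StructureGroup(group) if isinstance(group, str) and group else None,
            terminal_motif=str(rec.get("terminal_motif") or ""),
        )
    label = version_label if version_label is not None else Path(str(path)).stem
    return GlycanCatalog(version_label=label, annotations=anns)


def write_catalog(catalog: GlycanCatalog, path: str | Path) -> None:
    rows = [
        {
            "chart_number": n,
            "structure": ann.structure,
            "linkage_class": ann.linkage_class.value,
            "structure_group": ann.structure_group.value if ann.structure_group else "",
            "terminal_motif": ann.terminal_motif,
        }
        for n, ann in sorted(catalog.annotations.items())
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
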