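"""Reading and writing GenePix Results (GPR) files.

GPR is the tab-delimited per-spot quantification table emitted by GenePix
Pro after scanning a microarray slide.  It is an ATF (Axon Text File)
dialect: a two-line magic/size preamble, a block of quoted ``"Key=Value"``
header records (scanner settings, wavelengths, ...), a line of quoted
column names, then one tab-separated row per printed spot.

This module parses that format into :class:`GprFile` /
:class:`SpotRecord`, writes it back losslessly, and assembles a
multi-concentration file set into an :class:`ExperimentManifest` — the
input of a dose-response experiment where each file holds the array
probed at one protein concentration (in µM).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

__all__ = [
    "SpotRecord",
    "GprFile",
    "ManifestEntry",
    "ExperimentManifest",
    "GprError",
    "GprFormatError",
    "GprSchemaError",
    "ManifestError",
    "parse_gpr",
    "write_gpr",
    "build_manifest",
    "spot_rfu",
]


class GprError(ValueError):
    """Base class for GPR parsing/validation failures."""


class GprFormatError(GprError):
    """Malformed ATF structure or unparseable data row."""


class GprSchemaError(GprError):
    """A required column is missing from the data section."""


class ManifestError(GprError):
    """A multi-concentration file set is inconsistent."""


#: Columns every GPR data section must carry, besides one
#: foreground/background statistic pair for the analysis channel.
REQUIRED_COLUMNS = ("Block", "Column", "Row", "Name", "ID", "Flags")

_FG_RE = re.compile(r"^F(\d+) Median$")
_BG_RE = re.compile(r"^B(\d+) Median$")


@dataclass(frozen=True)
class SpotRecord:
    """One printed spot: grid position, glycan identity, intensities.

    ``glycan_id`` is the catalog chart number kept as text (the ID column
    of the GPR file).  ``flag`` follows GenePix QC conventions: 0 means
    good, negative values mark spots excluded by the scanner software.
    """

    block: int
    column: int
    row: int
    name: str
    glycan_id: str
    foreground: float
    background: float
    flag: int = 0

    def __post_init__(self) -> None:
        if self.block < 1 or self.column < 1 or self.row < 1:
            raise GprFormatError(
                f"spot position must be positive, got "
                f"({self.block}, {self.column}, {self.row})"
            )
        for label, v in (("foreground", self.foreground), ("background", self.background)):
            if not (v == v and abs(v) != float("inf")):
                raise GprFormatError(f"{label} intensity is not finite: {v!r}")
            if v < 0:
                raise GprFormatError(f"{label} intensity is negative: {v!r}")


@dataclass
class GprFile:
    """A parsed GPR file: ATF header records plus ordered spot rows."""

    header: dict[str, str]
    spots: list[SpotRecord]
    source_path: str = field(default="", compare=False)
    wavelength: int | None = None
    extra_columns: tuple[str, ...] = field(default=(), compare=False)

    def glycan_ids(self) -> set[str]:
        return {s.glycan_id for s in self.spots}

    def __len__(self) -> int:
        return len(self.spots)


def spot_rfu(spot: SpotRecord, clamp_negative: bool = True) -> float:
    """Background-subtracted signal of one spot, in RFU.

    RFU = foreground median − background median; negative differences
    (background over-estimates) are clamped to 0 by default, since RFU is
    a non-negative binding signal.
    """
    v = spot.foreground - spot.background
    if clamp_negative and v < 0:
        return 0.0
    return v


# ---------------------------------------------------------------------------
# parsing

def _split(line: str) -> list[str]:
    return next(csv.reader([line], delimiter="\t"))


def _resolve_channel(
    columns: Sequence[str],
    header: dict[str, str],
    channel: int | None,
) -> tuple[int, str, str]:
    """Pick the (wavelength, fg column, bg column) triple to quantify."""
    fg = {int(m.group(1)): c for c in columns if (m := _FG_RE.match(c))}
    bg = {int(m.group(1)): c for c in columns if (m := _BG_RE.match(c))}
    pairs = sorted(set(fg) & set(bg))
    if not pairs:
        raise GprSchemaError(
            "missing required column: no 'F<wavelength> Median' / "
            "'B<wavelength> Median' pair found"
        )
    if channel is not None:
        if channel not in pairs:
            raise GprSchemaError(
                f"requested channel {channel} not present; available: {pairs}"
            )
        w = channel
    elif len(pairs) == 1:
        w = pairs[0]
    else:
        # multi-channel scan: take the first wavelength the header declares
        declared = re.findall(r"\d+", header.get("Wavelengths", ""))
        for d in declared:
            if int(d) in pairs:
                w = int(d)
                break
        else:
            raise GprSchemaError(
                f"multiple channels {pairs} present and none selected; "
                "pass channel= explicitly"
            )
    return w, fg[w], bg[w]


def parse_gpr(
    source: TextIO | str | Path,
    *,
    channel: int | None = None,
    foreground_column: str | None = None,
    background_column: str | None = None,
) -> GprFile:
    """Parse a GenePix Results file.

    Parameters
    ----------
    source:
        Open text stream, or a path to the file.
    channel:
        Scan wavelength (nm) whose median statistics provide the
        intensities.  Auto-detected when the file has a single channel or
        when the ATF header declares the wavelength order.
    foreground_column, background_column:
        Override the intensity columns entirely (e.g. to use a
        precomputed RFU column; set ``background_column=None``-like
        behaviour by pointing both at the same column is not supported —
        pass a zero background column instead).

    Raises
    ------
    GprSchemaError
        When a required column is absent (the message names it).
    GprFormatError
        On a malformed header, an empty data section, or a non-numeric
        intensity (the message carries the 1-based line number).
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", newline="") as fh:
            gpr = parse_gpr(
                fh,
                channel=channel,
                foreground_column=foreground_column,
                background_column=background_column,
            )
            gpr.source_path = str(source)
            return gpr

    lines = source.read().splitlines()
    if not lines or not re.match(r"^ATF[\t ]+1\.0\s*$", lines[0]):
        raise GprFormatError("not an ATF file: first line must be 'ATF 1.0'")
    try:
        n_records, _n_cols = (int(t) for t in lines[1].split())
    except (IndexError, ValueError) as e:
        raise GprFormatError("malformed ATF size line (line 2)") from e

    header: dict[str, str] = {}
    for i in range(2, 2 + n_records):
        try:
            rec = _split(lines[i])[0]
        except IndexError as e:
            raise GprFormatError(f"truncated header: expected {n_records} records") from e
        key, _, value = rec.partition("=")
        header[key] = value

    col_line_idx = 2 + n_records
    if col_line_idx >= len(lines):
        raise GprFormatError("missing column-name line")
    columns = _split(lines[col_line_idx])

    for col in REQUIRED_COLUMNS:
        if col not in columns:
            raise GprSchemaError(f"missing required column: {col!r}")

    if foreground_column is not None or background_column is not None:
        if foreground_column is None or background_column is None:
            raise GprSchemaError(
                "foreground_column and background_column must be given together"
            )
        for col in (foreground_column, background_column):
            if col not in columns:
                raise GprSchemaError(f"missing required column: {col!r}")
        wavelength = None
        fg_col, bg_col = foreground_column, background_column
    else:
        wavelength, fg_col, bg_col = _resolve_channel(columns, header, channel)

    idx = {c: i for i, c in enumerate(columns)}
    known = set(REQUIRED_COLUMNS) | {fg_col, bg_col}
    extra = tuple(c for c in columns if c not in known)

    spots: list[SpotRecord] = []
    seen: set[tuple[int, int, int]] = set()
    data_lines = lines[col_line_idx + 1 :]
    reader = csv.reader(data_lines, delimiter="\t")
    for offset, row in enumerate(reader):
        lineno = col_line_idx + 2 + offset  # 1-based line number in the file
        if not row or all(not t.strip() for t in row):
            continue
        if len(row) < len(columns):
            raise GprFormatError(
                f"line {lineno}: expected {len(columns)} fields, got {len(row)}"
            )
        try:
            spot = SpotRecord(
                block=int(row[idx["Block"]]),
                column=int(row[idx["Column"]]),
                row=int(row[idx["Row"]]),
                name=row[idx["Name"]],
                glycan_id=row[idx["ID"]],
                foreground=float(row[idx[fg_col]]),
                background=float(row[idx[bg_col]]),
                flag=int(float(row[idx["Flags"]])),
            )
        except ValueError as e:
            raise GprFormatError(f"line {lineno}: {e}") from e
        pos = (spot.block, spot.column, spot.row)
        if pos in seen:
            raise GprFormatError(f"line {lineno}: duplicate spot position {pos}")
        seen.add(pos)
        spots.append(spot)

    if not spots:
        raise GprFormatError("empty data section: GPR file contains no spots")

    return GprFile(
        header=header,
        spots=spots,
        wavelength=wavelength,
        extra_columns=extra,
    )


# ---------------------------------------------------------------------------
# writing

def _fmt(v: float) -> str:
    # repr() is the shortest string that round-trips the float exactly
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def _quote(s: str) -> str:
    return '"' + s.replace('"', '""') + '"'


def write_gpr(gpr: GprFile, destination: TextIO | str | Path) -> None:
    """Write ``gpr`` in the ATF/GPR dialect that :func:`parse_gpr` reads.

    Numeric fields are rendered with round-trip precision so that
    ``parse_gpr(write_gpr(x)) == x`` field for field.
    """
    if not gpr.spots:
        raise GprFormatError("refusing to write a GPR file with no spots")
    if isinstance(destination, (str, Path)):
        with open(destination, "w", newline="") as fh:
            write_gpr(gpr, fh)
        return

    w = gpr.wavelength if gpr.wavelength is not None else 488
    header = dict(gpr.header)
    header.setdefault("Type", "GenePix Results 3")
    header.setdefault("Wavelengths", str(w))
    columns = list(REQUIRED_COLUMNS[:5]) + [f"F{w} Median", f"B{w} Median", "Flags"]

    out = destination
    out.write("ATF\t1.0\n")
    out.write(f"{len(header)}\t{len(columns)}\n")
    for key, value in header.items():
        out.write(_quote(f"{key}={value}") + "\n")
    out.write("\t".join(_quote(c) for c in columns) + "\n")
    for s in gpr.spots:
        out.write(
            "\t".join(
                (
                    str(s.block),
                    str(s.column),
                    str(s.row),
                    _quote(s.name),
                    _quote(s.glycan_id),
                    _fmt(s.foreground),
                    _fmt(s.background),
                    str(s.flag),
                )
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# manifest

@dataclass
class ManifestEntry:
    concentration: float  # µM
    gpr: GprFile


@dataclass
class ExperimentManifest:
    """One dose-response experiment: GPR files ordered by concentration."""

    entries: list[ManifestEntry]
    protein_name: str = ""

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(e.concentration for e in self.entries)

    def glycan_ids(self) -> set[str]:
        return self.entries[0].gpr.glycan_ids() if self.entries else set()


def build_manifest(
    paths_with_concentrations: Iterable[tuple[str | Path | TextIO, float]],
    protein_name: str = "",
    **parse_kwargs,
) -> ExperimentManifest:
    """Parse a multi-concentration GPR file set into a manifest.

    Entries are sorted by ascending concentration; at least two distinct
    concentrations are required (a single dose cannot support an isotherm
    fit), and every file must cover the same glycan-ID set.
    """
    items = list(paths_with_concentrations)
    if len(items) < 2:
        raise ManifestError(
            "at least 2 concentrations are required: isotherm fits need "
            "RFU values at multiple doses"
        )
    concs = [c for _, c in items]
    if any(c <= 0 for c in concs):
        bad = [c for c in concs if c <= 0]
        raise ManifestError(f"concentrations must be positive µM values, got {bad}")
    if len(set(concs)) != len(concs):
        dupes = sorted({c for c in concs if concs.count(c) > 1})
        raise ManifestError(f"duplicate concentration(s): {dupes}")

    entries = [
        ManifestEntry(concentration=c, gpr=parse_gpr(p, **parse_kwargs))
        for p, c in items
    ]
    entries.sort(key=lambda e: e.concentration)

    ref = entries[0].gpr.glycan_ids()
    for e in entries[1:]:
        ids = e.gpr.glycan_ids()
        if ids != ref:
            diff = sorted(ids ^ ref, key=lambda s: (len(s), s))
            raise ManifestError(
                f"glycan-ID sets differ across files; symmetric difference: {diff}"
            )
    return ExperimentManifest(entries=entries, protein_name=protein_name)
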