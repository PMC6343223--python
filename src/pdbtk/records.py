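"""The PDB record grammar: parse, classify and re-emit 80-column records.

The PDB flat-file format (v3.3) stores one record per line, each at most 80
characters wide, with every field at a fixed column position.  This module is
the single place that knows the column map.  Everything else in the toolkit
operates on the typed records defined here and relies on two guarantees:

* **Losslessness** — for any well-formed line ``x``,
  ``format_record(parse_line(x)) == pad80(x)``.  Raw sub-fields that carry
  no semantics for the tools (atom-name justification, residue-name padding,
  the ANISOU tensor block) are stored verbatim so the round-trip is
  byte-exact.
* **Streaming** — records are plain immutable-ish dataclasses; parsing and
  formatting are per-line, so tools can run as generators holding O(1 residue)
  of state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO, Union

__all__ = [
    "PDBError",
    "ParseError",
    "FormatOverflowError",
    "AtomRecord",
    "AnisouRecord",
    "TerRecord",
    "ModelRecord",
    "OtherRecord",
    "Record",
    "RECORD_NAMES",
    "COORDINATE_TAGS",
    "pad80",
    "pad_atom_name",
    "element_of",
    "parse_line",
    "format_record",
    "is_coordinate",
    "read_records",
    "records_from_text",
    "render",
    "write_records",
]


class PDBError(Exception):
    """Base class for toolkit errors."""


class ParseError(PDBError):
    """A malformed numeric field in a coordinate line.

    Carries the 1-based line number and the 1-based inclusive column span of
    the offending field.
    """

    def __init__(self, message: str, lineno: int, columns: tuple[int, int]):
        super().__init__(f"line {lineno}, cols {columns[0]}-{columns[1]}: {message}")
        self.lineno = lineno
        self.columns = columns


class FormatOverflowError(PDBError):
    """A field value exceeds its fixed-width ceiling (e.g. serial > 99999)."""

    def __init__(self, fieldname: str, value):
        super().__init__(f"{fieldname} value {value!r} exceeds the PDB format ceiling")
        self.fieldname = fieldname
        self.value = value


# The 44 record types of PDB v3.3 (counting the ORIGXn/SCALEn/MTRIXn matrix
# families as one type each, expanded here to their concrete names).
RECORD_NAMES = frozenset({
    "HEADER", "OBSLTE", "TITLE", "SPLIT", "CAVEAT", "COMPND", "SOURCE",
    "KEYWDS", "EXPDTA", "NUMMDL", "MDLTYP", "AUTHOR", "REVDAT", "SPRSDE",
    "JRNL", "REMARK",
    "DBREF", "DBREF1", "DBREF2", "SEQADV", "SEQRES", "MODRES",
    "HET", "HETNAM", "HETSYN", "FORMUL",
    "HELIX", "SHEET", "SSBOND", "LINK", "CISPEP", "SITE",
    "CRYST1",
    "ORIGX1", "ORIGX2", "ORIGX3",
    "SCALE1", "SCALE2", "SCALE3",
    "MTRIX1", "MTRIX2", "MTRIX3",
    "MODEL", "ATOM", "ANISOU", "TER", "HETATM", "ENDMDL",
    "CONECT", "MASTER", "END",
})

COORDINATE_TAGS = frozenset({"ATOM", "HETATM", "TER", "MODEL", "ENDMDL", "END", "ANISOU"})

SERIAL_MAX = 99999
RESSEQ_MAX = 9999
RESSEQ_MIN = -999


def pad80(line: str) -> str:
    """Right-pad a line with spaces to 80 characters (longer lines untouched)."""
    return line if len(line) >= 80 else line.ljust(80)


@dataclass(frozen=True)
class AtomRecord:
    """One parsed ATOM/HETATM line.

    String sub-fields (``name``, ``resname``, ``altloc``, ``icode``,
    ``segid``, ``element``, ``charge``) hold the raw fixed-width slices so
    re-emission is byte-exact; use the ``*_id`` properties for stripped
    comparisons.
    """

    kind: str                     # "ATOM" | "HETATM"
    serial: int                   # cols 7-11
    name: str                     # cols 13-16, raw 4 chars
    altloc: str                   # col 17
    resname: str                  # cols 18-20, raw 3 chars
    chain: str                    # col 22
    resseq: int                   # cols 23-26, may be negative
    icode: str                    # col 27
    x: float                      # cols 31-38, fixed 8.3
    y: float                      # cols 39-46
    z: float                      # cols 47-54
    occupancy: float              # cols 55-60, fixed 6.2
    bfactor: float                # cols 61-66, fixed 6.2
    segid: str = "    "           # cols 73-76
    element: str = "  "           # cols 77-78, raw, right-justified
    charge: str = "  "            # cols 79-80
    lineno: int = 0

    @property
    def atom_name(self) -> str:
        return self.name.strip()

    @property
    def resname_id(self) -> str:
        return self.resname.strip()

    @property
    def element_id(self) -> str:
        return self.element.strip()

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain, resseq, icode) — identifies a residue within one model."""
        return (self.chain, self.resseq, self.icode)


@dataclass(frozen=True)
class AnisouRecord:
    """An ANISOU line: anisotropic B tensor for the preceding atom.

    Only the identification header (cols 1-27) is typed; the tensor block and
    trailing columns (28-80) are carried verbatim in ``tail`` so edits to
    serial/chain/residue numbering can be re-emitted losslessly without
    touching tensor math.
    """

    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    tail: str                     # cols 28-80, exactly 53 chars
    lineno: int = 0

    @property
    def atom_name(self) -> str:
        return self.name.strip()


@dataclass(frozen=True)
class TerRecord:
    """A TER chain terminator; consumes an atom serial when numbered."""

    serial: int | None = None
    resname: str = "   "
    chain: str = " "
    resseq: int | None = None
    icode: str = " "
    lineno: int = 0


@dataclass(frozen=True)
class ModelRecord:
    number: int
    lineno: int = 0


@dataclass(frozen=True)
class OtherRecord:
    """Any non-coordinate record (or END/ENDMDL): tag plus verbatim text."""

    tag: str
    text: str
    lineno: int = 0


Record = Union[AtomRecord, AnisouRecord, TerRecord, ModelRecord, OtherRecord]


def element_of(r: AtomRecord) -> str:
    """Element symbol of an atom, falling back to the atom name.

    Uses cols 77-78 when present.  When blank (legacy files), derives the
    element from the atom name: a name starting in column 13 with two letters
    is a two-letter element (FE, CL, ...); otherwise the first alphabetic
    character of the name is the element.  Hydrogen names like "1HB2" resolve
    to H.
    """
    el = r.element.strip()
    if el:
        return el.upper()
    name = r.name
    # two-letter elements occupy cols 13-14 (both alphabetic)
    if len(name) == 4 and name[0].isalpha() and name[1].isalpha() and r.kind == "HETATM":
        return (name[0] + name[1]).upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def pad_atom_name(name: str, element: str = "") -> str:
    """Justify a stripped atom name into its 4-character field.

    Names whose element code is a single character start at column 14;
    4-character names and names of 2-character elements start at column 13.
    """
    name = name.strip()
    if len(name) >= 4:
        return name[:4]
    element = element.strip()
    if len(element) == 2 or (name and name[0].isdigit()):
        return name.ljust(4)
    return (" " + name).ljust(4)


def _int_field(text: str, lineno: int, cols: tuple[int, int], what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"malformed {what} field {text!r}", lineno, cols) from None


def _float_field(text: str, lineno: int, cols: tuple[int, int], what: str,
                 default: float | None = None) -> float:
    s = text.strip()
    if not s and default is not None:
        return default
    try:
        return float(s)
    except ValueError:
        raise ParseError(f"malformed {what} field {text!r}", lineno, cols) from None


def parse_line(line: str, lineno: int = 0) -> Record:
    """Parse one physical line (no newline) into a typed record.

    Coordinate lines (ATOM/HETATM/ANISOU/TER/MODEL) yield fully typed
    records; everything else is an :class:`OtherRecord` whose text is kept
    byte-for-byte.  Lines shorter than 80 characters are implicitly
    space-padded before slicing.
    """
    line = line.rstrip("\r\n")
    padded = pad80(line)
    tag = padded[0:6].strip()

    if tag in ("ATOM", "HETATM"):
        return AtomRecord(
            kind=tag,
            serial=_int_field(padded[6:11], lineno, (7, 11), "serial"),
            name=padded[12:16],
            altloc=padded[16],
            resname=padded[17:20],
            chain=padded[21],
            resseq=_int_field(padded[22:26], lineno, (23, 26), "residue number"),
            icode=padded[26],
            x=_float_field(padded[30:38], lineno, (31, 38), "x"),
            y=_float_field(padded[38:46], lineno, (39, 46), "y"),
            z=_float_field(padded[46:54], lineno, (47, 54), "z"),
            occupancy=_float_field(padded[54:60], lineno, (55, 60), "occupancy", 1.00),
            bfactor=_float_field(padded[60:66], lineno, (61, 66), "b-factor", 0.00),
            segid=padded[72:76],
            element=padded[76:78],
            charge=padded[78:80],
            lineno=lineno,
        )
    if tag == "ANISOU":
        return AnisouRecord(
            serial=_int_field(padded[6:11], lineno, (7, 11), "serial"),
            name=padded[12:16],
            altloc=padded[16],
            resname=padded[17:20],
            chain=padded[21],
            resseq=_int_field(padded[22:26], lineno, (23, 26), "residue number"),
            icode=padded[26],
            tail=padded[27:80],
            lineno=lineno,
        )
    if tag == "TER":
        serial_s = padded[6:11].strip()
        resseq_s = padded[22:26].strip()
        return TerRecord(
            serial=_int_field(serial_s, lineno, (7, 11), "serial") if serial_s else None,
            resname=padded[17:20],
            chain=padded[21],
            resseq=_int_field(resseq_s, lineno, (23, 26), "residue number") if resseq_s else None,
            icode=padded[26],
            lineno=lineno,
        )
    if tag == "MODEL":
        num_s = padded[10:14].strip() or padded[6:80].strip()
        return ModelRecord(number=_int_field(num_s, lineno, (11, 14), "model number"),
                           lineno=lineno)
    return OtherRecord(tag=tag, text=line, lineno=lineno)


def format_record(r: Record) -> str:
    """Re-emit a record as an exactly-80-character line.

    Inverse of :func:`parse_line` on well-formed input.  Raises
    :class:`FormatOverflowError` when a numeric field exceeds its fixed-width
    ceiling rather than emitting a corrupt line.
    """
    if isinstance(r, AtomRecord):
        _check_ceilings(r.serial, r.resseq)
        return (
            f"{r.kind:<6}{r.serial:5d} {r.name:<4.4}{r.altloc:1.1}{r.resname:>3.3} "
            f"{r.chain:1.1}{r.resseq:4d}{r.icode:1.1}   "
            f"{r.x:8.3f}{r.y:8.3f}{r.z:8.3f}{r.occupancy:6.2f}{r.bfactor:6.2f}"
            f"      {r.segid:<4.4}{r.element:>2.2}{r.charge:<2.2}"
        )
    if isinstance(r, AnisouRecord):
        _check_ceilings(r.serial, r.resseq)
        return (
            f"ANISOU{r.serial:5d} {r.name:<4.4}{r.altloc:1.1}{r.resname:>3.3} "
            f"{r.chain:1.1}{r.resseq:4d}{r.icode:1.1}{r.tail:<53.53}"
        )
    if isinstance(r, TerRecord):
        if r.serial is None:
            return pad80("TER")
        _check_ceilings(r.serial, r.resseq if r.resseq is not None else 0)
        resseq = f"{r.resseq:4d}" if r.resseq is not None else "    "
        return pad80(
            f"TER   {r.serial:5d}      {r.resname:>3.3} {r.chain:1.1}{resseq}{r.icode:1.1}"
        )
    if isinstance(r, ModelRecord):
        return pad80(f"MODEL     {r.number:4d}")
    # OtherRecord: preserve content byte-for-byte, pad to 80 when shorter
    return pad80(r.text)


def _check_ceilings(serial: int, resseq: int) -> None:
    if not 0 <= serial <= SERIAL_MAX:
        raise FormatOverflowError("serial", serial)
    if not RESSEQ_MIN <= resseq <= RESSEQ_MAX:
        raise FormatOverflowError("resseq", resseq)


def is_coordinate(r: Record) -> bool:
    """True iff the record belongs to the coordinate section.

    Coordinate records are ATOM, HETATM, TER, MODEL, ENDMDL, END and ANISOU.
    """
    if isinstance(r, (AtomRecord, AnisouRecord, TerRecord, ModelRecord)):
        return True
    return r.tag in ("END", "ENDMDL")


def read_records(lines: Iterable[str]) -> Iterator[Record]:
    """Lazily parse an iterable of lines (a file object, stdin, a list)."""
    for lineno, line in enumerate(lines, start=1):
        yield parse_line(line, lineno)


def records_from_text(text: str) -> Iterator[Record]:
    return read_records(text.splitlines())


def render(records: Iterable[Record]) -> str:
    """Format a stream back to PDB text (trailing newline included)."""
    out = "".join(format_record(r) + "\n" for r in records)
    return out


def write_records(records: Iterable[Record], fh: TextIO) -> None:
    """Stream records to a file object one line at a time."""
    for r in records:
        fh.write(format_record(r))
        fh.write("\n")
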