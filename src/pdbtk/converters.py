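"""Format conversion: structure → FASTA, PDB → mmCIF, mmCIF → PDB.

The FASTA converter reads the sequence directly off the coordinate records
(one letter per distinct residue), which reflects what was actually modelled
rather than the construct in SEQRES.

The mmCIF converters pivot through a minimal ``atom_site`` loop carrying the
author-assigned identifiers.  PDB → mmCIF never fails; the reverse direction
fails exactly when a value cannot fit the fixed-width PDB columns (chain ids
longer than one character, residue numbers above 9999, serials above 99999)
— the reason very large structures are distributed only in mmCIF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .records import (
    AtomRecord,
    ModelRecord,
    OtherRecord,
    PDBError,
    Record,
    RESSEQ_MAX,
    RESSEQ_MIN,
    SERIAL_MAX,
    pad_atom_name,
)

__all__ = [
    "ConversionError",
    "FastaSeq",
    "CifAtomSiteRow",
    "to_fasta",
    "format_fasta",
    "pdb_to_cif",
    "cif_to_pdb",
    "THREE_TO_ONE",
    "WATER_RESNAMES",
]


class ConversionError(PDBError):
    """A structure cannot be represented in the target format."""


# standard amino acids
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # nucleotides (ribo and deoxy)
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "U",
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U",
    # common modified residues
    "MSE": "M", "SEC": "U", "PYL": "O", "SEP": "S", "TPO": "T",
    "PTR": "Y", "HYP": "P", "MLY": "K", "CSO": "C", "CME": "C",
}

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD"})

ONE_TO_THREE = {v: k for k, v in reversed(list(THREE_TO_ONE.items()))
                if len(k) == 3}


@dataclass(frozen=True)
class FastaSeq:
    """One FASTA record: '>PDB|<chains>' header plus a 60-column sequence."""

    chains: str        # chain id(s) contributing residues, first-appearance order
    sequence: str

    @property
    def header(self) -> str:
        return f">PDB|{self.chains}"


def to_fasta(records: Iterable[Record], multi: bool = False) -> list[FastaSeq]:
    """Extract the modelled sequence from ATOM/HETATM records.

    One letter per distinct residue (waters excluded); unknown residue names
    map to ``X``.  Multi-model structures contribute model 1 only.  With
    ``multi`` each chain becomes its own record; otherwise a single record
    concatenates all chains and lists their ids in the header.
    """
    per_chain: dict[str, list[str]] = {}
    seen: set[tuple[str, int, str]] = set()
    model = None
    first_model = None
    for r in records:
        if isinstance(r, ModelRecord):
            model = r.number
            if first_model is None:
                first_model = model
        elif isinstance(r, AtomRecord):
            if model is not None and first_model is not None and model != first_model:
                continue
            if r.resname_id in WATER_RESNAMES:
                continue
            key = r.residue_key
            if key in seen:
                continue
            seen.add(key)
            letter = THREE_TO_ONE.get(r.resname_id.upper(), "X")
            per_chain.setdefault(r.chain, []).append(letter)
    if not per_chain:
        raise ConversionError("no coordinate records to extract a sequence from")
    if multi:
        return [FastaSeq(chains=c, sequence="".join(s)) for c, s in per_chain.items()]
    chains = "".join(per_chain)
    seq = "".join("".join(s) for s in per_chain.values())
    return [FastaSeq(chains=chains, sequence=seq)]


def format_fasta(seqs: Sequence[FastaSeq], width: int = 60) -> str:
    lines: list[str] = []
    for s in seqs:
        lines.append(s.header)
        lines.extend(s.sequence[i:i + width] for i in range(0, len(s.sequence), width))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# mmCIF
# ---------------------------------------------------------------------------

#: tags of the minimal atom_site loop, in emission order
ATOM_SITE_TAGS = (
    "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
    "label_comp_id", "auth_asym_id", "auth_seq_id", "pdbx_PDB_ins_code",
    "Cartn_x", "Cartn_y", "Cartn_z", "occupancy", "B_iso_or_equiv",
    "pdbx_PDB_model_num",
)


@dataclass(frozen=True)
class CifAtomSiteRow:
    """One row of the mmCIF ``atom_site`` loop; bijective with AtomRecord
    fields within the PDB format ceilings."""

    group_PDB: str
    id: str
    type_symbol: str
    label_atom_id: str
    label_alt_id: str
    label_comp_id: str
    auth_asym_id: str
    auth_seq_id: str
    pdbx_PDB_ins_code: str
    Cartn_x: str
    Cartn_y: str
    Cartn_z: str
    occupancy: str
    B_iso_or_equiv: str
    pdbx_PDB_model_num: str

    def values(self) -> tuple[str, ...]:
        return tuple(getattr(self, t) for t in ATOM_SITE_TAGS)


def _cif_quote(value: str) -> str:
    if value == "":
        return "."
    if any(ch.isspace() for ch in value) or value[0] in "_#$'\"[]" or value in ("loop_",):
        if "'" not in value:
            return f"'{value}'"
        return f'"{value}"'
    return value


def _row_from_atom(r: AtomRecord, model: int) -> CifAtomSiteRow:
    # fixed-point text preserves the PDB precision, keeping round-trips bit-exact
    return CifAtomSiteRow(
        group_PDB=r.kind,
        id=str(r.serial),
        type_symbol=r.element_id or "?",
        label_atom_id=r.atom_name,
        label_alt_id=r.altloc.strip() or ".",
        label_comp_id=r.resname_id,
        auth_asym_id=r.chain.strip() or ".",
        auth_seq_id=str(r.resseq),
        pdbx_PDB_ins_code=r.icode.strip() or ".",
        Cartn_x=f"{r.x:.3f}",
        Cartn_y=f"{r.y:.3f}",
        Cartn_z=f"{r.z:.3f}",
        occupancy=f"{r.occupancy:.2f}",
        B_iso_or_equiv=f"{r.bfactor:.2f}",
        pdbx_PDB_model_num=str(model),
    )


def pdb_to_cif(records: Iterable[Record], block_name: str = "structure") -> str:
    """Emit a minimal mmCIF document with one ``atom_site`` loop.

    One value row per atom, author identifiers only.  This direction never
    overflows: every PDB value fits an mmCIF field.
    """
    model = 1
    rows: list[CifAtomSiteRow] = []
    for r in records:
        if isinstance(r, ModelRecord):
            model = r.number
        elif isinstance(r, AtomRecord):
            rows.append(_row_from_atom(r, model))
    if not rows:
        raise ConversionError("no coordinate records to convert")
    out = [f"data_{block_name}", "#", "loop_"]
    out.extend(f"_atom_site.{tag}" for tag in ATOM_SITE_TAGS)
    for row in rows:
        out.append(" ".join(_cif_quote(v) for v in row.values()))
    out.append("#")
    return "\n".join(out) + "\n"


def _cif_tokens(line: str) -> list[str]:
    """Tokenize one CIF data line (quoted strings, # comments)."""
    tokens: list[str] = []
    i, n = 0, len(line)
    while i < n:
        ch = line[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "#":
            break
        if ch in "'\"":
            j = i + 1
            while j < n:
                # a closing quote must be followed by whitespace or EOL
                if line[j] == ch and (j + 1 == n or line[j + 1].isspace()):
                    break
                j += 1
            if j >= n:
                raise ConversionError(f"unterminated quoted value in CIF line: {line!r}")
            tokens.append(line[i + 1:j])
            i = j + 1
        else:
            j = i
            while j < n and not line[j].isspace():
                j += 1
            tokens.append(line[i:j])
            i = j
    return tokens


def _parse_atom_site_loop(text: str) -> tuple[list[str], list[list[str]]]:
    lines = iter(text.splitlines())
    tags: list[str] = []
    values: list[str] = []
    in_loop = False
    collecting = False
    for line in lines:
        stripped = line.strip()
        if not stripped and not collecting:
            continue
        if collecting:
            if (stripped.startswith("_") or stripped.startswith("loop_")
                    or stripped.startswith("data_") or stripped == "#"
                    or stripped.startswith("stop_")):
                break
            if stripped.startswith(";"):
                raise ConversionError("multi-line (;) values are not supported "
                                      "in atom_site loops")
            values.extend(_cif_tokens(line))
            continue
        if stripped.startswith("loop_"):
            in_loop = True
            tags = []
            continue
        if in_loop and stripped.startswith("_atom_site."):
            tags.append(stripped.split()[0][len("_atom_site."):])
            continue
        if in_loop and tags:
            if stripped.startswith("_") :
                in_loop = False   # some other category's loop
                tags = []
                continue
            collecting = True
            values.extend(_cif_tokens(line))
            continue
        if in_loop and stripped.startswith("_"):
            in_loop = False
    if not tags:
        raise ConversionError("no atom_site loop found in mmCIF input")
    if len(values) % len(tags) != 0:
        raise ConversionError("atom_site loop has a ragged number of values")
    rows = [values[i:i + len(tags)] for i in range(0, len(values), len(tags))]
    return tags, rows


def _get(row: dict[str, str], *names: str, default: str = "") -> str:
    """First present, non-placeholder value among aliased tags."""
    for n in names:
        v = row.get(n)
        if v not in (None, ".", "?"):
            return v
    return default


def cif_to_pdb(text: str) -> Iterator[Record]:
    """Convert an mmCIF ``atom_site`` loop to PDB coordinate records.

    Author identifiers (``auth_*``) are preferred over ``label_*`` when both
    are present.  Values that cannot fit the fixed PDB columns raise
    :class:`ConversionError` naming the offending limit.
    """
    tags, raw_rows = _parse_atom_site_loop(text)
    current_model: int | None = None
    multi_model = len({dict(zip(tags, rr)).get("pdbx_PDB_model_num", "1")
                       for rr in raw_rows}) > 1
    for rr in raw_rows:
        row = dict(zip(tags, rr))
        kind = _get(row, "group_PDB", default="ATOM")
        serial_s = _get(row, "id", default="0")
        try:
            serial = int(serial_s)
        except ValueError:
            raise ConversionError(f"non-integer atom id {serial_s!r}") from None
        if serial > SERIAL_MAX:
            raise ConversionError(
                f"atom id {serial} exceeds the PDB serial ceiling of {SERIAL_MAX} "
                "(too many atoms for the PDB format)")
        chain = _get(row, "auth_asym_id", "label_asym_id", default=" ")
        if len(chain) > 1:
            raise ConversionError(
                f"chain id {chain!r} too long for PDB (single-character column)")
        seq_s = _get(row, "auth_seq_id", "label_seq_id", default="0")
        try:
            resseq = int(seq_s)
        except ValueError:
            raise ConversionError(f"non-integer residue number {seq_s!r}") from None
        if resseq > RESSEQ_MAX or resseq < RESSEQ_MIN:
            raise ConversionError(
                f"residue number {resseq} outside the PDB range "
                f"[{RESSEQ_MIN}, {RESSEQ_MAX}] (too many residues for the PDB format)")
        element = _get(row, "type_symbol")
        name = _get(row, "auth_atom_id", "label_atom_id")
        altloc = _get(row, "label_alt_id", default=" ") or " "
        icode = _get(row, "pdbx_PDB_ins_code", default=" ") or " "
        resname = _get(row, "auth_comp_id", "label_comp_id")
        model_s = _get(row, "pdbx_PDB_model_num", default="1")
        model = int(model_s) if model_s.isdigit() else 1
        if multi_model and model != current_model:
            if current_model is not None:
                yield OtherRecord(tag="ENDMDL", text="ENDMDL")
            yield ModelRecord(number=model)
            current_model = model
        try:
            x = float(_get(row, "Cartn_x", default="0"))
            y = float(_get(row, "Cartn_y", default="0"))
            z = float(_get(row, "Cartn_z", default="0"))
            occupancy = float(_get(row, "occupancy", default="1.00"))
            bfactor = float(_get(row, "B_iso_or_equiv", default="0.00"))
        except ValueError as exc:
            raise ConversionError(f"malformed numeric value in atom_site row: {exc}") from None
        yield AtomRecord(
            kind="HETATM" if kind == "HETATM" else "ATOM",
            serial=serial,
            name=pad_atom_name(name, element),
            altloc=(altloc + " ")[0],
            resname=f"{resname:>3.3}",
            chain=chain if chain.strip() else " ",
            resseq=resseq,
            icode=(icode + " ")[0],
            x=x, y=y, z=z,
            occupancy=occupancy,
            bfactor=bfactor,
            element=f"{element:>2.2}" if element else "  ",
        )
    if multi_model and current_model is not None:
        yield OtherRecord(tag="ENDMDL", text="ENDMDL")
    yield OtherRecord(tag="END", text="END")
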