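"""Deterministic synthetic-PDB generation for offline testing.

:func:`make_structure` builds a well-formed multi-chain (optionally
multi-model) PDB document from a :class:`FixtureSpec` and returns it together
with ground-truth tallies (atom counts per chain/element/name, coordinate
line count, ...), so selector and editor behaviour can be checked against
exact bookkeeping rather than golden files.  The same spec and seed always
produce byte-identical text.

Coordinates sit on a spaced lattice — no physical realism is needed or
attempted — and occupancies are drawn from {1.00, 0.60, 0.40} to exercise
altloc logic with human-checkable values.

:func:`inject_defects` plants format violations of known classes at known
lines and returns the exact issue list the validator must report, giving the
validator an independent ground truth.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable

from .records import (
    AtomRecord,
    OtherRecord,
    ModelRecord,
    TerRecord,
    Record,
    pad_atom_name,
    render,
)
from .validator import ValidationIssue

__all__ = ["FixtureSpec", "make_structure", "inject_defects", "DEFECT_CLASSES"]

AMINO3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# backbone first, then generic side-chain names (element = first letter)
_ATOM_NAMES = ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ", "OG",
               "SD", "CZ", "OH", "NE"]

CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic structure; same spec + seed → same bytes."""

    n_chains: int = 2
    residues_per_chain: int = 5
    atoms_per_residue: int = 4
    altloc_fraction: float = 0.0     # fraction of residues with a split CB/CA
    hetatm_groups: int = 0           # trailing water molecules
    insertion_codes: bool = False    # every 3rd residue repeats its number + icode
    negative_start: bool = False     # chains start at residue -3 instead of 1
    n_models: int = 1
    seed: int = 0


def _lattice(i: int) -> tuple[float, float, float]:
    return (round((i % 30) * 1.500, 3),
            round(((i // 30) % 30) * 1.500, 3),
            round((i // 900) * 1.500, 3))


def make_structure(spec: FixtureSpec) -> tuple[str, dict]:
    """Generate PDB text plus exact ground-truth tallies.

    Raises ``ValueError`` when the requested size exceeds the format ceilings
    (serial > 99999 or residue number > 9999).
    """
    if spec.n_chains < 1 or spec.residues_per_chain < 1 or spec.atoms_per_residue < 1:
        raise ValueError("spec sizes must be positive")
    if spec.n_chains > len(CHAIN_IDS):
        raise ValueError("too many chains for single-character identifiers")
    if spec.atoms_per_residue > len(_ATOM_NAMES):
        raise ValueError(f"at most {len(_ATOM_NAMES)} atoms per residue supported")
    start = -3 if spec.negative_start else 1
    if start + spec.residues_per_chain - 1 > 9999:
        raise ValueError("residue numbers would exceed the PDB ceiling of 9999")

    rng = random.Random(spec.seed)
    records: list[Record] = [
        OtherRecord(tag="HEADER", text="HEADER    SYNTHETIC STRUCTURE"),
        OtherRecord(tag="REMARK", text=f"REMARK 999 FIXTURE SEED {spec.seed}"),
    ]
    tallies: dict = {
        "n_atom": 0, "n_hetatm": 0, "n_ter": 0, "n_altloc_extra": 0,
        "per_chain": {}, "per_element": {}, "per_name": {},
        "n_residues": {}, "coordinate_lines": 0,
    }

    serial = 0
    atom_counter = 0

    def atom(kind: str, name: str, resname: str, chain: str, resseq: int,
             icode: str, altloc: str = " ", occ: float = 1.00) -> AtomRecord:
        nonlocal serial, atom_counter
        serial += 1
        if serial > 99999:
            raise ValueError("atom serials would exceed the PDB ceiling of 99999")
        atom_counter += 1
        x, y, z = _lattice(atom_counter)
        element = name[0]
        tallies["n_atom" if kind == "ATOM" else "n_hetatm"] += 1
        tallies["per_chain"][chain] = tallies["per_chain"].get(chain, 0) + 1
        tallies["per_element"][element] = tallies["per_element"].get(element, 0) + 1
        tallies["per_name"][name] = tallies["per_name"].get(name, 0) + 1
        return AtomRecord(
            kind=kind, serial=serial, name=pad_atom_name(name, element),
            altloc=altloc, resname=f"{resname:>3}", chain=chain, resseq=resseq,
            icode=icode, x=x, y=y, z=z, occupancy=occ,
            bfactor=round(10.0 + (atom_counter % 50) * 0.25, 2),
            element=f"{element:>2}",
        )

    for m in range(1, spec.n_models + 1):
        if spec.n_models > 1:
            records.append(ModelRecord(number=m))
            serial = 0
        for ci in range(spec.n_chains):
            chain = CHAIN_IDS[ci]
            resseq = start - 1
            icode_next = " "
            n_res = 0
            for ri in range(spec.residues_per_chain):
                if spec.insertion_codes and ri % 3 == 2 and ri > 0:
                    icode = "A"          # repeat previous number with an icode
                else:
                    resseq += 1
                    icode = " "
                resname = AMINO3[rng.randrange(len(AMINO3))]
                split = rng.random() < spec.altloc_fraction
                for ai in range(spec.atoms_per_residue):
                    name = _ATOM_NAMES[ai]
                    if split and name == "CA":
                        records.append(atom("ATOM", name, resname, chain,
                                            resseq, icode, "A", 0.60))
                        records.append(atom("ATOM", name, resname, chain,
                                            resseq, icode, "B", 0.40))
                        tallies["n_altloc_extra"] += 1
                    else:
                        records.append(atom("ATOM", name, resname, chain,
                                            resseq, icode))
                n_res += 1
                if m == 1:
                    tallies["n_residues"][chain] = tallies["n_residues"].get(chain, 0) + 1
            serial += 1   # TER consumes a serial
            records.append(TerRecord(serial=serial, resname=records[-1].resname,
                                     chain=chain, resseq=resseq,
                                     icode=" "))
            tallies["n_ter"] += 1
        # trailing waters on their own chain, one O atom each
        if spec.hetatm_groups:
            wchain = CHAIN_IDS[spec.n_chains]
            for wi in range(spec.hetatm_groups):
                records.append(atom("HETATM", "O", "HOH", wchain, wi + 1, " "))
        if spec.n_models > 1:
            records.append(OtherRecord(tag="ENDMDL", text="ENDMDL"))
    records.append(OtherRecord(tag="END", text="END"))

    tallies["coordinate_lines"] = (
        tallies["n_atom"] + tallies["n_hetatm"] + tallies["n_ter"]
        + (2 * spec.n_models if spec.n_models > 1 else 0) + 1   # MODEL/ENDMDL + END
    )
    return render(records), tallies


# ---------------------------------------------------------------------------
# defect injection
# ---------------------------------------------------------------------------

DEFECT_CLASSES = (
    "LINE_TOO_LONG", "UNKNOWN_RECORD", "BAD_FIELD", "SERIAL_ORDER",
    "DUP_ATOM", "MISSING_END", "NON_ASCII", "DANGLING_TER", "MODEL_PAIRING",
    "END_PLACEMENT",
)


def inject_defects(text: str, defects: Iterable[str], seed: int = 0,
                   ) -> tuple[str, list[ValidationIssue]]:
    """Plant format violations of the named classes into well-formed text.

    Returns the mutated text and the exact error-issue list the validator is
    expected to produce (computed from the injection sites, independently of
    the validator).  Injections are designed not to cascade into other rules.
    Unknown defect classes raise ``ValueError``.
    """
    rng = random.Random(seed)
    lines = text.splitlines()
    expected: list[tuple[int, str]] = []   # 0-based index, rule

    def atom_indices() -> list[int]:
        return [i for i, ln in enumerate(lines) if ln.startswith("ATOM  ")]

    if not atom_indices():
        raise ValueError("need at least one ATOM line to inject defects into")

    def shift_from(pos: int, by: int = 1) -> None:
        nonlocal expected
        expected = [(i + by if i >= pos else i, rule) for i, rule in expected]

    def bump_serials_after(pos: int) -> None:
        for j in range(pos, len(lines)):
            ln = lines[j]
            if ln.startswith(("ATOM  ", "HETATM")) or (ln.startswith("TER")
                                                       and ln[6:11].strip()):
                lines[j] = ln[:6] + f"{int(ln[6:11]) + 1:5d}" + ln[11:]

    for defect in defects:
        idxs = atom_indices()
        if defect == "LINE_TOO_LONG":
            i = rng.choice(idxs)
            lines[i] = lines[i].ljust(85) + "XXXXX"
            expected.append((i, "LINE_TOO_LONG"))
        elif defect == "UNKNOWN_RECORD":
            i = idxs[0]
            shift_from(i)
            lines.insert(i, "XYZZYX    not a standard record")
            expected.append((i, "UNKNOWN_RECORD"))
        elif defect == "BAD_FIELD":
            i = rng.choice(idxs)
            lines[i] = lines[i][:30] + "abc.def " + lines[i][38:]
            expected.append((i, "BAD_FIELD"))
        elif defect == "SERIAL_ORDER":
            # give an ATOM line the serial of the ATOM directly above it
            consecutive = [i for i in idxs if i - 1 in set(idxs)]
            if not consecutive:
                raise ValueError("need two consecutive ATOM lines for SERIAL_ORDER")
            i = rng.choice(consecutive)
            lines[i] = lines[i][:6] + lines[i - 1][6:11] + lines[i][11:]
            expected.append((i, "SERIAL_ORDER"))
        elif defect == "DUP_ATOM":
            # duplicate the last ATOM right after itself with the next serial;
            # every later serial is bumped so ordering stays strictly increasing
            i = idxs[-1]
            serial = int(lines[i][6:11])
            dup = lines[i][:6] + f"{serial + 1:5d}" + lines[i][11:]
            shift_from(i + 1)
            bump_serials_after(i + 1)
            lines.insert(i + 1, dup)
            expected.append((i + 1, "DUP_ATOM"))
        elif defect == "MISSING_END":
            kept = [ln for ln in lines if ln.rstrip() != "END"]
            if len(kept) != len(lines):
                lines = kept
            expected.append((len(lines) - 1, "MISSING_END"))
        elif defect == "NON_ASCII":
            i = idxs[0] - 1 if idxs[0] > 0 else len(lines) - 1
            lines[i] = lines[i].rstrip() + " é"
            expected.append((i, "NON_ASCII"))
        elif defect == "DANGLING_TER":
            shift_from(0)
            lines.insert(0, "TER")
            expected.append((0, "DANGLING_TER"))
        elif defect == "MODEL_PAIRING":
            end_at = next((j for j, ln in enumerate(lines) if ln.rstrip() == "END"),
                          len(lines))
            shift_from(end_at)
            lines.insert(end_at, "ENDMDL")
            expected.append((end_at, "MODEL_PAIRING"))
        elif defect == "END_PLACEMENT":
            lines.append("REMARK 999 TRAILING RECORD AFTER END")
            expected.append((len(lines) - 1, "END_PLACEMENT"))
        else:
            raise ValueError(f"unknown defect class {defect!r}")

    issues = [ValidationIssue(i + 1, rule, "error", "") for i, rule in expected]
    issues.sort(key=lambda v: (v.lineno, v.rule))
    return "\n".join(lines) + "\n", issues
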