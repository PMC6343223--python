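"""Synthetic stand-ins for the worked-example PDB entries 1CTF and 1BRS.

These builders produce *synthetic* structures for offline demonstration and
testing: they reproduce the published features the worked examples depend on
— chain layout, residue identities, atom ordering, and the handful of
published coordinate values — while every other coordinate is a placeholder
on a lattice.  They are NOT the deposited structures; anything beyond the
documented anchor values is invented.

``synthetic_1ctf``:  a single-chain protein fragment in original (non-1-based)
residue numbering.  The first two residues carry the full glutamate and
phenylalanine atom complements so that, after renumbering from 1, the
C-alpha records match the published values: CA of GLU A 1 at serial 2,
(17.706, 17.982, -14.905), B = 16.74; CA of PHE A 2 at serial 11,
(17.509, 14.262, -14.184), B = 13.24.

``synthetic_1brs``:  a six-chain barnase–barstar-like complex (chains A–F,
C-alpha trace) whose chain-A and chain-B sequences are the published
ATOM-record sequences of barnase in that entry; chains C–F carry plausible
synthetic sequences.  Includes altloc pairs and trailing waters so the
HADDOCK-style preparation pipeline has something to clean up.
"""

from __future__ import annotations

from .converters import ONE_TO_THREE
from .records import AtomRecord, OtherRecord, Record, TerRecord, pad_atom_name, render

__all__ = ["synthetic_1ctf", "synthetic_1brs"]

# published anchors: (atom names of residue, CA coordinates, CA b-factor)
_GLU_ATOMS = ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"]
_PHE_ATOMS = ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
_CA_ANCHORS = {
    1: (17.706, 17.982, -14.905, 16.74),
    2: (17.509, 14.262, -14.184, 13.24),
}

# chain-A/B sequences as published in the entry's ATOM-record FASTA output;
# chains C-F are synthetic stand-in sequences of realistic length
_BARNASE_A = ("VINTFDGVADYLQTYHKLPDNYITKSEAQALGWVASKGNLADVAPGKSIGGDIFSNREGK"
              "LPGKSGRTWREADINYTSGFRNSDRILYSSDWLIYKTTDHYQTFTKIR")
_BARNASE_B = ("AQVINTFDGVADYLQTYHKLPDNYITKSEAQALGWVASKGNLADVAPGKSIGGDIFSNRE"
              "GKLPGKSGRTWREADINYTSGFRNSDRILYSSDWLIYKTTDHYQTFTKIR")
_BARSTAR = ("KKAVINGEQIRSISDLHQTLKKELALPEYYGENLDALWDALTGWVEYPLVLEWRQFEQSK"
            "QLTENGAESVLQVFREAKAEGADITIILS")
_1BRS_CHAINS = {
    "A": _BARNASE_A,
    "B": _BARNASE_B,
    "C": _BARNASE_A,
    "D": _BARSTAR,
    "E": _BARSTAR,
    "F": _BARSTAR,
}

_FILLER_SEQ = "ADEFGHIKLMNPQRSTVWY"   # cycled for synthetic residues


def _placeholder(i: int) -> tuple[float, float, float]:
    return (round((i % 25) * 1.700, 3),
            round(((i // 25) % 25) * 1.700, 3),
            round((i // 625) * 1.700, 3))


def _atom(serial: int, name: str, resname: str, chain: str, resseq: int,
          x: float, y: float, z: float, b: float, occ: float = 1.00,
          altloc: str = " ") -> AtomRecord:
    element = name[0]
    return AtomRecord(kind="ATOM", serial=serial, name=pad_atom_name(name, element),
                      altloc=altloc, resname=f"{resname:>3}", chain=chain,
                      resseq=resseq, icode=" ", x=x, y=y, z=z,
                      occupancy=occ, bfactor=b, element=f"{element:>2}")


def _water(serial: int, chain: str, resseq: int, i: int) -> AtomRecord:
    x, y, z = _placeholder(i)
    return AtomRecord(kind="HETATM", serial=serial, name=pad_atom_name("O", "O"),
                      altloc=" ", resname=f"{'HOH':>3}", chain=chain, resseq=resseq,
                      icode=" ", x=x, y=y, z=z, occupancy=1.00, bfactor=30.00,
                      element=" O")


def synthetic_1ctf(n_residues: int = 68, start_resseq: int = 47) -> str:
    """Synthetic single-chain stand-in for entry 1CTF (see module docstring)."""
    records: list[Record] = [
        OtherRecord(tag="HEADER", text="HEADER    RIBOSOMAL PROTEIN (SYNTHETIC STAND-IN)"),
        OtherRecord(tag="TITLE", text="TITLE     SYNTHETIC STAND-IN FOR PDB ENTRY 1CTF"),
        OtherRecord(tag="REMARK", text="REMARK 999 COORDINATES ARE PLACEHOLDERS EXCEPT "
                                       "PUBLISHED CA ANCHORS"),
    ]
    serial = 0
    counter = 0
    resseq = start_resseq - 1
    for ri in range(1, n_residues + 1):
        resseq += 1
        if ri == 1:
            resname, names = "GLU", _GLU_ATOMS
        elif ri == 2:
            resname, names = "PHE", _PHE_ATOMS
        else:
            resname = ONE_TO_THREE[_FILLER_SEQ[ri % len(_FILLER_SEQ)]]
            names = ["N", "CA", "C", "O"]
        for name in names:
            serial += 1
            counter += 1
            if name == "CA" and ri in _CA_ANCHORS:
                x, y, z, b = _CA_ANCHORS[ri]
            else:
                x, y, z = _placeholder(counter)
                b = round(15.0 + (counter % 40) * 0.5, 2)
            records.append(_atom(serial, name, resname, "A", resseq, x, y, z, b))
    serial += 1
    records.append(TerRecord(serial=serial, resname=records[-1].resname,
                             chain="A", resseq=resseq, icode=" "))
    for wi in range(1, 6):
        serial += 1
        counter += 1
        records.append(_water(serial, "A", resseq + wi, counter))
    records.append(OtherRecord(tag="MASTER", text="MASTER"))
    records.append(OtherRecord(tag="END", text="END"))
    return render(records)


def synthetic_1brs(waters_per_chain: int = 3) -> str:
    """Synthetic six-chain stand-in for entry 1BRS (see module docstring)."""
    records: list[Record] = [
        OtherRecord(tag="HEADER", text="HEADER    COMPLEX (SYNTHETIC STAND-IN)"),
        OtherRecord(tag="TITLE", text="TITLE     SYNTHETIC STAND-IN FOR PDB ENTRY 1BRS"),
        OtherRecord(tag="REMARK", text="REMARK 999 CA TRACE WITH PUBLISHED CHAIN "
                                       "LAYOUT AND A/B SEQUENCES"),
    ]
    serial = 0
    counter = 0
    for chain, seq in _1BRS_CHAINS.items():
        resseq = 0
        for ri, letter in enumerate(seq, start=1):
            resseq = ri
            resname = ONE_TO_THREE[letter]
            serial += 1
            counter += 1
            x, y, z = _placeholder(counter)
            b = round(20.0 + (counter % 30) * 0.5, 2)
            if chain in ("A", "D") and ri == 5:
                # an altloc pair to exercise occupancy-based selection
                records.append(_atom(serial, "CA", resname, chain, resseq,
                                     x, y, z, b, occ=0.60, altloc="A"))
                serial += 1
                records.append(_atom(serial, "CA", resname, chain, resseq,
                                     round(x + 0.300, 3), y, z, b,
                                     occ=0.40, altloc="B"))
            else:
                records.append(_atom(serial, "CA", resname, chain, resseq, x, y, z, b))
        serial += 1
        records.append(TerRecord(serial=serial, resname=records[-1].resname,
                                 chain=chain, resseq=resseq, icode=" "))
    for chain in _1BRS_CHAINS:
        for wi in range(1, waters_per_chain + 1):
            serial += 1
            counter += 1
            records.append(_water(serial, chain, 200 + wi, counter))
    records.append(OtherRecord(tag="MASTER", text="MASTER"))
    records.append(OtherRecord(tag="END", text="END"))
    return render(records)
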