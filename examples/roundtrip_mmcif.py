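"""Round-trip a structure through mmCIF and show where conversion back fails.

PDB -> mmCIF always succeeds; the reverse fails exactly when a value cannot
fit the fixed PDB columns (the reason very large structures are
mmCIF-only).
"""

from pdbtk import AtomRecord, cif_to_pdb, pdb_to_cif, records_from_text
from pdbtk.converters import ConversionError
from pdbtk.fixtures import FixtureSpec, make_structure
from pdbtk.records import format_record

text, _ = make_structure(FixtureSpec(n_chains=2, residues_per_chain=10,
                                     atoms_per_residue=5, seed=8))
cif = pdb_to_cif(records_from_text(text))
back = [r for r in cif_to_pdb(cif) if isinstance(r, AtomRecord)]
orig = [r for r in records_from_text(text) if isinstance(r, AtomRecord)]
identical = sum(1 for a, b in zip(orig, back)
                if format_record(a) == format_record(b))
print(f"atoms through mmCIF and back : {len(back)}")
print(f"bit-identical records        : {identical}/{len(orig)}")

two_char_chain = cif.replace(" A ", " AB ")
try:
    list(cif_to_pdb(two_char_chain))
except ConversionError as exc:
    print(f"expected failure             : {exc}")
# every record survives the round trip unchanged; a two-character chain id
# is refused because the PDB chain column holds a single character.
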