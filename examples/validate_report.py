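"""Break a well-formed file on purpose and read the validator's report.

The defect injector plants one violation per rule class at a known line;
the validator reports each as lineno:severity:rule:message.
"""

from pdbtk import inject_defects, validate_text
from pdbtk.fixtures import FixtureSpec, make_structure

text, _ = make_structure(FixtureSpec(n_chains=2, residues_per_chain=6,
                                     atoms_per_residue=4, seed=12))
print(f"pristine file : {len(validate_text(text))} issues")

broken, expected = inject_defects(text, ["LINE_TOO_LONG", "DUP_ATOM"], seed=1)
for issue in validate_text(broken):
    print(issue)
# each planted defect is reported at the exact line it was injected;
# a clean file produces an empty report and pdb_validate exits 0.
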