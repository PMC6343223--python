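"""Read the modelled sequence straight off the coordinate records.

Unlike SEQRES, which lists the expression construct, the ATOM records show
what was actually resolved — the sequence a homology-modelling alignment
should use.
"""

from pdbtk import format_fasta, records_from_text, to_fasta
from pdbtk.refdata import synthetic_1brs

text = synthetic_1brs()
per_chain = to_fasta(records_from_text(text), multi=True)
for seq in per_chain:
    print(f"chain {seq.chains}: {len(seq.sequence)} residues")
print()
print(format_fasta(per_chain[:1]), end="")
# chain A of the barnase-barstar stand-in has 108 modelled residues; the
# FASTA block wraps at 60 columns with a '>PDB|A' header.
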