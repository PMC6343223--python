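# Methods

## The record model

The toolkit treats a PDB document as an ordered stream of typed records.
Coordinate-section lines (ATOM, HETATM, ANISOU, TER, MODEL, ENDMDL, END) are
parsed into dataclasses with typed numeric fields; every other record is kept
as a `(tag, verbatim text)` pair, since editing tools must never destroy
header content they do not understand. Unknown record names pass through
untouched by every tool and are reported only by the validator.

Losslessness is the central contract: `format(parse(x)) == pad80(x)` for any
well-formed line. Two design choices make it cheap to honour. First, string
sub-fields with layout freedom — the 4-character atom-name field, the
residue-name field, the ANISOU tensor block (columns 28–80) — are stored as
raw fixed-width slices and re-emitted verbatim. Second, numeric fields are
fixed-point by definition (8.3 for coordinates, 6.2 for occupancy and
B-factor), so float round-tripping is exact at the format's own precision.
When records are *built* rather than parsed (mmCIF import, the generator),
atom names follow the element-dependent justification convention: names of
single-character elements start at column 14; four-character names,
digit-led hydrogen names and two-character elements start at column 13.

Every operation is a Python generator over records. Per-record tools hold
O(1) state; `pdb_selaltloc` buffers one residue; three operations buffer by
necessity and are documented as such: `pdb_sort` and `pdb_merge` (whole
stream) and `pdb_tidy` (one MODEL block, needed to find the final polymer
residue of each chain before placing TER).

Limits are enforced, not worked around: serials above 99 999 or residue
numbers outside [−999, 9999] raise overflow errors rather than emitting
hybrid-36 or corrupt columns. This mirrors the mmCIF converters' stated
failure mode for oversized structures.

## Interpretations where the behaviour was open

* **ANISOU lines track their parent atom.** Any filter that drops an atom
  drops the tensor line that follows it; renumbering and altloc blanking
  apply the parent's edit. Nothing else about ANISOU is interpreted.
* **`pdb_selaltloc` without an argument keeps the highest-occupancy
  alternate** (ties: first in file order), blanking the survivor's altloc
  flag; an explicitly requested altloc that is absent for a conflicted atom
  group drops the group with a warning. Occupancy-based selection is the
  motivating use case for the tool, hence the default.
* **`pdb_reres` numbers residues in order of first appearance** within each
  chain (per model), not numeric order, and clears insertion codes: the new
  numbering is gap-free, so icodes would carry no information. Compose with
  `pdb_sort` first when numeric order is wanted.
* **TER placement** (`pdb_tidy`): one TER after the final ATOM-bearing
  residue of each chain per model; pure-HETATM chains (e.g. a water chain)
  get none. Serials are renumbered continuously across the document, TER
  consuming a serial.
* **`pdb_selres` filters HETATM as well as ATOM** — it is a residue filter,
  not a polymer filter — and leaves any orphaned TER for `pdb_tidy` to
  repair.
* **Single-record FASTA** concatenates chains with no separator, and the
  header lists every contributing chain id in first-appearance order.
  Waters (HOH/WAT/DOD) never contribute a letter; common modified residues
  (MSE, SEP, PTR, ...) map to their parent letter; anything else maps to X.
  Multi-model structures contribute model 1 only.

## Validation rules

The format names validation as a task without fixing a rule set; the set
here is: line length ≤ 80, ASCII only, record name in the standard
vocabulary, numeric fields parseable at their columns, serials strictly
increasing within a model, no duplicate (residue, atom name, altloc), TER
only after coordinate records, exactly one terminal END, MODEL/ENDMDL
paired. Those are errors. A blank element field and a chain resuming after
other chains are warnings — files with those quirks interoperate fine.
`pdb_validate` exits 0 when there are no errors (warnings allowed).
Blank occupancy/B-factor columns parse as 1.00/0.00 for the same
interoperability reason; only non-blank garbage is a field error.

## mmCIF conversion

The converters pivot through a minimal `atom_site` loop restricted to the
author-assigned identifiers (`auth_asym_id`, `auth_seq_id`, insertion code,
altloc, occupancy, B, model number). Reading prefers `auth_*` over
`label_*` when both appear. Numeric text preserves the PDB fixed-point
precision (3 decimals for coordinates, 2 for occupancy/B), which is what
makes PDB → mmCIF → PDB bit-exact. The reader is a deliberately small loop
tokenizer (quoted values, comments, multi-row lines); multi-line `;` values
do not occur in `atom_site` loops and are rejected rather than guessed at.
Conversion to PDB fails precisely at the format ceilings: chain ids longer
than one character, residue numbers above 9999, serials above 99 999.
Independent cross-checks in the test suite re-read the emitted mmCIF with
gemmi and compare parsed fixtures against biopython.

## Synthetic data

`pdbtk.fixtures.make_structure` generates deterministic structures
(same spec + seed → identical bytes) with configurable chain/residue/atom
counts, altloc pairs at occupancies 0.60/0.40, insertion codes, negative
residue numbers, trailing waters on their own chain, and multiple models.
Coordinates sit on a 1.5 Å lattice and occupancies come from
{1.00, 0.60, 0.40}: the generator emulates the *bookkeeping* structure of
real files (the part these tools operate on), not geometry, chemistry or
sequence plausibility — passing tests say nothing about stereochemistry and
everything about record handling. Ground-truth tallies (atoms per chain,
element, name) are returned alongside the text so tests assert against exact
bookkeeping instead of golden files. `inject_defects` plants one violation
per named rule at a known line — engineered not to cascade into other rules
— giving the validator an independent oracle.

The worked-example inputs (`pdbtk.refdata`) are *synthetic stand-ins* for
entries 1CTF and 1BRS: they embed the published anchor values these examples
are known by (the first two C-alpha records of renumbered 1CTF; the
six-chain layout and chain-A/B sequences of 1BRS) while all other
coordinates are lattice placeholders. They exercise the pipelines offline;
they are not the deposited structures.

## Problem sizes

The default suite generates structures up to ~10⁴ coordinate lines for the
round-trip and conservation laws, an eight-copy merge (~85 000 atoms), and
one 64 606-atom structure to confirm large renumberings complete. These
sizes keep the full suite under half a minute on one core while covering
every format ceiling the tools enforce.

## Known limitations

* No hybrid-36 or extended serial dialects; structures beyond the PDB
  ceilings must stay in mmCIF.
* SEQRES, CONECT and other non-coordinate records are preserved but their
  internals are not parsed; FASTA extraction is coordinate-based by design.
* `pdb_sort` orders chains lexicographically; it does not reproduce an
  arbitrary original chain order.
* The mmCIF writer emits only the `atom_site` category; entity, assembly
  and chemical-component categories are out of scope.
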