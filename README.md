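# pdbtk

Composable command-line tools — and the record-level Python library behind
them — for working with macromolecular structures in the legacy PDB flat-file
format: downloading, filtering, editing, merging, sorting, validating, and
converting to and from PDBx/mmCIF and FASTA.

## Who this is for

Structural biologists and modellers who need quick, scriptable edits to
coordinate files — select chains or residue ranges, strip heteroatoms,
resolve alternate locations, renumber residues, merge structures, tidy up
TER/END bookkeeping — without opening a molecular viewer or writing a parser.
Every tool follows one convention:

```
tool [-option] [file.pdb] < stdin > stdout
```

so tools chain through UNIX pipes with no intermediary files. Data goes to
stdout, diagnostics to stderr; exit codes are 0 (success or help), 1 (usage
error), 2 (invalid input data).

## The format, in brief

A PDB file is a sequence of 80-column records, 44 record types, each field at
a fixed column position. A coordinate record (ATOM/HETATM) carries, among
others: serial (cols 7–11), atom name (13–16), altloc (17), residue name
(18–20), chain (22), residue number (23–26, possibly negative), insertion
code (27), x/y/z in Å as fixed 8.3 (31–54), occupancy and B-factor as fixed
6.2 (55–66), and the element symbol (77–78). The core guarantee of the
library is *losslessness*: for every well-formed line `x`,
`format(parse(x)) == pad80(x)` byte for byte. Serial numbers are capped at
99 999 and residue numbers at 9999 by the format itself — which is exactly
where the mmCIF converters report that a structure cannot be expressed as PDB.

## The tool catalogue

| task      | tools |
|-----------|-------|
| download  | `pdb_fetch` |
| filter    | `pdb_keepcoord`, `pdb_selchain`, `pdb_selres`, `pdb_selatom`, `pdb_selaltloc`, `pdb_delhetatm`, `pdb_delelement` |
| edit      | `pdb_reres`, `pdb_reatom`, `pdb_chain` |
| assemble  | `pdb_merge`, `pdb_sort`, `pdb_tidy` |
| convert   | `pdb_tofasta`, `pdb_tocif`, `pdb_fromcif` |
| validate  | `pdb_validate` |
| develop   | `pdb_mkfixture` (deterministic synthetic test structures) |

Run any tool without arguments for its help text. The same operations are
importable from Python (`pdbtk.select_chains`, `pdbtk.tidy`, ...) as
generator-based filters over typed records; see `examples/`.

## Worked example

Extract a C-alpha trace of the first 30 residues of ribosomal protein domain
1CTF, renumbered from 1 (with no network, point `PDBTK_FETCH_URL` at any
`file://{id}.pdb` template; the test data ships a synthetic stand-in):

```
$ pdb_fetch 1ctf | pdb_keepcoord | pdb_reres > 1ctf.pdb
$ pdb_selres -1:30 1ctf.pdb | pdb_selatom -CA | head -2
ATOM      2  CA  GLU A   1      17.706  17.982 -14.905  1.00 16.74           C
ATOM     11  CA  PHE A   2      17.509  14.262 -14.184  1.00 13.24           C
```

Each line is one alpha-carbon: serial 2 is the second atom of the file (the
glutamate's backbone N is serial 1), residue GLU A 1 after renumbering, at
(17.706, 17.982, −14.905) Å with full occupancy and a B-factor of 16.74 Å².

Preparing a two-chain docking input from the barnase–barstar complex 1BRS
(six chains: three barnase, three barstar) and reading off its sequence:

```
$ pdb_fetch 1brs | pdb_keepcoord > 1brs.pdb        # 6 chains
$ pdb_selchain -A,D 1brs.pdb | pdb_delhetatm | pdb_selaltloc | pdb_tidy > 1brs_AD.pdb
$ pdb_validate < 1brs_AD.pdb ; echo $?
pdb_validate: 0 error(s), 0 warning(s)
0
$ pdb_tofasta -multi 1brs.pdb | head -2
>PDB|A
VINTFDGVADYLQTYHKLPDNYITKSEAQALGWVASKGNLADVAPGKSIGGDIFSNREGK
```

The sequence is read from the coordinate records themselves — the residues
actually modelled — not from SEQRES, which lists the construct.

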