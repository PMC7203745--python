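# Methods

## The convergence model

The package treats structure parsing as a pipeline with one mandatory
meeting point. Each format parser produces a *file-specific dictionary*
that is lossless with respect to its source: for PDB, every 80-column line
bucketed by record name with coordinate records grouped per MODEL block;
for mmCIF, every category (single items and `loop_` tables alike) as a
list of row mappings whose values are still strings, `?` and `.`
included; for MMTF, the decoded top-level field map of the msgpack
container. The *standardizer* then converts any of these into the standard
data dictionary with a fixed key skeleton:

```
description  code, title, deposition_date, classification, keywords, authors
experiment   technique, source_organism, expression_system
quality      resolution (Å), rvalue, rfree
geometry     assemblies: [{id, software, transformations:
                           [{chain_ids, matrix (3×3), vector (3)}]}]
models       [{polymer: {chain → {internal_id, sequence, residues}},
               non-polymer: {het id → {name, atoms}},
               water:       {het id → {name, atoms}}}]
missing_residues  [{id, name}]
```

Unavailable fields are null or empty, never absent, so the JSON shape is
identical for every source. Atom records are keyed by serial number (as
strings, because they are JSON keys) and carry name, element, x/y/z in
ångströms, formal charge in elementary-charge units and the B-factor in
Å². Het IDs are dotted, `<chain>.<number><insertion?>`. Residue order
within a chain follows (number, insertion code); atoms follow serial
order.

What each format genuinely carries differs. Missing-residue records exist
only in PDB (`REMARK 465`) and mmCIF (`pdbx_unobs_or_zero_occ_residues`);
the MMTF container has no field for them, nor for classification,
keywords, authors, source organism, expression system or the
assembly-annotation software. Convergence therefore means: `models` and
`geometry` are equal across all three formats, `missing_residues` is
equal between PDB and mmCIF and empty for MMTF. Chain sequences converge
because all three formats natively carry the full sequence including
unresolved residues (SEQRES, `entity_poly.pdbx_seq_one_letter_code`, the
MMTF `entityList`), so the standardizer reads the sequence from those
records rather than reconstructing it.

## Numerical and format choices

- **Element masses** come from a bundled IUPAC standard-atomic-weight
  table at 3-decimal precision. Unknown symbols contribute 0 Da with a
  logged warning rather than failing, so malformed files still parse.
  Mass-based filters (`mass__gt=14`) use the same standard weights, not
  isotopic masses.
- **Altloc resolution** keeps, per (chain, residue, atom-name) group, the
  records whose altloc letter sorts first alphabetically; blank-altloc
  records always survive. Occupancy is deliberately ignored — the rule is
  positional, not probabilistic; an occupancy-based strategy is left as a
  reserved option.
- **Water identification** is by residue name, default {HOH, DOD, WAT},
  configurable via `structparse.elements.WATER_NAMES`.
- **PDB writing** renumbers atom serials sequentially per model and emits
  only records it can source from the data model (HEADER, TITLE, KEYWDS,
  AUTHOR, EXPDTA, SOURCE, REMARK 2/3/350/465, SEQRES, MODEL/ATOM/HETATM/
  TER, END). Every line is exactly 80 characters; serials above 99999 and
  chain IDs wider than one column are refused, the format's historical
  limits. TER lines carry no serial so atom numbering stays aligned with
  the mmCIF and MMTF renderings of the same structure.
- **MMTF writing** uses the format's conventional codecs: coordinates as
  delta + recursive-index + fixed-point with divisor 1000 (0.001 Å
  resolution), B-factors divisor 100, run-length encodings for IDs,
  insertion codes and altlocs. All fifteen published codecs are
  implemented in both directions; decoding validates the declared element
  count and rejects unknown codec IDs loudly.
- **mmCIF tokenization** follows CIF 1.1 quoting: a quote opens a token
  only at a token boundary and closes it only when followed by whitespace
  or end-of-line, so `'a dog's life'` is one token; semicolon-first-column
  blocks become single tokens with newlines preserved. On quote-free input
  the tokenizer is exactly a whitespace split (property-tested).
- **Rotation does not recentre**: `rotate` maps r to M·r about the
  origin; in-place rotation about a centre is composed as
  translate∘rotate∘translate.
- **RMSD** pairs atoms by (het ID, atom name) and applies no
  superposition — it measures coordinates as deposited; Kabsch fitting is
  out of scope. Unpairable sets raise an error naming the unmatched keys.
- **Proximity search** uses the closed ball (atoms exactly at the radius
  included) and excludes the origin atom. A uniform cell-list
  acceleration is available and is required by the tests to agree
  set-for-set with the flat scan.
- **Grids** enumerate all lattice points (i·s, j·s, k·s) with
  ⌊min/s⌋ ≤ i ≤ ⌈max/s⌉ per axis, so the hull always contains every atom
  and a degenerate box (an atom exactly on a lattice point) yields a
  single point.
- **Assemblies** apply r′ = M·r + v to each referenced chain; ligands and
  waters follow the chain named in the dotted prefix of their het ID.
  Copies keep their original IDs (the StructureSet multimap holds them
  all); an optional renaming helper assigns numeric-suffix IDs and is off
  by default in the library, but on in the CLI `assembly` command because
  the output formats key chains by ID. Crystallographic symmetry
  expansion from space-group operators is not performed — only the
  explicit per-file instructions.
- **Traversal** descends mapping keys and zero-based list indices given
  as decimal strings; dotted het IDs are plain mapping keys. The CLI
  expresses the same paths as positional arguments rather than URL
  segments.

## The synthetic-structure generator

Tests and the acceptance script run entirely offline against
`structparse.fixtures`. A `FixtureSpec` (chain lengths, ligands, waters,
model count, altloc groups, missing residues, assembly instructions,
seed) deterministically yields renderings in all three formats plus the
expected data dictionary, assembled by independent template code — not by
the package's writers — so parser and writer tests are non-circular.

The generator emulates the *structural* features the pipeline must
handle: multi-chain polymers with 4-atom backbone residues, mono- and
polyatomic hetero groups with formal charges, waters, NMR-style
multi-model entries, alternate-location groups with shared serials,
terminal missing residues, and assembly instructions built from exact
rotation matrices (entries representable in 6 decimals) with translations
quantized to 3 decimals. Coordinates are drawn uniformly in ±30 Å and
quantized to 3 decimals, B-factors to 2, which is the precision of the
text formats — so text round trips are exact and the MMTF fixed-point
divisor (1000) loses nothing. What it does **not** emulate: realistic
covalent geometry or side chains, occupancies other than the altloc
convention, insertion codes in generated residues, ANISOU/bond records,
multi-character chain IDs, or files that violate their own format — so
passing tests demonstrate contract correctness on well-formed inputs, not
robustness against every archival irregularity.

Default study sizes keep everything fast: the standard matrix is 20 specs
spanning the feature combinations, oracle checks run on 100 seeded random
models of ~24 atoms, and the assembly check uses a 16-atom chain under 6
operators. The whole suite and the acceptance script each complete in a
few seconds.

## Known limitations

- PDB parsing tolerates missing element columns by inferring the element
  from the atom-name field, which can misread unusual ligand names.
- mmCIF parsing targets CIF 1.1 syntax; CIF 2.0 and dictionary validation
  are out of scope. `oper_expression` supports plain IDs, comma lists and
  simple ranges, not Cartesian products of operator lists.
- Remote fetching needs the network; the transport is injectable and the
  SSH transport is declared but deliberately unimplemented.
- Connectivity (CONECT/bond graphs), secondary structure, solvent
  accessibility and superposition-based RMSD are intentionally outside
  the package's remit.
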