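# excompose

Post-processing toolkit for composite excited-state benchmarks of capped
peptides. It covers the workflow downstream of the electronic-structure
engines (which are out of scope): assembling adiabatic ZPVE-corrected 0–0
excitation energies from per-method term tables, fitting and applying
mode-dependent N–H stretch frequency scaling, comparing conformer geometries
on named internal coordinates, classifying excited-state character from
transition-amplitude matrices, and computing the benchmark MAE/ME statistics
and report tables.

## Modules

| module | purpose |
|---|---|
| `excompose.dataio` | CSV/XYZ/annotation I/O and the bundled 11-conformer benchmark tables |
| `excompose.composite` | term decomposition (`e_00 = e_vert + dd_ad + dd_00`) and P1/P2 composite assembly |
| `excompose.freqscale` | linear `nu_exp = a*nu_theo + b` scaling fits, S1–S0 shifts, shift RMSD |
| `excompose.geomcompare` | dihedrals/distances, deviation reports (MAD, range, RMSD), Kabsch superposition |
| `excompose.benchstats` | pairwise MAE/ME, residue-count subgroups, report tables, printed-summary cross-check |
| `excompose.statechar` | NTO decomposition by SVD and ππ*/nπ*CO/CT/mixed character labels |
| `excompose.synthetic` | seeded synthetic benchmarks with known ground truth for validation |
| `excompose.cli` | `excompose` command-line entry point |

The bundled dataset (`excompose/data/`) holds the printed benchmark tables:
0–0 energies for 11 conformers (Fa A–D; GFa A, B'; FFa A1, A2, C; QFa A, C)
at CC2, ωB97X-D, P1, P2 and experiment (plus CAM-B3LYP for Fa), and the
harmonic/corrected amide-A S1–S0 shifts with experimental counterparts.
Composite P1/P2 columns are carried as data: their term-level inputs are not
publicly deposited, so the assembly path is validated on synthetic fixtures.

## CLI

```sh
excompose paper-tables --out out/            # bundled tables + MAE/ME summary + flags
excompose bench --input energies.csv --test wB97X-D --reference CC2 \
    --group residue_count --out out/
excompose assemble --input terms.csv --protocol P2.txt --out out/
excompose freqscale fit --input pairs.csv --mode-class NH --state S0 --out out/
excompose freqscale shifts --input freqs.csv --out out/
excompose geomcmp a.xyz b.xyz --annotations ann.txt --superpose-ring phenyl --out out/
excompose ntochar --matrix amplitudes.csv --fragments fragments.txt --out out/
excompose simulate --seed 1 --out out/
```

Every command writes a `run.log` (config echo, excluded-pair counts) next to
its artifacts and exits nonzero with a one-line diagnostic on error.

## Conventions

- Energies in eV; residuals are `test - reference`; reported statistics are
  rounded half-away-from-zero to 2 decimals (shifts to integer cm⁻¹).
- A handful of printed summary entries were derived from unrounded engine
  outputs and cannot be reproduced from the 3-decimal tables;
  `benchstats.check_printed_summaries` reports them as flagged mismatches
  rather than forcing agreement.
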