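# mir30design

Design tool for miR30-context shRNAs. Given a target transcript, it
enumerates every 22-nt guide candidate, scores each one with an
ε-regression SVM trained on harmonized potency labels from pooled
sensor assays, filters out sequences unsuitable for synthesis, and
emits clone-ready 97-mer hairpin oligos together with the predicted
~190-bp isothermal-assembly PCR product.

It is aimed at labs building inducible RNAi reagents (lentiviral or
RMCE cassettes) who want a scriptable, reproducible way to go from a
FASTA file to an oligo order sheet.

## The model

Each candidate guide *g* (22 nt, antisense to the mRNA) is read with
10 nt of mRNA context past its 5' end and 16 nt past its 3' end,
giving a 48-nt window encoded as 192 per-position base indicators.
Four auxiliary features are appended: a rule-based siRNA design score,
a target-site accessibility score in [0,1], the nearest-neighbor
duplex free energy ΔG(g:target) in kcal/mol, and the end-asymmetry
ΔΔG = ΔG(four 5'-terminal stacks) − ΔG(four 3'-terminal stacks).

Potency labels from the two supported training-table dialects are
harmonized to one scale; sort-round readout pairs (h, s) map via

    score = 4·2^((log₂h + log₂s)/2) − 10 = 4·√(h·s) − 10.

The regressor is an ε-SVR with RBF kernel, C = 2.25, γ = 0.1, ε = 0.1.
Ranked candidates with any homopolymer run longer than 4 nt in their
synthesis oligo are excluded; the top 10 survivors per transcript
become designs. Each design's 97-mer is
`anchor5(18) + sense(22) + loop(19) + guide(22) + anchor3(16)`, and
the universal primer pair (72 nt forward, 56 nt reverse) yields a
predicted 191-bp product. See `docs/methods.md` for details and
assumptions.

## Worked example

No training data ships with the package; the `simulate` subcommand
generates synthetic training tables with a planted, recoverable
potency signal (see `docs/methods.md`):

```bash
$ mir30design simulate --n 2000 --seed 42 --out fixtures
fellmann: fixtures/fellmann.tsv
tan: fixtures/tan.tsv
truth: fixtures/truth.tsv

$ mir30design train --fellmann fixtures/fellmann.tsv \
      --tan fixtures/tan.tsv --out potency.joblib --seed 42
trained on 4000 records -> potency.joblib

$ mir30design design --fasta target.fasta --model potency.joblib --out designs
10 designs -> designs
```

`designs/design_report.tsv` ranks the selected guides (here against a
500-nt transcript named `MyGene`, which has 500 − 48 + 1 = 453
candidates):

```
rank  transcript_id  target_start  guide22                 score    ...
1     MyGene         465           GACGATAGCCTCTTTATACCGA  13.9809
2     MyGene         201           GTGCTTGCTATGCCAACTAGCG  13.9411
```

The score is the SVM's predicted potency on the harmonized label
scale (higher = stronger predicted knockdown). The order sheet and
FASTA hold the synthesis templates; every oligo is exactly 97 nt and
every predicted amplicon 191 bp:

```
name                    guide22                 product_len
MyGene_shRNA_01_pos465  GACGATAGCCTCTTTATACCGA  191

>MyGene_shRNA_01_pos465
TGCTGTTGACAGTGAGCGTCGGTATAAAGAGGCTATCGTCTAGTGAAGCCACAGATGTAGACGATAGCCTCTTTATACCGATGCCTACTGCCTCGGA
```

Reading the 97-mer: the first 18 nt are the 5' anchor, positions
19–40 the sense arm (reverse complement of the guide), then the 19-nt
loop, the guide itself, and the 16-nt 3' anchor.

The same pipeline is available as a library (`mir30design.train`,
`predict`, `select`, `assemble_97mer`, ...), and genuine external-tool
feature tables can replace the built-in auxiliary heuristics via
`mir30design.ingest_aux_table`.

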