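# RNA/RNA Watson-Crick nearest-neighbor stack free energies, dG37 kcal/mol
# (Xia et al. 1998, Turner group). Key = 5'->3' dinucleotide on one strand,
# DNA alphabet (T stands for U); value = stack dG for that dinucleotide
# paired with its full Watson-Crick complement. Symmetric under reverse
# complement of the key.
AA	-0.93
AC	-2.24
AG	-2.08
AT	-1.10
CA	-2.11
CC	-3.26
CG	-2.36
CT	-2.08
GA	-2.35
GC	-3.42
GG	-3.26
GT	-2.24
TA	-1.33
TC	-2.35
TG	-2.11
TT	-0.93
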