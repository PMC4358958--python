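"""miR30-context hairpin oligo assembly and isothermal-assembly PCR prediction.

Each selected 22-nt guide is synthesized as a single-stranded 97-mer
template holding the complete hairpin:

    anchor5 (18) + sense22 (22) + loop (19) + guide22 (22) + anchor3 (16)

The sense (passenger) arm is the exact reverse complement of the guide
and corresponds to the target mRNA sequence.  The two anchors are the
3' termini of the universal amplification primers, so a single primer
pair converts any 97-mer template into a 191-bp double-stranded product
ready for isothermal assembly into a miR30-context vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, TextIO, Tuple

from .sequence import SequenceError, reverse_complement

#: 3' terminus of the forward amplification primer (miR30 5' junction)
ANCHOR5 = "TGCTGTTGACAGTGAGCG"
#: reverse complement of the reverse primer's 3' terminus (miR30 3' junction)
ANCHOR3 = "TGCCTACTGCCTCGGA"
#: hairpin loop (Dow et al. 2012 protocol); configurable but length-checked
DEFAULT_LOOP = "TAGTGAAGCCACAGATGTA"

#: universal amplification primers for the ~190-bp assembly product
M30C_ISO_F = "CTTGCTGGGATTACTTCTTCAGGTTAACCCAACAGAAGGCTCGAGAAGGTATATTGCTGTTGACAGTGAGCG"
M30C_ISO_R = "AACAAGATAATTGCTCCTAAAGTAGCCCCTTGAATTCGATTCCGAGGCAGTAGGCA"

FWD_OVERLAP = len(ANCHOR5)   # 18 nt exact-match annealing on the forward side
REV_OVERLAP = len(ANCHOR3)   # 16 nt on the reverse side

assert M30C_ISO_F[-FWD_OVERLAP:] == ANCHOR5
assert reverse_complement(M30C_ISO_R[-REV_OVERLAP:]) == ANCHOR3


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class HairpinOligo:
    guide22: str
    sense22: str
    loop: str
    anchor5: str = ANCHOR5
    anchor3: str = ANCHOR3

    @property
    def oligo97(self) -> str:
        return self.anchor5 + self.sense22 + self.loop + self.guide22 + self.anchor3


@dataclass(frozen=True)
class AssemblyAmplicon:
    forward_primer: str
    reverse_primer: str
    product_seq: str  # top strand of the double-stranded product

    @property
    def product_len(self) -> int:
        return len(self.product_seq)


def assemble_97mer(guide22: str, loop: str = DEFAULT_LOOP) -> HairpinOligo:
    """Build the 97-mer hairpin synthesis template for one guide.

    Layout in 0-based half-open coordinates with the default 19-nt loop:
    anchor5 [0,18), sense [18,40), loop [40,59), guide [59,81),
    anchor3 [81,97).  A loop of any other length fails loudly rather than
    silently shifting the downstream coordinates.
    """
    g = guide22.upper()
    if len(g) != 22:
        raise AssemblyError(f"guide must be 22 nt, got {len(g)}")
    if set(g) - set("ACGT"):
        raise AssemblyError(f"guide contains non-ACGT characters: {guide22!r}")
    oligo = HairpinOligo(guide22=g, sense22=reverse_complement(g), loop=loop)
    if len(oligo.oligo97) != 97:
        raise AssemblyError(
            f"hairpin template is {len(oligo.oligo97)} nt, not 97 "
            f"(loop length {len(loop)} != 19?)"
        )
    return oligo


def simulate_assembly_pcr(
    oligo: HairpinOligo,
    forward_primer: str = M30C_ISO_F,
    reverse_primer: str = M30C_ISO_R,
) -> AssemblyAmplicon:
    """Predict the amplification product from the 97-mer template.

    Primers anneal by exact 3'-end match only (18 nt forward, 16 nt
    reverse).  Product top strand = forward primer + template past the
    forward anchor + reverse complement of the reverse primer's
    non-annealing tail; with the universal primers the product is
    72 + 79 + 40 = 191 bp, the "~190 bp" cloning fragment.
    """
    template = oligo.oligo97
    f_anchor = forward_primer[-FWD_OVERLAP:]
    if not template.startswith(f_anchor):
        raise AssemblyError(
            f"forward primer cannot anneal: template does not start with {f_anchor}"
        )
    r_anchor = reverse_complement(reverse_primer[-REV_OVERLAP:])
    if not template.endswith(r_anchor):
        raise AssemblyError(
            f"reverse primer cannot anneal: template does not end with {r_anchor}"
        )
    product = (
        forward_primer
        + template[FWD_OVERLAP:]
        + reverse_complement(reverse_primer[:-REV_OVERLAP])
    )
    return AssemblyAmplicon(
        forward_primer=forward_primer,
        reverse_primer=reverse_primer,
        product_seq=product,
    )


ORDER_SHEET_COLUMNS = (
    "name",
    "guide22",
    "oligo97",
    "forward_primer",
    "reverse_primer",
    "product_len",
)


def emit_oligo_order_sheet(
    designs: Sequence[Tuple[str, HairpinOligo]],
    sheet: TextIO,
    fasta: TextIO,
) -> int:
    """Write the synthesis order sheet (TSV) and an oligo FASTA.

    One row / FASTA record per (name, oligo) design; the amplification
    primer columns are identical on every row.  Duplicate names error.
    """
    if not designs:
        raise AssemblyError("no designs to emit")
    names = [name for name, _ in designs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise AssemblyError(f"duplicate design names: {dupes}")
    sheet.write("\t".join(ORDER_SHEET_COLUMNS) + "\n")
    for name, oligo in designs:
        amplicon = simulate_assembly_pcr(oligo)
        sheet.write(
            f"{name}\t{oligo.guide22}\t{oligo.oligo97}\t"
            f"{M30C_ISO_F}\t{M30C_ISO_R}\t{amplicon.product_len}\n"
        )
        fasta.write(f">{name}\n{oligo.oligo97}\n")
    return len(designs)
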