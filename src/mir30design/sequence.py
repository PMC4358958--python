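"""Transcript handling and enumeration of 22-nt guide candidates.

A guide candidate targets a 22-nt site on the mRNA.  The scoring model
reads the guide in its own (antisense) orientation together with two
flanks copied from the mRNA: 10 nt past the guide's 5' end (3' on the
mRNA) and 16 nt past its 3' end (5' on the mRNA), giving a 48-nt context
``flank5_guide + guide22 + flank3_guide``.

Coordinates are 0-based, half-open, in mRNA sense.  The internal alphabet
is DNA: U is mapped to T on ingest and all oligo outputs are DNA.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, TextIO, Tuple

from Bio import SeqIO

VALID_BASES = frozenset("ACGTUN")
_COMPLEMENT_DNA = str.maketrans("ACGTN", "TGCAN")
_COMPLEMENT_RNA = str.maketrans("ACGUN", "UGCAN")

#: default guide length in nt (the Fellmann/Dow miR30 convention)
GUIDE_LEN = 22
#: nt of mRNA context past the guide's 5' end
FLANK5_LEN = 10
#: nt of mRNA context past the guide's 3' end
FLANK3_LEN = 16


class SequenceError(ValueError):
    """Raised for sequences outside the {A,C,G,T,U,N} alphabet."""


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet.

    Idempotent: ``normalize_seq(normalize_seq(s)) == normalize_seq(s)``.
    """
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise SequenceError(
            f"invalid characters {sorted(bad)!r}; expected A,C,G,T,U or N"
        )
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; preserves the T/U alphabet of the input.

    N maps to N.  Mixed T+U input is rejected along with any character
    outside {A,C,G,T,U,N}.
    """
    s = seq.upper()
    bad = set(s) - VALID_BASES
    if bad:
        raise SequenceError(
            f"invalid characters {sorted(bad)!r} in reverse_complement input"
        )
    if "U" in s:
        if "T" in s:
            raise SequenceError("sequence mixes T and U")
        return s.translate(_COMPLEMENT_RNA)[::-1]
    return s.translate(_COMPLEMENT_DNA)[::-1]


@dataclass(frozen=True)
class Transcript:
    """A named nucleotide sequence, uppercase DNA after normalization."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_seq(self.seq))

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GuideCandidate:
    """One 22-nt guide with its encoding context.

    ``target_start`` is the 0-based offset of the 22-nt target site on the
    mRNA (half-open interval ``[target_start, target_start + 22)``).
    ``guide22`` is the reverse complement of ``target22``.  ``context48``
    is ``flank5_guide + guide22 + flank3_guide`` in guide orientation.
    """

    transcript_id: str
    target_start: int
    target22: str
    guide22: str
    flank5_guide: str
    flank3_guide: str

    @property
    def context48(self) -> str:
        return self.flank5_guide + self.guide22 + self.flank3_guide


def _make_candidate(t: Transcript, start: int, guide_len: int) -> GuideCandidate:
    target = t.seq[start : start + guide_len]
    # guide 5' flank pairs with mRNA downstream of the site; guide 3' flank
    # with mRNA upstream of it (antisense orientation flips the ends)
    flank5 = reverse_complement(t.seq[start + guide_len : start + guide_len + FLANK5_LEN])
    flank3 = reverse_complement(t.seq[start - FLANK3_LEN : start])
    return GuideCandidate(
        transcript_id=t.id,
        target_start=start,
        target22=target,
        guide22=reverse_complement(target),
        flank5_guide=flank5,
        flank3_guide=flank3,
    )


def enumerate_candidates(
    t: Transcript,
    guide_len: int = GUIDE_LEN,
    region: Optional[Tuple[int, int]] = None,
) -> List[GuideCandidate]:
    """Enumerate every guide candidate whose full context window fits.

    One candidate per target start where the window
    ``[start - 16, start + guide_len + 10)`` lies inside the transcript and
    contains no N.  For ``guide_len=22`` on an N-free transcript of length
    L this yields ``max(0, L - 48 + 1)`` candidates, in ascending
    ``target_start`` order.

    ``region`` optionally restricts ``target_start`` to a half-open
    coordinate range (e.g. to design only against the CDS); default is the
    whole transcript.
    """
    if guide_len < 1:
        raise ValueError("guide_len must be >= 1")
    lo, hi = region if region is not None else (0, t.length)
    out: List[GuideCandidate] = []
    for start in range(max(FLANK3_LEN, lo), min(t.length - guide_len - FLANK5_LEN, hi - 1) + 1):
        window = t.seq[start - FLANK3_LEN : start + guide_len + FLANK5_LEN]
        if "N" in window:
            continue
        out.append(_make_candidate(t, start, guide_len))
    return out


def candidate_from_context(context48: str, record_id: str = "record") -> Tuple[GuideCandidate, Transcript]:
    """Rebuild a candidate (and its minimal mRNA fragment) from a bare context.

    Training records carry only the 48-nt guide-orientation context.  The
    corresponding mRNA-sense fragment is its reverse complement, with the
    22-nt target site at positions [16, 38).  Features that look at the
    transcript neighborhood see only this 48-nt fragment.
    """
    ctx = normalize_seq(context48)
    if len(ctx) != 48:
        raise SequenceError(f"context must be 48 nt, got {len(ctx)}")
    if "N" in ctx:
        raise SequenceError("context contains N")
    t = Transcript(record_id, reverse_complement(ctx))
    cands = enumerate_candidates(t)
    assert len(cands) == 1 and cands[0].context48 == ctx
    return cands[0], t


def read_fasta(path_or_handle) -> List[Transcript]:
    """Read a (multi-record, wrapped, case-insensitive) FASTA file."""
    return [Transcript(rec.id, str(rec.seq)) for rec in SeqIO.parse(path_or_handle, "fasta")]


def write_candidate_table(candidates: Iterable[GuideCandidate], handle: TextIO) -> int:
    """Write candidates as TSV; returns the number of rows written."""
    handle.write("transcript_id\ttarget_start\ttarget22\tguide22\tcontext48\n")
    n = 0
    for c in candidates:
        handle.write(
            f"{c.transcript_id}\t{c.target_start}\t{c.target22}\t{c.guide22}\t{c.context48}\n"
        )
        n += 1
    return n
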