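"""Ranking and selection of scored guide candidates.

Candidates are sorted by descending SVM score; any candidate whose
synthesis oligo contains a homopolymer run longer than 4 nt is excluded
(long runs compromise oligo synthesis and sequencing); the top N
survivors per transcript (default 10) form the design set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .oligo import HairpinOligo
from .sequence import GuideCandidate


@dataclass(frozen=True)
class HomopolymerRun:
    base: str
    start: int  # 0-based offset of the run
    length: int


def has_homopolymer(seq: str, max_len: int = 4) -> Optional[HomopolymerRun]:
    """Leftmost longest homopolymer run exceeding ``max_len``, or None.

    A run of exactly ``max_len`` identical bases is allowed; only runs of
    ``max_len + 1`` or more are reported.
    """
    best: Optional[HomopolymerRun] = None
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i > max_len and (best is None or j - i > best.length):
            best = HomopolymerRun(base=seq[i], start=i, length=j - i)
        i = j
    return best


@dataclass(frozen=True)
class SelectionConfig:
    top_n: int = 10
    max_homopolymer: int = 4
    homopolymer_scope: str = "oligo97"  # or "guide_context"
    min_separation: int = 0  # optional spacing between selected target sites

    def __post_init__(self):
        if self.top_n < 1 or self.max_homopolymer < 1:
            raise ValueError("top_n and max_homopolymer must be >= 1")
        if self.homopolymer_scope not in ("oligo97", "guide_context"):
            raise ValueError(f"unknown homopolymer scope {self.homopolymer_scope!r}")


@dataclass(frozen=True)
class Design:
    rank: int
    candidate: GuideCandidate
    score: float
    oligo: HairpinOligo


@dataclass(frozen=True)
class Exclusion:
    candidate: GuideCandidate
    score: float
    reason: str


@dataclass(frozen=True)
class SelectionResult:
    designs: List[Design]
    exclusions: List[Exclusion]

    @property
    def empty(self) -> bool:
        return not self.designs


def select(
    scored: Sequence[Tuple[GuideCandidate, float]],
    oligos: Sequence[HairpinOligo],
    cfg: SelectionConfig = SelectionConfig(),
) -> SelectionResult:
    """Filter, rank, and pick the design set.

    Homopolymer exclusion is score-independent, so filtering before or
    after ranking gives the same result.  Ties in score are broken toward
    the smaller (5'-most) target_start.  An empty survivor set yields an
    empty result, not an exception.
    """
    if len(scored) != len(oligos):
        raise ValueError("scored candidates and oligos must align 1:1")
    survivors: List[Tuple[GuideCandidate, float, HairpinOligo]] = []
    exclusions: List[Exclusion] = []
    for (cand, score), oligo in zip(scored, oligos):
        probe = oligo.oligo97 if cfg.homopolymer_scope == "oligo97" else cand.context48
        run = has_homopolymer(probe, cfg.max_homopolymer)
        if run is not None:
            exclusions.append(
                Exclusion(
                    cand,
                    score,
                    f"homopolymer {run.base}x{run.length} at {cfg.homopolymer_scope} "
                    f"position {run.start} (limit {cfg.max_homopolymer})",
                )
            )
        else:
            survivors.append((cand, score, oligo))
    survivors.sort(key=lambda cso: (-cso[1], cso[0].target_start))
    designs: List[Design] = []
    for cand, score, oligo in survivors:
        if len(designs) >= cfg.top_n:
            break
        if cfg.min_separation and any(
            abs(cand.target_start - d.candidate.target_start) < cfg.min_separation
            for d in designs
        ):
            exclusions.append(
                Exclusion(cand, score, f"within {cfg.min_separation} nt of a selected site")
            )
            continue
        designs.append(Design(rank=len(designs) + 1, candidate=cand, score=score, oligo=oligo))
    return SelectionResult(designs=designs, exclusions=exclusions)


DESIGN_REPORT_COLUMNS = (
    "rank",
    "transcript_id",
    "target_start",
    "guide22",
    "score",
    "oligo97",
    "excluded_flag",
    "exclusion_reason",
)


def write_design_report(result: SelectionResult, handle) -> None:
    """TSV report: ranked designs followed by the exclusion log."""
    handle.write("\t".join(DESIGN_REPORT_COLUMNS) + "\n")
    for d in result.designs:
        handle.write(
            f"{d.rank}\t{d.candidate.transcript_id}\t{d.candidate.target_start}\t"
            f"{d.candidate.guide22}\t{d.score:.6g}\t{d.oligo.oligo97}\tFalse\t\n"
        )
    for e in result.exclusions:
        handle.write(
            f"\t{e.candidate.transcript_id}\t{e.candidate.target_start}\t"
            f"{e.candidate.guide22}\t{e.score:.6g}\t\tTrue\t{e.reason}\n"
        )
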