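"""Homopolymer filtering and top-N candidate selection."""

import re

import pytest

from mir30design import SelectionConfig, assemble_97mer, has_homopolymer, select
from mir30design.selection import write_design_report
from mir30design.sequence import GuideCandidate, reverse_complement


def make_candidate(guide, start=16):
    return GuideCandidate(
        transcript_id="t",
        target_start=start,
        target22=reverse_complement(guide),
        guide22=guide,
        flank5_guide="ACGTACGTAC",
        flank3_guide="ACGTACGTACGTACGT",
    )


@pytest.mark.parametrize(
    "seq,max_len,expect",
    [
        ("ACGTAAAAC", 4, None),  # run of exactly 4 allowed
        ("ACGGGGGT", 4, ("G", 2, 5)),
        ("AAAAA", 4, ("A", 0, 5)),
        ("ACGT", 4, None),
        ("TTTTTCCCCCC", 4, ("C", 5, 6)),  # leftmost *longest* run
    ],
)
def test_has_homopolymer_examples(seq, max_len, expect):
    run = has_homopolymer(seq, max_len)
    if expect is None:
        assert run is None
    else:
        assert (run.base, run.start, run.length) == expect


def test_has_homopolymer_matches_regex_oracle(rng):
    """Agreement with an independent regex scanner on random 97-mers."""
    for _ in range(2000):
        seq = "".join(rng.choice(list("ACGT"), size=97))
        run = has_homopolymer(seq, 4)
        oracle = [m for m in re.finditer(r"(.)\1{4,}", seq)]
        if run is None:
            assert not oracle
        else:
            longest = max(m.end() - m.start() for m in oracle)
            assert run.length == longest


def _scored(guides_scores):
    scored = [(make_candidate(g, start=16 + 30 * i), s) for i, (g, s) in enumerate(guides_scores)]
    oligos = [assemble_97mer(c.guide22) for c, _ in scored]
    return scored, oligos


CLEAN = [
    "ACGTACGTACGTACGTACGTAC",
    "TGCATGCATGCATGCATGCATG",
    "GATCGATCGATCGATCGATCGA",
]


def test_select_sorts_by_score():
    scored, oligos = _scored(list(zip(CLEAN, [3.0, 5.0, 1.0])))
    result = select(scored, oligos, SelectionConfig(top_n=2))
    assert [d.score for d in result.designs] == [5.0, 3.0]
    assert [d.rank for d in result.designs] == [1, 2]
    assert not result.exclusions


def test_homopolymer_exclusion_beats_score():
    bad = "ACGTTTTTACGTACGTACGTAC"  # TTTTT in the guide -> in the 97-mer
    scored, oligos = _scored([(bad, 99.0), (CLEAN[0], 1.0)])
    result = select(scored, oligos, SelectionConfig())
    assert [d.candidate.guide22 for d in result.designs] == [CLEAN[0]]
    assert len(result.exclusions) == 1
    assert "homopolymer" in result.exclusions[0].reason
    assert result.exclusions[0].candidate.guide22 == bad


def test_tie_break_prefers_5prime_most():
    scored, oligos = _scored([(CLEAN[0], 2.0), (CLEAN[1], 2.0)])
    result = select(scored, oligos, SelectionConfig())
    starts = [d.candidate.target_start for d in result.designs]
    assert starts == sorted(starts)


def test_filter_then_rank_equals_rank_then_filter(rng):
    """The exclusion is score-independent, so the two orders agree."""
    guides, scores = [], []
    for _ in range(40):
        guides.append("".join(rng.choice(list("ACGT"), size=22)))
        scores.append(float(rng.normal()))
    scored, oligos = _scored(list(zip(guides, scores)))
    cfg = SelectionConfig(top_n=10)
    result = select(scored, oligos, cfg)
    # rank first (no filter), then filter the ranked list by hand
    ranked = sorted(zip(scored, oligos), key=lambda x: (-x[0][1], x[0][0].target_start))
    survivors = [
        (c, s) for (c, s), o in ranked if has_homopolymer(o.oligo97, 4) is None
    ][: cfg.top_n]
    assert [(d.candidate.guide22, d.score) for d in result.designs] == [
        (c.guide22, s) for c, s in survivors
    ]


def test_selection_caps_and_logs(rng):
    guides = ["".join(rng.choice(list("ACGT"), size=22)) for _ in range(60)]
    scored, oligos = _scored([(g, float(i)) for i, g in enumerate(guides)])
    cfg = SelectionConfig(top_n=10)
    result = select(scored, oligos, cfg)
    assert len(result.designs) <= 10
    n_excluded = sum(has_homopolymer(o.oligo97, 4) is not None for o in oligos)
    assert len(result.exclusions) == n_excluded
    # purity: second run identical
    again = select(scored, oligos, cfg)
    assert [(d.candidate.guide22, d.score) for d in again.designs] == [
        (d.candidate.guide22, d.score) for d in result.designs
    ]


def test_empty_survivor_set_is_result_not_error():
    bad = "ACGTTTTTTACGTACGTACGT" + "A"
    scored, oligos = _scored([(bad, 1.0)])
    result = select(scored, oligos, SelectionConfig())
    assert result.empty and len(result.exclusions) == 1


def test_guide_context_scope():
    # homopolymer in the flank, not the guide: excluded only under guide_context/oligo97 probes that see it
    cand = make_candidate(CLEAN[0])
    cand = GuideCandidate(
        transcript_id="t",
        target_start=16,
        target22=cand.target22,
        guide22=cand.guide22,
        flank5_guide="AAAAAWWWWW".replace("W", "C"),
        flank3_guide="ACGTACGTACGTACGT",
    )
    oligo = assemble_97mer(cand.guide22)
    res_ctx = select([(cand, 1.0)], [oligo], SelectionConfig(homopolymer_scope="guide_context"))
    res_oligo = select([(cand, 1.0)], [oligo], SelectionConfig(homopolymer_scope="oligo97"))
    assert res_ctx.empty  # AAAAA in context48
    assert not res_oligo.empty  # clean 97-mer


def test_min_separation_flag():
    scored = [(make_candidate(CLEAN[0], start=16), 5.0), (make_candidate(CLEAN[1], start=20), 4.0)]
    oligos = [assemble_97mer(c.guide22) for c, _ in scored]
    res = select(scored, oligos, SelectionConfig(min_separation=22))
    assert len(res.designs) == 1
    assert any("within" in e.reason for e in res.exclusions)


def test_design_report_round_trip(tmp_path, rng):
    guides = ["".join(rng.choice(list("ACGT"), size=22)) for _ in range(5)]
    scored, oligos = _scored([(g, float(i)) for i, g in enumerate(guides)])
    result = select(scored, oligos, SelectionConfig())
    path = tmp_path / "report.tsv"
    with open(path, "w") as fh:
        write_design_report(result, fh)
    lines = path.read_text().strip().split("\n")
    assert len(lines) == 1 + len(result.designs) + len(result.exclusions)
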