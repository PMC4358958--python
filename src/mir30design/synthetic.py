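"""Synthetic transcripts and training tables with a planted potency signal.

Real training data for this kind of model comes from pooled sensor
assays; no such table ships here.  Instead this module generates random
transcripts and labels their guide candidates with a *known* potency
function — linear in the positional one-hot basis plus a guide-GC term —
so that every downstream stage (encoding, label harmonization, SVR fit,
selection) can be tested for signal recovery against ground truth.

The planted effects concentrate in the guide 5'-end region of the
context (positions 10-21), mimicking the known 5'-end sequence
asymmetry of effective siRNAs; that placement is a test convenience,
not a biological claim.  Labels are mapped to a ProdEn-like range
(offset 10, scale 2) and corrupted with Gaussian noise; by default the
noise sd is half the sd of the true scores.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .sequence import GuideCandidate, Transcript, enumerate_candidates
from .training import PotencyRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass(frozen=True)
class PlantedSignalSpec:
    """Ground-truth potency function plus noise model.

    ``noise_sd=None`` means "half the empirical sd of the true scores of
    the candidate set being labelled" — the default study condition.
    """

    positional_weights: Dict[Tuple[int, str], float]
    gc_weight: float = 2.0
    noise_sd: Optional[float] = None
    score_offset: float = 10.0
    score_scale: float = 2.0
    seed: int = 0


def default_signal_spec(
    seed: int = 0,
    n_effects: int = 12,
    effect_sd: float = 1.5,
    noise_sd: Optional[float] = None,
) -> PlantedSignalSpec:
    """Planted signal with ``n_effects`` positional effects at context
    positions 10-21 (the guide 5'-end region) drawn N(0, effect_sd)."""
    rng = np.random.default_rng(seed)
    positions = rng.choice(np.arange(10, 22), size=n_effects, replace=False)
    weights = {
        (int(p), BASES[int(rng.integers(0, 4))]): float(rng.normal(0, effect_sd))
        for p in positions
    }
    return PlantedSignalSpec(positional_weights=weights, noise_sd=noise_sd, seed=seed)


def generate_transcripts(
    n: int, length: int, gc: float = 0.5, seed: int = 0
) -> List[Transcript]:
    """i.i.d. random transcripts with expected GC fraction ``gc``; seeded."""
    if n < 1 or length < 48:
        raise ValueError("need n >= 1 and length >= 48")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    mat = rng.choice(list("ACGT"), size=(n, length), p=probs)
    return [Transcript(f"synth_{i:05d}", "".join(row)) for i, row in enumerate(mat)]


def true_potency(candidate: GuideCandidate, spec: PlantedSignalSpec) -> float:
    """Noiseless ground-truth potency of one candidate."""
    ctx = candidate.context48
    raw = sum(
        w for (pos, base), w in spec.positional_weights.items() if ctx[pos] == base
    )
    g = candidate.guide22
    raw += spec.gc_weight * (g.count("G") + g.count("C")) / len(g)
    return spec.score_offset + spec.score_scale * raw


def _resolve_noise_sd(spec: PlantedSignalSpec, truths: np.ndarray) -> float:
    if spec.noise_sd is not None:
        return spec.noise_sd
    return 0.5 * float(np.std(truths))


def sample_candidates(n: int, seed: int = 0, gc: float = 0.5) -> List[GuideCandidate]:
    """n independent candidates, one per random 48-nt transcript."""
    cands = []
    for t in generate_transcripts(n, 48, gc=gc, seed=seed):
        cands.extend(enumerate_candidates(t))
    return cands


def make_training_frames(
    candidates: Sequence[GuideCandidate],
    spec: PlantedSignalSpec,
    dialects: Iterable[str] = ("fellmann", "tan"),
) -> Dict[str, pd.DataFrame]:
    """Build the training tables (and the truth table) as DataFrames.

    The tan dialect encodes the noisy score y as h = s = (y + 10) / 4, so
    the harmonization transform 4*sqrt(h*s) - 10 inverts the construction
    exactly.  Scores at or below -10 cannot be encoded (h would be
    nonpositive); their noise is redrawn, and the event is logged.
    """
    rng = np.random.default_rng(spec.seed)
    truths = np.array([true_potency(c, spec) for c in candidates])
    sd = _resolve_noise_sd(spec, truths)
    frames: Dict[str, pd.DataFrame] = {
        "truth": pd.DataFrame(
            {"context48": [c.context48 for c in candidates], "true_score": truths}
        )
    }
    for dialect in dialects:
        noisy = truths + rng.normal(0, sd, len(candidates)) if sd > 0 else truths.copy()
        if dialect == "fellmann":
            frames["fellmann"] = pd.DataFrame(
                {"context48": [c.context48 for c in candidates], "proden": noisy}
            )
        elif dialect == "tan":
            bad = np.flatnonzero(noisy <= -10)
            tries = 0
            while bad.size and tries < 100:
                logger.info(
                    "resampling %d tan score(s) at or below -10 (not encodable)",
                    bad.size,
                )
                noisy[bad] = truths[bad] + rng.normal(0, sd, bad.size)
                bad = np.flatnonzero(noisy <= -10)
                tries += 1
            if bad.size:
                raise ValueError("cannot encode tan scores <= -10 after resampling")
            hs = (noisy + 10.0) / 4.0
            frames["tan"] = pd.DataFrame(
                {
                    "context48": [c.context48 for c in candidates],
                    "hyb_sort6": hs,
                    "seq_sort6": hs,
                }
            )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return frames


def emit_training_tables(
    candidates: Sequence[GuideCandidate],
    spec: PlantedSignalSpec,
    out_dir,
    dialects: Iterable[str] = ("fellmann", "tan"),
) -> Dict[str, str]:
    """Write the training tables + truth table as TSV; returns name->path."""
    frames = make_training_frames(candidates, spec, dialects)
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, frame in frames.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


def synthetic_records(
    n: int = 2000,
    seed: int = 0,
    dialect: str = "fellmann",
    spec: Optional[PlantedSignalSpec] = None,
) -> Tuple[List[PotencyRecord], np.ndarray]:
    """Convenience: n candidates -> noisy PotencyRecords + true scores.

    Labels go through the same construction as the emitted tables (for
    the tan dialect, including the transform round-trip).
    """
    from .training import transform_tan

    spec = spec if spec is not None else default_signal_spec(seed)
    if spec.seed != seed:
        spec = PlantedSignalSpec(
            positional_weights=spec.positional_weights,
            gc_weight=spec.gc_weight,
            noise_sd=spec.noise_sd,
            score_offset=spec.score_offset,
            score_scale=spec.score_scale,
            seed=seed,
        )
    candidates = sample_candidates(n, seed=seed)
    frames = make_training_frames(candidates, spec, dialects=(dialect,))
    truth = frames["truth"]["true_score"].to_numpy()
    if dialect == "fellmann":
        records = [
            PotencyRecord(ctx, float(y), source="synthetic")
            for ctx, y in zip(frames["fellmann"]["context48"], frames["fellmann"]["proden"])
        ]
    else:
        records = [
            PotencyRecord(ctx, transform_tan(h, s), source="synthetic", h=float(h), s=float(s))
            for ctx, h, s in zip(
                frames["tan"]["context48"],
                frames["tan"]["hyb_sort6"],
                frames["tan"]["seq_sort6"],
            )
        ]
    return records, truth
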