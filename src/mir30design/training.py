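"""Training-table ingestion and potency-label harmonization.

Two table dialects are supported, mirroring the two published pooled
sensor-assay datasets the model is trained on:

* ``fellmann`` — columns ``context48``, ``proden``: the ProdEn potency
  score is consumed as given.
* ``tan`` — columns ``context48``, ``hyb_sort6``, ``seq_sort6``: the
  round-6 hybridization and sequencing readouts are mapped onto the
  ProdEn-like scale by :func:`transform_tan`.

Both are plain TSV with a header row.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .sequence import normalize_seq

logger = logging.getLogger(__name__)

DIALECTS = ("fellmann", "tan")


class TrainingDataError(ValueError):
    pass


@dataclass(frozen=True)
class PotencyRecord:
    """One training example: sequence context + harmonized potency label."""

    context48: str
    label: float
    source: str
    h: Optional[float] = None  # sort-6 hybridization value (tan only)
    s: Optional[float] = None  # sort-6 sequencing value (tan only)


def transform_tan(h: float, s: float) -> float:
    """Map sort-6 (hybridization, sequencing) readouts to the ProdEn scale.

    Average the log2-transformed values, undo the log, multiply by 4 and
    subtract 10:

        4 * 2**((log2 h + log2 s) / 2) - 10  ==  4 * sqrt(h * s) - 10

    Implemented in the sqrt form (algebraically identical, numerically
    simpler); equivalence of the two forms is unit-tested to 1e-9.
    """
    if h <= 0 or s <= 0:
        raise TrainingDataError(
            f"nonpositive sort-6 value (h={h}, s={s}); logarithm undefined"
        )
    return 4.0 * math.sqrt(h * s) - 10.0


def _clean_context(raw: object) -> str:
    ctx = normalize_seq(str(raw).strip())
    if len(ctx) != 48:
        raise TrainingDataError(f"context is {len(ctx)} nt, expected 48")
    if "N" in ctx:
        raise TrainingDataError("context contains N")
    return ctx


def load_training_table(path, dialect: str) -> List[PotencyRecord]:
    """Parse one training table; malformed rows are rejected with a logged
    reason, and a table whose every row is rejected is a hard error."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    table = pd.read_csv(path, sep="\t")
    required = {"fellmann": ["context48", "proden"], "tan": ["context48", "hyb_sort6", "seq_sort6"]}
    missing = set(required[dialect]) - set(table.columns)
    if missing:
        raise TrainingDataError(f"{dialect} table missing columns {sorted(missing)}")

    records: List[PotencyRecord] = []
    n_rejected = 0
    for i, row in table.iterrows():
        try:
            ctx = _clean_context(row["context48"])
            if dialect == "fellmann":
                records.append(
                    PotencyRecord(ctx, float(row["proden"]), source="fellmann")
                )
            else:
                h, s = float(row["hyb_sort6"]), float(row["seq_sort6"])
                records.append(
                    PotencyRecord(ctx, transform_tan(h, s), source="tan", h=h, s=s)
                )
        except (TrainingDataError, ValueError) as exc:
            n_rejected += 1
            logger.warning("rejected row %d of %s: %s", i, path, exc)
    if not records:
        raise TrainingDataError(f"no usable rows in {path} ({n_rejected} rejected)")
    if n_rejected:
        logger.info("%s: loaded %d records, rejected %d rows", path, len(records), n_rejected)
    return records


def merge_training_sets(
    *record_sets: Sequence[PotencyRecord], dedup: str = "keep_both"
) -> List[PotencyRecord]:
    """Merge record lists across sources.

    ``keep_both`` (default): duplicate contexts are independent
    measurements and all are kept.  ``average``: records sharing a context
    collapse to one record with the mean label (source tag ``merged`` when
    the duplicates span sources).
    """
    merged = [r for rs in record_sets for r in rs]
    if dedup == "keep_both":
        return merged
    if dedup != "average":
        raise ValueError(f"unknown dedup policy {dedup!r}")
    by_ctx: dict = {}
    order: List[str] = []
    for r in merged:
        if r.context48 not in by_ctx:
            order.append(r.context48)
        by_ctx.setdefault(r.context48, []).append(r)
    out = []
    for ctx in order:
        group = by_ctx[ctx]
        if len(group) == 1:
            out.append(group[0])
        else:
            sources = {r.source for r in group}
            source = group[0].source if len(sources) == 1 else "merged"
            out.append(
                PotencyRecord(ctx, sum(r.label for r in group) / len(group), source)
            )
    return out
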