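"""Feature engineering: positional encoding of the 48-nt context plus
auxiliary thermodynamic / accessibility / rule-based scores.

The SVM consumes a fixed-order numeric vector per candidate:

    [ positional block (4 x 48 = 192) | sirna_score |
      accessibility_posterior | duplex_dG | end_asymmetry_ddG ]

The four auxiliary features historically came from external tools
(mir-scan, contrafold, sfold's sirna module).  Those tools are treated as
opaque feature sources: each has a *provider* slot with a deterministic
built-in stand-in, and genuine tool output can be ingested from a TSV
keyed by the 48-nt context (`ingest_aux_table`).  The built-in stand-ins
are documented in their docstrings and in docs/methods.md; they are this
package's own heuristics, not reimplementations of the external tools.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sequence import GuideCandidate, Transcript, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# 3-dimensional simplex (tetrahedron-vertex) coordinates per base, an
# alternative to the 4-way indicator encoding
_SIMPLEX = {
    "A": (1.0, 1.0, 1.0),
    "C": (1.0, -1.0, -1.0),
    "G": (-1.0, 1.0, -1.0),
    "T": (-1.0, -1.0, 1.0),
}

AUX_FEATURE_NAMES = (
    "sirna_score",
    "accessibility_posterior",
    "duplex_dG",
    "end_asymmetry_ddG",
)


class EncodingError(ValueError):
    pass


class ProviderError(RuntimeError):
    """An auxiliary-feature provider failed or returned a non-finite value."""


class IngestionError(ValueError):
    """An auxiliary-feature table could not be ingested."""


# ---------------------------------------------------------------------------
# positional encoding
# ---------------------------------------------------------------------------

def encode_positional(context48: str, encoding: str = "onehot") -> np.ndarray:
    """Encode the 48-nt context position-by-position.

    ``onehot`` (default): per-position 4-way indicator in base order
    A,C,G,T, position-major — 192 values summing to 48.  ``simplex``: each
    base mapped to a vertex of a regular tetrahedron in 3-D — 144 values.
    """
    if len(context48) != 48:
        raise EncodingError(f"context must be 48 nt, got {len(context48)}")
    if set(context48) - set(BASES):
        raise EncodingError(f"ambiguous base in context {context48!r}")
    if encoding == "onehot":
        vec = np.zeros(48 * 4)
        for pos, base in enumerate(context48):
            vec[pos * 4 + _BASE_INDEX[base]] = 1.0
        return vec
    if encoding == "simplex":
        return np.array([x for base in context48 for x in _SIMPLEX[base]])
    raise ValueError(f"unknown encoding {encoding!r}")


def positional_feature_names(encoding: str = "onehot") -> List[str]:
    if encoding == "onehot":
        return [f"pos{p:02d}_{b}" for p in range(48) for b in BASES]
    if encoding == "simplex":
        return [f"pos{p:02d}_s{k}" for p in range(48) for k in range(3)]
    raise ValueError(f"unknown encoding {encoding!r}")


# ---------------------------------------------------------------------------
# nearest-neighbor thermodynamics
# ---------------------------------------------------------------------------

def load_nn_table(path: Optional[str] = None) -> Dict[str, float]:
    """Load a stack->kcal/mol table (plain text, tab-separated key/value).

    Default: the packaged RNA/RNA Watson-Crick dG37 set of Xia et al. 1998.
    """
    if path is None:
        text = (
            resources.files("mir30design.data")
            .joinpath("nn_rna_xia1998.txt")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    table: Dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, val = line.split()
        table[key] = float(val)
    missing = {a + b for a in BASES for b in BASES} - set(table)
    if missing:
        raise IngestionError(f"NN table missing stacks: {sorted(missing)}")
    return table


_DEFAULT_NN = load_nn_table()


def duplex_delta_g(guide: str, nn_table: Optional[Mapping[str, float]] = None) -> float:
    """Free energy of the full Watson-Crick guide:target duplex.

    Sum of nearest-neighbor stack energies over the ``len(guide) - 1``
    stacks, read 5'->3' along the guide.  Always <= 0 for any standard
    parameter set.
    """
    nn = _DEFAULT_NN if nn_table is None else nn_table
    return sum(nn[guide[i : i + 2]] for i in range(len(guide) - 1))


def end_asymmetry_delta_delta_g(
    guide: str, nn_table: Optional[Mapping[str, float]] = None
) -> float:
    """Thermodynamic end asymmetry of the guide:target duplex.

    dG of the 4 terminal stacks at the guide 5' end minus dG of the 4
    terminal stacks at the guide 3' end.  Positive values mean the 5' end
    is *less* stable — the asymmetry that favors guide-strand loading.
    """
    nn = _DEFAULT_NN if nn_table is None else nn_table
    five = duplex_delta_g(guide[:5], nn)
    three = duplex_delta_g(guide[-5:], nn)
    return five - three


# ---------------------------------------------------------------------------
# built-in auxiliary providers (stand-ins for external tool output)
# ---------------------------------------------------------------------------

#: weights for the rule-based siRNA score; criterion -> points
DEFAULT_SIRNA_WEIGHTS: Dict[str, float] = {
    "gc_window": 1.0,          # guide GC fraction in [0.30, 0.52]
    "at_rich_guide5": 1.0,     # per A/T among the 5 guide-5'-end bases
    "weak_5prime_end": 1.0,    # guide 5'-end 4-stack dG above -6.5 kcal/mol
    "sense_pos3_A": 1.0,       # target (sense) position 3 is A
    "sense_pos10_T": 1.0,      # target position 10 is T (U)
    "sense_pos19_A": 1.0,      # target position 19 is A
    "sense_pos19_GC": -1.0,    # target position 19 is G or C
    "sense_pos13_G": -1.0,     # target position 13 is G
}


def sirna_rule_score(
    candidate: GuideCandidate,
    transcript: Transcript,
    weights: Optional[Mapping[str, float]] = None,
    nn_table: Optional[Mapping[str, float]] = None,
) -> float:
    """Rule-based siRNA potency score (Reynolds-style design criteria).

    Deterministic stand-in for an external siRNA scorer: rewards a
    moderate guide GC fraction, an A/T-rich and thermodynamically weak
    guide 5' end, and the classic position-specific base preferences on
    the sense (target) strand (1-based positions of the target site).
    """
    w = DEFAULT_SIRNA_WEIGHTS if weights is None else weights
    g, t22 = candidate.guide22, candidate.target22
    score = 0.0
    gc = (g.count("G") + g.count("C")) / len(g)
    if 0.30 <= gc <= 0.52:
        score += w["gc_window"]
    score += w["at_rich_guide5"] * sum(b in "AT" for b in g[:5])
    if duplex_delta_g(g[:5], nn_table) > -6.5:
        score += w["weak_5prime_end"]
    if t22[2] == "A":
        score += w["sense_pos3_A"]
    if t22[9] == "T":
        score += w["sense_pos10_T"]
    if t22[18] == "A":
        score += w["sense_pos19_A"]
    if t22[18] in "GC":
        score += w["sense_pos19_GC"]
    if t22[12] == "G":
        score += w["sense_pos13_G"]
    return score


#: window width for the accessibility heuristic
ACCESS_WORD = 8
#: nt of transcript examined on each side of the target site
ACCESS_CONTEXT = 40


def accessibility_heuristic(candidate: GuideCandidate, transcript: Transcript) -> float:
    """Target-site accessibility in [0,1] (structure-engine stand-in).

    Local self-complementarity penalty: of the 15 8-nt windows tiling the
    22-nt target site, count those whose reverse complement occurs within
    the site's +/-40-nt neighborhood on the transcript; accessibility is
    1 minus that fraction.  A site whose every window can pair locally
    scores 0; a site with no local pairing partner scores 1.  This is a
    deterministic heuristic, not a partition-function posterior.
    """
    start = candidate.target_start
    site = candidate.target22
    lo = max(0, start - ACCESS_CONTEXT)
    hi = min(transcript.length, start + len(site) + ACCESS_CONTEXT)
    region = transcript.seq[lo:hi]
    n_windows = len(site) - ACCESS_WORD + 1
    paired = sum(
        reverse_complement(site[i : i + ACCESS_WORD]) in region
        for i in range(n_windows)
    )
    return 1.0 - paired / n_windows


Provider = Callable[[GuideCandidate, Transcript], float]


def builtin_providers(
    nn_table: Optional[Mapping[str, float]] = None,
    sirna_weights: Optional[Mapping[str, float]] = None,
) -> Dict[str, Provider]:
    """The default provider set, one slot per auxiliary feature."""
    return {
        "sirna_score": lambda c, t: sirna_rule_score(c, t, sirna_weights, nn_table),
        "accessibility_posterior": accessibility_heuristic,
        "duplex_dG": lambda c, t: duplex_delta_g(c.guide22, nn_table),
        "end_asymmetry_ddG": lambda c, t: end_asymmetry_delta_delta_g(c.guide22, nn_table),
    }


# ---------------------------------------------------------------------------
# table-backed providers (genuine external-tool output)
# ---------------------------------------------------------------------------

class TableProvider:
    """Serves exact tabulated feature values keyed by context48.

    Built from a TSV with a ``context48`` column and one numeric column
    per feature.  Lookup of an absent key raises :class:`ProviderError`
    (never a silent default); duplicate keys with conflicting values are
    an :class:`IngestionError` at load time.
    """

    def __init__(self, table: pd.DataFrame, feature: str, key_col: str = "context48"):
        if key_col not in table.columns:
            raise IngestionError(f"table lacks key column {key_col!r}")
        if feature not in table.columns:
            raise IngestionError(f"table lacks feature column {feature!r}")
        self.feature = feature
        self._values: Dict[str, float] = {}
        for key, val in zip(table[key_col], table[feature]):
            val = float(val)
            if key in self._values and not math.isclose(
                self._values[key], val, rel_tol=0, abs_tol=1e-12
            ):
                raise IngestionError(
                    f"duplicate key {key!r} with conflicting values "
                    f"{self._values[key]} vs {val} for feature {feature!r}"
                )
            self._values[key] = val

    def __call__(self, candidate, transcript=None) -> float:
        key = candidate if isinstance(candidate, str) else candidate.context48
        try:
            return self._values[key]
        except KeyError:
            raise ProviderError(
                f"provider {self.feature!r}: no tabulated value for key {key!r}"
            ) from None

    def keys(self):
        return self._values.keys()

    def to_frame(self, key_col: str = "context48") -> pd.DataFrame:
        return pd.DataFrame(
            {key_col: list(self._values), self.feature: list(self._values.values())}
        )


def ingest_aux_table(path, features: Optional[Sequence[str]] = None) -> Dict[str, TableProvider]:
    """Load external-tool output into providers, one per feature column."""
    table = pd.read_csv(path, sep="\t")
    if features is None:
        features = [c for c in table.columns if c != "context48"]
    if not features:
        raise IngestionError("aux table has no feature columns")
    return {f: TableProvider(table, f) for f in features}


# ---------------------------------------------------------------------------
# assembled feature vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AuxFeatureSet:
    sirna_score: float
    accessibility_posterior: float
    duplex_dG: float
    end_asymmetry_ddG: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.sirna_score, self.accessibility_posterior,
             self.duplex_dG, self.end_asymmetry_ddG]
        )


def compute_aux_features(
    candidate: GuideCandidate,
    transcript: Transcript,
    providers: Optional[Mapping[str, Provider]] = None,
) -> AuxFeatureSet:
    """Evaluate every auxiliary provider for one candidate.

    ``providers`` maps feature name to a callable; omitted names fall back
    to the built-in stand-ins.  A provider returning a non-finite value is
    a :class:`ProviderError` naming the provider.
    """
    merged = builtin_providers()
    if providers:
        unknown = set(providers) - set(AUX_FEATURE_NAMES)
        if unknown:
            raise ProviderError(f"unknown auxiliary feature(s) {sorted(unknown)}")
        merged.update(providers)
    values = {}
    for name in AUX_FEATURE_NAMES:
        val = float(merged[name](candidate, transcript))
        if not math.isfinite(val):
            raise ProviderError(f"provider {name!r} returned non-finite value {val!r}")
        values[name] = val
    return AuxFeatureSet(**values)


@dataclass(frozen=True)
class FeatureVector:
    names: tuple
    values: np.ndarray
    schema_id: str

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")


def schema_digest(names: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:16]


def feature_names(encoding: str = "onehot") -> List[str]:
    return positional_feature_names(encoding) + list(AUX_FEATURE_NAMES)


def build_feature_vector(
    candidate: GuideCandidate,
    aux: AuxFeatureSet,
    encoding: str = "onehot",
) -> FeatureVector:
    """Concatenate [positional block | aux features] with a stable schema id."""
    names = tuple(feature_names(encoding))
    values = np.concatenate([encode_positional(candidate.context48, encoding), aux.as_array()])
    return FeatureVector(names=names, values=values, schema_id=schema_digest(names))


def feature_matrix(
    candidates: Sequence[GuideCandidate],
    transcript: Transcript,
    providers: Optional[Mapping[str, Provider]] = None,
    encoding: str = "onehot",
) -> np.ndarray:
    """Stack per-candidate feature vectors into an (n, d) matrix."""
    return np.array(
        [
            build_feature_vector(
                c, compute_aux_features(c, transcript, providers), encoding
            ).values
            for c in candidates
        ]
    )
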