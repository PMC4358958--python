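"""Positional encoding, thermodynamic features, and provider plumbing."""

import numpy as np
import pandas as pd
import pytest

from mir30design import (
    build_feature_vector,
    compute_aux_features,
    duplex_delta_g,
    encode_positional,
    end_asymmetry_delta_delta_g,
    ingest_aux_table,
    load_nn_table,
)
from mir30design.features import (
    AUX_FEATURE_NAMES,
    EncodingError,
    IngestionError,
    ProviderError,
    TableProvider,
    feature_names,
    schema_digest,
)
from mir30design.sequence import candidate_from_context

NN = load_nn_table()


def test_onehot_all_a():
    vec = encode_positional("A" * 48)
    assert vec.shape == (192,)
    assert vec.sum() == 48
    assert all(vec[p * 4] == 1 for p in range(48))  # A channel only


def test_onehot_sums_to_48_and_local_difference(rng):
    for _ in range(50):
        ctx = "".join(rng.choice(list("ACGT"), size=48))
        vec = encode_positional(ctx)
        assert vec.sum() == 48
        # mutate exactly one position
        pos = int(rng.integers(0, 48))
        other = rng.choice([b for b in "ACGT" if b != ctx[pos]])
        mut = ctx[:pos] + other + ctx[pos + 1 :]
        diff = np.flatnonzero(encode_positional(mut) != vec)
        assert set(diff) <= set(range(pos * 4, pos * 4 + 4))
        assert len(diff) == 2  # one indicator off, one on


def test_encoding_rejects_bad_input():
    with pytest.raises(EncodingError):
        encode_positional("A" * 47)
    with pytest.raises(EncodingError):
        encode_positional("A" * 47 + "N")


def test_simplex_encoding_dimensions():
    vec = encode_positional("ACGT" * 12, encoding="simplex")
    assert vec.shape == (144,)
    # tetrahedron vertices are unit-distance-equivalent: all norms equal
    norms = vec.reshape(48, 3)
    assert np.allclose((norms ** 2).sum(axis=1), 3.0)


def test_duplex_dg_all_g_hand_sum():
    assert duplex_delta_g("G" * 22) == pytest.approx(21 * NN["GG"])


def test_duplex_dg_au_weaker_than_gc():
    assert duplex_delta_g("A" * 22) > duplex_delta_g("G" * 22)
    assert duplex_delta_g("A" * 22) < 0  # still stable overall


def test_duplex_dg_monotone_in_gc_content(rng):
    """Swapping any A/T for G/C never destabilizes the duplex."""
    for _ in range(50):
        guide = "".join(rng.choice(list("ACGT"), size=22))
        base_dg = duplex_delta_g(guide)
        for pos in range(22):
            if guide[pos] in "AT":
                for new in "GC":
                    mut = guide[:pos] + new + guide[pos + 1 :]
                    assert duplex_delta_g(mut) <= base_dg + 1e-12


def test_end_asymmetry_zero_for_identical_ends():
    g = "GCATT" + "A" * 12 + "GCATT"
    assert end_asymmetry_delta_delta_g(g) == pytest.approx(0.0)
    # AT-rich 5' end vs GC-rich 3' end -> positive ddG (weak 5' end)
    g2 = "ATATA" + "C" * 12 + "GCGCG"
    assert end_asymmetry_delta_delta_g(g2) > 0


def test_nn_table_symmetric_under_reverse_complement():
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for k, v in NN.items():
        rc = comp[k[1]] + comp[k[0]]
        assert NN[rc] == v


def test_aux_features_finite_and_deterministic(candidates, transcript):
    c = candidates[0]
    a1 = compute_aux_features(c, transcript)
    a2 = compute_aux_features(c, transcript)
    assert a1 == a2
    assert 0.0 <= a1.accessibility_posterior <= 1.0
    assert a1.duplex_dG < 0


def test_provider_nonfinite_rejected(candidates, transcript):
    with pytest.raises(ProviderError, match="sirna_score"):
        compute_aux_features(
            candidates[0], transcript, {"sirna_score": lambda c, t: float("nan")}
        )
    with pytest.raises(ProviderError):
        compute_aux_features(candidates[0], transcript, {"bogus_feature": lambda c, t: 1.0})


def test_feature_vector_shape_and_determinism(candidates, transcript):
    c = candidates[0]
    aux = compute_aux_features(c, transcript)
    v1 = build_feature_vector(c, aux)
    v2 = build_feature_vector(c, aux)
    assert len(v1.names) == len(v1.values) == 196
    assert np.array_equal(v1.values, v2.values)
    assert v1.schema_id == v2.schema_id
    assert v1.values[:192].sum() == 48


def test_schema_id_tracks_feature_set():
    onehot = schema_digest(feature_names("onehot"))
    simplex = schema_digest(feature_names("simplex"))
    assert onehot != simplex
    assert schema_digest(list(feature_names("onehot")) + ["extra"]) != onehot


def test_table_provider_passthrough_and_missing_key(candidates):
    key = candidates[0].context48
    table = pd.DataFrame({"context48": [key], "sirna_score": [0.5]})
    provider = TableProvider(table, "sirna_score")
    assert provider(key) == 0.5
    assert provider(candidates[0]) == 0.5
    with pytest.raises(ProviderError):
        provider("T" * 48)


def test_table_provider_conflicting_duplicates():
    table = pd.DataFrame({"context48": ["A" * 48, "A" * 48], "x": [1.0, 2.0]})
    with pytest.raises(IngestionError):
        TableProvider(table, "x")
    # consistent duplicates are fine
    ok = pd.DataFrame({"context48": ["A" * 48, "A" * 48], "x": [1.0, 1.0]})
    assert TableProvider(ok, "x")("A" * 48) == 1.0


def test_aux_table_round_trip(tmp_path, candidates):
    keys = [c.context48 for c in candidates[:5]]
    table = pd.DataFrame({"context48": keys, "accessibility_posterior": np.linspace(0, 1, 5)})
    path = tmp_path / "aux.tsv"
    table.to_csv(path, sep="\t", index=False)
    providers = ingest_aux_table(path)
    assert set(providers) == {"accessibility_posterior"}
    rewritten = tmp_path / "aux2.tsv"
    providers["accessibility_posterior"].to_frame().to_csv(rewritten, sep="\t", index=False)
    again = ingest_aux_table(rewritten)["accessibility_posterior"]
    for k in keys:
        assert again(k) == providers["accessibility_posterior"](k)


def test_ingested_provider_feeds_feature_vector(candidates, transcript):
    c = candidates[0]
    table = pd.DataFrame({"context48": [c.context48], "sirna_score": [3.25]})
    aux = compute_aux_features(c, transcript, {"sirna_score": TableProvider(table, "sirna_score")})
    assert aux.sirna_score == 3.25
    assert tuple(AUX_FEATURE_NAMES)[0] == "sirna_score"
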