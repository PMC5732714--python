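"""RSS, normalized RSS, NMD, and SimNMD formula behavior."""

import math
import random

import pytest

from cooclink import nmd, normalize_rss, rss, score_all, sim_nmd
from cooclink.cooccur import CooccurrenceIndex
from cooclink.errors import (
    DegenerateCorpusError,
    InputError,
    NotScorableError,
)
from cooclink.scoring import PairScoreTable

from conftest import make_index


@pytest.fixture
def two_pair_index():
    """COV triples (10,100,1000) and (100,100,1000): raw RSS -4 and -3."""
    return make_index(
        pair_counts={("t1", "t2"): 10, ("t1", "t3"): 100},
        sent_counts={"t1": 100, "t2": 1000, "t3": 1000},
    )


def test_rss_hand_value(two_pair_index):
    assert rss(two_pair_index, "t1", "t2") == pytest.approx(-4.0, abs=1e-12)
    assert rss(two_pair_index, "t1", "t3") == pytest.approx(-3.0, abs=1e-12)


def test_rss_self_pair():
    index = make_index(pair_counts={}, sent_counts={"t": 100})
    assert rss(index, "t", "t") == pytest.approx(-2.0, abs=1e-12)


def test_rss_symmetry(two_pair_index):
    assert rss(two_pair_index, "t1", "t2") == rss(two_pair_index, "t2", "t1")


def test_zero_cov_not_scorable(two_pair_index):
    with pytest.raises(NotScorableError):
        rss(two_pair_index, "t2", "t3")


def test_normalization_endpoints_and_midpoint():
    raw = PairScoreTable(method="RSS",
                         scores={("a", "b"): -4.0, ("a", "c"): -2.0,
                                 ("b", "c"): -3.0})
    table = normalize_rss(raw)
    assert table.scores[("a", "b")] == pytest.approx(1.0, abs=1e-12)
    assert table.scores[("a", "c")] == pytest.approx(100.0, abs=1e-12)
    assert table.scores[("b", "c")] == pytest.approx(50.5, abs=1e-12)
    assert (table.rss_min, table.rss_max) == (-4.0, -2.0)


def test_degenerate_normalization_warns():
    raw = PairScoreTable(method="RSS", scores={("a", "b"): -2.0,
                                               ("a", "c"): -2.0})
    with pytest.warns(UserWarning, match="identical"):
        table = normalize_rss(raw)
    assert set(table.scores.values()) == {100.0}


def test_nmd_hand_value():
    index = make_index(pair_counts={("t1", "t2"): 50},
                       sent_counts={"t1": 100, "t2": 100}, M=1000)
    expected = (math.log10(100) - math.log10(50)) / (
        math.log10(1000) - math.log10(100))
    assert nmd(index, "t1", "t2") == pytest.approx(expected, abs=1e-12)
    assert nmd(index, "t1", "t2") == pytest.approx(0.30103, abs=1e-5)


def test_nmd_identity_and_containment():
    index = make_index(pair_counts={("t1", "t2"): 40},
                       sent_counts={"t1": 40, "t2": 40}, M=1000)
    assert nmd(index, "t1", "t1") == 0.0
    assert nmd(index, "t1", "t2") == 0.0  # D12 = D1 = D2


def test_nmd_degenerate_corpus():
    index = make_index(pair_counts={("t1", "t2"): 5},
                       sent_counts={"t1": 10, "t2": 10}, M=10)
    with pytest.raises(DegenerateCorpusError):
        nmd(index, "t1", "t2")


def test_sim_nmd_transform():
    assert sim_nmd(0.0) == 1.0
    assert sim_nmd(0.30103) == pytest.approx(0.69897, abs=1e-12)
    assert sim_nmd(1.7) == 0.0
    with pytest.raises(InputError):
        sim_nmd(-0.1)


def test_score_all_rss_n_bounds(two_pair_index):
    table = score_all(two_pair_index, "RSS_N")
    assert len(table) == 2
    assert max(table.scores.values()) == pytest.approx(100.0)
    assert min(table.scores.values()) == pytest.approx(1.0)
    assert table.method == "RSS_N"


def test_score_all_sim_nmd_range(two_pair_index):
    table = score_all(two_pair_index, "SIM_NMD")
    assert all(0.0 <= v <= 1.0 for v in table.scores.values())


def test_min_cov_restriction_renormalizes():
    index = make_index(
        pair_counts={("a", "b"): 1, ("a", "c"): 5, ("b", "c"): 20},
        sent_counts={"a": 50, "b": 60, "c": 70}, M=500,
        pair_doc_counts={("a", "b"): 1, ("a", "c"): 5, ("b", "c"): 20},
        doc_counts={"a": 40, "b": 50, "c": 60},
    )
    full_nmd = score_all(index, "NMD", min_cov=1)
    part_nmd = score_all(index, "NMD", min_cov=5)
    for pair in part_nmd.scores:
        assert part_nmd.scores[pair] == full_nmd.scores[pair]
    full_n = score_all(index, "RSS_N", min_cov=1)
    part_n = score_all(index, "RSS_N", min_cov=5)
    assert part_n.scores[("a", "c")] != full_n.scores[("a", "c")]
    assert part_n.scores[("a", "c")] == pytest.approx(1.0)


def test_empty_pair_list_warns():
    index = make_index(pair_counts={}, sent_counts={"t": 10})
    with pytest.warns(UserWarning, match="no pairs"):
        table = score_all(index, "RSS")
    assert len(table) == 0


def test_unknown_method_rejected(two_pair_index):
    with pytest.raises(InputError):
        score_all(two_pair_index, "EMI")


def test_rss_monotone_in_joint_count():
    previous = -math.inf
    for cov12 in (1, 5, 20, 50):
        index = make_index(pair_counts={("a", "b"): cov12},
                           sent_counts={"a": 100, "b": 100})
        value = rss(index, "a", "b")
        assert value > previous
        previous = value


def test_nmd_monotone_decreasing_in_joint_doc_count():
    previous = math.inf
    for d12 in (1, 5, 20, 50):
        index = make_index(pair_counts={("a", "b"): d12},
                           sent_counts={"a": 100, "b": 100}, M=10_000)
        value = nmd(index, "a", "b")
        assert value < previous
        previous = value


def test_nmd_direction_when_corpus_grows():
    small = make_index(pair_counts={("a", "b"): 10},
                       sent_counts={"a": 100, "b": 100}, M=1000)
    large = make_index(pair_counts={("a", "b"): 10},
                       sent_counts={"a": 100, "b": 100}, M=100_000)
    # extra unrelated documents enlarge the denominator, shrinking NMD
    assert nmd(large, "a", "b") < nmd(small, "a", "b")


def test_rss_and_sim_nmd_rank_agreement_with_equal_marginals():
    rng = random.Random(4)
    pairs = {(f"p{i}", f"q{i}"): rng.randint(1, 40) for i in range(12)}
    counts = {t: 50 for pair in pairs for t in pair}
    index = make_index(pair_counts=pairs, sent_counts=counts, M=5000)
    rss_table = score_all(index, "RSS")
    sim_table = score_all(index, "SIM_NMD")
    order = sorted(pairs)
    rss_rank = sorted(order, key=lambda p: rss_table.scores[p])
    sim_rank = sorted(order, key=lambda p: sim_table.scores[p])
    assert rss_rank == sim_rank


def test_score_table_roundtrip(tmp_path, two_pair_index):
    from cooclink.scoring import read_scores, write_scores

    table = score_all(two_pair_index, "RSS_N")
    path = tmp_path / "scores.tsv"
    write_scores(table, path)
    again = read_scores(path)
    assert again.method == table.method
    assert again.scores == table.scores
    assert again.rss_min == table.rss_min
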