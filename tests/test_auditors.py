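"""Auditor mechanics: recurrence scoring, degree features, balancing,
masking determinism and the framework orchestration."""

import itertools

import numpy as np
import pytest

from pairaudit.auditors import (
    AuditResult,
    RecurrencePair,
    benchmark,
    debias_audit,
    default_balance_candidates,
    degree_pair_features,
    feature_audit,
    generalizability_audit,
    node_balanced_subsample,
    node_degree_audit,
    recurrence_audit,
    recurrence_score,
    run_framework,
)
from pairaudit.core import (
    InteractionDataset,
    PairAuditError,
    PairExample,
    Protein,
    compute_degree_table,
)
from pairaudit.features import conjoint_triad_features
from pairaudit.models import RandomForestAdapter
from pairaudit.splitting import split_in_network
from pairaudit.synthetic import SyntheticConfig, generate_interactions, generate_proteome

FAST_GRID = [{"n_estimators": 20}]


def forest(**hp):
    hp.setdefault("n_estimators", 20)
    return RandomForestAdapter(**hp)


@pytest.fixture(scope="module")
def biased_rounds():
    """A small hub-biased dataset split into 3 rounds (shared, read-only)."""
    # universe large enough that every hub can be degree-balanced
    cfg = SyntheticConfig(n_proteins=120, n_pos=250, seq_len=(20, 40),
                          bias_beta=1.0, seed=13, name="small_bias")
    reg = generate_proteome(cfg)
    ds = generate_interactions(reg, cfg)
    return reg, ds, split_in_network(ds, rounds=3, seed=13)


# ---------------------------------------------------------------------------
# Recurrence scoring
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("degrees,expected", [
    ((3, 1, 1, 3), 0.5),
    ((0, 2, 0, 1), 0.0),
    ((5, 1, 2, 0), 0.875),
    ((0, 0, 0, 0), 0.5),   # both proteins unseen in training
    ((2, 2, 3, 3), 0.5),   # per-protein balanced degrees
])
def test_recurrence_score_values(degrees, expected):
    assert recurrence_score(RecurrencePair(*degrees)) == pytest.approx(expected)


def test_recurrence_score_protein_swap_invariant():
    for a_pos, a_neg, b_pos, b_neg in itertools.product(range(4), repeat=4):
        s1 = recurrence_score(RecurrencePair(a_pos, a_neg, b_pos, b_neg))
        s2 = recurrence_score(RecurrencePair(b_pos, b_neg, a_pos, a_neg))
        assert s1 == s2
        assert 0 <= s1 <= 1


def test_recurrence_score_rejects_negative_degree():
    with pytest.raises(PairAuditError):
        recurrence_score(RecurrencePair(-1, 0, 0, 0))


# ---------------------------------------------------------------------------
# Degree pair features
# ---------------------------------------------------------------------------

def test_degree_pair_features_lookup(toy_registry):
    pairs = [PairExample.make("P1", "P2", 1), PairExample.make("P1", "P3", 1),
             PairExample.make("P2", "P3", 0)]
    dt = compute_degree_table(InteractionDataset(toy_registry, pairs, "train"))
    v = degree_pair_features(dt, PairExample.make("P1", "P2", 1))
    np.testing.assert_array_equal(v, [2, 0, 1, 1])
    assert v.shape == (4,)
    absent = degree_pair_features(dt, PairExample.make("P4", "P5", 0))
    np.testing.assert_array_equal(absent, [0, 0, 0, 0])


# ---------------------------------------------------------------------------
# Node-balanced subsampling
# ---------------------------------------------------------------------------

def _registry(ids):
    return {p: Protein(p, "ACDEFGHIKL") for p in ids}


def exhaustive_best_balance(positives, candidates):
    """Oracle: smallest residual over all candidate subsets."""
    d_pos = {}
    for a, b in positives:
        d_pos[a] = d_pos.get(a, 0) + 1
        d_pos[b] = d_pos.get(b, 0) + 1
    best = None
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            d_neg = {}
            for a, b in combo:
                d_neg[a] = d_neg.get(a, 0) + 1
                d_neg[b] = d_neg.get(b, 0) + 1
            resid = sum(abs(d_pos.get(p, 0) - d_neg.get(p, 0))
                        for p in set(d_pos) | set(d_neg))
            if best is None or resid < best:
                best = resid
    return best


def test_balance_worked_example_is_perfect():
    reg = _registry("ABCD")
    train = InteractionDataset(
        reg, [PairExample.make("A", "B", 1), PairExample.make("C", "D", 1)], "t")
    candidates = [("A", "C"), ("B", "D"), ("A", "D"), ("B", "C")]
    assert exhaustive_best_balance([("A", "B"), ("C", "D")], candidates) == 0
    balanced, residual = node_balanced_subsample(train, candidates, seed=0)
    assert residual == {}
    dt = compute_degree_table(balanced)
    for p in "ABCD":
        d_pos, d_neg = dt.degrees(p)
        assert d_pos == d_neg == 1


def test_balance_already_balanced_fixed_point():
    reg = _registry("ABCD")
    train = InteractionDataset(
        reg, [PairExample.make("A", "B", 1), PairExample.make("C", "D", 1)], "t")
    balanced, residual = node_balanced_subsample(
        train, [("A", "C"), ("B", "D")], seed=1)
    assert residual == {}
    assert {p.key for p in balanced.negatives()} == {("A", "C"), ("B", "D")}


def test_balance_star_infeasibility_reported():
    ids = ["H"] + [f"X{i}" for i in range(1, 6)] + ["Y1", "Y2"]
    reg = _registry(ids)
    positives = [PairExample.make("H", f"X{i}", 1) for i in range(1, 6)]
    train = InteractionDataset(reg, positives, "t")
    candidates = [("H", "Y1"), ("H", "Y2")]  # only 2 negatives touch H
    with pytest.raises(PairAuditError):
        node_balanced_subsample(train, [], seed=0)
    balanced, residual = node_balanced_subsample(train, candidates, seed=0)
    assert residual["H"] >= 3


def test_balance_rejects_positive_candidate():
    reg = _registry("ABCD")
    train = InteractionDataset(reg, [PairExample.make("A", "B", 1)], "t")
    with pytest.raises(PairAuditError, match="positive"):
        node_balanced_subsample(train, [("B", "A")], seed=0)


def test_balance_deterministic(biased_rounds):
    _, ds, rounds = biased_rounds
    cands = default_balance_candidates(ds, rounds)[0]
    b1, r1 = node_balanced_subsample(rounds[0].train, cands, seed=3)
    b2, r2 = node_balanced_subsample(rounds[0].train, cands, seed=3)
    assert b1.pair_keys() == b2.pair_keys()
    assert r1 == r2


def test_balance_zeroes_recurrence_signal(biased_rounds):
    """With empty residual every in-network pair scores exactly 0.5."""
    _, ds, rounds = biased_rounds
    cands = default_balance_candidates(ds, rounds)[0]
    balanced, residual = node_balanced_subsample(rounds[0].train, cands, seed=3)
    assert sum(residual.values()) <= 4  # parity leftovers at most
    dt = compute_degree_table(balanced)
    scores = []
    for p in rounds[0].test.pairs:
        a_pos, a_neg = dt.degrees(p.a)
        b_pos, b_neg = dt.degrees(p.b)
        if a_pos == a_neg and b_pos == b_neg:
            scores.append(recurrence_score(RecurrencePair(a_pos, a_neg, b_pos, b_neg)))
    assert scores and all(s == 0.5 for s in scores)


# ---------------------------------------------------------------------------
# AuditResult bookkeeping
# ---------------------------------------------------------------------------

def test_audit_result_delta_recomputable():
    r = AuditResult("x", [0.8, 0.9], reference_auc=0.6, verdict="inconclusive",
                    tolerance=0.05)
    assert r.mean_auc == pytest.approx(0.85)
    assert r.delta == pytest.approx(0.25)
    d = r.to_dict()
    assert d["delta"] == pytest.approx(d["mean_auc"] - d["reference_auc"])


# ---------------------------------------------------------------------------
# Auditor behavior on the small biased network
# ---------------------------------------------------------------------------

def test_benchmark_bookkeeping(biased_rounds):
    reg, _, rounds = biased_rounds
    fm = conjoint_triad_features(reg)
    res, adapters = benchmark(forest, FAST_GRID, rounds, fm, seed=2)
    assert len(res.per_round_auc) == len(rounds) == len(adapters)
    assert res.verdict == "inconclusive"
    assert res.mean_auc > 0.6  # planted hub bias is learnable


def test_feature_audit_deterministic(biased_rounds):
    reg, _, rounds = biased_rounds
    r1 = feature_audit(forest, FAST_GRID, rounds, reg, conjoint_triad_features, seed=2)
    r2 = feature_audit(forest, FAST_GRID, rounds, reg, conjoint_triad_features, seed=2)
    assert r1.per_round_auc == r2.per_round_auc


def test_degree_auditor_feature_dimension_is_four(biased_rounds):
    _, _, rounds = biased_rounds
    captured = {}

    class Probe(RandomForestAdapter):
        def _fit(self, X, y, seed):
            captured["dim"] = X.shape[1]
            super()._fit(X, y, seed)

    node_degree_audit(lambda: Probe(n_estimators=5), rounds, seed=0,
                      reference_auc=0.8)
    assert captured["dim"] == 4


def test_recurrence_audit_needs_no_learner(biased_rounds):
    _, _, rounds = biased_rounds
    res = recurrence_audit(rounds, reference_auc=0.8)
    assert len(res.per_round_auc) == len(rounds)
    assert res.mean_auc > 0.6  # degree leakage alone ranks test pairs


def test_generalizability_self_comparison_is_zero_delta(biased_rounds):
    """Foreign identical to the home test set reproduces home AUC exactly."""
    reg, _, rounds = biased_rounds
    fm = conjoint_triad_features(reg)
    res, adapters = benchmark(forest, FAST_GRID, rounds[:1], fm, seed=2)
    foreign = rounds[0].test
    gen = generalizability_audit(adapters, rounds[:1], foreign, fm, fm,
                                 mode="in_network", seed=2)
    assert gen.delta == pytest.approx(0.0, abs=1e-12)
    assert gen.verdict == "no_bias_indicated"


def test_generalizability_empty_filter_errors(biased_rounds):
    reg, _, rounds = biased_rounds
    fm = conjoint_triad_features(reg)
    _, adapters = benchmark(forest, FAST_GRID, rounds[:1], fm, seed=2)
    foreign = rounds[0].test
    with pytest.raises(PairAuditError, match="0 foreign pairs"):
        generalizability_audit(adapters, rounds[:1], foreign, fm, fm,
                               mode="out_of_network", seed=2)


def test_debias_audit_requires_pool_per_round(biased_rounds):
    reg, ds, rounds = biased_rounds
    with pytest.raises(PairAuditError, match="per round"):
        debias_audit(forest, FAST_GRID, rounds, reg, conjoint_triad_features,
                     [[("A", "B")]], seed=0)


def test_run_framework_report_order(biased_rounds):
    reg, ds, rounds = biased_rounds
    results, narrative = run_framework(
        reg, rounds, forest, FAST_GRID, conjoint_triad_features, seed=2,
        auditors=("benchmark", "feature", "node_degree", "recurrence", "debias"),
        dataset=ds)
    names = [r.auditor for r in results]
    assert names == ["benchmark", "feature_masking", "node_degree",
                     "recurrence", "debias_masked"]
    assert isinstance(narrative, str) and "Benchmark" in narrative


def test_run_framework_short_circuit_on_clean_features():
    cfg = SyntheticConfig(n_proteins=80, n_pos=250, seq_len=(20, 40),
                          bias_beta=0.0, signal="motif", noise_eps=0.05,
                          neg_scheme="degree_matched", seed=21, name="sig")
    reg = generate_proteome(cfg)
    ds = generate_interactions(reg, cfg)
    rounds = split_in_network(ds, rounds=2, seed=21)
    results, narrative = run_framework(
        reg, rounds, forest, FAST_GRID, conjoint_triad_features, seed=21,
        auditors=("benchmark", "feature", "recurrence", "debias"),
        dataset=ds, short_circuit=True)
    names = [r.auditor for r in results]
    assert names == ["benchmark", "feature_masking"]  # cycle resolved early
    assert "sequence features" in narrative
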