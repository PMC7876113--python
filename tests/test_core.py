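"""Core data model: I/O, canonicalization, degrees, sampling, AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pairaudit.core import (
    InteractionDataset,
    PairAuditError,
    PairExample,
    Protein,
    auc,
    canonical,
    compute_degree_table,
    group_based_negative_sampling,
    pkd_from_kd,
    random_negative_sampling,
    read_fasta,
    read_pairs,
    write_pairs,
)


# ---------------------------------------------------------------------------
# Protein / pair invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pid,seq", [
    ("", "ACD"), ("has space", "ACD"), ("P1", "AC"), ("P1", "ACDXZ"),
])
def test_protein_invariants_rejected(pid, seq):
    with pytest.raises(PairAuditError):
        Protein(pid, seq)


def test_pair_canonicalization():
    p = PairExample.make("P2", "P1", 1)
    assert (p.a, p.b) == ("P1", "P2")
    assert canonical("B", "A") == ("A", "B")
    with pytest.raises(PairAuditError):
        PairExample("P2", "P1", 1)  # non-canonical direct construction


def test_dataset_rejects_conflicting_duplicates(toy_registry):
    pairs = [PairExample.make("P1", "P2", 1), PairExample.make("P2", "P1", 0)]
    with pytest.raises(PairAuditError, match="conflicting"):
        InteractionDataset(toy_registry, pairs)


def test_dataset_rejects_unknown_protein(toy_registry):
    with pytest.raises(PairAuditError, match="P9"):
        InteractionDataset(toy_registry, [PairExample.make("P1", "P9", 1)])


# ---------------------------------------------------------------------------
# FASTA and pair TSV I/O
# ---------------------------------------------------------------------------

def test_read_fasta_parsing(tmp_path):
    f = tmp_path / "t.fasta"
    f.write_text(">P1 some description\nacdef\n>P2\nKLMNP\n")
    reg = read_fasta(f)
    assert set(reg) == {"P1", "P2"}
    assert reg["P1"].sequence == "ACDEF"  # tokenized id, upper-cased


def test_read_fasta_duplicate_and_empty(tmp_path):
    dup = tmp_path / "dup.fasta"
    dup.write_text(">P1\nACDEF\n>P1\nKLMNP\n")
    with pytest.raises(PairAuditError, match="P1"):
        read_fasta(dup)
    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    with pytest.raises(PairAuditError):
        read_fasta(empty)


def test_read_fasta_residue_policy(tmp_path):
    f = tmp_path / "t.fasta"
    f.write_text(">P1\nACXDEF\n")
    assert read_fasta(f, residue_policy="drop")["P1"].sequence == "ACDEF"
    with pytest.raises(PairAuditError):
        read_fasta(f, residue_policy="error")


def test_read_pairs_label_mode(tmp_path, toy_registry):
    f = tmp_path / "pairs.tsv"
    f.write_text("a\tb\tlabel\n# comment\nP2\tP1\t1\nP1\tP3\t0\n")
    ds = read_pairs(f, toy_registry)
    keys = {(p.a, p.b): p.label for p in ds.pairs}
    assert keys == {("P1", "P2"): 1, ("P1", "P3"): 0}


def test_read_pairs_affinity_threshold(tmp_path, toy_registry):
    f = tmp_path / "aff.tsv"
    f.write_text("a\tb\taffinity\nP1\tP2\t6.8\nP1\tP3\t5.0\n")
    ds = read_pairs(f, toy_registry, threshold=6.3)
    labels = {(p.a, p.b): p.label for p in ds.pairs}
    assert labels == {("P1", "P2"): 1, ("P1", "P3"): 0}
    with pytest.raises(PairAuditError, match="threshold"):
        read_pairs(f, toy_registry)


def test_read_pairs_conflicting_duplicate(tmp_path, toy_registry):
    f = tmp_path / "bad.tsv"
    f.write_text("a\tb\tlabel\nP1\tP2\t1\nP2\tP1\t0\n")
    with pytest.raises(PairAuditError, match="conflicting"):
        read_pairs(f, toy_registry)


def test_pair_tsv_roundtrip(tmp_path, toy_dataset):
    """Reading, writing and re-reading a pair TSV is idempotent."""
    f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_pairs(toy_dataset, f1)
    ds = read_pairs(f1, toy_dataset.proteins)
    write_pairs(ds, f2)
    assert f1.read_text() == f2.read_text()
    assert ds.pair_keys() == toy_dataset.pair_keys()


# ---------------------------------------------------------------------------
# pK_d conversion
# ---------------------------------------------------------------------------

def test_pkd_from_kd_values():
    assert round(pkd_from_kd(5e-7), 1) == 6.3  # 500 nM
    assert pkd_from_kd(1.0) == 0.0
    assert pkd_from_kd(1e-9) == pytest.approx(9.0)
    with pytest.raises(PairAuditError):
        pkd_from_kd(0.0)


# ---------------------------------------------------------------------------
# Degree table
# ---------------------------------------------------------------------------

def test_degree_table_hand_count(toy_registry):
    pairs = [PairExample.make("P1", "P2", 1), PairExample.make("P1", "P3", 1),
             PairExample.make("P2", "P3", 0)]
    dt = compute_degree_table(InteractionDataset(toy_registry, pairs, "train"))
    assert dt.degrees("P1") == (2, 0)
    assert dt.degrees("P2") == (1, 1)
    assert dt.degrees("P3") == (1, 1)
    assert dt.degrees("P4") == (0, 0)  # registered but pairless
    assert dt.source == "train"


def test_degree_table_self_pair(toy_registry):
    ds = InteractionDataset(toy_registry, [PairExample.make("P1", "P1", 1)])
    assert compute_degree_table(ds).degrees("P1") == (2, 0)


def test_degree_table_empty(toy_registry):
    dt = compute_degree_table(InteractionDataset(toy_registry, []))
    assert all(dt.degrees(p) == (0, 0) for p in toy_registry)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 7), st.integers(0, 7), st.booleans()),
                max_size=40))
def test_degree_conservation(raw_pairs):
    """sum(d_pos) == 2*|positives| and sum(d_neg) == 2*|negatives|."""
    registry = {f"Q{i}": Protein(f"Q{i}", "ACDEFGH") for i in range(8)}
    seen, pairs = set(), []
    for i, j, lab in raw_pairs:
        key = canonical(f"Q{i}", f"Q{j}")
        if key in seen:
            continue
        seen.add(key)
        pairs.append(PairExample(*key, int(lab)))
    ds = InteractionDataset(registry, pairs)
    dt = compute_degree_table(ds)
    assert sum(dt.d_pos.values()) == 2 * len(ds.positives())
    assert sum(dt.d_neg.values()) == 2 * len(ds.negatives())


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------

def test_random_negatives_small_universe():
    registry = {p: Protein(p, "ACDEFG") for p in ("P1", "P2", "P3")}
    got = random_negative_sampling(registry, {("P1", "P2")}, 2, seed=0)
    assert {g.key for g in got} == {("P1", "P3"), ("P2", "P3")}


def test_random_negatives_exhaustion_and_error():
    registry = {p: Protein(p, "ACDEFG") for p in ("P1", "P2", "P3", "P4")}
    positives = {("P1", "P2")}
    full = random_negative_sampling(registry, positives, 5, seed=1)
    assert len({g.key for g in full}) == 5  # C(4,2) - 1
    with pytest.raises(PairAuditError, match="5"):
        random_negative_sampling(registry, positives, 6, seed=1)


def test_random_negatives_deterministic():
    registry = {f"P{i}": Protein(f"P{i}", "ACDEFG") for i in range(20)}
    a = random_negative_sampling(registry, set(), 30, seed=42)
    b = random_negative_sampling(registry, set(), 30, seed=42)
    c = random_negative_sampling(registry, set(), 30, seed=43)
    assert a == b
    assert a != c


def test_group_based_negatives():
    registry = {p: Protein(p, "ACDEFG") for p in ("P1", "P2", "P3")}
    tags = {"P1": {"nucleus"}, "P2": {"nucleus"}, "P3": {"cytoplasm"}}
    got = group_based_negative_sampling(registry, tags, set(), 2, seed=0)
    assert {g.key for g in got} == {("P1", "P3"), ("P2", "P3")}
    shared = {p: {"nucleus"} for p in registry}
    with pytest.raises(PairAuditError, match="0"):
        group_based_negative_sampling(registry, shared, set(), 1, seed=0)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def brute_force_auc(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_examples():
    assert auc([0.9, 0.4], [0.5, 0.1]) == pytest.approx(0.75)
    assert auc([0.3] * 5, [0.3] * 7) == pytest.approx(0.5)
    assert auc([0.8, 0.9], [0.1, 0.2]) == 1.0
    with pytest.raises(PairAuditError):
        auc([], [0.1])


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.integers(1, 60), st.integers(1, 60), st.integers(0, 10**6),
       st.booleans())
def test_auc_matches_brute_force(n_pos, n_neg, seed, coarse):
    """Midrank AUC equals the double loop over all pos-neg comparisons."""
    rng = np.random.default_rng(seed)
    pos = rng.random(n_pos)
    neg = rng.random(n_neg)
    if coarse:  # force ties
        pos, neg = np.round(pos, 1), np.round(neg, 1)
    assert auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
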