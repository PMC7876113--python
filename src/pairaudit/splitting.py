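"""Train/validation/test split construction for paired-input data.

Two membership regimes matter for paired-input evaluation:

* in-network — every protein occurring in a test pair also occurs in
  at least one training pair (the regime under which node-degree
  leakage can inflate performance);
* out-of-network — no test-pair protein occurs in any training pair
  (the cold-start regime, where per-entity memorization cannot help).

Datasets are split into R independent rounds (default 10); each round
keeps its three subsets pair-disjoint and class-balanced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    InteractionDataset,
    PairAuditError,
    PairExample,
    read_pairs,
    stable_subseed,
    write_pairs,
)

logger = logging.getLogger(__name__)

IN_NETWORK = "in_network"
OUT_OF_NETWORK = "out_of_network"

DEFAULT_FRACTIONS = (0.70, 0.10, 0.20)
DEFAULT_ROUNDS = 10


@dataclass
class SplitRound:
    """One train/validation/test split plus its provenance."""

    round_index: int
    train: InteractionDataset
    validation: InteractionDataset
    test: InteractionDataset
    mode: str
    removed: dict[str, int] = field(default_factory=dict)

    def check_invariants(self) -> None:
        tr, va, te = self.train.pair_keys(), self.validation.pair_keys(), self.test.pair_keys()
        if tr & va or tr & te or va & te:
            raise PairAuditError(f"round {self.round_index}: pair leakage across subsets")
        train_prot = self.train.protein_ids_in_pairs()
        test_prot = self.test.protein_ids_in_pairs()
        if self.mode == IN_NETWORK:
            missing = test_prot - train_prot
            if missing:
                raise PairAuditError(
                    f"round {self.round_index}: in-network violated for {sorted(missing)[:5]}")
        elif self.mode == OUT_OF_NETWORK:
            overlap = test_prot & train_prot
            if overlap:
                raise PairAuditError(
                    f"round {self.round_index}: out-of-network violated for {sorted(overlap)[:5]}")
        for name, subset in (("train", self.train), ("validation", self.validation),
                             ("test", self.test)):
            if not subset.is_balanced:
                raise PairAuditError(f"round {self.round_index}: {name} not class-balanced")


def _check_fractions(fractions) -> tuple[float, float, float]:
    f = tuple(float(x) for x in fractions)
    if len(f) != 3 or any(x <= 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
        raise PairAuditError(f"fractions must be 3 positive numbers summing to 1, got {fractions}")
    return f


def _partition_counts(n: int, fractions) -> tuple[int, int, int]:
    n_tr = int(round(fractions[0] * n))
    n_va = int(round(fractions[1] * n))
    n_tr = min(n_tr, n)
    n_va = min(n_va, n - n_tr)
    return n_tr, n_va, n - n_tr - n_va


def _downsample_balance(pairs: list[PairExample], rng) -> tuple[list[PairExample], int]:
    """Down-sample the majority label to equalize class counts."""
    pos = [p for p in pairs if p.label == 1]
    neg = [p for p in pairs if p.label == 0]
    k = min(len(pos), len(neg))
    removed = len(pairs) - 2 * k

    def take(group):
        if len(group) == k:
            return group
        idx = rng.choice(len(group), size=k, replace=False)
        return [group[i] for i in sorted(idx)]

    return take(pos) + take(neg), removed


def split_in_network(data: InteractionDataset,
                     rounds: int = DEFAULT_ROUNDS,
                     fractions=DEFAULT_FRACTIONS,
                     seed: int = 0) -> list[SplitRound]:
    """R rounds of pair-level splits restricted to in-network testing.

    Pairs are partitioned per class by the fractions (so train is
    balanced by construction), then any validation/test pair with an
    endpoint absent from the training protein set is removed, and class
    balance is restored within validation and test by down-sampling.
    The training subset is never altered after partitioning, which
    keeps the in-network guarantee monotone.
    """
    fractions = _check_fractions(fractions)
    if not data.is_balanced:
        raise PairAuditError("split_in_network requires a class-balanced dataset")
    out: list[SplitRound] = []
    for r in range(1, rounds + 1):
        rng = np.random.default_rng(stable_subseed(seed, "split_in", r))
        train_pairs: list[PairExample] = []
        rest: list[list[PairExample]] = [[], []]  # validation, test
        for group in (data.positives(), data.negatives()):
            perm = rng.permutation(len(group))
            n_tr, n_va, _ = _partition_counts(len(group), fractions)
            train_pairs += [group[i] for i in perm[:n_tr]]
            rest[0] += [group[i] for i in perm[n_tr:n_tr + n_va]]
            rest[1] += [group[i] for i in perm[n_tr + n_va:]]
        train = data.subset(train_pairs, f"{data.name}/round{r}/train")
        train_prot = train.protein_ids_in_pairs()
        removed = {}
        subsets = []
        for name, pairs in zip(("validation", "test"), rest):
            kept = [p for p in pairs if p.a in train_prot and p.b in train_prot]
            n_filtered = len(pairs) - len(kept)
            kept, n_balance = _downsample_balance(kept, rng)
            removed[f"{name}_out_of_network"] = n_filtered
            removed[f"{name}_balance"] = n_balance
            if n_filtered or n_balance:
                logger.info("round %d %s: removed %d out-of-network, %d for balance",
                            r, name, n_filtered, n_balance)
            subsets.append(data.subset(kept, f"{data.name}/round{r}/{name}"))
        if len(subsets[1]) == 0:
            raise PairAuditError(
                f"round {r}: test set empty after in-network filtering; "
                "use more data or a larger train fraction")
        rnd = SplitRound(r, train, subsets[0], subsets[1], IN_NETWORK, removed)
        rnd.check_invariants()
        out.append(rnd)
    return out


def split_out_of_network(data: InteractionDataset,
                         rounds: int = DEFAULT_ROUNDS,
                         fractions=DEFAULT_FRACTIONS,
                         seed: int = 0) -> list[SplitRound]:
    """R rounds of protein-level (cold-start) splits.

    Proteins, not pairs, are partitioned into train/validation/test
    blocks by the fractions; a pair is kept only when both endpoints
    fall in the same block, so no test protein has any training
    example.  Straddling pairs are discarded and logged; each subset is
    then balanced by down-sampling.
    """
    fractions = _check_fractions(fractions)
    if not data.is_balanced:
        raise PairAuditError("split_out_of_network requires a class-balanced dataset")
    ids = sorted(data.protein_ids_in_pairs())
    out: list[SplitRound] = []
    for r in range(1, rounds + 1):
        rng = np.random.default_rng(stable_subseed(seed, "split_out", r))
        perm = rng.permutation(len(ids))
        n_tr, n_va, _ = _partition_counts(len(ids), fractions)
        block: dict[str, int] = {}
        for j, i in enumerate(perm):
            block[ids[i]] = 0 if j < n_tr else (1 if j < n_tr + n_va else 2)
        buckets: list[list[PairExample]] = [[], [], []]
        straddling = 0
        for p in data.pairs:
            if block[p.a] == block[p.b]:
                buckets[block[p.a]].append(p)
            else:
                straddling += 1
        removed = {"straddling": straddling}
        subsets = []
        for name, pairs in zip(("train", "validation", "test"), buckets):
            kept, n_balance = _downsample_balance(pairs, rng)
            removed[f"{name}_balance"] = n_balance
            subsets.append(data.subset(kept, f"{data.name}/round{r}/{name}"))
        if len(subsets[2]) == 0:
            raise PairAuditError(f"round {r}: test set empty after out-of-network blocking")
        rnd = SplitRound(r, subsets[0], subsets[1], subsets[2], OUT_OF_NETWORK, removed)
        rnd.check_invariants()
        out.append(rnd)
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_splits(rounds: list[SplitRound], directory, seed: int | None = None,
                 fractions=None) -> None:
    """Serialize rounds as round_<k>/{train,valid,test}.tsv plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "mode": rounds[0].mode if rounds else None,
        "rounds": len(rounds),
        "seed": seed,
        "fractions": list(fractions) if fractions else None,
        "removed": {str(r.round_index): r.removed for r in rounds},
    }
    for r in rounds:
        d = directory / f"round_{r.round_index}"
        d.mkdir(exist_ok=True)
        write_pairs(r.train, d / "train.tsv")
        write_pairs(r.validation, d / "valid.tsv")
        write_pairs(r.test, d / "test.tsv")
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_splits(directory, registry) -> list[SplitRound]:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    out = []
    for k in range(1, manifest["rounds"] + 1):
        d = directory / f"round_{k}"
        out.append(SplitRound(
            k,
            read_pairs(d / "train.tsv", registry, name=f"round{k}/train"),
            read_pairs(d / "valid.tsv", registry, name=f"round{k}/validation"),
            read_pairs(d / "test.tsv", registry, name=f"round{k}/test"),
            manifest["mode"],
            manifest["removed"].get(str(k), {}),
        ))
    return out
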