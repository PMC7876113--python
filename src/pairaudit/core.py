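"""Core data model for paired-input interaction datasets.

Proteins, labeled pairs, node-degree bookkeeping, negative-example
construction and the rank-based AUC shared by every auditor.  All pair
storage is canonical (lexicographic id order) because interactions are
non-directional.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Default binding threshold on the pK_d scale (500 nM K_d).
DEFAULT_PKD_THRESHOLD = 6.3

POSITIVE = 1
NEGATIVE = 0


class PairAuditError(ValueError):
    """Raised for violated data-model invariants and malformed inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Protein:
    """An identifier bound to an amino-acid sequence.

    The sequence must use the 20 standard residue letters and be at
    least 3 residues long (the minimum window for 3-mer features).
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise PairAuditError(f"protein id must be a non-empty token, got {self.id!r}")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise PairAuditError(
                f"protein {self.id}: non-standard residues {sorted(bad)}; "
                "apply a residue policy before construction"
            )
        if len(self.sequence) < 3:
            raise PairAuditError(f"protein {self.id}: sequence shorter than 3 residues")


def canonical(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographic) orientation of an unordered pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PairExample:
    """A labeled protein pair, stored in canonical orientation."""

    a: str
    b: str
    label: int
    affinity: float | None = None

    def __post_init__(self) -> None:
        if self.a > self.b:
            raise PairAuditError(f"pair ({self.a},{self.b}) not in canonical orientation")
        if self.label not in (POSITIVE, NEGATIVE):
            raise PairAuditError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.a, self.b)

    @staticmethod
    def make(a: str, b: str, label: int, affinity: float | None = None) -> "PairExample":
        x, y = canonical(a, b)
        return PairExample(x, y, int(label), affinity)


@dataclass
class InteractionDataset:
    """A set of labeled canonical pairs over a protein registry."""

    proteins: dict[str, Protein]
    pairs: list[PairExample]
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[tuple[str, str], int] = {}
        for p in self.pairs:
            for pid in (p.a, p.b):
                if pid not in self.proteins:
                    raise PairAuditError(
                        f"dataset {self.name}: pair ({p.a},{p.b}) references "
                        f"unregistered protein {pid}"
                    )
            if p.key in seen:
                kind = "conflicting labels" if seen[p.key] != p.label else "duplicate"
                raise PairAuditError(
                    f"dataset {self.name}: {kind} for canonical pair {p.key}"
                )
            seen[p.key] = p.label

    # -- views -------------------------------------------------------------
    def positives(self) -> list[PairExample]:
        return [p for p in self.pairs if p.label == POSITIVE]

    def negatives(self) -> list[PairExample]:
        return [p for p in self.pairs if p.label == NEGATIVE]

    def pair_keys(self) -> set[tuple[str, str]]:
        return {p.key for p in self.pairs}

    def protein_ids_in_pairs(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.add(p.a)
            out.add(p.b)
        return out

    @property
    def is_balanced(self) -> bool:
        return len(self.positives()) == len(self.negatives())

    def subset(self, pairs: list[PairExample], name: str | None = None) -> "InteractionDataset":
        return InteractionDataset(self.proteins, list(pairs), name or self.name)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DegreeTable:
    """Per-protein positive/negative node degrees of a training set.

    An endpoint count: each pair contributes 1 to both endpoints, a
    self-pair contributes 2 to its single protein, so the degrees obey
    sum(d_pos) == 2 * n_positive_pairs (and likewise for negatives).
    """

    d_pos: dict[str, int]
    d_neg: dict[str, int]
    source: str

    def degrees(self, protein_id: str) -> tuple[int, int]:
        """(d_pos, d_neg) for a protein; (0, 0) if never seen in training."""
        return self.d_pos.get(protein_id, 0), self.d_neg.get(protein_id, 0)

    def to_tsv(self, path) -> None:
        ids = sorted(set(self.d_pos) | set(self.d_neg))
        with open(path, "w") as fh:
            fh.write("protein\td_pos\td_neg\n")
            for pid in ids:
                fh.write(f"{pid}\t{self.d_pos.get(pid, 0)}\t{self.d_neg.get(pid, 0)}\n")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

#: Residue policy names for non-standard letters (B, J, O, U, X, Z, ...).
RESIDUE_POLICIES = ("drop", "error")


def clean_sequence(seq: str, policy: str = "drop", protein_id: str = "?") -> str:
    """Upper-case a raw sequence and apply the non-standard-residue policy."""
    seq = seq.upper()
    bad = set(seq) - _AA_SET
    if not bad:
        return seq
    if policy == "error":
        raise PairAuditError(f"protein {protein_id}: non-standard residues {sorted(bad)}")
    if policy != "drop":
        raise PairAuditError(f"unknown residue policy {policy!r}; use one of {RESIDUE_POLICIES}")
    logger.warning("protein %s: dropping %d non-standard residues (%s)",
                   protein_id, sum(seq.count(c) for c in bad), "".join(sorted(bad)))
    return "".join(c for c in seq if c in _AA_SET)


def read_fasta(path, residue_policy: str = "drop") -> dict[str, Protein]:
    """Read a FASTA file into a protein registry keyed by record id.

    The id is the first whitespace-delimited token of the header line;
    sequences are upper-cased and non-standard residues handled per
    ``residue_policy``.
    """
    from Bio import SeqIO

    registry: dict[str, Protein] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        pid = record.id
        if pid in registry:
            raise PairAuditError(f"duplicate protein id {pid!r} in {path}")
        seq = clean_sequence(str(record.seq), residue_policy, pid)
        registry[pid] = Protein(pid, seq)
    if not registry:
        raise PairAuditError(f"no FASTA records found in {path}")
    return registry


def write_fasta(registry: dict[str, Protein], path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(registry):
            fh.write(f">{pid}\n{registry[pid].sequence}\n")


def read_pairs(path, registry: dict[str, Protein],
               threshold: float | None = None,
               name: str | None = None) -> InteractionDataset:
    """Read a pair TSV into an :class:`InteractionDataset`.

    Accepts columns ``a b label`` (label in {0,1}) or ``a b affinity``
    with an explicit threshold; affinities are converted to labels via
    ``affinity >= threshold``.  Lines starting with ``#`` are ignored.
    """
    pairs: list[PairExample] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                if len(header) != 3 or header[0] != "a" or header[1] != "b":
                    raise PairAuditError(
                        f"{path}:{lineno}: expected header 'a<TAB>b<TAB>label' or "
                        f"'a<TAB>b<TAB>affinity', got {line!r}")
                if header[2] == "affinity" and threshold is None:
                    raise PairAuditError(f"{path}: affinity column requires a threshold")
                continue
            if len(fields) != 3:
                raise PairAuditError(f"{path}:{lineno}: expected 3 tab-separated fields")
            a, b, value = fields
            for pid in (a, b):
                if pid not in registry:
                    raise PairAuditError(f"{path}:{lineno}: unknown protein {pid!r}")
            if header[2] == "affinity":
                affinity = float(value)
                label = POSITIVE if affinity >= threshold else NEGATIVE
                pairs.append(PairExample.make(a, b, label, affinity))
            else:
                if value not in ("0", "1"):
                    raise PairAuditError(f"{path}:{lineno}: label must be 0 or 1, got {value!r}")
                pairs.append(PairExample.make(a, b, int(value)))
    ds = InteractionDataset(registry, pairs, name or str(path))
    return ds


def write_pairs(dataset: InteractionDataset, path, affinity: bool = False) -> None:
    with open(path, "w") as fh:
        if affinity:
            fh.write("a\tb\taffinity\n")
            for p in dataset.pairs:
                fh.write(f"{p.a}\t{p.b}\t{p.affinity}\n")
        else:
            fh.write("a\tb\tlabel\n")
            for p in dataset.pairs:
                fh.write(f"{p.a}\t{p.b}\t{p.label}\n")


def pkd_from_kd(kd: float) -> float:
    """pK_d = -log10(K_d) with K_d in molar units; 5e-7 M (500 nM) -> 6.3."""
    if kd <= 0:
        raise PairAuditError(f"K_d must be positive, got {kd}")
    return -math.log10(kd)


# ---------------------------------------------------------------------------
# Degrees
# ---------------------------------------------------------------------------

def compute_degree_table(train: InteractionDataset) -> DegreeTable:
    """Endpoint counts per protein in the positive and negative pair sets.

    Every registered protein gets an entry (zero if it occurs in no
    pair); self-pairs contribute 2 to their protein's degree.  Degrees
    must only ever be computed from training pairs.
    """
    d_pos = {pid: 0 for pid in train.proteins}
    d_neg = {pid: 0 for pid in train.proteins}
    for p in train.pairs:
        table = d_pos if p.label == POSITIVE else d_neg
        table[p.a] += 1
        table[p.b] += 1
    return DegreeTable(d_pos, d_neg, source=train.name)


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------

def _all_candidate_pairs(ids: list[str], excluded: set[tuple[str, str]]) -> list[tuple[str, str]]:
    ids = sorted(ids)
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if (a, b) not in excluded:
                out.append((a, b))
    return out


def random_negative_sampling(registry: dict[str, Protein],
                             positives: set[tuple[str, str]],
                             n: int, seed: int) -> list[PairExample]:
    """Draw n distinct non-positive, non-self pairs uniformly as negatives.

    This is the random-pairing scheme: proteins not reported to
    interact are paired at random.  Deterministic per seed.
    """
    if n < 1:
        raise PairAuditError("n must be >= 1")
    candidates = _all_candidate_pairs(list(registry), positives)
    if n > len(candidates):
        raise PairAuditError(
            f"requested {n} negatives but only {len(candidates)} non-positive pairs exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [PairExample(*candidates[i], NEGATIVE) for i in sorted(idx)]


def group_based_negative_sampling(registry: dict[str, Protein],
                                  group_labels: dict[str, set[str]],
                                  positives: set[tuple[str, str]],
                                  n: int, seed: int) -> list[PairExample]:
    """Negatives drawn among pairs whose group-tag sets are disjoint.

    Generalizes non-co-localization sampling: a pair is a candidate
    negative only when the two proteins share no group tag (e.g. no
    common subcellular compartment).
    """
    for pid in registry:
        if not group_labels.get(pid):
            raise PairAuditError(f"protein {pid} has no group tags")
    candidates = [
        (a, b) for (a, b) in _all_candidate_pairs(list(registry), positives)
        if group_labels[a].isdisjoint(group_labels[b])
    ]
    if n > len(candidates):
        raise PairAuditError(
            f"requested {n} negatives but only {len(candidates)} disjoint-group "
            "non-positive pairs exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [PairExample(*candidates[i], NEGATIVE) for i in sorted(idx)]


# ---------------------------------------------------------------------------
# Metric
# ---------------------------------------------------------------------------

def auc(scores_pos, scores_neg) -> float:
    """Rank-based AUC: P(s_pos > s_neg) + 0.5 * P(tie).

    The Mann-Whitney U statistic with midranks, normalized by the
    number of positive-negative comparisons; all-tied scores give
    exactly 0.5 (the random baseline).
    """
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise PairAuditError("auc requires non-empty positive and negative score lists")
    u = mannwhitneyu(scores_pos, scores_neg, alternative="two-sided").statistic
    return float(u / (scores_pos.size * scores_neg.size))


# ---------------------------------------------------------------------------
# Misc
# ---------------------------------------------------------------------------

def stable_subseed(seed: int, *tokens) -> int:
    """A deterministic child seed from a parent seed and string/int tokens.

    Kept below 2**31 so it is always a valid seed for every RNG API.
    """
    h = zlib.crc32(repr(tuple(tokens)).encode())
    return int((seed * 0x9E3779B1 + h) % (2**31 - 1))
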