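"""Synthetic paired-input datasets with known ground truth.

The generator plants the two mechanisms an auditor must distinguish,
independently tunable:

* node-degree bias — positive-pair endpoints are drawn with
  probability proportional to exp(beta * h_i), h_i ~ N(0,1) per
  protein, so beta > 0 concentrates positives on hub proteins while
  (under the ``random`` negative scheme) negatives stay uniform.  That
  is exactly the differential-recurrence leakage the degree and
  recurrence auditors detect.
* sequence signal — each protein carries a hidden compatibility key
  whose short motif is embedded in its sequence; a pair interacts iff
  the keys are compatible (lock-and-key), with a small label-flip
  noise.  The motif is an exact substring, so 3-mer features can
  recover the rule.

The ``degree_matched`` negative scheme draws negative endpoints from
the same propensity distribution as positives, severing any
degree-label association so only the sequence signal remains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    AMINO_ACIDS,
    InteractionDataset,
    NEGATIVE,
    POSITIVE,
    PairAuditError,
    PairExample,
    Protein,
    canonical,
    random_negative_sampling,
    stable_subseed,
    write_fasta,
    write_pairs,
)

#: Number of hidden compatibility keys and the symmetric lock-and-key
#: compatibility relation between them.
N_KEYS = 4
COMPATIBLE_KEYS = frozenset({frozenset({0, 1}), frozenset({2, 3})})


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults give a moderate, hub-biased study."""

    n_proteins: int = 300
    seq_len: tuple[int, int] = (50, 150)
    n_pos: int = 1000
    bias_beta: float = 0.0
    signal: str = "none"               # {"none", "motif"}
    motif_len: int = 6
    noise_eps: float = 0.05
    neg_scheme: str = "random"         # {"random", "degree_matched"}
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_pos > self.n_proteins * (self.n_proteins - 1) // 2:
            raise PairAuditError("n_pos exceeds the number of distinct pairs")
        if not (0 <= self.noise_eps < 0.5):
            raise PairAuditError("noise_eps must lie in [0, 0.5)")
        if self.signal not in ("none", "motif"):
            raise PairAuditError(f"unknown signal mode {self.signal!r}")
        if self.neg_scheme not in ("random", "degree_matched"):
            raise PairAuditError(f"unknown negative scheme {self.neg_scheme!r}")
        if self.bias_beta < 0:
            raise PairAuditError("bias_beta must be >= 0")
        if self.seq_len[0] < max(3, self.motif_len):
            raise PairAuditError("minimum sequence length too short")


def _protein_ids(cfg: SyntheticConfig) -> list[str]:
    width = max(4, len(str(cfg.n_proteins)))
    return [f"P{i:0{width}d}" for i in range(1, cfg.n_proteins + 1)]


def assign_keys(cfg: SyntheticConfig) -> dict[str, int]:
    """Hidden compatibility key per protein (uniform over the K keys)."""
    rng = np.random.default_rng(stable_subseed(cfg.seed, "keys"))
    ids = _protein_ids(cfg)
    return dict(zip(ids, rng.integers(N_KEYS, size=len(ids)).tolist()))


def motif_strings(cfg: SyntheticConfig) -> list[str]:
    """One fixed random motif per key, distinct by construction."""
    rng = np.random.default_rng(stable_subseed(cfg.seed, "motifs"))
    motifs: list[str] = []
    while len(motifs) < N_KEYS:
        m = "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=cfg.motif_len))
        if m not in motifs:
            motifs.append(m)
    return motifs


def keys_compatible(ka: int, kb: int) -> bool:
    return frozenset({ka, kb}) in COMPATIBLE_KEYS


def generate_proteome(cfg: SyntheticConfig) -> dict[str, Protein]:
    """Random sequences; in motif mode each carries its key's motif."""
    rng = np.random.default_rng(stable_subseed(cfg.seed, "proteome"))
    keys = assign_keys(cfg) if cfg.signal == "motif" else None
    motifs = motif_strings(cfg) if cfg.signal == "motif" else None
    lo, hi = cfg.seq_len
    registry: dict[str, Protein] = {}
    for pid in _protein_ids(cfg):
        L = int(rng.integers(lo, hi + 1))
        seq = list(AMINO_ACIDS[i] for i in rng.integers(20, size=L))
        if keys is not None:
            motif = motifs[keys[pid]]
            start = int(rng.integers(0, L - cfg.motif_len + 1))
            seq[start:start + cfg.motif_len] = motif
        registry[pid] = Protein(pid, "".join(seq))
    return registry


def _propensity_probs(cfg: SyntheticConfig) -> np.ndarray:
    rng = np.random.default_rng(stable_subseed(cfg.seed, "propensity"))
    h = rng.standard_normal(cfg.n_proteins)
    w = np.exp(cfg.bias_beta * h)
    return w / w.sum()


def _noisy_label(cfg: SyntheticConfig, keys: dict[str, int], a: str, b: str) -> int:
    """Compatibility label with a deterministic per-pair noise flip."""
    label = POSITIVE if keys_compatible(keys[a], keys[b]) else NEGATIVE
    flip_rng = np.random.default_rng(stable_subseed(cfg.seed, "flip", a, b))
    if flip_rng.random() < cfg.noise_eps:
        label = POSITIVE - label
    return label


def _draw_pairs(cfg: SyntheticConfig, ids: list[str], probs: np.ndarray | None,
                want_label: int | None, keys: dict[str, int] | None,
                n: int, exclude: set[tuple[str, str]], stream: str) -> list[tuple[str, str]]:
    """Draw n distinct canonical non-self pairs by endpoint sampling.

    ``probs`` None means uniform endpoints.  With ``want_label`` set,
    drawn pairs are kept only when the motif rule (plus noise) assigns
    that label.
    """
    rng = np.random.default_rng(stable_subseed(cfg.seed, stream))
    out: list[tuple[str, str]] = []
    chosen: set[tuple[str, str]] = set()
    attempts = 0
    cap = 2000 * n + 100000
    while len(out) < n:
        attempts += 1
        if attempts > cap:
            raise PairAuditError(
                f"could not draw {n} pairs for stream {stream!r} "
                f"(got {len(out)}); reduce n_pos or bias_beta")
        i, j = rng.choice(len(ids), size=2, p=probs)
        if i == j:
            continue
        key = canonical(ids[i], ids[j])
        if key in chosen or key in exclude:
            continue
        if want_label is not None and _noisy_label(cfg, keys, *key) != want_label:
            continue
        chosen.add(key)
        out.append(key)
    return out


def generate_interactions(registry: dict[str, Protein],
                          cfg: SyntheticConfig) -> InteractionDataset:
    """Class-balanced labeled pairs with the configured bias and signal."""
    ids = _protein_ids(cfg)
    probs = _propensity_probs(cfg) if cfg.bias_beta > 0 else None
    keys = assign_keys(cfg) if cfg.signal == "motif" else None
    want_pos = POSITIVE if cfg.signal == "motif" else None

    pos_keys = _draw_pairs(cfg, ids, probs, want_pos, keys, cfg.n_pos,
                           exclude=set(), stream="positives")
    positives = [PairExample(a, b, POSITIVE) for a, b in pos_keys]

    if cfg.signal == "motif":
        neg_probs = probs if cfg.neg_scheme == "degree_matched" else None
        neg_keys = _draw_pairs(cfg, ids, neg_probs, NEGATIVE, keys, cfg.n_pos,
                               exclude=set(pos_keys), stream="negatives")
        negatives = [PairExample(a, b, NEGATIVE) for a, b in neg_keys]
    elif cfg.neg_scheme == "degree_matched":
        neg_keys = _draw_pairs(cfg, ids, probs, None, None, cfg.n_pos,
                               exclude=set(pos_keys), stream="negatives")
        negatives = [PairExample(a, b, NEGATIVE) for a, b in neg_keys]
    else:
        negatives = random_negative_sampling(
            registry, set(pos_keys), cfg.n_pos, stable_subseed(cfg.seed, "negatives"))

    return InteractionDataset(registry, positives + negatives, cfg.name)


# ---------------------------------------------------------------------------
# Canned fixtures
# ---------------------------------------------------------------------------

#: Fixture configurations: each isolates one ground truth so every
#: auditor verdict is known by construction.  pure_bias uses the largest
#: bias strength at which node balancing can fully remove the planted
#: signal: beta such that even the two strongest hubs' mutual pair has
#: expected positive-draw intensity 2*n_pos*p_i*p_j <= 0.5, leaving
#: enough hub-hub non-positive pairs for balanced negative selection
#: (at 300 proteins / 1000 positives that bound gives beta ~ 0.6).
FIXTURES: dict[str, SyntheticConfig] = {
    "pure_bias": SyntheticConfig(
        n_proteins=300, n_pos=1000, bias_beta=0.6, signal="none",
        neg_scheme="random", name="pure_bias"),
    "pure_signal": SyntheticConfig(
        n_proteins=300, n_pos=1000, bias_beta=0.0, signal="motif",
        noise_eps=0.05, neg_scheme="degree_matched", name="pure_signal"),
    "mixed": SyntheticConfig(
        n_proteins=300, n_pos=1000, bias_beta=1.5, signal="motif",
        noise_eps=0.05, neg_scheme="random", name="mixed"),
    "null": SyntheticConfig(
        n_proteins=200, n_pos=600, bias_beta=0.0, signal="none",
        neg_scheme="random", name="null"),
}

#: Ground-truth verdict chain per fixture (feature / recurrence / debias).
EXPECTED_CHAINS: dict[str, dict[str, str]] = {
    "pure_bias": {"feature_masking": "bias_indicated",
                  "node_degree": "bias_indicated",
                  "recurrence": "bias_indicated",
                  "debias_masked": "no_bias_indicated"},
    "pure_signal": {"feature_masking": "no_bias_indicated"},
    "mixed": {"feature_masking": "bias_indicated"},
    "null": {"feature_masking": "no_bias_indicated",
             "debias_masked": "no_bias_indicated"},
}


def make_fixture(name: str, seed: int = 7):
    """(registry, dataset, expected verdict chain) for a named fixture."""
    if name not in FIXTURES:
        raise PairAuditError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    cfg = dc_with_seed(FIXTURES[name], seed)
    registry = generate_proteome(cfg)
    dataset = generate_interactions(registry, cfg)
    return registry, dataset, dict(EXPECTED_CHAINS[name])


def dc_with_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    from dataclasses import replace
    return replace(cfg, seed=seed)


def write_dataset(registry, dataset: InteractionDataset, directory,
                  cfg: SyntheticConfig | None = None) -> None:
    """Serialize as FASTA + pair TSV + manifest JSON (round-trippable)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(registry, directory / "proteins.fasta")
    write_pairs(dataset, directory / "pairs.tsv")
    manifest = {"name": dataset.name,
                "n_proteins": len(registry),
                "n_pairs": len(dataset.pairs),
                "n_positive": len(dataset.positives())}
    if cfg is not None:
        manifest["config"] = {k: (list(v) if isinstance(v, tuple) else v)
                              for k, v in vars(cfg).items()}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
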