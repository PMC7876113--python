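"""Sequence-only protein feature extractors and pair-feature assembly.

Three descriptor families that cover the common sequence-based PPI
feature designs:

* 3-mer composition — frequencies of the 20^3 = 8000 overlapping
  amino-acid triplets;
* conjoint triad — residues mapped to 7 physicochemical groups, then
  7^3 = 343 group-triplet frequencies;
* autocovariance — lagged covariance of 7 per-residue physicochemical
  scales along the sequence (neighborhood context).

Also provides the feature-masking operation used by the Feature
Auditor: every sequence is replaced by a random one of the same length
so any remaining classifier performance cannot come from the real
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AMINO_ACIDS, PairAuditError, Protein, stable_subseed

# Classic 7-class dipole/side-chain-volume partition of the amino acids.
CONJOINT_TRIAD_GROUPS: dict[str, int] = {}
for _g, _members in enumerate(("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")):
    for _aa in _members:
        CONJOINT_TRIAD_GROUPS[_aa] = _g

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Seven classic physicochemical scales (rows: amino acids in AMINO_ACIDS
# order).  Columns: hydrophobicity, hydrophilicity, side-chain volume,
# polarity, polarizability, solvent-accessible surface area, net charge
# index.  Raw published values; z-scored over the 20 residues on load.
_RAW_PROPERTIES = np.array([
    # hydroph hydrophil volume polarity polarizab  sasa    nci
    [0.62,  -0.5,   27.5,  8.1,  0.046, 1.181,  0.007187],   # A
    [0.29,  -1.0,   44.6,  5.5,  0.128, 1.461, -0.036610],   # C
    [-0.90,  3.0,   40.0, 13.0,  0.105, 1.587, -0.023820],   # D
    [-0.74,  3.0,   62.0, 12.3,  0.151, 1.862,  0.006802],   # E
    [1.19,  -2.5,  115.5,  5.2,  0.290, 2.228,  0.037552],   # F
    [0.48,   0.0,    0.0,  9.0,  0.000, 0.881,  0.179052],   # G
    [-0.40, -0.5,   79.0, 10.4,  0.230, 2.025, -0.010690],   # H
    [1.38,  -1.8,   93.5,  5.2,  0.186, 1.810,  0.021631],   # I
    [-1.50,  3.0,  100.0, 11.3,  0.219, 2.258,  0.017708],   # K
    [1.06,  -1.8,   93.5,  4.9,  0.186, 1.931,  0.051672],   # L
    [0.64,  -1.3,   94.1,  5.7,  0.221, 2.034,  0.002683],   # M
    [-0.78,  0.2,   58.7, 11.6,  0.134, 1.655,  0.005392],   # N
    [0.12,   0.0,   41.9,  8.0,  0.131, 1.468,  0.239531],   # P
    [-0.85,  0.2,   80.7, 10.5,  0.180, 1.932,  0.049211],   # Q
    [-2.53,  3.0,  105.0, 10.5,  0.291, 2.560,  0.043587],   # R
    [-0.18,  0.3,   29.3,  9.2,  0.062, 1.298,  0.004627],   # S
    [-0.05, -0.4,   51.3,  8.6,  0.108, 1.525,  0.003352],   # T
    [1.08,  -1.5,   71.5,  5.9,  0.140, 1.645,  0.057004],   # V
    [0.81,  -3.4,  145.5,  5.4,  0.409, 2.663,  0.037977],   # W
    [0.26,  -2.3,  117.3,  6.2,  0.298, 2.368,  0.023599],   # Y
])

PROPERTY_NAMES = ("hydrophobicity", "hydrophilicity", "volume", "polarity",
                  "polarizability", "sasa", "net_charge_index")

DEFAULT_MAX_LAG = 30


@dataclass
class PropertyTable:
    """20 x 7 physicochemical scales, each column z-scored over the residues."""

    values: np.ndarray                     # (20, n_properties), standardized
    names: tuple[str, ...] = PROPERTY_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != 20:
            raise PairAuditError("PropertyTable needs one row per standard amino acid")
        mu = self.values.mean(axis=0)
        sd = self.values.std(axis=0)
        if np.any(sd == 0):
            raise PairAuditError("constant property column cannot be standardized")
        self.values = (self.values - mu) / sd

    @property
    def n_properties(self) -> int:
        return self.values.shape[1]

    @classmethod
    def default(cls) -> "PropertyTable":
        return cls(_RAW_PROPERTIES.copy())

    @classmethod
    def from_tsv(cls, path) -> "PropertyTable":
        """Load a table with header `aa<TAB>prop1<TAB>...`, one row per residue."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = set(AMINO_ACIDS) - set(df.index)
        if missing:
            raise PairAuditError(f"property table missing residues {sorted(missing)}")
        ordered = df.loc[list(AMINO_ACIDS)]
        return cls(ordered.to_numpy(dtype=float), tuple(ordered.columns))


@dataclass
class FeatureMap:
    """Per-protein real feature vectors from one named extractor."""

    extractor: str
    dim: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for pid, v in self.vectors.items():
            if v.shape != (self.dim,):
                raise PairAuditError(f"feature vector for {pid} has dim {v.shape}, want ({self.dim},)")
            if not np.all(np.isfinite(v)):
                raise PairAuditError(f"non-finite feature values for {pid}")

    def __getitem__(self, pid: str) -> np.ndarray:
        try:
            return self.vectors[pid]
        except KeyError:
            raise PairAuditError(f"protein {pid} not in feature map {self.extractor!r}") from None

    def __contains__(self, pid: str) -> bool:
        return pid in self.vectors

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein\t" + "\t".join(f"f{i}" for i in range(self.dim)) + "\n")
            for pid in sorted(self.vectors):
                fh.write(pid + "\t" + "\t".join(f"{x:.6g}" for x in self.vectors[pid]) + "\n")


def _triplet_frequencies(encoded: np.ndarray, alphabet_size: int) -> np.ndarray:
    """Normalized counts of overlapping 3-mers of an integer-encoded sequence."""
    idx = (encoded[:-2] * alphabet_size + encoded[1:-1]) * alphabet_size + encoded[2:]
    counts = np.bincount(idx, minlength=alphabet_size ** 3).astype(float)
    return counts / counts.sum()


def kmer3_features(registry: dict[str, Protein]) -> FeatureMap:
    """3-mer composition: 8000 overlapping-triplet frequencies per protein."""
    vectors = {}
    for pid, prot in registry.items():
        if len(prot.sequence) < 3:
            raise PairAuditError(f"protein {pid}: sequence too short for 3-mers")
        enc = np.array([_AA_INDEX[c] for c in prot.sequence])
        vectors[pid] = _triplet_frequencies(enc, 20)
    return FeatureMap("kmer3", 20 ** 3, vectors)


def load_group_partition(path) -> dict[str, int]:
    """Load an alternative residue->group partition from a two-column TSV
    (`aa<TAB>group`, groups numbered 0..6); must cover all 20 residues."""
    groups: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("aa"):
            raise PairAuditError(f"{path}: expected header 'aa<TAB>group'")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            aa, g = line.split("\t")
            groups[aa.strip()] = int(g)
    missing = set(AMINO_ACIDS) - set(groups)
    if missing:
        raise PairAuditError(f"group partition missing residues {sorted(missing)}")
    if not set(groups.values()) <= set(range(7)):
        raise PairAuditError("group indices must lie in 0..6")
    return groups


def conjoint_triad_features(registry: dict[str, Protein],
                            groups: dict[str, int] | None = None) -> FeatureMap:
    """Conjoint triad: 343 group-triplet frequencies over the 7-class partition."""
    groups = groups or CONJOINT_TRIAD_GROUPS
    vectors = {}
    for pid, prot in registry.items():
        if len(prot.sequence) < 3:
            raise PairAuditError(f"protein {pid}: sequence too short for triads")
        enc = np.array([groups[c] for c in prot.sequence])
        vectors[pid] = _triplet_frequencies(enc, 7)
    return FeatureMap("conjoint_triad", 7 ** 3, vectors)


def autocovariance_features(registry: dict[str, Protein],
                            table: PropertyTable | None = None,
                            max_lag: int = DEFAULT_MAX_LAG) -> FeatureMap:
    """Lagged autocovariance of physicochemical profiles.

    AC(p, g) = (1/(L-g)) * sum_i (x_{p,i} - xbar_p)(x_{p,i+g} - xbar_p)
    for each property p and lag g = 1..max_lag; the feature vector is
    the concatenation over properties then lags.
    """
    table = table or PropertyTable.default()
    n_props = table.n_properties
    vectors = {}
    for pid, prot in registry.items():
        L = len(prot.sequence)
        if L <= max_lag:
            raise PairAuditError(
                f"protein {pid}: length {L} <= max_lag {max_lag}")
        enc = np.array([_AA_INDEX[c] for c in prot.sequence])
        profile = table.values[enc]                    # (L, n_props)
        centered = profile - profile.mean(axis=0)
        ac = np.empty((n_props, max_lag))
        for g in range(1, max_lag + 1):
            ac[:, g - 1] = (centered[:-g] * centered[g:]).sum(axis=0) / (L - g)
        vectors[pid] = ac.ravel()
    return FeatureMap("autocovariance", n_props * max_lag, vectors)


EXTRACTORS = {
    "kmer3": kmer3_features,
    "conjoint_triad": conjoint_triad_features,
    "autocovariance": autocovariance_features,
}


def get_extractor(name: str):
    try:
        return EXTRACTORS[name]
    except KeyError:
        raise PairAuditError(
            f"unknown extractor {name!r}; available: {sorted(EXTRACTORS)}") from None


# ---------------------------------------------------------------------------
# Pair-feature assembly
# ---------------------------------------------------------------------------

def pair_features(fm: FeatureMap, pair, symmetric: bool = False) -> list[np.ndarray]:
    """Concatenated pair vector(s) [v_a || v_b] for one canonical pair.

    With ``symmetric`` the caller receives both orientations as separate
    rows (one row for a self-pair, where the orientations coincide).
    """
    va, vb = fm[pair.a], fm[pair.b]
    rows = [np.concatenate([va, vb])]
    if symmetric and pair.a != pair.b:
        rows.append(np.concatenate([vb, va]))
    return rows


def pair_matrix(fm: FeatureMap, pairs, symmetric: bool = False,
                dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair rows and labels into (X, y) arrays for a learner.

    ``symmetric`` duplicates each training pair in both orientations so
    that orientation-sensitive learners respect the non-directionality
    of interactions.
    """
    pairs = list(pairs)
    ids = sorted({pid for p in pairs for pid in (p.a, p.b)})
    index = {pid: i for i, pid in enumerate(ids)}
    P = np.stack([fm[pid] for pid in ids]).astype(dtype)
    ia = np.array([index[p.a] for p in pairs])
    ib = np.array([index[p.b] for p in pairs])
    y = np.array([p.label for p in pairs], dtype=np.int64)
    X = np.concatenate([P[ia], P[ib]], axis=1)
    if symmetric:
        swap = ia != ib  # a single row suffices for self-pairs
        X = np.concatenate(
            [X, np.concatenate([P[ib[swap]], P[ia[swap]]], axis=1)], axis=0)
        y = np.concatenate([y, y[swap]])
    return X, y


# ---------------------------------------------------------------------------
# Feature Auditor masking
# ---------------------------------------------------------------------------

def mask_sequences(registry: dict[str, Protein], seed: int) -> dict[str, Protein]:
    """Replace every sequence by an i.i.d.-uniform random one of equal length.

    The replacement depends only on (seed, protein id), so one masked
    proteome is reused across every round and extractor of an auditing
    experiment.  Masking severs any dependence of downstream features
    on the real sequences while preserving the length distribution.
    """
    masked = {}
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    for pid, prot in registry.items():
        rng = np.random.default_rng(stable_subseed(seed, "mask", pid))
        seq = rng.choice(aa, size=len(prot.sequence)).tobytes().decode()
        masked[pid] = Protein(pid, seq)
    return masked
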