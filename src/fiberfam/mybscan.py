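"""Profile-based identification of MYB DNA-binding repeats in proteins.

The MYB domain is a tandem array of up to four imperfect repeats of ~53
residues, each folding into a helix-turn-helix.  Family membership in plants
is conventionally read off the repeat count: one repeat -> 1R, two -> R2R3
(the dominant plant subfamily), three -> 3R, four or more -> 4R.

The scanner scores every length-L window of a protein against a log-odds
position-specific scoring matrix (PSSM) estimated from a seed alignment of
repeats, keeps windows above a bit-score threshold, and resolves overlaps
greedily by score.  Insertions and deletions inside a repeat are not
modelled; imperfect matches are absorbed by the log-odds scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SequenceRecord

__all__ = [
    "AMINO_ACIDS",
    "RepeatProfile",
    "MybRepeat",
    "FamilyCall",
    "ConservationProfile",
    "build_profile",
    "calibrate_threshold",
    "scan_repeats",
    "classify_family",
    "logo_stats",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_REPEAT_LENGTH = 53
DEFAULT_MAX_GAP = 30


def _encode(seq: str) -> np.ndarray:
    """Map residues to 0..19; unknown residues (e.g. X) map to -1."""
    return np.array([_AA_INDEX.get(aa, -1) for aa in seq], dtype=np.int64)


@dataclass
class RepeatProfile:
    """Log-odds PSSM over one MYB repeat unit.

    ``pssm`` has shape (L, 20) in bits; ``background`` is the residue
    frequency vector the odds are taken against; ``score_threshold`` is the
    bit score above which a window counts as a repeat hit.
    """

    length: int
    pssm: np.ndarray
    background: np.ndarray
    score_threshold: float

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pssm.shape != (self.length, 20):
            raise ValueError(f"pssm must have shape ({self.length}, 20)")
        if np.any(self.background <= 0) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be positive and sum to 1")

    @property
    def max_score(self) -> float:
        """Bit score of the profile's consensus sequence."""
        return float(self.pssm.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.pssm.argmax(axis=1))


@dataclass(frozen=True)
class MybRepeat:
    """One scored repeat hit, 0-based half-open residue coordinates."""

    protein_id: str
    start: int
    end: int
    score: float
    repeat_index: int


@dataclass(frozen=True)
class FamilyCall:
    """Per-gene subfamily call from the repeat count."""

    protein_id: str
    n_repeats: int
    subfamily: str


@dataclass
class ConservationProfile:
    """Column-wise conservation statistics of a repeat alignment."""

    frequencies: np.ndarray  # (L, 20), rows sum to 1 over observed residues
    information_content: np.ndarray  # bits, 0..log2(20)
    modal_residues: list[str] = field(default_factory=list)
    modal_frequencies: np.ndarray | None = None


def build_profile(
    seed_alignment: list[str],
    background: np.ndarray | None = None,
    pseudocount: float = 0.5,
    score_threshold: float | None = None,
) -> RepeatProfile:
    """Estimate a log-odds PSSM from a gap-free seed alignment of repeats.

    ``pssm[p, r] = log2((count[p, r] + pseudocount * background[r])
    / (n_rows + pseudocount) / background[r])``.  When *score_threshold* is
    not given it defaults to half the consensus score, which separates
    genuine (imperfect) repeats from background windows by a wide margin;
    :func:`calibrate_threshold` offers a shuffle-null alternative.
    """
    if not seed_alignment:
        raise ValueError("empty seed alignment")
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs at least 2 rows")
    length = len(seed_alignment[0])
    if any(len(row) != length for row in seed_alignment):
        raise ValueError("seed alignment rows have unequal lengths")
    if background is None:
        background = np.full(20, 1.0 / 20)
    background = np.asarray(background, dtype=float)

    counts = np.zeros((length, 20))
    for row in seed_alignment:
        enc = _encode(row.upper())
        if np.any(enc < 0):
            raise ValueError("seed alignment contains gaps or non-standard residues")
        counts[np.arange(length), enc] += 1.0
    n_rows = len(seed_alignment)
    with np.errstate(divide="ignore"):
        pssm = np.log2(
            (counts + pseudocount * background) / (n_rows + pseudocount) / background
        )
    profile = RepeatProfile(length, pssm, background, score_threshold or 0.0)
    if score_threshold is None:
        profile.score_threshold = 0.5 * profile.max_score
    return profile


def window_scores(seq: str, profile: RepeatProfile) -> np.ndarray:
    """Bit score of every length-L window of *seq* (empty if too short)."""
    enc = _encode(seq.upper())
    L = profile.length
    n_windows = enc.size - L + 1
    if n_windows <= 0:
        return np.empty(0)
    idx = np.arange(n_windows)[:, None] + np.arange(L)[None, :]
    residues = enc[idx]  # (n_windows, L)
    positions = np.broadcast_to(np.arange(L), residues.shape)
    # unknown residues (X) contribute 0 bits
    per_pos = np.where(
        residues >= 0,
        profile.pssm[positions, np.where(residues >= 0, residues, 0)],
        0.0,
    )
    return per_pos.sum(axis=1)


def calibrate_threshold(
    profile: RepeatProfile,
    sequences: list[str],
    quantile: float = 0.999,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> float:
    """Bit-score quantile of a shuffle null.

    Residues of each input sequence are permuted *n_shuffles* times and every
    window of every shuffle is scored; the requested quantile of the pooled
    null scores is returned.
    """
    rng = np.random.default_rng(seed)
    null: list[np.ndarray] = []
    for seq in sequences:
        chars = np.array(list(seq.upper()))
        for _ in range(n_shuffles):
            shuffled = "".join(rng.permutation(chars))
            scores = window_scores(shuffled, profile)
            if scores.size:
                null.append(scores)
    if not null:
        raise ValueError("no scorable windows in the null")
    return float(np.quantile(np.concatenate(null), quantile))


def scan_repeats(
    protein: SequenceRecord | str,
    profile: RepeatProfile,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[MybRepeat]:
    """Locate non-overlapping repeat hits in one protein.

    Every window scoring at or above the profile threshold is a candidate;
    candidates are accepted greedily by descending score (ties to the
    leftmost start) with overlap exclusion.  Accepted repeats separated by
    more than *max_gap* residues split into clusters and only the largest
    cluster (leftmost on ties) is returned, indexed left to right.

    A protein shorter than the repeat length yields an empty list.
    """
    if isinstance(protein, SequenceRecord):
        pid, seq = protein.id, protein.seq
    else:
        pid, seq = "query", protein
    L = profile.length
    scores = window_scores(seq, profile)
    candidates = [
        (float(scores[s]), s) for s in np.flatnonzero(scores >= profile.score_threshold)
    ]
    # greedy: descending score, leftmost start on ties
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken: list[tuple[int, float]] = []
    occupied: list[tuple[int, int]] = []
    for score, start in candidates:
        if any(start < e and o_start < start + L for o_start, e in occupied):
            continue
        occupied.append((start, start + L))
        taken.append((start, score))
    taken.sort()
    if not taken:
        return []

    clusters: list[list[tuple[int, float]]] = [[taken[0]]]
    for start, score in taken[1:]:
        prev_end = clusters[-1][-1][0] + L
        if start - prev_end > max_gap:
            clusters.append([])
        clusters[-1].append((start, score))
    best = max(clusters, key=len)  # max() keeps the leftmost on ties
    return [
        MybRepeat(pid, start, start + L, score, i)
        for i, (start, score) in enumerate(best)
    ]


_SUBFAMILY = {0: "none", 1: "1R", 2: "R2R3", 3: "3R"}


def classify_family(repeats: list[MybRepeat], protein_id: str | None = None) -> FamilyCall:
    """Map a protein's repeat count to its MYB subfamily label.

    0 -> none, 1 -> 1R, 2 -> R2R3, 3 -> 3R, >=4 -> 4R.
    """
    n = len(repeats)
    pid = protein_id if protein_id is not None else (repeats[0].protein_id if repeats else "")
    return FamilyCall(pid, n, _SUBFAMILY.get(n, "4R"))


def logo_stats(repeat_alignment: list[str]) -> ConservationProfile:
    """Per-column residue frequencies and information content of an alignment.

    IC[p] = log2(20) - H[p] with H the Shannon entropy of the observed column
    frequencies (no small-sample correction), as drawn by standard sequence
    logos.  The modal residue and its frequency are reported per column.
    """
    if not repeat_alignment:
        raise ValueError("empty alignment")
    length = len(repeat_alignment[0])
    if any(len(row) != length for row in repeat_alignment):
        raise ValueError("alignment rows have unequal lengths")
    counts = np.zeros((length, 20))
    for row in repeat_alignment:
        enc = _encode(row.upper())
        valid = enc >= 0
        counts[np.flatnonzero(valid), enc[valid]] += 1.0
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("alignment has a column with no standard residues")
    freqs = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = np.log2(20.0) - entropy
    modal_idx = freqs.argmax(axis=1)
    return ConservationProfile(
        frequencies=freqs,
        information_content=ic,
        modal_residues=[AMINO_ACIDS[i] for i in modal_idx],
        modal_frequencies=freqs[np.arange(length), modal_idx],
    )
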