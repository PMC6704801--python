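"""Ortholog retention/loss scenarios across an allopolyploid complex and
pairwise dN/dS with selection calls.

The genome roles are the two diploid progenitors of cultivated cotton
(A2 = G. arboreum, D5 = G. raimondii) and the A/D subgenomes of the two
allotetraploids (At/Dt of AD1 = G. hirsutum and AD2 = G. barbadense).  An
ortholog group records presence or absence of a family member in each of
the six roles; the presence pattern maps by a fixed decision table onto a
named duplication/loss scenario.

dN/dS uses Nei-Gojobori (1986) counting: per-codon synonymous site
fractions averaged over the two sequences, observed differences averaged
over all minimal mutational pathways for multi-hit codons, and the
Jukes-Cantor correction d = -3/4 ln(1 - 4p/3).  omega = dN/dS < 1 indicates
purifying selection, > 1 positive selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "SLOTS",
    "SCENARIOS",
    "OrthologGroup",
    "LossSummary",
    "DnDsResult",
    "classify_scenario",
    "count_losses",
    "ng86_dnds",
    "subgenome_asymmetry",
]

#: six genome/subgenome roles, fixed order
SLOTS = ("A2", "D5", "At_AD1", "Dt_AD1", "At_AD2", "Dt_AD2")

SCENARIOS = (
    "RETAINED_ALL",
    "LOSS_ONE_SUBGENOME_AD1",
    "LOSS_ONE_SUBGENOME_AD2",
    "LOSS_BOTH_SUBGENOMES_AD1",
    "LOSS_BOTH_SUBGENOMES_AD2",
    "LOSS_DIPLOID_ONLY",
    "LOSS_SUBGENOME_AND_PROGENITOR",
    "OTHER",
)

#: progenitor of each tetraploid subgenome slot
_PROGENITOR = {"At_AD1": "A2", "Dt_AD1": "D5", "At_AD2": "A2", "Dt_AD2": "D5"}
_SUBGENOME_SLOTS = {"AD1": ("At_AD1", "Dt_AD1"), "AD2": ("At_AD2", "Dt_AD2")}


@dataclass(frozen=True)
class OrthologGroup:
    """Gene-id slots (or None for absent) across the six genome roles."""

    group_id: str
    A2: str | None = None
    D5: str | None = None
    At_AD1: str | None = None
    Dt_AD1: str | None = None
    At_AD2: str | None = None
    Dt_AD2: str | None = None

    def __post_init__(self) -> None:
        if not any(getattr(self, s) for s in SLOTS):
            raise ValueError(f"group {self.group_id!r}: all six slots are absent")

    def present(self, slot: str) -> bool:
        return getattr(self, slot) is not None

    def pattern(self) -> tuple[bool, ...]:
        return tuple(self.present(s) for s in SLOTS)


@dataclass
class LossSummary:
    """Per-genome lost-pair counts and per-scenario histogram."""

    n_groups: int
    lost_pairs: dict[str, int] = field(default_factory=dict)  # AD1/AD2
    scenario_counts: dict[str, int] = field(default_factory=dict)


def classify_scenario(group: OrthologGroup) -> str:
    """Map a six-slot presence pattern to its duplication/loss scenario.

    Decision table (first match wins):

    * all six present -> ``RETAINED_ALL``
    * exactly one absent slot, a tetraploid subgenome whose progenitor is
      present -> ``LOSS_ONE_SUBGENOME_{AD1|AD2}``
    * both subgenome slots of one tetraploid absent, the other four present
      -> ``LOSS_BOTH_SUBGENOMES_{AD1|AD2}``
    * exactly one absent slot, a diploid, with both of its descendant
      subgenome slots present -> ``LOSS_DIPLOID_ONLY``
    * exactly one subgenome slot and its progenitor absent, the other four
      present -> ``LOSS_SUBGENOME_AND_PROGENITOR``
    * anything else -> ``OTHER``
    """
    absent = {s for s in SLOTS if not group.present(s)}
    if not absent:
        return "RETAINED_ALL"
    if len(absent) == 1:
        (slot,) = absent
        if slot in _PROGENITOR:  # a tetraploid subgenome slot
            # its progenitor is present since only this slot is absent
            return "LOSS_ONE_SUBGENOME_AD1" if slot.endswith("AD1") else "LOSS_ONE_SUBGENOME_AD2"
        # a diploid slot; both descendant subgenome slots present
        return "LOSS_DIPLOID_ONLY"
    if len(absent) == 2:
        for species, slots in _SUBGENOME_SLOTS.items():
            if absent == set(slots):
                return f"LOSS_BOTH_SUBGENOMES_{species}"
        for slot, progenitor in _PROGENITOR.items():
            if absent == {slot, progenitor}:
                return "LOSS_SUBGENOME_AND_PROGENITOR"
    return "OTHER"


def count_losses(groups: list[OrthologGroup]) -> LossSummary:
    """Lost-pair counts per tetraploid and a scenario histogram.

    A group counts as lost in a tetraploid when at least one of that
    species' two subgenome slots is absent (never double-counted).
    """
    if not groups:
        raise ValueError("empty group list")
    lost = {"AD1": 0, "AD2": 0}
    histogram = {label: 0 for label in SCENARIOS}
    for group in groups:
        for species, slots in _SUBGENOME_SLOTS.items():
            if any(not group.present(s) for s in slots):
                lost[species] += 1
        histogram[classify_scenario(group)] += 1
    return LossSummary(len(groups), lost, histogram)


# ---------------------------------------------------------------------------
# NG86 dN/dS

_STOPS = set(standard_dna_table.stop_codons)
_CODE = dict(standard_dna_table.forward_table)
_BASES = "ACGT"


def _aa(codon: str) -> str | None:
    """Amino acid, or None for a stop codon."""
    return None if codon in _STOPS else _CODE[codon]


def _syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3).

    Each position contributes the fraction of its three single-base mutants
    that are synonymous; mutants creating a stop codon count as
    nonsynonymous.
    """
    total = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in _STOPS and _aa(mutant) == _aa(codon):
                syn += 1
        total += syn / 3.0
    return total


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences, averaged over minimal pathways.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are excluded.  If every pathway is blocked by
    stops, the raw number of differences is charged as nonsynonymous.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    syn_totals: list[int] = []
    for order in permutations(diff_positions):
        current = codon_a
        syn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in _STOPS:  # endpoints are validated non-stop upstream
                blocked = True
                break
            if _aa(nxt) == _aa(current):
                syn += 1
            current = nxt
        if not blocked:
            syn_totals.append(syn)
    n_diffs = len(diff_positions)
    if not syn_totals:
        return 0.0, float(n_diffs)
    mean_syn = sum(syn_totals) / len(syn_totals)
    return mean_syn, n_diffs - mean_syn


def _jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN when saturated (p >= 3/4)."""
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class DnDsResult:
    N: float  # nonsynonymous sites (average of the two sequences)
    S: float  # synonymous sites
    Nd: float  # observed nonsynonymous differences
    Sd: float  # observed synonymous differences
    pN: float
    pS: float
    dN: float
    dS: float
    omega: float | None
    selection: str  # purifying | neutral | positive | undefined


def ng86_dnds(cds_a: str, cds_b: str) -> DnDsResult:
    """Nei-Gojobori dN/dS between two aligned in-frame coding sequences.

    Sequences must be equal length, a multiple of 3, and free of internal
    stop codons (a terminal stop shared by neither is not special-cased:
    any stop raises).  ``selection`` is ``purifying`` for omega < 1,
    ``positive`` for omega > 1, ``neutral`` for omega == 1, and
    ``undefined`` when dS = 0 or a distance is saturated.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ ({len(a)} vs {len(b)})")
    if len(a) % 3 != 0:
        raise ValueError("sequence length is not a multiple of 3")
    n_codons = len(a) // 3
    S = N = Sd = Nd = 0.0
    for i in range(n_codons):
        codon_a, codon_b = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
        for codon, name in ((codon_a, "first"), (codon_b, "second")):
            if codon in _STOPS:
                raise ValueError(f"internal stop codon at codon index {i} in {name} sequence")
            if any(base not in _BASES for base in codon):
                raise ValueError(f"non-ACGT base in codon index {i}")
        s_a, s_b = _syn_sites(codon_a), _syn_sites(codon_b)
        S += (s_a + s_b) / 2.0
        N += 3.0 - (s_a + s_b) / 2.0
        sd, nd = _pathway_differences(codon_a, codon_b)
        Sd += sd
        Nd += nd

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)

    omega: float | None
    if math.isnan(dS) or math.isnan(dN) or dS == 0.0:
        omega = None
        selection = "undefined"
    else:
        omega = dN / dS
        selection = "purifying" if omega < 1 else ("positive" if omega > 1 else "neutral")
    return DnDsResult(N, S, Nd, Sd, pN, pS, dN, dS, omega, selection)


def subgenome_asymmetry(
    omegas_a: list[float], omegas_d: list[float]
) -> dict[str, float]:
    """Median omega of A-subgenome vs D-subgenome ortholog pairs.

    Reports the two medians and their difference (A minus D); a positive
    difference indicates faster/more relaxed evolution of the A subgenome.
    """
    import statistics

    if not omegas_a or not omegas_d:
        raise ValueError("both omega lists must be non-empty")
    med_a = statistics.median(omegas_a)
    med_d = statistics.median(omegas_d)
    return {"median_A": med_a, "median_D": med_d, "difference": med_a - med_d}
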