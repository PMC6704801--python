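"""Ortholog loss scenarios and NG86 dN/dS.

Oracles: the scenario classifier is checked against an independently
constructed pattern->label table over all 63 nonempty presence patterns;
NG86 site and difference counts are checked against a plain pathway
enumeration written directly from the counting definitions.
"""

import math
from itertools import permutations, product

import numpy as np
import pytest

from fiberfam import evolution, synth
from fiberfam.evolution import SLOTS, OrthologGroup, classify_scenario, ng86_dnds

# --- scenario oracle: build the full expected mapping constructively -------

_SUBGENOMES = {"At_AD1": "A2", "Dt_AD1": "D5", "At_AD2": "A2", "Dt_AD2": "D5"}


def expected_scenario_table():
    """pattern (presence 6-tuple, SLOTS order) -> label, built rule by rule."""
    table = {}
    all_present = tuple([True] * 6)

    def pattern(absent):
        return tuple(slot not in absent for slot in SLOTS)

    # default: everything nonempty is OTHER, specific rules overwrite
    for bits in product([True, False], repeat=6):
        if any(bits):
            table[bits] = "OTHER"
    table[all_present] = "RETAINED_ALL"
    for slot, progenitor in _SUBGENOMES.items():
        species = slot.split("_")[1]
        table[pattern({slot})] = f"LOSS_ONE_SUBGENOME_{species}"
        table[pattern({slot, progenitor})] = "LOSS_SUBGENOME_AND_PROGENITOR"
    for species in ("AD1", "AD2"):
        table[pattern({f"At_{species}", f"Dt_{species}"})] = f"LOSS_BOTH_SUBGENOMES_{species}"
    for diploid in ("A2", "D5"):
        table[pattern({diploid})] = "LOSS_DIPLOID_ONLY"
    return table


def group_from_pattern(bits):
    slots = {s: ("g" if present else None) for s, present in zip(SLOTS, bits)}
    return OrthologGroup("g", **slots)


class TestClassifyScenario:
    def test_all_present_retained(self):
        assert classify_scenario(group_from_pattern([True] * 6)) == "RETAINED_ALL"

    def test_diploid_loss_with_tetraploid_retention(self):
        """D5 absent but both Dt subgenome copies retained."""
        group = OrthologGroup("g", A2="a", D5=None, At_AD1="b", Dt_AD1="c", At_AD2="d", Dt_AD2="e")
        assert classify_scenario(group) == "LOSS_DIPLOID_ONLY"

    def test_all_absent_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            OrthologGroup("g")

    def test_exhaustive_enumeration_agrees_with_oracle(self):
        table = expected_scenario_table()
        assert len(table) == 63
        for bits, expected in table.items():
            assert classify_scenario(group_from_pattern(bits)) == expected


class TestCountLosses:
    def test_planted_loss_counts_recovered(self):
        groups, truth = synth.gen_ortholog_groups(11)
        summary = evolution.count_losses(groups)
        assert summary.lost_pairs == {"AD1": 3, "AD2": 5}
        assert sum(summary.scenario_counts.values()) == summary.n_groups == len(groups)
        expected_hist = truth["truth_scenario"].value_counts().to_dict()
        observed_hist = {k: v for k, v in summary.scenario_counts.items() if v}
        assert observed_hist == expected_hist

    def test_all_retained_means_zero_losses(self):
        groups, _ = synth.gen_ortholog_groups(1, n_groups=5, proportions={"RETAINED_ALL": 1.0})
        summary = evolution.count_losses(groups)
        assert summary.lost_pairs == {"AD1": 0, "AD2": 0}

    def test_double_subgenome_loss_counted_once(self):
        group = OrthologGroup("g", A2="a", D5="b", At_AD1=None, Dt_AD1=None, At_AD2="c", Dt_AD2="d")
        summary = evolution.count_losses([group])
        assert summary.lost_pairs == {"AD1": 1, "AD2": 0}
        assert summary.scenario_counts["LOSS_BOTH_SUBGENOMES_AD1"] == 1


# --- NG86 oracle -----------------------------------------------------------

_BASES = "ACGT"
_CODONS = ["".join(c) for c in product(_BASES, repeat=3)]
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [c for c in _CODONS if c not in _STOPS]


from functools import lru_cache


@lru_cache(maxsize=None)
def translate(codon):
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def oracle_sites(codon):
    """Synonymous sites: fraction of the nine single-base mutants preserving
    the amino acid (mutants to stop count as nonsynonymous)."""
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in _STOPS and translate(mutant) == translate(codon):
                syn += 1 / 3
    return syn


def oracle_differences(codon_a, codon_b):
    """Pathway enumeration straight from the definition."""
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    pathway_syn = []
    for order in permutations(positions):
        codons = [codon_a]
        for pos in order:
            codons.append(codons[-1][:pos] + codon_b[pos] + codons[-1][pos + 1 :])
        if any(c in _STOPS for c in codons[1:-1]):
            continue
        pathway_syn.append(
            sum(translate(x) == translate(y) for x, y in zip(codons, codons[1:]))
        )
    if not pathway_syn:
        return 0.0, float(len(positions))
    syn = sum(pathway_syn) / len(pathway_syn)
    return syn, len(positions) - syn


class TestNg86:
    def test_identical_sequences(self):
        result = ng86_dnds("ATGGCT", "ATGGCT")
        assert (result.Nd, result.Sd, result.dN, result.dS) == (0, 0, 0, 0)
        assert result.selection == "undefined"

    def test_phe_codon_site_count(self):
        """TTT has exactly one synonymous mutant (TTC) among its nine."""
        result = ng86_dnds("TTT", "TTA")
        assert oracle_sites("TTT") == pytest.approx(1 / 3)
        assert result.Sd == 0.0 and result.Nd == 1.0
        # averaged sites: TTT contributes 1/3 and TTA (Leu) 2/3
        assert result.S == pytest.approx(0.5)

    def test_site_counts_sum_to_sequence_length(self):
        result = ng86_dnds("ATGGCTAAAGGG", "ATGGCGAAAGGA")
        assert result.N + result.S == pytest.approx(12)

    def test_errors(self):
        with pytest.raises(ValueError, match="lengths"):
            ng86_dnds("ATG", "ATGGCT")
        with pytest.raises(ValueError, match="multiple of 3"):
            ng86_dnds("ATGG", "ATGG")
        with pytest.raises(ValueError, match="codon index 1"):
            ng86_dnds("ATGTAAGCT", "ATGTAAGCT")

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = "".join(rng.choice(_SENSE, size=20))
            b = "".join(rng.choice(_SENSE, size=20))
            ra, rb = ng86_dnds(a, b), ng86_dnds(b, a)
            assert ra.Sd == pytest.approx(rb.Sd)
            assert ra.Nd == pytest.approx(rb.Nd)
            assert ra.S == pytest.approx(rb.S)

    def test_all_codon_pairs_match_pathway_oracle(self):
        for codon_a in _SENSE:
            for codon_b in _SENSE:
                result = ng86_dnds(codon_a, codon_b)
                syn, nonsyn = oracle_differences(codon_a, codon_b)
                assert result.Sd == pytest.approx(syn), (codon_a, codon_b)
                assert result.Nd == pytest.approx(nonsyn), (codon_a, codon_b)
                assert result.S == pytest.approx(
                    (oracle_sites(codon_a) + oracle_sites(codon_b)) / 2
                )

    def test_saturation_yields_undefined(self):
        assert math.isnan(evolution._jukes_cantor(0.8))


class TestNg86Simulation:
    def test_purifying_selection_detected(self):
        omegas = []
        for a, b in synth.gen_codon_pairs(5, n_pairs=30):
            result = ng86_dnds(a, b)
            assert result.omega is not None
            omegas.append(result.omega)
        assert np.median(omegas) < 1.0


class TestAsymmetry:
    def test_reports_medians_and_difference(self):
        stats = evolution.subgenome_asymmetry([0.4, 0.5, 0.6], [0.2, 0.3, 0.4])
        assert stats == {"median_A": 0.5, "median_D": 0.3, "difference": pytest.approx(0.2)}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evolution.subgenome_asymmetry([], [0.1])
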