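"""Seeded synthetic-data generators emulating the statistical structure of
each pipeline input.

Every generator is a pure function of its seed and parameters: each draws
from its own named pseudo-random substream, so adding or reordering
generators never perturbs another's output, and identical calls are
byte-identical.  Alongside the data, every generator returns a *truth
table* sufficient to score downstream recovery without re-deriving ground
truth.

Defaults mirror the study conditions the pipeline targets: a 180-line
BC1F7 backcross inbred population (donor-allele frequency 0.25: one
backcross leaves a quarter donor genome and selfing fixes it) phenotyped
in four environments; 53-residue MYB repeats with ~10% per-position
divergence from the family consensus; fiber-trait QTL clustered on a cM
map with a 20-cM hotspot rule in mind.
"""

from __future__ import annotations

import zlib
from itertools import product

import numpy as np
import pandas as pd

from .evolution import SLOTS, OrthologGroup
from .io import ALLELE_SOURCE_COLUMNS, SequenceRecord
from .mybscan import AMINO_ACIDS
from .qtlcoloc import MarkerAnchor, QtlRecord

__all__ = [
    "REPEAT_CONSENSUS",
    "gen_repeat_family",
    "gen_proteome",
    "gen_qtl_map",
    "gen_bil",
    "gen_allele_matrix",
    "gen_ortholog_groups",
]

#: synthetic 53-residue MYB-repeat consensus with the field's canonical
#: regularly spaced tryptophans; used as the planted-repeat generating model.
REPEAT_CONSENSUS = "LKKGPWTPEEDEILVDYIQKHGHGNWRALPKQAGLLRCGKSCRLRWTNYLRPD"

FIBER_TRAITS = ("FL", "FS", "FE", "FU", "MIC", "SFC", "LP")


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: a generator keyed by (seed, crc32(name))."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _allocate(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n items to classes by proportion."""
    if any(p < 0 or p > 1 for p in proportions.values()):
        raise ValueError("proportions must lie in [0, 1]")
    total = sum(proportions.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"proportions must sum to 1 (got {total})")
    raw = {k: n * p for k, p in proportions.items()}
    counts = {k: int(v) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    out = list(seq)
    for i, residue in enumerate(out):
        if rng.random() < rate:
            choices = [aa for aa in AMINO_ACIDS if aa != residue]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def gen_repeat_family(seed: int, n_rows: int = 20, sub_rate: float = 0.1) -> list[str]:
    """Seed alignment: consensus-derived repeats at the given divergence."""
    rng = _rng(seed, "repeat_family")
    return [_mutate(REPEAT_CONSENSUS, rng, sub_rate) for _ in range(n_rows)]


def gen_proteome(
    seed: int,
    n_proteins: int = 200,
    family_fraction: float = 0.3,
    repeat_count_probs: dict[int, float] | None = None,
    sub_rate: float = 0.1,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Proteome with planted repeat-family members.

    Family proteins carry ``k`` repeats sampled from the consensus at
    *sub_rate* per-position substitution, separated by short linkers and
    flanked by random sequence; background proteins are i.i.d. uniform over
    the 20 residues.  The truth table lists ``protein_id``, ``k``, and the
    semicolon-joined 0-based repeat offsets.
    """
    if repeat_count_probs is None:
        # R2R3 dominant, as in plant MYB families
        repeat_count_probs = {1: 0.15, 2: 0.60, 3: 0.15, 4: 0.10}
    rng = _rng(seed, "proteome")
    n_family = int(round(n_proteins * family_fraction))
    ks = list(repeat_count_probs)
    probs = np.array([repeat_count_probs[k] for k in ks], dtype=float)
    probs = probs / probs.sum()
    L = len(REPEAT_CONSENSUS)

    records: list[SequenceRecord] = []
    truth_rows: list[dict] = []
    for i in range(n_proteins):
        pid = f"P{i:04d}"
        if i < n_family:
            k = int(np.asarray(ks)[rng.choice(len(ks), p=probs)])
            parts: list[str] = [_random_protein(rng, int(rng.integers(20, 61)))]
            offsets: list[int] = []
            pos = len(parts[0])
            for j in range(k):
                if j > 0:
                    linker = int(rng.integers(1, 11))
                    parts.append(_random_protein(rng, linker))
                    pos += linker
                offsets.append(pos)
                parts.append(_mutate(REPEAT_CONSENSUS, rng, sub_rate))
                pos += L
            parts.append(_random_protein(rng, int(rng.integers(20, 61))))
            records.append(SequenceRecord(pid, "".join(parts)))
            truth_rows.append(
                {"protein_id": pid, "k": k, "offsets": ";".join(map(str, offsets))}
            )
        else:
            records.append(SequenceRecord(pid, _random_protein(rng, int(rng.integers(150, 401)))))
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "k", "offsets"])
    return records, truth


def gen_qtl_map(
    seed: int,
    chroms: tuple[str, ...] = ("c1", "c2", "c3", "c4", "c5"),
    n_clusters: int = 5,
    cluster_size_range: tuple[int, int] = (4, 8),
    cluster_span: float = 15.0,
    window: float = 20.0,
    n_background: int = 50,
    traits: tuple[str, ...] = FIBER_TRAITS,
    chrom_length: float = 150.0,
    anchors_per_chrom: int = 8,
    bp_per_cm: float = 1e6,
) -> tuple[list[QtlRecord], dict[str, list[MarkerAnchor]], pd.DataFrame]:
    """Genetic map with planted same-trait QTL clusters and scattered noise.

    Planted clusters hold ``cluster_size_range`` same-trait peaks within a
    span below *window*.  Background QTL are scattered but kept at least
    2 x *window* from any same-trait planted cluster and more than *window*
    apart from each other (same trait and chromosome), so planted clusters
    are exactly the detectable hotspots by construction.  Marker anchors
    are monotone in cM and bp with jittered spacing.  Truth lists each
    planted cluster's trait, chromosome, peak interval, and member ids.
    """
    if cluster_span >= window:
        raise ValueError("cluster span must be smaller than the hotspot window")
    rng = _rng(seed, "qtl_map")
    qtls: list[QtlRecord] = []
    truth_rows: list[dict] = []
    planted: dict[tuple[str, str], list[tuple[float, float]]] = {}

    for ci in range(n_clusters):
        chrom = chroms[ci % len(chroms)]
        trait = traits[ci % len(traits)]
        size = int(rng.integers(cluster_size_range[0], cluster_size_range[1] + 1))
        lo = float(rng.uniform(0, chrom_length - cluster_span))
        peaks = np.sort(rng.uniform(lo, lo + cluster_span, size=size))
        # pin the extremes so the truth interval is exact
        peaks[0], peaks[-1] = lo, lo + cluster_span
        member_ids = []
        for j, peak in enumerate(peaks):
            qid = f"q_cluster{ci}_{j}"
            member_ids.append(qid)
            qtls.append(QtlRecord(qid, trait, chrom, round(float(peak), 3), source="planted"))
        planted.setdefault((trait, chrom), []).append((lo, lo + cluster_span))
        truth_rows.append(
            {
                "cluster_id": f"cluster{ci}",
                "trait": trait,
                "chrom": chrom,
                "cM_lo": round(peaks[0], 3),
                "cM_hi": round(peaks[-1], 3),
                "n_members": size,
                "member_qtl_ids": ";".join(member_ids),
            }
        )

    accepted: dict[tuple[str, str], list[float]] = {}
    attempts = 0
    bg = 0
    while bg < n_background and attempts < 100 * n_background:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        trait = traits[int(rng.integers(len(traits)))]
        pos = float(rng.uniform(0, chrom_length))
        key = (trait, chrom)
        near_cluster = any(
            lo - 2 * window <= pos <= hi + 2 * window for lo, hi in planted.get(key, [])
        )
        near_background = any(abs(pos - other) <= window for other in accepted.get(key, []))
        if near_cluster or near_background:
            continue
        accepted.setdefault(key, []).append(pos)
        qtls.append(QtlRecord(f"q_bg{bg}", trait, chrom, round(pos, 3), source="background"))
        bg += 1

    anchors: dict[str, list[MarkerAnchor]] = {}
    for chrom in chroms:
        cms = np.linspace(0, chrom_length, anchors_per_chrom)
        increments = rng.uniform(0.5, 1.5, size=anchors_per_chrom - 1) * bp_per_cm
        bps = np.concatenate([[0.0], np.cumsum(increments * np.diff(cms))])
        anchors[chrom] = [
            MarkerAnchor(f"m_{chrom}_{i}", chrom, float(c), int(round(b)))
            for i, (c, b) in enumerate(zip(cms, bps))
        ]
    return qtls, anchors, pd.DataFrame(truth_rows)


def gen_bil(
    seed: int,
    n_lines: int = 180,
    n_markers: int = 10,
    effects: dict[str, tuple[str, float]] | None = None,
    traits: tuple[str, ...] = ("FL", "FS"),
    n_environments: int = 4,
    resid_sd: float = 1.0,
    donor_freq: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """BIL genotypes and multi-environment phenotypes with planted effects.

    Genotypes are Bernoulli(*donor_freq*) per marker (1 = donor allele),
    independent across markers.  *effects* maps a marker name to
    ``(trait, target_r)``: the marker's additive effect size is chosen so
    the population point-biserial correlation with the trait equals
    ``target_r`` given the residual SD.  Each environment adds its own
    intercept and fresh N(0, resid_sd) noise.  Truth lists marker, trait,
    and target r.
    """
    if effects is None:
        effects = {"M0001": ("FL", 0.30)}
    rng = _rng(seed, "bil")
    marker_names = [f"M{i + 1:04d}" for i in range(n_markers)]
    unknown = set(effects) - set(marker_names)
    if unknown:
        raise ValueError(f"effects reference unknown markers: {sorted(unknown)}")

    genotypes = (rng.random((n_lines, n_markers)) < donor_freq).astype(float)
    geno = pd.DataFrame(genotypes, columns=marker_names)
    geno.insert(0, "line_id", [f"L{i + 1:03d}" for i in range(n_lines)])

    sd_g = float(np.sqrt(donor_freq * (1 - donor_freq)))
    betas: dict[str, dict[str, float]] = {t: {} for t in traits}
    for marker, (trait, target_r) in effects.items():
        if trait not in traits:
            raise ValueError(f"effect trait {trait!r} not in traits {traits}")
        betas[trait][marker] = target_r / np.sqrt(1 - target_r**2) * resid_sd / sd_g

    pheno_rows = []
    for e in range(n_environments):
        env = f"env{e + 1}"
        intercepts = {t: float(rng.normal(10.0, 2.0)) for t in traits}
        for i in range(n_lines):
            row = {"line_id": geno.loc[i, "line_id"], "environment": env}
            for trait in traits:
                signal = sum(
                    beta * genotypes[i, marker_names.index(m)]
                    for m, beta in betas[trait].items()
                )
                row[trait] = intercepts[trait] + signal + float(rng.normal(0, resid_sd))
            pheno_rows.append(row)
    pheno = pd.DataFrame(pheno_rows)
    truth = pd.DataFrame(
        [
            {"marker_id": m, "trait": t, "target_r": r}
            for m, (t, r) in sorted(effects.items())
        ]
    )
    return geno, pheno, truth


def gen_codon_pairs(
    seed: int,
    n_pairs: int = 200,
    n_codons: int = 100,
    omega: float = 0.2,
    n_proposals: int = 60,
) -> list[tuple[str, str]]:
    """Aligned coding-sequence pairs evolved under a known dN/dS.

    One lineage accumulates proposed single-base changes: synonymous
    proposals are always accepted, nonsynonymous ones with probability
    *omega*, and stop-creating ones rejected — so the generating
    nonsynonymous/synonymous rate ratio is *omega* by construction.
    """
    from Bio.Data.CodonTable import standard_dna_table

    stops = set(standard_dna_table.stop_codons)
    code = standard_dna_table.forward_table
    bases = "ACGT"
    sense = ["".join(c) for c in product(bases, repeat=3) if "".join(c) not in stops]
    rng = _rng(seed, "codon_pairs")
    pairs: list[tuple[str, str]] = []
    for _ in range(n_pairs):
        seq_a = list(rng.choice(sense, size=n_codons))
        seq_b = list(seq_a)
        for _ in range(n_proposals):
            idx = int(rng.integers(n_codons))
            pos = int(rng.integers(3))
            base = bases[int(rng.integers(4))]
            codon = seq_b[idx]
            if codon[pos] == base:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in stops:
                continue
            if code[mutant] == code[codon] or rng.random() < omega:
                seq_b[idx] = mutant
        pairs.append(("".join(seq_a), "".join(seq_b)))
    return pairs


_SITE_CLASSES = (
    "interspecific",
    "parentA_specific",
    "parentB_specific",
    "conflicting",
    "unclassifiable",
)


def gen_allele_matrix(
    seed: int,
    n_sites: int = 30,
    mixture: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-assembly allele matrix with known site classes.

    Rows are constructed to satisfy (or deliberately violate) the SNP
    classification rule for their intended class, so a rule-consistent
    classifier recovers the truth exactly.
    """
    if mixture is None:
        mixture = {
            "interspecific": 0.6,
            "parentA_specific": 0.15,
            "parentB_specific": 0.15,
            "conflicting": 0.05,
            "unclassifiable": 0.05,
        }
    unknown = set(mixture) - set(_SITE_CLASSES)
    if unknown:
        raise ValueError(f"unknown site classes in mixture: {sorted(unknown)}")
    rng = _rng(seed, "allele_matrix")
    counts = _allocate(n_sites, mixture)

    rows: list[dict] = []
    truth: list[dict] = []
    i = 0
    for cls in _SITE_CLASSES:
        for _ in range(counts.get(cls, 0)):
            x, y, z = rng.choice(list("ACGT"), size=3, replace=False)
            if cls == "interspecific":
                alleles = [x, x, x, y, y, y, y]
            elif cls == "parentA_specific":
                alleles = [x, x, z, x, x, x, x]
            elif cls == "parentB_specific":
                alleles = [x, x, x, y, y, x, x]
            elif cls == "conflicting":
                alleles = [x, x, z, y, y, x, x]
            else:  # unclassifiable: parents agree
                alleles = [x, x, y, y, y, x, x]
            gene_id = f"G{i // 2 + 1:03d}"  # roughly two sites per gene
            site_id = f"c{i % 13 + 1}_SNP_{1_000_000 + 1000 * i}"
            row = {"gene_id": gene_id, "site_id": site_id}
            row.update(dict(zip(ALLELE_SOURCE_COLUMNS, alleles)))
            rows.append(row)
            truth.append({"site_id": site_id, "truth_class": cls})
            i += 1
    matrix = pd.DataFrame(rows, columns=["gene_id", "site_id", *ALLELE_SOURCE_COLUMNS])
    return matrix, pd.DataFrame(truth)


def gen_ortholog_groups(
    seed: int,
    n_groups: int = 40,
    proportions: dict[str, float] | None = None,
) -> tuple[list[OrthologGroup], pd.DataFrame]:
    """Ortholog groups with known retention/loss scenarios.

    *proportions* maps scenario labels to mixing proportions (summing to 1);
    counts are allocated by largest remainder so planted counts are exact.
    """
    if proportions is None:
        proportions = {
            "RETAINED_ALL": 0.80,
            "LOSS_ONE_SUBGENOME_AD1": 0.075,
            "LOSS_ONE_SUBGENOME_AD2": 0.125,
        }
    rng = _rng(seed, "ortholog_groups")
    counts = _allocate(n_groups, proportions)

    groups: list[OrthologGroup] = []
    truth: list[dict] = []
    i = 0
    for label, count in counts.items():
        for _ in range(count):
            absent: set[str] = set()
            if label == "RETAINED_ALL":
                pass
            elif label.startswith("LOSS_ONE_SUBGENOME_"):
                species = label.rsplit("_", 1)[1]
                sub = "At" if rng.random() < 0.5 else "Dt"
                absent = {f"{sub}_{species}"}
            elif label.startswith("LOSS_BOTH_SUBGENOMES_"):
                species = label.rsplit("_", 1)[1]
                absent = {f"At_{species}", f"Dt_{species}"}
            elif label == "LOSS_DIPLOID_ONLY":
                absent = {"A2" if rng.random() < 0.5 else "D5"}
            elif label == "LOSS_SUBGENOME_AND_PROGENITOR":
                species = "AD1" if rng.random() < 0.5 else "AD2"
                if rng.random() < 0.5:
                    absent = {"A2", f"At_{species}"}
                else:
                    absent = {"D5", f"Dt_{species}"}
            elif label == "OTHER":
                absent = {"A2", "At_AD1", "At_AD2"}
            else:
                raise ValueError(f"unknown scenario label {label!r}")
            gid = f"og{i:03d}"
            slots = {s: (None if s in absent else f"{gid}_{s}") for s in SLOTS}
            groups.append(OrthologGroup(gid, **slots))
            truth.append({"group_id": gid, "truth_scenario": label})
            i += 1
    return groups, pd.DataFrame(truth)
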