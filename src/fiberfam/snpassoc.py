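"""Interspecific SNP typing, marker-trait association, and expression
concordance for an interspecific backcross inbred line (BIL) population.

The allele matrix compares, at each coding SNP site, the two BIL parents
(G. hirsutum CCRI 36 and G. barbadense Hai 7124) against independent genome
assemblies of both species.  A site is *interspecific* when each parent's
allele is characteristic of its species across assemblies, and
parent-specific when one parent deviates from its own species' references.

Association uses the point-biserial Pearson correlation between a 0/1
donor-allele genotype (1 = Hai 7124 allele present) and a quantitative
fiber trait, per environment, with per-test significance stars at 0.05 (*)
and 0.01 (**) and a stability count of significant environments.  qPCR
relative expression uses the 2^-ddCt method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from .io import ALLELE_SOURCE_COLUMNS

__all__ = [
    "SnpSite",
    "AssociationResult",
    "DdctResult",
    "ConcordanceCall",
    "call_nonsynonymous",
    "classify_snp_site",
    "site_from_row",
    "classify_matrix",
    "associate_markers",
    "ddct",
    "expression_concordance",
]

_STOPS = set(standard_dna_table.stop_codons)
_CODE = dict(standard_dna_table.forward_table)


@dataclass(frozen=True)
class SnpSite:
    """A multi-assembly allele vector at one coding SNP site.

    Species A is G. hirsutum (parent CCRI 36; reference assemblies TM-1 NAU
    and JGI); species B is G. barbadense (parent Hai 7124, whose own genome
    assembly is the ZJU one; further references Xinhai 21 and 3-79).
    """

    gene_id: str
    site_id: str
    speciesA_refs: tuple[str, ...]
    speciesA_parent: str
    speciesB_parent: str
    speciesB_own_assembly: str
    speciesB_other_refs: tuple[str, ...]


@dataclass
class AssociationResult:
    marker_id: str
    trait: str
    environment: str
    r: float | None
    n: int
    p: float | None
    stars: str  # "", "*", "**"
    stability: int = 0  # filled in per (marker, trait) after all environments


@dataclass(frozen=True)
class DdctResult:
    target_gene: str
    sample: str
    delta_ct: float
    delta_delta_ct: float
    fold: float


@dataclass
class ConcordanceCall:
    gene_id: str
    association_sign: str  # "+" or "-"
    concordant: bool
    supporting_stages: list[str] = field(default_factory=list)


def call_nonsynonymous(ref_codon: str, offset: int, alt_base: str) -> str:
    """Classify a single-base coding change.

    Returns ``synonymous``, ``nonsynonymous``, ``stop_gained``,
    ``stop_lost``, or ``unclassifiable`` (codon containing N).  Raises if
    *alt_base* equals the reference base at *offset*.
    """
    ref_codon = ref_codon.upper()
    alt_base = alt_base.upper()
    if offset not in (0, 1, 2):
        raise ValueError(f"offset must be 0, 1, or 2 (got {offset})")
    if "N" in ref_codon or alt_base == "N":
        return "unclassifiable"
    if ref_codon[offset] == alt_base:
        raise ValueError("alt base equals the reference base at the given offset")
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    ref_stop, alt_stop = ref_codon in _STOPS, alt_codon in _STOPS
    if ref_stop and not alt_stop:
        return "stop_lost"
    if alt_stop and not ref_stop:
        return "stop_gained"
    if ref_stop and alt_stop:
        return "synonymous"
    return "synonymous" if _CODE[ref_codon] == _CODE[alt_codon] else "nonsynonymous"


def classify_snp_site(site: SnpSite) -> str:
    """Classify an allele vector as interspecific or parent-specific.

    Rule, evaluated on non-missing parental alleles:

    1. parents equal -> ``unclassifiable``;
    2. species-A parent differing from every species-A reference assembly
       -> candidate ``parentA_specific``;
    3. species-B parent matching its own assembly AND differing from every
       other species-B reference -> candidate ``parentB_specific``;
    4. both 2 and 3 -> ``conflicting``;
    5. neither -> ``interspecific``.

    The own-assembly confirmation in rule 3 is what separates a
    parent-specific variant (an accession-private allele) from a genuine
    between-species difference.
    """
    if "N" in (site.speciesA_parent, site.speciesB_parent):
        return "unclassifiable"
    if site.speciesA_parent == site.speciesB_parent:
        return "unclassifiable"
    a_specific = all(site.speciesA_parent != ref for ref in site.speciesA_refs)
    b_specific = site.speciesB_parent == site.speciesB_own_assembly and all(
        site.speciesB_parent != ref for ref in site.speciesB_other_refs
    )
    if a_specific and b_specific:
        return "conflicting"
    if a_specific:
        return "parentA_specific"
    if b_specific:
        return "parentB_specific"
    return "interspecific"


def site_from_row(row: pd.Series | dict) -> SnpSite:
    """Build a :class:`SnpSite` from one allele-matrix table row."""
    cols = ALLELE_SOURCE_COLUMNS
    return SnpSite(
        gene_id=row["gene_id"],
        site_id=row["site_id"],
        speciesA_refs=(row[cols[0]], row[cols[1]]),
        speciesA_parent=row[cols[2]],
        speciesB_parent=row[cols[3]],
        speciesB_own_assembly=row[cols[4]],
        speciesB_other_refs=(row[cols[5]], row[cols[6]]),
    )


def classify_matrix(matrix: pd.DataFrame) -> pd.Series:
    """Classify every row of an allele-matrix table; returns a label Series."""
    return matrix.apply(lambda row: classify_snp_site(site_from_row(row)), axis=1)


def _stars(p: float, alpha1: float, alpha2: float) -> str:
    if p < alpha2:
        return "**"
    if p < alpha1:
        return "*"
    return ""


def associate_markers(
    genotype: pd.DataFrame,
    phenotype: pd.DataFrame,
    alpha1: float = 0.05,
    alpha2: float = 0.01,
) -> list[AssociationResult]:
    """Marker-trait correlation per environment in a BIL population.

    *genotype* is wide (``line_id`` + one 0/1 column per marker; 1 = donor
    allele, missing = NaN); *phenotype* is ``line_id``, ``environment``,
    plus one numeric column per trait.  For each (marker, trait,
    environment) the Pearson (point-biserial) r and its two-sided t-test
    p-value (df = n - 2) are computed over lines with both values present;
    a constant genotype or phenotype yields an undefined result (r and p
    None) rather than an exception.  ``stability`` is the number of
    environments significant at *alpha1* for the (marker, trait) pair.
    """
    markers = [c for c in genotype.columns if c != "line_id"]
    traits = [c for c in phenotype.columns if c not in ("line_id", "environment")]
    environments = list(dict.fromkeys(phenotype["environment"]))
    geno = genotype.set_index("line_id")

    results: list[AssociationResult] = []
    for marker in markers:
        for trait in traits:
            per_env: list[AssociationResult] = []
            for env in environments:
                pheno_env = phenotype[phenotype["environment"] == env].set_index("line_id")
                joined = pd.concat(
                    [geno[marker], pheno_env[trait]], axis=1, join="inner"
                ).dropna()
                g = joined[marker].to_numpy(dtype=float)
                y = joined[trait].to_numpy(dtype=float)
                n = len(joined)
                if n < 3 or np.ptp(g) == 0 or np.ptp(y) == 0:
                    per_env.append(AssociationResult(marker, trait, env, None, n, None, ""))
                    continue
                r, p = stats.pearsonr(g, y)
                per_env.append(
                    AssociationResult(
                        marker, trait, env, float(r), n, float(p), _stars(p, alpha1, alpha2)
                    )
                )
            stability = sum(1 for res in per_env if res.stars)
            for res in per_env:
                res.stability = stability
            results.extend(per_env)
    return results


def ddct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> list[DdctResult]:
    """Relative expression by the 2^-ddCt method.

    *ct_table* has columns ``sample``, ``gene``, ``ct`` with one row per
    replicate; replicate Cts are averaged per (sample, gene) before
    differencing.  dCt = Ct_target - Ct_reference per sample; ddCt =
    dCt_sample - dCt_calibrator; fold = 2^-ddCt.  A sample lacking the
    reference gene raises an error naming it.
    """
    means = ct_table.groupby(["sample", "gene"])["ct"].mean()
    samples = list(dict.fromkeys(ct_table["sample"]))
    targets = [g for g in dict.fromkeys(ct_table["gene"]) if g != reference_gene]
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")

    delta_ct: dict[tuple[str, str], float] = {}
    for sample in samples:
        if (sample, reference_gene) not in means.index:
            raise ValueError(f"sample {sample!r} is missing the reference gene Ct")
        for gene in targets:
            if (sample, gene) in means.index:
                delta_ct[(sample, gene)] = float(
                    means[(sample, gene)] - means[(sample, reference_gene)]
                )

    results: list[DdctResult] = []
    for gene in targets:
        if (calibrator_sample, gene) not in delta_ct:
            raise ValueError(f"calibrator sample lacks Ct for target gene {gene!r}")
        calib = delta_ct[(calibrator_sample, gene)]
        for sample in samples:
            if (sample, gene) not in delta_ct:
                continue
            ddct_value = delta_ct[(sample, gene)] - calib
            results.append(
                DdctResult(gene, sample, delta_ct[(sample, gene)], ddct_value, 2.0 ** -ddct_value)
            )
    return results


def expression_concordance(
    association_sign: str,
    speciesB_expression: dict[str, float],
    speciesA_expression: dict[str, float],
    gene_id: str = "",
    require_all_stages: bool = False,
) -> ConcordanceCall:
    """Test whether allele-pair expression ordering matches the association sign.

    With a negative marker-trait association (donor allele lowers the
    trait), concordance requires the species-B (donor) allele to be
    expressed below the species-A allele in at least one shared development
    stage; with a positive sign the ordering is reversed.  Stages supporting
    the call are listed.  *require_all_stages* strengthens "at least one"
    to "every shared stage".
    """
    if association_sign not in ("+", "-"):
        raise ValueError("association sign must be '+' or '-'")
    shared = [s for s in speciesB_expression if s in speciesA_expression]
    if not shared:
        raise ValueError("no shared stages between the two allele expression profiles")
    if association_sign == "-":
        supporting = [s for s in shared if speciesB_expression[s] < speciesA_expression[s]]
    else:
        supporting = [s for s in shared if speciesB_expression[s] > speciesA_expression[s]]
    concordant = len(supporting) == len(shared) if require_all_stages else bool(supporting)
    return ConcordanceCall(gene_id, association_sign, concordant, supporting)
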