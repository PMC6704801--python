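"""SNP typing, marker-trait association, ddCt, and concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fiberfam import snpassoc, synth
from fiberfam.io import ALLELE_SOURCE_COLUMNS


class TestCallNonsynonymous:
    @pytest.mark.parametrize(
        "codon,offset,alt,expected",
        [
            ("GGT", 2, "C", "synonymous"),  # fourfold-degenerate Gly site
            ("TTT", 2, "A", "nonsynonymous"),  # Phe -> Leu
            ("TGG", 1, "A", "stop_gained"),  # Trp -> stop
            ("TAA", 0, "C", "stop_lost"),
            ("GNT", 2, "C", "unclassifiable"),
        ],
    )
    def test_examples(self, codon, offset, alt, expected):
        assert snpassoc.call_nonsynonymous(codon, offset, alt) == expected

    def test_alt_equal_to_ref_rejected(self):
        with pytest.raises(ValueError, match="alt base equals"):
            snpassoc.call_nonsynonymous("GGT", 0, "G")


def site(alleles):
    row = {"gene_id": "g", "site_id": "s"}
    row.update(dict(zip(ALLELE_SOURCE_COLUMNS, alleles)))
    return snpassoc.site_from_row(row)


class TestClassifySnpSite:
    @pytest.mark.parametrize(
        "alleles,expected",
        [
            ("CCCAAAA", "interspecific"),  # canonical between-species site
            ("GGAGGGG", "parentA_specific"),  # parent A deviates from its refs
            ("TTTGGTT", "parentB_specific"),  # own assembly confirms, others differ
            ("GAGAGGG", "interspecific"),  # one A-ref matches parent A; B unconfirmed
            ("GGGAAAG", "interspecific"),  # one B-other-ref carries the B allele
            ("AANNAAA", "unclassifiable"),  # missing parental allele
            ("AACCAAA", "unclassifiable"),  # parents agree
        ],
    )
    def test_rule(self, alleles, expected):
        assert snpassoc.classify_snp_site(site(list(alleles))) == expected

    def test_conflicting_when_both_parent_rules_fire(self):
        assert snpassoc.classify_snp_site(site(list("GGAtTGG".upper()))) == "conflicting"

    def test_table1_reproduced_exactly(self, table1):
        labels = snpassoc.classify_matrix(table1)
        printed = table1["snp_type"].map(
            {
                "Interspecific": "interspecific",
                "CCRI 36-specific": "parentA_specific",
                "Hai 7124-specific": "parentB_specific",
            }
        )
        assert (labels == printed).all()
        counts = labels.value_counts().to_dict()
        assert counts == {"interspecific": 20, "parentB_specific": 4, "parentA_specific": 3}
        interspecific_genes = table1.loc[labels == "interspecific", "gene_id"].nunique()
        assert interspecific_genes == 14

    def test_synthetic_matrix_classes_recovered(self):
        matrix, truth = synth.gen_allele_matrix(23)
        labels = snpassoc.classify_matrix(matrix)
        assert list(labels) == list(truth["truth_class"])


def make_tables(genotype_vectors, trait_values, environments=("e1",)):
    lines = [f"L{i}" for i in range(len(next(iter(genotype_vectors.values()))))]
    geno = pd.DataFrame({"line_id": lines, **genotype_vectors})
    rows = []
    for env in environments:
        for i, line in enumerate(lines):
            rows.append({"line_id": line, "environment": env, **{t: v[i] for t, v in trait_values.items()}})
    return geno, pd.DataFrame(rows)


class TestAssociateMarkers:
    def test_perfect_separation(self):
        geno, pheno = make_tables({"M1": [0, 0, 1, 1]}, {"FL": [1, 1, 3, 3]})
        (result,) = snpassoc.associate_markers(geno, pheno)
        assert result.r == pytest.approx(1.0)

    def test_constant_phenotype_undefined(self):
        geno, pheno = make_tables({"M1": [0, 1, 0, 1]}, {"FL": [2, 2, 2, 2]})
        (result,) = snpassoc.associate_markers(geno, pheno)
        assert (result.r, result.p, result.stars) == (None, None, "")

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 2, size=40).astype(float)
        y = g + rng.normal(0, 1, size=40)
        geno, pheno = make_tables({"M1": g}, {"FL": y})
        swapped, _ = make_tables({"M1": 1 - g}, {"FL": y})
        (a,) = snpassoc.associate_markers(geno, pheno)
        (b,) = snpassoc.associate_markers(swapped, pheno)
        assert a.r == pytest.approx(-b.r)
        assert a.p == pytest.approx(b.p)

    def test_missing_values_excluded_pairwise(self):
        geno, pheno = make_tables(
            {"M1": [0, 0, 1, 1, np.nan]}, {"FL": [1.0, 1.1, 3.0, 2.9, 100.0]}
        )
        (result,) = snpassoc.associate_markers(geno, pheno)
        assert result.n == 4

    def test_stability_counts_significant_environments(self):
        rng = np.random.default_rng(17)
        g = (rng.random(120) < 0.5).astype(float)
        envs = ("e1", "e2", "e3")
        # strong effect in two environments, pure noise in the third
        geno = pd.DataFrame({"line_id": [f"L{i}" for i in range(120)], "M1": g})
        rows = []
        for env in envs:
            effect = 1.5 if env != "e3" else 0.0
            y = effect * g + rng.normal(0, 1, 120)
            rows += [
                {"line_id": f"L{i}", "environment": env, "FL": y[i]} for i in range(120)
            ]
        results = snpassoc.associate_markers(geno, pd.DataFrame(rows))
        assert {r.environment: bool(r.stars) for r in results} == {"e1": True, "e2": True, "e3": False}
        assert all(r.stability == 2 for r in results)


class TestDdct:
    def make_ct(self):
        rows = []
        for sample, target_ct, ref_ct in [("calib", 24.0, 20.0), ("s1", 22.0, 20.0), ("s2", 25.0, 20.0)]:
            for rep_offset in (-0.5, 0.0, 0.5):  # technical replicates average out
                rows.append({"sample": sample, "gene": "MYB", "ct": target_ct + rep_offset})
                rows.append({"sample": sample, "gene": "UBQ7", "ct": ref_ct + rep_offset})
        return pd.DataFrame(rows)

    def test_fold_changes(self):
        results = snpassoc.ddct(self.make_ct(), "UBQ7", "calib")
        folds = {r.sample: r.fold for r in results}
        assert folds["calib"] == pytest.approx(1.0)  # ddCt = 0
        assert folds["s1"] == pytest.approx(4.0)  # ddCt = -2
        assert folds["s2"] == pytest.approx(0.5)  # ddCt = +1

    def test_missing_reference_names_sample(self):
        table = pd.DataFrame(
            [{"sample": "s1", "gene": "MYB", "ct": 22.0}, {"sample": "calib", "gene": "MYB", "ct": 24.0},
             {"sample": "calib", "gene": "UBQ7", "ct": 20.0}]
        )
        with pytest.raises(ValueError, match="s1"):
            snpassoc.ddct(table, "UBQ7", "calib")

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=-20, max_value=20, allow_nan=False))
    def test_fold_inverts_exactly(self, ddct_value):
        assert 2.0**-ddct_value * 2.0**ddct_value == pytest.approx(1.0)
        result = snpassoc.DdctResult("g", "s", 0.0, ddct_value, 2.0**-ddct_value)
        assert result.fold > 0


class TestConcordance:
    def test_negative_sign_lower_donor_expression(self):
        call = snpassoc.expression_concordance(
            "-", {"10DPA": 2, "20DPA": 3, "25DPA": 4}, {"10DPA": 5, "20DPA": 6, "25DPA": 7}
        )
        assert call.concordant
        assert call.supporting_stages == ["10DPA", "20DPA", "25DPA"]

    def test_positive_sign_with_always_lower_donor_is_discordant(self):
        call = snpassoc.expression_concordance(
            "+", {"10DPA": 2, "20DPA": 3}, {"10DPA": 5, "20DPA": 6}
        )
        assert not call.concordant

    def test_single_supporting_stage_suffices(self):
        """Donor allele higher only at the elongation stage still concords."""
        call = snpassoc.expression_concordance(
            "+", {"10DPA": 9, "20DPA": 3}, {"10DPA": 5, "20DPA": 6}
        )
        assert call.concordant and call.supporting_stages == ["10DPA"]
        strict = snpassoc.expression_concordance(
            "+", {"10DPA": 9, "20DPA": 3}, {"10DPA": 5, "20DPA": 6}, require_all_stages=True
        )
        assert not strict.concordant

    def test_no_shared_stages_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            snpassoc.expression_concordance("-", {"10DPA": 1}, {"20DPA": 2})
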