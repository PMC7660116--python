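"""Reading, allele orientation and exposure/outcome harmonization."""

import io

import numpy as np
import pandas as pd
import pytest

import periomr as pm
from periomr.exceptions import ConfigurationError, HarmonizationError, ValidationError


def _tsv(text):
    return io.StringIO(text.replace(" | ", "\t"))


class TestReadGwasTable:
    def test_reads_rows_with_column_map(self):
        buf = _tsv(
            "SNP | EA | NEA | FREQ | BETA | SE | P\n"
            "rs1537415 | c | g | 0.41 | 0.4637 | 0.08 | 5.51e-9\n"
        )
        df = pm.read_gwas_table(
            buf,
            column_map={
                "variant_id": "SNP",
                "effect_allele": "EA",
                "other_allele": "NEA",
                "eaf": "FREQ",
                "beta": "BETA",
                "se": "SE",
                "p_value": "P",
            },
        )
        assert len(df) == 1
        row = df.iloc[0]
        assert row["effect_allele"] == "C" and row["other_allele"] == "G"
        assert row["eaf"] == 0.41
        assert np.isnan(row["n_total"])

    def test_header_only_file_gives_empty_collection(self):
        df = pm.read_gwas_table(_tsv("variant_id | effect_allele | other_allele | beta | se\n"))
        assert len(df) == 0

    def test_zero_se_names_the_row(self):
        buf = _tsv(
            "variant_id | effect_allele | other_allele | beta | se\n"
            "rs1 | A | G | 0.1 | 0.05\n"
            "rs2 | A | G | 0.1 | 0\n"
        )
        with pytest.raises(ValidationError, match="row 2"):
            pm.read_gwas_table(buf)

    def test_non_acgt_allele_rejected(self):
        buf = _tsv("variant_id | effect_allele | other_allele | beta | se\nrs1 | A | I | 0.1 | 0.05\n")
        with pytest.raises(ValidationError, match="A/C/G/T"):
            pm.read_gwas_table(buf)

    def test_unknown_mapped_header_is_configuration_error(self):
        buf = _tsv("variant_id | effect_allele | other_allele | beta | se\n")
        with pytest.raises(ConfigurationError, match="nope"):
            pm.read_gwas_table(buf, column_map={"beta": "nope"})

    def test_comma_delimited_accepted(self):
        buf = io.StringIO("variant_id,effect_allele,other_allele,beta,se\nrs1,A,G,0.2,0.1\n")
        df = pm.read_gwas_table(buf)
        assert df.loc[0, "beta"] == 0.2

    def test_round_trip_through_writer(self, tmp_path):
        cfg = pm.SyntheticConfig(n_variants=8, theta=0.05, seed=42)
        exposure, _, _ = pm.simulate_two_sample(cfg)
        path = tmp_path / "exposure.tsv"
        pm.write_gwas_table(exposure, path, header_comment="seed=42")
        back = pm.read_gwas_table(path)
        pd.testing.assert_frame_equal(back, exposure.reset_index(drop=True), check_exact=False, rtol=1e-12)


class TestOrientRiskIncreasing:
    def test_negative_beta_swaps_alleles_and_complements_frequency(self):
        df = pd.DataFrame(
            [{"variant_id": "rs1537415", "effect_allele": "G", "other_allele": "C",
              "eaf": 0.59, "beta": -0.464, "se": 0.08}]
        )
        out = pm.orient_risk_increasing(df)
        row = out.iloc[0]
        assert (row["effect_allele"], row["other_allele"]) == ("C", "G")
        assert row["beta"] == pytest.approx(0.464)
        assert row["eaf"] == pytest.approx(0.41)

    def test_positive_beta_unchanged(self):
        df = pd.DataFrame(
            [{"variant_id": "rs1", "effect_allele": "A", "other_allele": "G",
              "eaf": 0.2, "beta": 0.25, "se": 0.05}]
        )
        pd.testing.assert_frame_equal(pm.orient_risk_increasing(df), df)

    def test_instrument_fixture_already_risk_increasing(self, instruments):
        out = pm.orient_risk_increasing(instruments)
        assert (out["beta"] > 0).all()
        assert list(out["effect_allele"]) == list(instruments["effect_allele"])

    def test_involution(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "variant_id": [f"rs{i}" for i in range(20)],
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": rng.uniform(0.05, 0.95, 20),
                "beta": rng.normal(0, 0.3, 20),
                "se": 0.05,
            }
        )
        once = pm.orient_risk_increasing(df)
        twice = pm.orient_risk_increasing(once)
        pd.testing.assert_frame_equal(once, twice)


def _variant(vid, ea, oa, eaf, beta, se=0.05):
    return {"variant_id": vid, "effect_allele": ea, "other_allele": oa,
            "eaf": eaf, "beta": beta, "se": se}


class TestHarmonize:
    def test_label_swap_flips_outcome_sign(self):
        exposure = pd.DataFrame([_variant("rs1", "T", "C", 0.3, 0.4)])
        outcome = pd.DataFrame([_variant("rs1", "C", "T", 0.7, 0.1, se=0.02)])
        pairs, report = pm.harmonize(exposure, outcome)
        assert report.actions["rs1"] == "allele-swap"
        assert pairs.loc[0, "beta_outcome"] == pytest.approx(-0.1)
        assert pairs.loc[0, "eaf_outcome"] == pytest.approx(0.3)

    def test_opposite_strand_alleles_aligned_after_complementing(self):
        exposure = pd.DataFrame([_variant("rs1", "A", "G", 0.3, 0.4)])
        outcome = pd.DataFrame([_variant("rs1", "T", "C", 0.3, 0.1, se=0.02)])
        pairs, report = pm.harmonize(exposure, outcome)
        assert report.actions["rs1"] == "as-is"
        assert pairs.loc[0, "beta_outcome"] == pytest.approx(0.1)

    def test_palindromic_concordant_frequencies_resolved(self):
        exposure = pd.DataFrame([_variant("rs1537415", "C", "G", 0.41, 0.46)])
        outcome = pd.DataFrame([_variant("rs1537415", "C", "G", 0.40, 0.02, se=0.01)])
        pairs, report = pm.harmonize(exposure, outcome)
        assert report.actions["rs1537415"] == "frequency-resolved"
        assert pairs.loc[0, "beta_outcome"] == pytest.approx(0.02)

    def test_palindromic_frequency_inside_window_dropped(self):
        # 0.43 is within the default +/-0.08 band around 0.5 -> too ambiguous
        exposure = pd.DataFrame([_variant("rs1537415", "C", "G", 0.41, 0.46)])
        outcome = pd.DataFrame([_variant("rs1537415", "C", "G", 0.43, 0.02, se=0.01)])
        _, report = pm.harmonize(exposure, outcome)
        assert report.actions["rs1537415"] == "dropped-ambiguous"
        # a narrower window keeps it
        _, report = pm.harmonize(exposure, outcome, ambiguity_window=0.05)
        assert report.actions["rs1537415"] == "frequency-resolved"

    def test_palindromic_discordant_frequencies_flipped(self):
        exposure = pd.DataFrame([_variant("rs1", "A", "T", 0.3, 0.46)])
        outcome = pd.DataFrame([_variant("rs1", "A", "T", 0.7, 0.02, se=0.01)])
        pairs, _ = pm.harmonize(exposure, outcome)
        assert pairs.loc[0, "beta_outcome"] == pytest.approx(-0.02)
        assert pairs.loc[0, "eaf_outcome"] == pytest.approx(0.3)

    def test_palindromic_near_half_frequency_dropped(self):
        exposure = pd.DataFrame([_variant("rs1", "A", "T", 0.3, 0.46)])
        outcome = pd.DataFrame([_variant("rs1", "A", "T", 0.50, 0.02, se=0.01)])
        pairs, report = pm.harmonize(exposure, outcome)
        assert report.actions["rs1"] == "dropped-ambiguous"
        assert len(pairs) == 0

    def test_palindromic_missing_frequency_dropped_not_guessed(self):
        exposure = pd.DataFrame([_variant("rs1", "C", "G", 0.41, 0.46)])
        outcome = pd.DataFrame([_variant("rs1", "C", "G", np.nan, 0.02, se=0.01)])
        _, report = pm.harmonize(exposure, outcome)
        assert report.actions["rs1"] == "dropped-ambiguous"

    def test_irreconcilable_alleles_dropped_mismatch(self):
        exposure = pd.DataFrame([_variant("rs1", "A", "G", 0.3, 0.4), _variant("rs2", "A", "G", 0.3, 0.4)])
        outcome = pd.DataFrame([_variant("rs1", "A", "C", 0.3, 0.1), _variant("rs2", "A", "G", 0.3, 0.1)])
        pairs, report = pm.harmonize(exposure, outcome)
        assert report.actions["rs1"] == "dropped-mismatch"
        assert list(pairs["variant_id"]) == ["rs2"]

    def test_no_overlap_is_hard_error(self):
        exposure = pd.DataFrame([_variant("rs1", "A", "G", 0.3, 0.4)])
        outcome = pd.DataFrame([_variant("rs2", "A", "G", 0.3, 0.1)])
        with pytest.raises(HarmonizationError, match="no overlapping instruments"):
            pm.harmonize(exposure, outcome)

    def test_self_harmonization_is_identity(self, pairs_factory):
        cfg = pm.SyntheticConfig(
            n_variants=20, theta=0.1, seed=3, palindromic_fraction=0.3, eaf_range=(0.1, 0.4)
        )
        exposure, _, _ = pm.simulate_two_sample(cfg)
        exposure = pm.orient_risk_increasing(exposure)
        pairs, report = pm.harmonize(exposure, exposure)
        assert len(pairs) == 20
        assert set(report.actions.values()) <= {"as-is", "frequency-resolved"}
        np.testing.assert_allclose(
            pairs["ratio_estimate"], pairs["beta_outcome"] / pairs["beta_exposure"]
        )
        np.testing.assert_allclose(pairs["ratio_estimate"], 1.0)

    def test_idempotence_of_harmonized_output(self):
        cfg = pm.SyntheticConfig(n_variants=30, theta=0.1, seed=9, palindromic_fraction=0.2)
        exposure, outcome, _ = pm.simulate_two_sample(cfg)
        exposure = pm.orient_risk_increasing(exposure)
        pairs1, _ = pm.harmonize(exposure, outcome)
        # feed the harmonized outcome back in: nothing further should change
        outcome2 = pairs1[["variant_id", "effect_allele", "other_allele"]].copy()
        outcome2["eaf"] = pairs1["eaf_outcome"]
        outcome2["beta"] = pairs1["beta_outcome"]
        outcome2["se"] = pairs1["se_outcome"]
        pairs2, _ = pm.harmonize(exposure, outcome2)
        for col in ("variant_id", "beta_outcome", "se_outcome", "ratio_estimate", "weight"):
            np.testing.assert_array_equal(pairs1[col].to_numpy(), pairs2[col].to_numpy())

    def test_sign_consistency_under_outcome_allele_flip(self):
        cfg = pm.SyntheticConfig(n_variants=30, theta=0.1, seed=17, palindromic_fraction=0.2)
        exposure, outcome, _ = pm.simulate_two_sample(cfg)
        exposure = pm.orient_risk_increasing(exposure)
        flipped = outcome.copy()
        flipped[["effect_allele", "other_allele"]] = outcome[["other_allele", "effect_allele"]].to_numpy()
        flipped["beta"] = -outcome["beta"]
        flipped["eaf"] = 1.0 - outcome["eaf"]
        pairs1, _ = pm.harmonize(exposure, outcome)
        pairs2, _ = pm.harmonize(exposure, flipped)
        # every numeric column identical; only the recorded action label may
        # differ (it describes the relabelling that was needed, which flips)
        pd.testing.assert_frame_equal(
            pairs1.drop(columns="harmonization_action"),
            pairs2.drop(columns="harmonization_action"),
        )

    def test_action_counts_conserve_intersection(self):
        cfg = pm.SyntheticConfig(n_variants=40, theta=0.0, seed=23, palindromic_fraction=0.4)
        exposure, outcome, _ = pm.simulate_two_sample(cfg)
        exposure = pm.orient_risk_increasing(exposure)
        _, report = pm.harmonize(exposure, outcome)
        assert sum(report.counts.values()) == report.n_intersection == 40

    def test_weight_is_inverse_squared_first_order_se(self, pairs_factory):
        pairs, _ = pairs_factory(n_variants=12, seed=1)
        np.testing.assert_allclose(pairs["weight"], 1.0 / pairs["ratio_se_first_order"] ** 2)
        assert (pairs["weight"] > 0).all() and np.isfinite(pairs["weight"]).all()
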