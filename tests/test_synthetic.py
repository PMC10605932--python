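import dataclasses

import numpy as np
import pytest

from gmnet.network import build_similarity_matrix
from gmnet.synthetic import (
    CohortDesign,
    CohortParseError,
    SCORE_NAMES,
    attach_cognitive_scores,
    default_design,
    generate_cognitive_scores,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from conftest import small_design


class TestDesignValidation:
    def test_default_design_counts_244_split_three_ways(self):
        d = default_design()
        assert d.group_sizes == {"CSVD-c": 49, "CSVD-n": 121, "control": 74}
        assert sum(d.group_sizes.values()) == 244

    def test_nonpositive_group_size_rejected(self):
        with pytest.raises(ValueError, match="size"):
            small_design(group_sizes={"CSVD-c": 1, "control": 4})

    def test_control_homogenization_must_be_zero(self):
        with pytest.raises(ValueError, match="control"):
            small_design(homogenization_effect={"CSVD-c": 0.5, "control": 0.3})

    def test_empty_regional_effect_set_rejected(self):
        with pytest.raises(ValueError, match="empty region set"):
            small_design(regional_bc_effect={"CSVD-c": [((), 1.5)]})

    def test_design_json_round_trip(self, tmp_path):
        d = small_design()
        path = tmp_path / "design.json"
        d.to_json(path)
        d2 = CohortDesign.from_json(path)
        assert d2 == d

    def test_unknown_design_field_rejected(self):
        with pytest.raises(ValueError, match="unknown design fields"):
            CohortDesign.from_json('{"not_a_field": 3}')


class TestGenerateCohort:
    def test_subject_count_and_grouping(self, tiny_cohort):
        assert len(tiny_cohort) == 12
        by_group = {}
        for s in tiny_cohort:
            by_group[s.group] = by_group.get(s.group, 0) + 1
        assert by_group == {"CSVD-c": 4, "CSVD-n": 4, "control": 4}

    def test_seed_determinism_bit_identical(self, tmp_path):
        d = small_design()
        c1, c2 = generate_cohort(d), generate_cohort(d)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_cohort(c1, p1)
        write_cohort(c2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        c1 = generate_cohort(small_design(seed=1))
        c2 = generate_cohort(small_design(seed=2))
        assert not np.array_equal(c1[0].region_values[0],
                                  c2[0].region_values[0])

    def test_subject_invariants(self, tiny_cohort):
        for s in tiny_cohort:
            s.validate()
            assert len(s.region_values) == 90
            assert s.tiv > 0
            assert 0 <= s.cognitive_scores["MoCA"] <= 30
            assert s.cognitive_scores["SCWT"] > 0
            assert s.cognitive_scores["TMT_BA"] > 0

    def test_homogenization_monotonically_raises_mean_similarity(self):
        """The patient effect must strictly raise cohort-mean pairwise
        histogram similarity across increasing effect levels."""
        means = []
        for e in (0.0, 0.5, 1.0):
            d = small_design(
                group_sizes={"CSVD-c": 4},
                homogenization_effect={"CSVD-c": e, "control": 0.0},
                regional_bc_effect={})
            sims = []
            for s in generate_cohort(d):
                S = build_similarity_matrix(s)
                sims.append(S[np.triu_indices(90, 1)].mean())
            means.append(np.mean(sims))
        assert means[0] < means[1] < means[2]


class TestCognitiveScores:
    def test_control_moca_mean_near_table_value(self):
        d = small_design()
        rng = np.random.default_rng(0)
        vals = [generate_cognitive_scores(0.0, "control", d, rng)["MoCA"]
                for _ in range(4000)]
        # ceiling at 30 pulls the realized mean slightly below 26.51
        assert np.mean(vals) == pytest.approx(26.51, abs=0.5)

    def test_zero_noise_zero_coupling_gives_group_mean(self):
        model = {name: {g: (m, 0.0) for g, (m, _) in per.items()}
                 for name, per in CohortDesign().cognition_model.items()}
        d = small_design(cognition_model=model,
                         sdmt_coupling={"CSVD-c": 0.0, "CSVD-n": 0.0,
                                        "control": 0.0})
        rng = np.random.default_rng(0)
        scores = generate_cognitive_scores(1.3, "CSVD-n", d, rng)
        assert scores["MoCA"] == pytest.approx(25.23)
        assert scores["SDMT"] == pytest.approx(31.32)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            generate_cognitive_scores(0.0, "patients", small_design(),
                                      np.random.default_rng(0))

    def test_negative_coupling_gives_negative_correlation(self):
        d = small_design(group_sizes={"CSVD-c": 100},
                         sdmt_coupling={"CSVD-c": -0.5, "CSVD-n": -0.5,
                                        "control": 0.0})
        rng = np.random.default_rng(1)
        z = rng.standard_normal(100)
        sdmt = [generate_cognitive_scores(zi, "CSVD-c", d,
                                          np.random.default_rng(i))["SDMT"]
                for i, zi in enumerate(z)]
        assert np.corrcoef(z, sdmt)[0, 1] < -0.2

    def test_designed_coupling_recovered_within_tolerance(self):
        """Sample correlation between standardized efficiency and SDMT
        approaches the configured rho at n=120."""
        rho = -0.45
        d = small_design(group_sizes={"CSVD-c": 120},
                         sdmt_coupling={"CSVD-c": rho, "CSVD-n": rho,
                                        "control": 0.0})
        cohort = generate_cohort(d)
        eff = dict(zip((s.subject_id for s in cohort),
                       np.random.default_rng(3).standard_normal(120)))
        attach_cognitive_scores(cohort, eff, d)
        z = np.array([eff[s.subject_id] for s in cohort])
        sdmt = np.array([s.cognitive_scores["SDMT"] for s in cohort])
        r = np.corrcoef((z - z.mean()) / z.std(ddof=1), sdmt)[0, 1]
        assert r == pytest.approx(rho, abs=0.1)

    def test_measured_efficiency_correlates_negatively_with_sdmt(self):
        """End-to-end coupling check: SDMT attached from the *measured*
        global-efficiency AUC is negatively correlated with it in patients."""
        from gmnet.topology import (auc_over_sparsity, compute_global_metrics,
                                    sparsity_sweep)

        d = small_design(group_sizes={"CSVD-c": 100},
                         voxels_per_region=(50, 80), seed=11)
        cohort = generate_cohort(d)
        eff = {}
        for s in cohort:
            S = build_similarity_matrix(s)
            vals = [compute_global_metrics(g, metrics=("Eglob",))["Eglob"]
                    for g in sparsity_sweep(S)]
            eff[s.subject_id] = auc_over_sparsity(vals)
        attach_cognitive_scores(cohort, eff, d)
        e = np.array([eff[s.subject_id] for s in cohort])
        sdmt = np.array([s.cognitive_scores["SDMT"] for s in cohort])
        assert np.corrcoef(e, sdmt)[0, 1] < 0

    def test_attach_is_deterministic(self):
        d = small_design()
        cohort = generate_cohort(d)
        eff = {s.subject_id: i * 0.01 for i, s in enumerate(cohort)}
        attach_cognitive_scores(cohort, eff, d)
        first = {s.subject_id: dict(s.cognitive_scores) for s in cohort}
        attach_cognitive_scores(cohort, eff, d)
        assert first == {s.subject_id: dict(s.cognitive_scores)
                         for s in cohort}


class TestCohortIO:
    def test_round_trip_identity(self, tiny_cohort, tmp_path):
        path = tmp_path / "cohort.tsv"
        write_cohort(tiny_cohort, path)
        back = read_cohort(path)
        assert len(back) == len(tiny_cohort)
        by_id = {s.subject_id: s for s in back}
        for s in tiny_cohort:
            b = by_id[s.subject_id]
            assert b.group == s.group
            assert b.age == s.age and b.sex == s.sex
            assert b.education == s.education and b.tiv == s.tiv
            assert b.cognitive_scores == s.cognitive_scores
            for a, v in zip(s.region_values, b.region_values):
                assert np.array_equal(a, v)

    def test_reserialization_is_byte_identical(self, tiny_cohort, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_cohort(tiny_cohort, p1)
        write_cohort(read_cohort(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_region_rows_name_the_region(self, tiny_cohort, tmp_path):
        path = tmp_path / "cohort.tsv"
        write_cohort(tiny_cohort, path)
        sid = tiny_cohort[0].subject_id
        lines = [ln for ln in path.read_text().splitlines()
                 if not ln.startswith(f"{sid}\t37\t")]
        (tmp_path / "broken.tsv").write_text("\n".join(lines) + "\n")
        with pytest.raises(CohortParseError, match=r"37"):
            read_cohort(tmp_path / "broken.tsv")

    def test_malformed_line_error_names_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("[subjects]\n"
                        "subject_id\tgroup\tage\tsex\teducation\ttiv\t"
                        "MoCA\tAVLT\tSDMT\tSCWT\tTMT_BA\n"
                        "s1\tcontrol\tNOT_A_NUMBER\t0\t12\t1.5\t"
                        "25\t60\t30\t150\t100\n")
        with pytest.raises(CohortParseError, match="line 3"):
            read_cohort(path)


def test_covariates_group_independent_by_default():
    """With the default covariate model all groups share one distribution;
    large-sample group means agree."""
    d = dataclasses.replace(
        small_design(), group_sizes={"CSVD-c": 150, "control": 150},
        voxels_per_region=(2, 3))
    cohort = generate_cohort(d)
    ages = {g: np.mean([s.age for s in cohort if s.group == g])
            for g in ("CSVD-c", "control")}
    assert abs(ages["CSVD-c"] - ages["control"]) < 3.0
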