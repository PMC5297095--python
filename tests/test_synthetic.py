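"""The factor-model cohort generator: determinism, planted structure, survival."""

import numpy as np
import pandas as pd
import pytest

from seedgcn.surv import dichotomize_by_median, km_estimate, logrank, survival_at
from seedgcn.synthetic import CohortSpec, generate_cohort, generate_gmt, generate_survival


class TestSpecValidation:
    def test_bad_field_named(self):
        with pytest.raises(ValueError, match="noise_sd"):
            CohortSpec(noise_sd=-1).validate()
        with pytest.raises(ValueError, match="n_genes"):
            CohortSpec(n_genes=10).validate()


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        m1, a1, t1 = generate_cohort(CohortSpec(rng_seed=5, n_genes=80,
                                                n_cases=20, n_controls=15,
                                                n_background_de=10))
        m2, a2, t2 = generate_cohort(CohortSpec(rng_seed=5, n_genes=80,
                                                n_cases=20, n_controls=15,
                                                n_background_de=10))
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(a1, a2)
        assert t1["module_loadings"] == t2["module_loadings"]

    def test_different_seed_differs(self):
        m1, _, _ = generate_cohort(CohortSpec(rng_seed=1, n_genes=80, n_cases=20,
                                              n_controls=15, n_background_de=10))
        m2, _, _ = generate_cohort(CohortSpec(rng_seed=2, n_genes=80, n_cases=20,
                                              n_controls=15, n_background_de=10))
        assert not np.allclose(m1.values, m2.values)


class TestPlantedCorrelationStructure:
    def test_zero_loadings_leave_module_uncorrelated(self):
        spec = CohortSpec(rng_seed=11, n_cases=120, n_controls=80,
                          module_loading_range=(0.0, 0.0), seed_loading=0.0)
        m, _, truth = generate_cohort(spec)
        cases = m.cases_only()
        x = cases.values.loc[truth["module_genes"][:8]].to_numpy()
        r = np.corrcoef(x)
        off = r[np.triu_indices_from(r, k=1)]
        assert np.all(np.abs(off) < 0.25)
        assert np.mean(np.abs(off)) < 0.12

    def test_pairwise_correlation_matches_factor_model_closed_form(self):
        spec = CohortSpec(rng_seed=13, n_cases=8000, n_controls=10,
                          n_genes=120, n_background_de=10)
        m, _, truth = generate_cohort(spec)
        cases = m.cases_only()
        lam = truth["module_loadings"]
        genes = truth["module_genes"][:6]
        s2 = spec.noise_sd ** 2
        for i, gi in enumerate(genes):
            for gj in genes[i + 1:]:
                expected = lam[gi] * lam[gj] / np.sqrt(
                    (lam[gi] ** 2 + s2) * (lam[gj] ** 2 + s2))
                observed = np.corrcoef(cases.gene(gi), cases.gene(gj))[0, 1]
                assert observed == pytest.approx(expected, abs=0.03)

    def test_planted_logfc_recovered(self):
        spec = CohortSpec(rng_seed=17, n_cases=200, n_controls=200,
                          noise_sd=0.5, n_genes=120, n_background_de=10)
        m, _, truth = generate_cohort(spec)
        from seedgcn.de import moderated_t
        tab = moderated_t(m)
        for g, shift in list(truth["case_shifts"].items())[:10]:
            assert tab.loc[g, "logFC"] == pytest.approx(shift, abs=0.2)


class TestSurvivalGeneration:
    def test_null_beta_keeps_logrank_calibrated(self):
        rng = np.random.default_rng(23)
        spec = CohortSpec(signature_beta=0.0)
        rejections = 0
        reps = 200
        for _ in range(reps):
            ann = pd.DataFrame({"sample_id": [f"s{i}" for i in range(100)],
                                "group": ["case"] * 100})
            score = rng.normal(size=100)
            out = generate_survival(ann, score, spec, rng)
            split = dichotomize_by_median(score, ann["sample_id"])
            hi = (split == "high").to_numpy()
            _, p = logrank(out["time"][hi], out["event"][hi],
                           out["time"][~hi], out["event"][~hi])
            rejections += p < 0.05
        assert 0.01 <= rejections / reps <= 0.10

    def test_zero_censor_window_all_censored(self):
        spec = CohortSpec(censor_window=0.0)
        ann = pd.DataFrame({"sample_id": ["a", "b", "c"], "group": ["case"] * 3})
        out = generate_survival(ann, np.array([0.0, 1.0, -1.0]), spec,
                                np.random.default_rng(0))
        assert (out["event"] == 0).all()
        c = km_estimate(out["time"], out["event"])
        assert survival_at(c, 100)[0] == 1.0

    def test_positive_beta_shortens_high_score_survival(self):
        rng = np.random.default_rng(29)
        spec = CohortSpec(signature_beta=1.0)
        ann = pd.DataFrame({"sample_id": [f"s{i}" for i in range(400)],
                            "group": ["case"] * 400})
        score = rng.normal(size=400)
        out = generate_survival(ann, score, spec, rng)
        hi = score > np.median(score)
        _, p = logrank(out["time"][hi], out["event"][hi],
                       out["time"][~hi], out["event"][~hi])
        assert p < 1e-4
        s_hi = survival_at(km_estimate(out["time"][hi], out["event"][hi]), 5.0)[0]
        s_lo = survival_at(km_estimate(out["time"][~hi], out["event"][~hi]), 5.0)[0]
        assert s_hi < s_lo


class TestGmt:
    def test_true_term_is_module_and_decoys_deterministic(self):
        spec = CohortSpec(rng_seed=31, n_genes=100, n_cases=10, n_controls=10,
                          n_background_de=5)
        m, _, truth = generate_cohort(spec)
        c1 = generate_gmt(spec, truth["module_genes"], m.gene_ids)
        c2 = generate_gmt(spec, truth["module_genes"], m.gene_ids)
        assert c1.terms["TERM_MODULE"] == set(truth["module_genes"])
        assert c1.terms.keys() == c2.terms.keys()
        assert all(c1.terms[t] == c2.terms[t] for t in c1.terms)

    def test_zero_decoys_single_term(self):
        spec = CohortSpec(rng_seed=1, n_genes=100, n_cases=10, n_controls=10,
                          n_background_de=5)
        m, _, truth = generate_cohort(spec)
        c = generate_gmt(spec, truth["module_genes"], m.gene_ids, n_decoys=0)
        assert list(c.terms) == ["TERM_MODULE"]

    def test_gmt_round_trip(self, tmp_path):
        spec = CohortSpec(rng_seed=2, n_genes=100, n_cases=10, n_controls=10,
                          n_background_de=5)
        m, _, truth = generate_cohort(spec)
        c = generate_gmt(spec, truth["module_genes"], m.gene_ids, n_decoys=5)
        c.to_gmt(tmp_path / "sets.gmt")
        from seedgcn.enrichment import GeneSetCollection
        back = GeneSetCollection.from_gmt(tmp_path / "sets.gmt", m.gene_ids)
        assert back.terms == c.terms
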