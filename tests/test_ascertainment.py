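import numpy as np
import pytest
from scipy import stats

import triadgen as tg
from triadgen.ascertainment import retention_rule
from triadgen.traits import pathway_indicator_matrix


@pytest.fixture(scope="module")
def setup(tiny_source):
    triads = tg.build_triads(tiny_source.samples)
    pool, _ = tg.build_pool(
        tiny_source.marker_map, tiny_source.samples, tiny_source.genotypes, triads
    )
    track = tg.hotspots_to_boundaries(tiny_source.hotspots, tiny_source.marker_map)
    pw = tg.PathwaySpec([[5], [47]])
    return tiny_source.marker_map, pool, track, pw


class TestRetentionRule:
    d = {k: tg.StudyDesign(k, 10) for k in
         ("case_parents", "control_parents", "case_only", "population_qt")}

    def test_case_designs_keep_affected_only(self):
        assert retention_rule(self.d["case_parents"], True)
        assert not retention_rule(self.d["case_parents"], False)
        assert retention_rule(self.d["case_only"], True)

    def test_control_parents_keeps_unaffected(self):
        assert retention_rule(self.d["control_parents"], False)
        assert not retention_rule(self.d["control_parents"], True)

    def test_population_qt_keeps_everything(self):
        assert retention_rule(self.d["population_qt"], True)
        assert retention_rule(self.d["population_qt"], False)

    def test_case_control_respects_quotas(self):
        d = tg.StudyDesign("case_control", 10, control_ratio=1.0)
        assert retention_rule(d, True, {"cases": 1, "controls": 0})
        assert not retention_rule(d, False, {"cases": 1, "controls": 0})


def _model(alpha, beta=(0.0, 0.0), **kw):
    return tg.TraitModel("dichotomous", alpha=np.log(alpha), beta=np.log(beta), **kw)


def _subpop(pool, alpha, **kw):
    return tg.SubpopulationSpec(pool=pool, proportion=1.0, alpha=np.log(alpha), **kw)


class TestGenerateStudy:
    def test_half_penetrance_geometric_waiting(self, setup):
        mm, pool, track, pw = setup
        model = _model(0.5, (1.0, 1.0))
        study = tg.generate_study(
            [_subpop(pool, 0.5)], pw, model, tg.StudyDesign("case_parents", 100),
            track, 3, np.random.default_rng(2), marker_map=mm,
        )
        assert study.n_records == 100
        # geometric waiting time: ~200 candidates expected, sd ~ sqrt(2*100)
        assert 130 < study.candidates_used < 320

    def test_population_qt_has_zero_discards(self, setup):
        mm, pool, track, pw = setup
        model = tg.TraitModel("quantitative", alpha=0.0, beta=[0.1, 0.15])
        sp = tg.SubpopulationSpec(pool=pool, proportion=1.0, alpha=0.0)
        study = tg.generate_study(
            [sp], pw, model, tg.StudyDesign("population_qt", 500),
            track, 3, np.random.default_rng(3), marker_map=mm,
        )
        assert study.n_records == 500
        assert study.candidates_used == 500

    def test_case_control_ratio_and_single_stream(self, setup):
        mm, pool, track, pw = setup
        model = _model(0.3, (1.0, 1.0))
        study = tg.generate_study(
            [_subpop(pool, 0.3)], pw, model,
            tg.StudyDesign("case_control", 80, control_ratio=1.5),
            track, 3, np.random.default_rng(4), marker_map=mm,
        )
        affected = study.phenotype > 0
        assert int(affected.sum()) == 80
        assert int((~affected).sum()) == 120

    def test_subpopulation_proportions_respected(self, setup):
        mm, pool, track, pw = setup
        model = tg.TraitModel("quantitative", alpha=0.0, beta=[0.0, 0.0])
        sps = [
            tg.SubpopulationSpec(pool=pool, proportion=0.54, alpha=0.0, label="one"),
            tg.SubpopulationSpec(pool=pool, proportion=0.46, alpha=0.0, label="two"),
        ]
        study = tg.generate_study(
            [sps[0], sps[1]], pw, model, tg.StudyDesign("population_qt", 2000),
            track, 3, np.random.default_rng(5), marker_map=mm,
        )
        frac_two = np.mean(study.subpop == "two")
        se = np.sqrt(0.46 * 0.54 / 2000)
        assert abs(frac_two - 0.46) < 4 * se

    def test_zero_retention_aborts_with_diagnostic(self, setup):
        mm, pool, track, pw = setup
        model = _model(0.4, (1.0, 1.0))
        with pytest.raises(RuntimeError, match="candidate cap"):
            tg.generate_study(
                [_subpop(pool, 0.4)], pw, model,
                tg.StudyDesign("control_parents", 10**6),
                track, 3, np.random.default_rng(6), marker_map=mm,
                candidate_cap=2000,
            )

    def test_case_enrichment_of_variant_carriers(self, setup):
        """Among case offspring with one 1-SNP pathway at RR=3, carrier
        frequency exceeds the null carrier frequency."""
        mm, pool, track, _ = setup
        pw = tg.PathwaySpec([[5]])
        model = tg.TraitModel("dichotomous", alpha=np.log(0.05), beta=[np.log(3.0)])
        study = tg.generate_study(
            [_subpop(pool, 0.05)], pw, model, tg.StudyDesign("case_parents", 400),
            track, 3, np.random.default_rng(7), marker_map=mm,
        )
        carriers = np.mean(study.children[:, 5] >= 1)
        null = tg.simulate_null_study(pool, mm, 2000, track, 3,
                                      np.random.default_rng(8))
        null_carriers = np.mean(null.children[:, 5] >= 1)
        assert carriers > null_carriers + 0.03

    def test_subpop_baseline_ratio_among_noncarriers(self, setup):
        """Distinct baselines reproduce the specified prevalence ratio among
        noncarrier candidates (estimated from retained/candidate bookkeeping)."""
        mm, pool, track, pw = setup
        model = _model(1.0, (1.0, 1.0))  # placeholder; alphas come from subpops
        sps = [
            tg.SubpopulationSpec(pool=pool, proportion=0.5, alpha=np.log(0.2), label="a"),
            tg.SubpopulationSpec(pool=pool, proportion=0.5, alpha=np.log(0.26), label="b"),
        ]
        study = tg.generate_study(
            sps, pw, _model(0.2, (1.0, 1.0)), tg.StudyDesign("case_parents", 3000),
            track, 3, np.random.default_rng(9), marker_map=mm,
        )
        n_a = np.sum(study.subpop == "a")
        n_b = np.sum(study.subpop == "b")
        # cases accrue proportionally to baseline risk: expect ratio 1.3
        ratio = n_b / n_a
        assert abs(ratio - 1.3) < 0.18


class TestStripParents:
    def test_strip_and_idempotence(self, setup):
        mm, pool, track, pw = setup
        model = _model(0.5, (1.0, 1.0))
        study = tg.generate_study(
            [_subpop(pool, 0.5)], pw, model, tg.StudyDesign("case_parents", 50),
            track, 3, np.random.default_rng(11), marker_map=mm,
        )
        only = tg.strip_parents(study)
        assert not only.has_parents
        assert only.genotype_matrix().shape[0] == 50
        assert np.array_equal(only.children, study.children)
        assert tg.strip_parents(only) is only


def test_two_stage_equals_full_generation_distribution(setup):
    """Causal-first two-stage sampling matches full generation + filtering:
    chi-square goodness of fit on the joint pathway-genotype distribution of
    retained cases (high-prevalence micro-fixture)."""
    mm, pool, track, pw = setup
    model = _model(0.3, (2.0, 1.5))
    kw = dict(track=track, k_per_chromosome=2, marker_map=mm)
    design = tg.StudyDesign("case_parents", 2500)
    two = tg.generate_study([_subpop(pool, 0.3)], pw, model, design,
                            rng=np.random.default_rng(21), **kw)
    full = tg.generate_study([_subpop(pool, 0.3)], pw, model, design,
                             rng=np.random.default_rng(22), full_generation=True, **kw)
    # joint cell = (g1, g2) child genotype pair at the two pathway loci
    loci = pw.all_loci
    cells_two = study_cells = two.children[:, loci]
    cells_full = full.children[:, loci]
    code_two = cells_two[:, 0] * 3 + cells_two[:, 1]
    code_full = cells_full[:, 0] * 3 + cells_full[:, 1]
    obs = np.array([(code_two == k).sum() for k in range(9)])
    exp_frac = np.array([(code_full == k).sum() for k in range(9)]) / len(code_full)
    keep = exp_frac > 0
    chi2 = np.sum((obs[keep] - len(code_two) * exp_frac[keep]) ** 2
                  / (len(code_two) * exp_frac[keep]))
    p = stats.chi2.sf(chi2, df=keep.sum() - 1)
    assert p > 0.001
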