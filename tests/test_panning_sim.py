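"""Stochastic biopanning rounds: conservation, limits, analytic twin."""

import numpy as np
import pytest

from puredisplay.panning_sim import (
    CloneClass,
    ClonePopulation,
    PanningConfig,
    expectation_mode,
    run_campaign,
    simulate_round,
)

ALL_SURFACES = {"streptavidin_beads": 1.0, "streptavidin_plate": 1.0, "ni_nta": 1.0}


def two_clone_pop(spike_count=1000, bg_count=100_000, spike_class=None, bg_class=None):
    classes = {
        "target_binder": spike_class
        or CloneClass("target_binder", retention=0.9,
                      capture={s: 0.9 for s in ALL_SURFACES}),
        "nonbinder": bg_class
        or CloneClass("nonbinder", retention=0.3,
                      capture={s: 0.1 for s in ALL_SURFACES}),
    }
    return ClonePopulation(
        ids=("spike", "bg"),
        class_ids=("target_binder", "nonbinder"),
        counts=np.array([spike_count, bg_count], dtype=np.int64),
        spike=np.array([True, False]),
        classes=classes,
    )


def lossless_cfg(**kw):
    defaults = dict(display_efficiency=1.0, washes=3, amplification_factor=1.0)
    defaults.update(kw)
    return PanningConfig(**defaults)


def lossless_classes():
    return {
        "target_binder": CloneClass("target_binder", retention=1.0, capture=ALL_SURFACES),
        "nonbinder": CloneClass("nonbinder", retention=1.0, capture=ALL_SURFACES),
    }


class TestSimulateRound:
    def test_zero_efficiency_elutes_nothing(self, rng):
        pop = two_clone_pop()
        res = simulate_round(pop, PanningConfig(display_efficiency=0.0), rng)
        assert res.eluted.sum() == 0

    def test_lossless_limit_elutes_all_input(self, rng):
        pop = two_clone_pop()
        pop.classes.update(lossless_classes())
        res = simulate_round(pop, lossless_cfg(washes=5), rng)
        assert np.array_equal(res.eluted, pop.counts)

    def test_functional_complexes_binomial_mean(self, rng):
        # 1e5 copies at 4% efficiency: functional count within 4 SE of 4000
        pop = two_clone_pop(spike_count=100_000, bg_count=0)
        res = simulate_round(pop, PanningConfig(display_efficiency=0.04), rng)
        se = np.sqrt(100_000 * 0.04 * 0.96)
        assert abs(res.functional[0] - 4000) < 4 * se

    @pytest.mark.parametrize("elution", ["edta", "biotin_then_edta"])
    @pytest.mark.parametrize("washes", [0, 2, 5])
    def test_exact_count_conservation(self, rng, elution, washes):
        pop = two_clone_pop()
        cfg = PanningConfig(display_efficiency=0.3, washes=washes, elution=elution,
                            preincubation_depletion=0.5)
        res = simulate_round(pop, cfg, rng)
        recovered = res.flow_through + res.washes.sum(axis=1) + res.eluted + res.discarded
        assert np.array_equal(res.functional, recovered)
        if elution == "edta":
            assert res.discarded.sum() == 0

    def test_seeded_determinism(self):
        pop = two_clone_pop()
        cfg = PanningConfig(display_efficiency=0.1)
        a = simulate_round(pop, cfg, np.random.default_rng(5))
        b = simulate_round(pop, cfg, np.random.default_rng(5))
        assert np.array_equal(a.eluted, b.eluted)
        assert np.array_equal(a.amplified, b.amplified)


class TestElutionChemistry:
    def sticker_pop(self):
        classes = {
            "target_binder": CloneClass("target_binder", retention=1.0, capture=ALL_SURFACES),
            "surface_sticker": CloneClass("surface_sticker", retention=1.0, capture=ALL_SURFACES),
            "streptavidin_motif_binder": CloneClass(
                "streptavidin_motif_binder", retention=1.0,
                capture={"streptavidin_beads": 1.0, "streptavidin_plate": 1.0, "ni_nta": 0.05},
            ),
        }
        return ClonePopulation(
            ids=("t", "s", "h"),
            class_ids=("target_binder", "surface_sticker", "streptavidin_motif_binder"),
            counts=np.array([1000, 1000, 1000], dtype=np.int64),
            spike=np.array([False, False, False]),
            classes=classes,
        )

    def test_biotin_elution_never_recovers_stickers(self, rng):
        res = simulate_round(self.sticker_pop(), lossless_cfg(elution="biotin_then_edta"), rng)
        assert res.eluted[1] == 0 and res.discarded[1] == 1000
        assert res.eluted[0] == 1000 and res.eluted[2] == 1000

    def test_edta_recovers_superset_of_biotin_classes(self, rng):
        pop = self.sticker_pop()
        edta = simulate_round(pop, lossless_cfg(elution="edta"), rng)
        biotin = simulate_round(pop, lossless_cfg(elution="biotin_then_edta"), rng)
        assert np.all(edta.eluted >= biotin.eluted)

    def test_ni_nta_surface_sends_motif_binders_to_baseline(self, rng):
        # the rescue strategy: streptavidin-pocket binders barely capture on Ni-NTA
        pop = self.sticker_pop()
        strep = simulate_round(pop, lossless_cfg(surface="streptavidin_beads"), rng)
        ni = simulate_round(pop, lossless_cfg(surface="ni_nta"), rng)
        assert strep.eluted[2] == 1000
        assert ni.eluted[2] < 150  # ~5% capture

    def test_preincubation_depletes_only_motif_binders(self, rng):
        pop = self.sticker_pop()
        res = simulate_round(pop, lossless_cfg(preincubation_depletion=1.0), rng)
        assert res.eluted[2] == 0 and res.flow_through[2] == 1000
        assert res.eluted[0] == 1000

    def test_unknown_surface_combination_rejected(self, rng):
        pop = two_clone_pop()
        pop.classes["target_binder"] = CloneClass(
            "target_binder", retention=0.9, capture={"streptavidin_beads": 0.9}
        )
        with pytest.raises(ValueError, match="ni_nta"):
            simulate_round(pop, PanningConfig(display_efficiency=0.1, surface="ni_nta"), rng)


class TestCampaign:
    def test_lossless_round_keeps_spike_fraction(self):
        pop = two_clone_pop()
        pop.classes.update(lossless_classes())
        res = run_campaign(pop, [lossless_cfg()], rng=1)
        assert res.spike_trajectory[0] == pytest.approx(pop.spike_fraction())

    def test_two_type_competition_closed_form_in_expectation(self):
        # fraction after r rounds = p0 s^r / (p0 s^r + (1-p0) b^r)
        pop = two_clone_pop(spike_count=1000, bg_count=99_000)
        cfgs = [PanningConfig(display_efficiency=0.04, washes=2)] * 3
        res = expectation_mode(pop, cfgs)
        s = 0.04 * 0.9 * 0.9**2
        b = 0.04 * 0.1 * 0.3**2
        p0 = 0.01
        for r, frac in enumerate(res.spike_trajectory, start=1):
            expected = p0 * s**r / (p0 * s**r + (1 - p0) * b**r)
            assert frac == pytest.approx(expected, rel=1e-12)

    def test_sampler_mean_matches_expectation_within_3_se(self):
        # 3-clone toy, 1000 seeded replicates vs analytic eluted means
        classes = {
            "target_binder": CloneClass("target_binder", retention=0.8,
                                        capture={s: 0.7 for s in ALL_SURFACES}),
            "nonbinder": CloneClass("nonbinder", retention=0.4,
                                    capture={s: 0.2 for s in ALL_SURFACES}),
            "surface_sticker": CloneClass("surface_sticker", retention=0.6,
                                          capture={s: 0.5 for s in ALL_SURFACES}),
        }
        pop = ClonePopulation(
            ids=("a", "b", "c"),
            class_ids=("target_binder", "nonbinder", "surface_sticker"),
            counts=np.array([500, 2000, 800], dtype=np.int64),
            spike=np.array([True, False, False]),
            classes=classes,
        )
        cfg = PanningConfig(display_efficiency=0.3, washes=2)
        expect = expectation_mode(pop, [cfg]).rounds[0].eluted

        rng = np.random.default_rng(77)
        n_rep = 1000
        sums = np.zeros(3)
        sumsq = np.zeros(3)
        for _ in range(n_rep):
            eluted = simulate_round(pop, cfg, rng).eluted
            sums += eluted
            sumsq += eluted.astype(float) ** 2
        mean = sums / n_rep
        var = sumsq / n_rep - mean**2
        se = np.sqrt(var / n_rep)
        assert np.all(np.abs(mean - expect) < 3 * se + 1e-9)

    def test_spike_fraction_monotone_under_strict_survival_advantage(self):
        pop = two_clone_pop(spike_count=100, bg_count=1_000_000)
        cfgs = [PanningConfig(display_efficiency=0.04, washes=w) for w in (2, 2, 3, 3)]
        res = expectation_mode(pop, cfgs)
        traj = [pop.spike_fraction()] + res.spike_trajectory
        assert all(a < b for a, b in zip(traj, traj[1:]))

    def test_extinction_terminates_with_status(self):
        pop = two_clone_pop(spike_count=2, bg_count=5)
        cfgs = [PanningConfig(display_efficiency=0.001, amplification_factor=1.0)] * 4
        res = run_campaign(pop, cfgs, rng=0)
        assert res.status == "extinct"
        assert len(res.rounds) <= 4

    def test_display_efficiency_recovered_unbiased(self):
        # estimate efficiency from eluted/input over replicates; within 3 SE
        true_eff = 0.04
        classes = lossless_classes()
        pop = ClonePopulation(
            ids=("x",), class_ids=("target_binder",),
            counts=np.array([100_000], dtype=np.int64),
            spike=np.array([False]), classes=classes,
        )
        cfg = PanningConfig(display_efficiency=true_eff, washes=2)
        rng = np.random.default_rng(123)
        estimates = [
            simulate_round(pop, cfg, rng).eluted[0] / 100_000 for _ in range(200)
        ]
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - true_eff) < 3 * se

    def test_mutation_creates_variant_records(self):
        pop = two_clone_pop()
        cfg = PanningConfig(display_efficiency=0.5, washes=0, mutation_rate=0.01)
        res = run_campaign(pop, [cfg], rng=9)
        assert len(res.final_population.ids) > 2
        assert any(i.endswith("_mut") for i in res.final_population.ids)

    def test_empty_config_list_rejected(self):
        with pytest.raises(ValueError):
            run_campaign(two_clone_pop(), [], rng=0)


class TestValidation:
    def test_population_requires_known_classes(self):
        with pytest.raises(ValueError):
            ClonePopulation(
                ids=("x",), class_ids=("mystery",),
                counts=np.array([1]), spike=np.array([False]), classes={},
            )

    def test_single_spike_enforced(self):
        classes = lossless_classes()
        with pytest.raises(ValueError, match="spike"):
            ClonePopulation(
                ids=("a", "b"), class_ids=("target_binder", "target_binder"),
                counts=np.array([1, 1]), spike=np.array([True, True]), classes=classes,
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"display_efficiency": 1.5},
            {"display_efficiency": 0.1, "washes": -1},
            {"display_efficiency": 0.1, "surface": "agar"},
            {"display_efficiency": 0.1, "elution": "acid"},
        ],
    )
    def test_config_invariants(self, kwargs):
        with pytest.raises(ValueError):
            PanningConfig(**kwargs)
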