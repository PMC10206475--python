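"""Synthetic troop generator: structure, determinism and sampling laws."""

import math
from datetime import timedelta

import numpy as np
import pytest

from matrinet import SimulationConfig, simulate_dataset
from matrinet.config import AttachmentParams, ConfigurationError, ImmatureSpec
from matrinet.records import Individual
from matrinet.simulate import (
    Population,
    PropensityModel,
    inheritance_weight,
    latent_propensities,
    make_population,
    reference_date,
    simulate_dominance,
    simulate_grooming,
    simulate_scans,
)


def small_config(**kw):
    base = dict(
        n_troops=1,
        n_matrilines=2,
        adults_per_matriline=2,
        adult_males_per_troop=1,
        immatures=[ImmatureSpec(24.0, "F", 0)],
        seasons=[(2019, 1)],
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestMakePopulation:
    def test_counts_match_config(self):
        cfg = SimulationConfig(
            n_troops=1,
            n_matrilines=4,
            adults_per_matriline=3,
            adult_males_per_troop=0,
            immatures_per_troop=8,
        )
        pop = make_population(cfg)
        assert len(pop.individuals) == 20
        ref = reference_date(cfg)
        assert sum(i.mother_id is not None and i.is_immature(ref) for i in pop.individuals) == 8

    def test_every_immature_has_mother_in_troop(self, default_data):
        ids = {i.id: i for i in default_data.individuals}
        for ind in default_data.individuals:
            if ind.mother_id is not None:
                mother = ids[ind.mother_id]
                assert mother.troop == ind.troop
                assert mother.sex == "F"

    def test_determinism(self):
        cfg = SimulationConfig(rng_seed=7)
        assert make_population(cfg).individuals == make_population(cfg).individuals

    def test_invalid_matriline_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(immatures=[ImmatureSpec(12.0, "F", 5)])


class TestLatentPropensities:
    def test_newborn_with_full_inheritance_copies_mother_row(self):
        cfg = small_config(immatures=[ImmatureSpec(0.0, "F", 0)], lambda0=1.0)
        pop = make_population(cfg)
        prop = latent_propensities(pop, cfg, reference_date(cfg), "T1")
        imm = next(i for i in pop.individuals if i.mother_id is not None)
        ki, km = prop.ids.index(imm.id), prop.ids.index(imm.mother_id)
        keep = [k for k in range(len(prop.ids)) if k not in (ki, km)]
        np.testing.assert_allclose(
            prop.association[ki, keep], prop.association[km, keep], atol=1e-12
        )

    def test_inheritance_weight_decreases_with_age_and_faster_for_males(self):
        cfg = SimulationConfig(delta_male=0.02)
        ages = np.linspace(0, 60, 20)
        w = [inheritance_weight(cfg, a, False) for a in ages]
        assert all(a >= b for a, b in zip(w, w[1:]))
        assert inheritance_weight(cfg, 36, True) < inheritance_weight(cfg, 36, False)

    def test_no_inheritance_decorrelates_rows(self):
        """With lambda0 = 0 the immature/mother propensity rows are unrelated
        (correlation across replicate populations centred near 0); with
        lambda0 = 0.9 they are strongly correlated."""
        rng = np.random.default_rng(0)

        def corrs(lambda0, n=100, max_age=57.0):
            out = []
            for _ in range(n):
                spec = ImmatureSpec(
                    float(rng.uniform(3, max_age)),
                    "F" if rng.random() < 0.5 else "M",
                    int(rng.integers(0, 3)),
                )
                cfg = SimulationConfig(
                    n_troops=1,
                    n_matrilines=3,
                    adults_per_matriline=3,
                    immatures=[spec],
                    lambda0=lambda0,
                    rng_seed=int(rng.integers(2**31)),
                )
                pop = make_population(cfg)
                prop = latent_propensities(pop, cfg, reference_date(cfg), "T1")
                imm = next(i for i in pop.individuals if i.mother_id is not None)
                ki, km = prop.ids.index(imm.id), prop.ids.index(imm.mother_id)
                keep = [k for k in range(len(prop.ids)) if k not in (ki, km)]
                u, v = prop.association[ki, keep], prop.association[km, keep]
                if u.std() > 0 and v.std() > 0:
                    out.append(np.corrcoef(u, v)[0, 1])
            return np.mean(out)

        assert abs(corrs(0.0)) < 0.15
        # positive control: young immatures under strong inheritance
        assert corrs(0.9, max_age=12.0) > 0.5


def three_adult_population():
    cfg = small_config()
    ref = reference_date(cfg)
    inds = [
        Individual(n, "F", ref - timedelta(days=3000), None, "T1") for n in "ABC"
    ]
    pop = Population(inds, {n: 0 for n in "ABC"}, {"A": 1, "B": 2, "C": 3})
    return cfg, pop


def override(assoc, groom=None):
    def factory(troop, date):
        ids = ["A", "B", "C"]
        g = groom if groom is not None else np.zeros((3, 3))
        return PropensityModel(ids, assoc, g, {})

    return factory


class TestSimulateScans:
    def test_certain_dyad_always_together(self, rng):
        cfg, pop = three_adult_population()
        assoc = np.zeros((3, 3))
        assoc[0, 1] = assoc[1, 0] = 1.0
        recs = simulate_scans(pop, cfg, rng, propensities=override(assoc))
        with_a = [r for r in recs if "A" in r.subgroup_ids]
        assert with_a and all("B" in r.subgroup_ids for r in with_a)

    def test_zero_propensity_means_everyone_alone(self, rng):
        cfg, pop = three_adult_population()
        recs = simulate_scans(pop, cfg, rng, propensities=override(np.zeros((3, 3))))
        assert recs and all(len(r.subgroup_ids) == 1 for r in recs)

    def test_half_propensity_binomial_sampling(self, rng):
        cfg, pop = three_adult_population()
        cfg = small_config(scans_per_individual_per_month=1000)
        assoc = np.zeros((3, 3))
        assoc[0, 1] = assoc[1, 0] = 0.5
        recs = simulate_scans(pop, cfg, rng, propensities=override(assoc))
        focal_a = [r for r in recs if r.focal_id == "A"]
        hits = sum("B" in r.subgroup_ids for r in focal_a)
        n = len(focal_a)
        sd = math.sqrt(n * 0.25)
        assert abs(hits - 0.5 * n) < 3 * sd

    def test_monthly_focal_counts_within_bounds(self, default_data):
        cfg = default_data.config
        first = [
            r
            for r in default_data.scans
            if r.troop == "T1" and r.when.date() < reference_date(cfg) + timedelta(days=30)
        ]
        counts = {}
        for r in first:
            counts[r.focal_id] = counts.get(r.focal_id, 0) + 1
        assert counts
        assert max(counts.values()) <= cfg.scans_per_individual_per_month
        assert min(counts.values()) >= cfg.scans_per_individual_per_month // 2


class TestSimulateGrooming:
    def test_zero_propensity_no_events(self, rng):
        cfg, pop = three_adult_population()
        assert simulate_grooming(pop, cfg, rng, propensities=override(np.zeros((3, 3)))) == []

    def test_half_hour_dyad_deduplication(self, rng):
        cfg, pop = three_adult_population()
        cfg = small_config(grooming_events_per_individual_per_month=400)
        groom = np.zeros((3, 3))
        groom[0, 1] = 1.0
        recs = simulate_grooming(pop, cfg, rng, propensities=override(np.zeros((3, 3)), groom))
        times = sorted(r.when for r in recs)
        gaps = [(b - a).total_seconds() for a, b in zip(times, times[1:])]
        assert recs and min(gaps) >= 30 * 60

    def test_propensity_ratio_recovered(self, rng):
        cfg, pop = three_adult_population()
        cfg = small_config(grooming_events_per_individual_per_month=200)
        groom = np.zeros((3, 3))
        groom[0, 1], groom[0, 2] = 0.6, 0.3
        recs = simulate_grooming(pop, cfg, rng, propensities=override(np.zeros((3, 3)), groom))
        ab = sum(r.recipient_id == "B" for r in recs)
        ac = sum(r.recipient_id == "C" for r in recs)
        assert ac > 20
        assert 1.5 < ab / ac < 2.6


class TestSimulateDominance:
    def test_infinite_steepness_is_deterministic_hierarchy(self, rng):
        cfg = small_config(dominance_steepness=math.inf)
        pop = make_population(cfg)
        recs = simulate_dominance(pop, cfg, rng)
        assert recs
        for r in recs:
            assert pop.latent_rank[r.giver_id] < pop.latent_rank[r.recipient_id]

    def test_zero_steepness_gives_even_wins(self, rng):
        cfg = small_config(dominance_steepness=0.0, interactions_per_dyad=100)
        pop = make_population(cfg)
        recs = simulate_dominance(pop, cfg, rng)
        higher = sum(pop.latent_rank[r.giver_id] < pop.latent_rank[r.recipient_id] for r in recs)
        frac = higher / len(recs)
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / len(recs))


def test_dataset_determinism():
    cfg = SimulationConfig(rng_seed=3, immatures_per_troop=6, n_matrilines=3)
    d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
    assert d1.scans == d2.scans
    assert d1.grooming == d2.grooming
    assert d1.dominance == d2.dominance
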