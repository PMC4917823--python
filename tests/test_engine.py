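"""Cellular-automaton processes and the annual step contract."""

import numpy as np
import pytest

import saltmarsh as sm
from saltmarsh.engine import (
    apply_competition,
    apply_mortality,
    clonal_spread,
    establish,
    produce_and_disperse_seeds,
    reclassify_waterline,
)


def _e_rel(state):
    return state.elev.values.copy()


class TestMortality:
    def test_extremes(self, flat_state, species):
        state = flat_state
        state.hab.codes[:] = int(sm.Habitat.SA)
        rng = np.random.default_rng(0)
        high = apply_mortality(state, species, np.full((9, 9), 4.0), rng)
        assert (high.hab.codes == int(sm.Habitat.SA)).all()
        low = apply_mortality(state, species, np.full((9, 9), 1.0), rng, stochastic=False)
        assert (low.hab.codes == int(sm.Habitat.MUDFLAT)).all()

    def test_binomial_rate_at_tipping(self, species):
        spec = sm.GridSpec(100, 100)
        elev = sm.ElevationGrid(spec, np.full(spec.shape, 2.5))
        hab = sm.HabitatGrid(spec, np.full(spec.shape, int(sm.Habitat.SA), dtype=np.int16))
        state = sm.LandscapeState(2008, elev, hab, {})
        out = apply_mortality(state, species, elev.values, np.random.default_rng(12))
        died = (out.hab.codes == int(sm.Habitat.MUDFLAT)).mean()
        # S = 0.5 at the tipping point; 5 sigma binomial band for n = 10^4
        assert died == pytest.approx(0.5, abs=5 * 0.5 / 100)


class TestDispersal:
    def test_interior_mass_conservation(self, flat_state, species):
        state = flat_state
        state.hab.codes[4, 4] = int(sm.Habitat.SA)
        e_rel = np.full((9, 9), 3.0)  # seed rate = clip(3.0 - 2.5, 0, 1) = 0.5
        out = produce_and_disperse_seeds(state, species, e_rel, radius=3)
        added = out.seedbank[sm.Habitat.SA] - state.seedbank[sm.Habitat.SA]
        assert added.sum() == pytest.approx(species[sm.Habitat.SA].fecundity * 0.5)
        assert added[4, 4] == added.max()  # kernel peaks at the source

    def test_zero_seed_rate_emits_nothing(self, flat_state, species):
        state = flat_state
        state.hab.codes[4, 4] = int(sm.Habitat.SA)
        out = produce_and_disperse_seeds(state, species, np.full((9, 9), 2.5), radius=3)
        assert out.seedbank[sm.Habitat.SA].sum() == 0.0

    def test_two_sources_superpose(self, flat_state, species):
        e_rel = np.full((9, 9), 3.0)
        one = flat_state.copy()
        one.hab.codes[3, 3] = int(sm.Habitat.SA)
        other = flat_state.copy()
        other.hab.codes[5, 5] = int(sm.Habitat.SA)
        both = flat_state.copy()
        both.hab.codes[3, 3] = both.hab.codes[5, 5] = int(sm.Habitat.SA)
        f1 = produce_and_disperse_seeds(one, species, e_rel).seedbank[sm.Habitat.SA]
        f2 = produce_and_disperse_seeds(other, species, e_rel).seedbank[sm.Habitat.SA]
        f12 = produce_and_disperse_seeds(both, species, e_rel).seedbank[sm.Habitat.SA]
        np.testing.assert_allclose(f12, f1 + f2, atol=1e-12)


class TestEstablishment:
    def test_band_gate(self, flat_state, species):
        from dataclasses import replace

        fertile = {h: replace(sp, germination_prob=1.0) for h, sp in species.items()}
        state = flat_state
        e_rel = np.full((9, 9), 2.2)  # inside SM band, below SA floor
        state.seedbank[sm.Habitat.SM][:] = 100.0
        out = establish(state, fertile, e_rel, stochastic=False)
        assert (out.hab.codes == int(sm.Habitat.SM)).all()
        state2 = flat_state.copy()
        state2.seedbank[sm.Habitat.SM][:] = 0.0
        state2.seedbank[sm.Habitat.SA][:] = 100.0
        out2 = establish(state2, fertile, e_rel, stochastic=False)
        assert (out2.hab.codes == int(sm.Habitat.MUDFLAT)).all()

    def test_zero_germination_is_inert(self, flat_state, species):
        from dataclasses import replace

        sterile = {h: replace(sp, germination_prob=0.0) for h, sp in species.items()}
        state = flat_state
        for h in state.seedbank:
            state.seedbank[h][:] = 1e6
        out = establish(state, sterile, np.full((9, 9), 2.2), stochastic=False)
        assert (out.hab.codes == int(sm.Habitat.MUDFLAT)).all()

    def test_conversion_probability_saturates(self):
        """With unbounded seeds, P(convert) -> 1 - (1 - g*S)^cap."""
        from dataclasses import replace

        species = sm.default_species_params()
        # tune g so that g*S = 0.3 exactly at e_rel where S = 1
        sp = replace(
            species[sm.Habitat.SM],
            germination_prob=0.3,
            establishment_band=(0.0, 100.0),
        )
        spec = sm.GridSpec(200, 200)
        elev = sm.ElevationGrid(spec, np.full(spec.shape, 10.0))
        hab = sm.HabitatGrid(spec, np.full(spec.shape, int(sm.Habitat.MUDFLAT), dtype=np.int16))
        state = sm.LandscapeState(2008, elev, hab, {sm.Habitat.SM: np.full(spec.shape, 1e9)})
        out = establish(
            state, {sm.Habitat.SM: sp}, elev.values, np.random.default_rng(4), cap=10.0
        )
        frac = (out.hab.codes == int(sm.Habitat.SM)).mean()
        expected = 1 - 0.7**10
        assert frac == pytest.approx(expected, abs=5 * np.sqrt(expected * (1 - expected)) / 200)

    def test_seedbank_consumed_and_retained(self, flat_state, species):
        from dataclasses import replace

        fertile = {h: replace(sp, germination_prob=1.0) for h, sp in species.items()}
        state = flat_state
        e_rel = np.full((9, 9), 2.2)
        state.seedbank[sm.Habitat.SM][:] = 100.0
        out = establish(state, fertile, e_rel, stochastic=False, retention=0.1)
        converted = out.hab.codes == int(sm.Habitat.SM)
        assert converted.all()
        assert (out.seedbank[sm.Habitat.SM][converted] == 0.0).all()
        # a cell outside every band keeps a decayed bank
        state2 = flat_state.copy()
        state2.seedbank[sm.Habitat.SM][:] = 100.0
        out2 = establish(state2, fertile, np.full((9, 9), 0.5), stochastic=False, retention=0.1)
        np.testing.assert_allclose(out2.seedbank[sm.Habitat.SM], 10.0)


class TestClonalSpread:
    def test_zero_lambda_identity(self, flat_state, species):
        from dataclasses import replace

        frozen = {h: replace(sp, annual_clonal_prob=0.0) for h, sp in species.items()}
        state = flat_state
        state.hab.codes[4, 4] = int(sm.Habitat.SA)
        out = clonal_spread(state, frozen, np.full((9, 9), 3.0), stochastic=False)
        np.testing.assert_array_equal(out.hab.codes, state.hab.codes)

    def test_neighbour_count_formula(self):
        """3 occupied neighbours at lambda=0.3 convert w.p. 1 - 0.7^3."""
        from dataclasses import replace

        sp = replace(sm.default_species_params()[sm.Habitat.SA], annual_clonal_prob=0.3)
        spec = sm.GridSpec(3, 300)
        elev = sm.ElevationGrid(spec, np.full(spec.shape, 3.0))
        codes = np.full(spec.shape, int(sm.Habitat.MUDFLAT), dtype=np.int16)
        codes[0, :] = int(sm.Habitat.SA)  # middle row cells see 3 SA neighbours
        state = sm.LandscapeState(2008, elev, sm.HabitatGrid(spec, codes), {})
        out = clonal_spread(
            state, {sm.Habitat.SA: sp}, elev.values, np.random.default_rng(8)
        )
        frac = (out.hab.codes[1, 1:-1] == int(sm.Habitat.SA)).mean()
        expected = 1 - 0.7**3
        assert frac == pytest.approx(expected, abs=5 * np.sqrt(expected * (1 - expected) / 298))
        # the far row has no SA neighbour and must stay mudflat
        assert (out.hab.codes[2] == int(sm.Habitat.MUDFLAT)).all()


class TestCompetition:
    def _sm_next_to_sa(self, e_rel_value):
        spec = sm.GridSpec(1, 2)
        elev = sm.ElevationGrid(spec, np.full(spec.shape, e_rel_value))
        codes = np.array([[int(sm.Habitat.SM), int(sm.Habitat.SA)]], dtype=np.int16)
        return sm.LandscapeState(2008, elev, sm.HabitatGrid(spec, codes), {})

    def test_band_gate_blocks_low_invasion(self, species):
        state = self._sm_next_to_sa(2.1)  # below the SA band floor
        out = apply_competition(
            state, species, state.elev.values, stochastic=False, invasion_prob=1.0
        )
        assert out.hab.codes[0, 0] == int(sm.Habitat.SM)

    def test_invasion_probability(self, species):
        spec = sm.GridSpec(2, 500)
        elev = sm.ElevationGrid(spec, np.full(spec.shape, 2.7))
        codes = np.full(spec.shape, int(sm.Habitat.SM), dtype=np.int16)
        codes[1, :] = int(sm.Habitat.SA)
        state = sm.LandscapeState(2008, elev, sm.HabitatGrid(spec, codes), {})
        out = apply_competition(
            state, species, elev.values, np.random.default_rng(2), invasion_prob=0.4
        )
        frac = (out.hab.codes[0] == int(sm.Habitat.SA)).mean()
        expected = 0.4 * sm.survival_probability(species[sm.Habitat.SA], 2.7)
        assert frac == pytest.approx(expected, abs=5 * np.sqrt(expected * (1 - expected) / 500))

    def test_no_sa_no_change(self, flat_state, species):
        state = flat_state
        state.hab.codes[:] = int(sm.Habitat.SM)
        out = apply_competition(state, species, np.full((9, 9), 2.7), stochastic=False)
        np.testing.assert_array_equal(out.hab.codes, state.hab.codes)


class TestWaterline:
    def test_symmetric_reclassification(self):
        spec = sm.GridSpec(1, 3)
        codes = np.array(
            [[int(sm.Habitat.WATER), int(sm.Habitat.MUDFLAT), int(sm.Habitat.SM)]],
            dtype=np.int16,
        )
        hab = sm.HabitatGrid(spec, codes)
        e_rel = np.array([[0.5, -0.5, -0.5]])
        out = reclassify_waterline(hab, e_rel)
        assert out.codes[0, 0] == int(sm.Habitat.MUDFLAT)  # emerged
        assert out.codes[0, 1] == int(sm.Habitat.WATER)  # drowned
        assert out.codes[0, 2] == int(sm.Habitat.SM)  # vegetation handled by mortality


class TestStepAndRun:
    def test_inert_fixed_point(self, small_landscape):
        """No rise, no accretion, no subsidence, sterile vegetation: the
        landscape is exactly unchanged after many years."""
        from dataclasses import replace

        state, sed = small_landscape
        sed = sm.SedimentRegimeGrid(sed.spec, np.zeros(sed.spec.shape))
        inert = {
            h: replace(sp, germination_prob=0.0, annual_clonal_prob=0.0)
            for h, sp in sm.default_species_params().items()
        }
        cfg = sm.EngineConfig(stochastic=False, competition=False)
        res = sm.run_smm(
            state,
            2038,
            sm.SLRScenario.named("NONE"),
            sed,
            species=inert,
            cfg=cfg,
            subsidence=sm.SubsidenceModel(0.0),
        )
        np.testing.assert_array_equal(res.final.hab.codes, state.hab.codes)
        np.testing.assert_allclose(res.final.elev.values, state.elev.values)

    def test_bit_identical_reruns(self, small_landscape):
        state, sed = small_landscape
        runs = [
            sm.run_smm(
                state, 2028, sm.SLRScenario.named("RCP85"), sed, cfg=sm.EngineConfig(seed=5)
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].final.hab.codes, runs[1].final.hab.codes)
        np.testing.assert_array_equal(runs[0].final.elev.values, runs[1].final.elev.values)
        assert runs[0].series.equals(runs[1].series)

    def test_area_conserved_and_codes_valid(self, small_landscape):
        state, sed = small_landscape
        total0 = sum(sm.habitat_areas(state.hab).values())
        res = sm.run_smm(state, 2038, sm.SLRScenario.named("RCP85"), sed)
        for year, snap in res.snapshots.items():
            assert sum(sm.habitat_areas(snap.hab).values()) == pytest.approx(total0)
            assert set(np.unique(snap.hab.codes)) <= {int(h) for h in sm.Habitat}

    def test_accretion_only_composition(self, small_landscape):
        """With inert vegetation the elevation change over one step equals the
        annual vertical budget exactly."""
        from dataclasses import replace
        from saltmarsh.engine import Forcing, step_year

        state, sed = small_landscape
        inert = {
            h: replace(sp, germination_prob=0.0, annual_clonal_prob=0.0)
            for h, sp in sm.default_species_params().items()
        }
        cfg = sm.EngineConfig(stochastic=False, competition=False)
        forcing = Forcing(scenario=sm.SLRScenario.named("NONE"), sediment=sed)
        out = step_year(state, forcing, inert, cfg)
        expected = sm.annual_elevation_update(
            state.elev, state.hab, sed, forcing.subsidence
        )
        np.testing.assert_allclose(out.elev.values, expected.values)
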