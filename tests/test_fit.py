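"""Likelihood correctness (brute-force oracle), merging, density, fitting."""

import numpy as np
import pytest
from scipy import stats

from scrval.fit import (
    CaptureData,
    SCRParameters,
    StateSpace,
    build_state_space,
    capture_from_encounters,
    estimate_density,
    fit_scr,
    merge_harvest_as_detections,
    scr_negative_log_likelihood,
    telemetry_negative_log_likelihood,
)
from scrval.harness import MODELS, ScenarioSpec, simulate_dataset
from scrval.landscape import LandscapeGrid
from scrval.observation import (
    EffortAllocation,
    EncounterData,
    HarvestData,
    TelemetryData,
)


def brute_force_nll(par: SCRParameters, cap: CaptureData, ss: StateSpace):
    """Direct enumeration of the integrated likelihood (independent oracle)."""
    lam = np.exp(par.density_intercept + par.density_habitat_slope * ss.habitat)
    psi = {"M": 1 / (1 + np.exp(-par.logit_psi))}
    psi["F"] = 1 - psi["M"]
    J, T = cap.effort.shape

    def p_and_q(k, sex, j, t):
        """Detection probability p and survival q = 1 - p, each computed
        directly from eta so neither loses precision near 0 or 1."""
        e = cap.effort[j, t]
        if e <= 0:
            return 0.0, 1.0
        sig = np.exp(par.log_sigma_male if sex == "M" else par.log_sigma_female)
        eta = (
            par.beta0_encounter
            + par.beta_eff * np.log(e)
            - ss.dist_to_traps[k, j] / (2 * sig * sig)
        )
        return -np.expm1(-np.exp(eta)), np.exp(-np.exp(eta))

    total = 0.0
    for i in range(cap.n_individuals):
        s = cap.sex[i]
        L_i = 0.0
        for k in range(ss.n_cells):
            pr = 1.0
            for j in range(J):
                for t in range(T):
                    if not cap.avail[i, t]:
                        continue
                    p, q = p_and_q(k, s, j, t)
                    pr *= p if cap.histories[i, j, t] else q
            L_i += lam[k] * psi[s] * pr
        total += np.log(L_i)
    for s in ("M", "F"):
        for k in range(ss.n_cells):
            prod = 1.0
            for j in range(J):
                for t in range(T):
                    prod *= p_and_q(k, s, j, t)[1]
            total -= psi[s] * lam[k] * (1 - prod)
    return -total


def _random_instance(seed, n_cells=6, n_traps=2, n_occ=2, n_ind=3):
    rng = np.random.default_rng(seed)
    ss = StateSpace(
        centers=rng.random((n_cells, 2)) * 10,
        habitat=rng.standard_normal(n_cells),
        cell_area_km2=4.0,
        dist_to_traps=rng.random((n_cells, n_traps)) * 2,
        distance_unit_km=5.0,
        landscape_to_state=np.arange(n_cells),
    )
    effort = rng.random((n_traps, n_occ)) * 30
    hist = np.zeros((n_ind, n_traps, n_occ), dtype=np.uint8)
    avail = np.ones((n_ind, n_occ), dtype=bool)
    for i in range(n_ind):
        t_max = n_occ if i % 2 == 0 else rng.integers(1, n_occ + 1)
        avail[i, t_max:] = False
        # at least one detection inside the availability window
        hist[i, rng.integers(n_traps), rng.integers(t_max)] = 1
    cap = CaptureData(
        histories=hist,
        sex=np.array(["M", "F", "M"])[:n_ind],
        ids=np.arange(n_ind),
        avail=avail,
        harvested=np.zeros(n_ind, dtype=bool),
        effort=effort,
    )
    par = SCRParameters(*rng.normal(0, 1, 7) + [-2, 1, -0.6, -0.8, -1, 0, 0])
    return par, cap, ss


class TestLikelihoodOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_enumeration(self, seed):
        par, cap, ss = _random_instance(seed)
        fast = scr_negative_log_likelihood(par, cap, ss)
        brute = brute_force_nll(par, cap, ss)
        assert fast == pytest.approx(brute, abs=1e-10)

    def test_degenerate_closed_form(self):
        """1 cell / 1 trap / 1 occasion: NLL = -(log(lam*p) - lam*p)."""
        ss = StateSpace(
            centers=np.array([[1.0, 1.0]]),
            habitat=np.array([0.0]),
            cell_area_km2=4.0,
            dist_to_traps=np.array([[0.0]]),
            distance_unit_km=5.0,
            landscape_to_state=np.array([0]),
        )
        cap = CaptureData(
            histories=np.ones((1, 1, 1), np.uint8),
            sex=np.array(["M"]),
            ids=np.array([0]),
            avail=np.ones((1, 1), bool),
            harvested=np.zeros(1, bool),
            effort=np.ones((1, 1)),
        )
        # choose beta0 so p = 0.3 at unit effort; lam = 0.5; psi -> 1
        par = SCRParameters(
            np.log(-np.log(0.7)), 0.0, -0.65, -0.85, np.log(0.5), 0.0, 40.0
        )
        expected = -(np.log(0.15) - 0.15)  # 2.0471
        assert scr_negative_log_likelihood(par, cap, ss) == pytest.approx(
            expected, abs=1e-9
        )

    def test_individual_order_invariance(self):
        par, cap, ss = _random_instance(7)
        perm = [2, 0, 1]
        cap2 = CaptureData(
            histories=cap.histories[perm],
            sex=cap.sex[perm],
            ids=cap.ids[perm],
            avail=cap.avail[perm],
            harvested=cap.harvested[perm],
            effort=cap.effort,
        )
        a = scr_negative_log_likelihood(par, cap, ss)
        b = scr_negative_log_likelihood(par, cap2, ss)
        assert a == pytest.approx(b, abs=1e-12)

    def test_effort_scaling_identity(self):
        """Doubling effort while shifting beta0 by -beta_eff*log2 is a no-op."""
        par, cap, ss = _random_instance(11)
        cap2 = CaptureData(
            histories=cap.histories,
            sex=cap.sex,
            ids=cap.ids,
            avail=cap.avail,
            harvested=cap.harvested,
            effort=2.0 * cap.effort,
        )
        par2 = SCRParameters.from_vector(
            par.to_vector() - np.eye(7)[0] * np.log(2) * par.beta_eff
        )
        a = scr_negative_log_likelihood(par, cap, ss)
        b = scr_negative_log_likelihood(par2, cap2, ss)
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonfinite_parameters_rejected(self):
        par, cap, ss = _random_instance(13)
        bad = par.to_vector()
        bad[2] = np.nan
        with pytest.raises(ValueError):
            scr_negative_log_likelihood(bad, cap, ss)

    def test_finite_difference_gradient_is_consistent(self):
        """Central differences at two step sizes agree (smooth objective)."""
        par, cap, ss = _random_instance(17)
        from scrval.fit import SCRLikelihood

        nll = SCRLikelihood(cap, ss)
        x = par.to_vector()

        def grad(h):
            g = np.zeros_like(x)
            for i in range(x.size):
                e = np.eye(x.size)[i] * h
                g[i] = (nll(x + e) - nll(x - e)) / (2 * h)
            return g

        g1, g2 = grad(1e-5), grad(3e-6)
        np.testing.assert_allclose(g1, g2, rtol=1e-5, atol=1e-8)


class TestTelemetryLikelihood:
    def _toy(self):
        ss = StateSpace(
            centers=np.array([[0.0, 0.0], [5.0, 0.0], [10.0, 0.0]]),
            habitat=np.zeros(3),
            cell_area_km2=25.0,
            dist_to_traps=np.zeros((3, 1)),
            distance_unit_km=5.0,
            landscape_to_state=np.arange(3),
        )
        tel = TelemetryData(
            ids=np.array([0]),
            sex=np.array(["M"]),
            counts=np.array([[25, 4, 1]]),
            n_fixes=30,
        )
        return ss, tel

    def test_matches_multinomial_pmf(self, truth_params):
        """Full multinomial log-pmf with kernel-based cell probabilities."""
        ss, tel = self._toy()
        par = SCRParameters(-5, 1, -0.65, -0.85, 0, 0, 0)
        d = np.array([0.0, 1.0, 2.0])
        w = np.exp(-d / (2 * np.exp(-0.65) ** 2))
        pi = w / w.sum()
        expected = -stats.multinomial.logpmf([25, 4, 1], 30, pi)
        got = telemetry_negative_log_likelihood(par, tel, ss)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_concentration_limit(self):
        """All fixes in the home cell: NLL falls as sigma shrinks."""
        ss, _ = self._toy()
        tel = TelemetryData(
            ids=np.array([0]), sex=np.array(["M"]),
            counts=np.array([[30, 0, 0]]), n_fixes=30,
        )
        nlls = [
            telemetry_negative_log_likelihood(
                SCRParameters(-5, 1, ls, ls, 0, 0, 0), tel, ss
            )
            for ls in (0.0, -0.5, -1.0, -1.5)
        ]
        assert all(a > b for a, b in zip(nlls, nlls[1:]))

    def test_bad_counts_rejected(self):
        ss, _ = self._toy()
        tel = TelemetryData(
            ids=np.array([0]), sex=np.array(["M"]),
            counts=np.array([[3, 2, 1]]), n_fixes=30,
        )
        with pytest.raises(ValueError):
            telemetry_negative_log_likelihood(
                SCRParameters(-5, 1, -0.65, -0.85, 0, 0, 0), tel, ss
            )

    def test_profile_minimum_near_generating_sigma(
        self, default_grids, habitat_landscape, truth_params
    ):
        """1-D grid search over log sigma bottoms out near the truth."""
        from scrval.landscape import draw_activity_centers, intensity_surface
        from scrval.observation import simulate_telemetry

        _, traps = default_grids
        surf = intensity_surface(habitat_landscape)
        pop = draw_activity_centers(surf, habitat_landscape, 50, 50, seed=31)
        tel = simulate_telemetry(
            pop, 4, 0, truth_params, habitat_landscape, traps=traps, seed=32
        )
        ss = build_state_space(habitat_landscape, traps)
        grid = np.linspace(-1.4, 0.1, 61)
        nlls = [
            telemetry_negative_log_likelihood(
                SCRParameters(-5, 1, ls, -0.85, 0, 0, 0), tel, ss
            )
            for ls in grid
        ]
        assert abs(grid[int(np.argmin(nlls))] - (-0.65)) <= 0.15


class TestMergeHarvest:
    def _encounters(self, n=4, J=3, T=4):
        det = np.zeros((n, J, T), dtype=np.uint8)
        det[0, 0, 0] = 1
        det[1, 2, 1] = 1
        return EncounterData(
            detections=det,
            ids=np.arange(n),
            sex=np.array(["M", "F", "M", "F"])[:n],
        )

    def _effort(self, J=3, T=4):
        return EffortAllocation(
            effort=np.arange(1.0, J * T + 1).reshape(J, T),
            total_per_occasion=1.0,
            mode="uncorrelated",
        )

    def test_empty_harvest_identity(self):
        enc, eff = self._encounters(), self._effort()
        cap = merge_harvest_as_detections(enc, None, eff)
        cap2 = capture_from_encounters(enc, eff)
        np.testing.assert_array_equal(cap.histories, cap2.histories)
        assert cap.avail.all()
        assert cap.n_individuals == 2

    def test_harvest_only_individual_enters_with_censoring(self):
        enc, eff = self._encounters(), self._effort()
        harvest = HarvestData(
            individual=np.array([2]), cell=np.array([1]),
            occasion=np.array([1]),  # harvested occasion 2 (1-based)
        )
        cap = merge_harvest_as_detections(enc, harvest, eff)
        assert cap.n_individuals == 3
        row = int(np.flatnonzero(cap.ids == 2)[0])
        assert cap.histories[row].sum() == 1
        assert cap.histories[row, 1, 1] == 1
        np.testing.assert_array_equal(
            cap.avail[row], [True, True, False, False]
        )
        assert cap.harvested[row]

    def test_unknown_individual_rejected(self):
        enc, eff = self._encounters(), self._effort()
        harvest = HarvestData(
            individual=np.array([99]), cell=np.array([0]),
            occasion=np.array([0]),
        )
        with pytest.raises(ValueError):
            merge_harvest_as_detections(enc, harvest, eff)

    def test_post_harvest_search_detections_dropped(self):
        enc, eff = self._encounters(), self._effort()
        harvest = HarvestData(
            individual=np.array([0]), cell=np.array([0]),
            occasion=np.array([0]),
        )
        det = enc.detections.copy()
        det[0, 1, 3] = 1  # stale detection after harvest
        enc2 = EncounterData(detections=det, ids=enc.ids, sex=enc.sex)
        cap = merge_harvest_as_detections(enc2, harvest, eff)
        row = int(np.flatnonzero(cap.ids == 0)[0])
        assert cap.histories[row, :, 1:].sum() == 0


class TestDensity:
    def _flat_statespace(self, n_cells=2500, cell_area=4.0):
        return StateSpace(
            centers=np.zeros((n_cells, 2)),
            habitat=np.zeros(n_cells),
            cell_area_km2=cell_area,
            dist_to_traps=np.zeros((n_cells, 1)),
            distance_unit_km=5.0,
            landscape_to_state=np.arange(n_cells),
        )

    def test_constant_intensity_arithmetic(self):
        ss = self._flat_statespace()
        par = SCRParameters(-5, 1, -0.65, -0.85, np.log(0.08), 0.0, 0.0)
        n_hat, density = estimate_density(par, ss)
        assert n_hat == pytest.approx(200.0)
        assert density == pytest.approx(2.0)

    def test_halving_area_preserves_density(self):
        par = SCRParameters(-5, 1, -0.65, -0.85, np.log(0.08), 0.0, 0.0)
        full = estimate_density(par, self._flat_statespace(2500))
        half = estimate_density(par, self._flat_statespace(1250))
        assert half[0] == pytest.approx(full[0] / 2)
        assert half[1] == pytest.approx(full[1])


@pytest.fixture(scope="module")
def scenario5_replicate():
    return simulate_dataset(ScenarioSpec.from_id(5), 2024, 3)


class TestFitting:

    def test_density_recovery_on_one_large_replicate(self, scenario5_replicate):
        """A single high-effort fit lands within a generous band of truth."""
        data = scenario5_replicate
        ss = build_state_space(data.landscape, data.traps, coarsen=2)
        cap = capture_from_encounters(data.encounters, data.effort)
        fit = fit_scr(cap, ss)
        assert fit.converged
        assert abs(fit.density_per_100km2 - 2.0) / 2.0 < 0.35

    def test_coarsening_changes_density_mildly(self, scenario5_replicate):
        """2x state-space coarsening moves the density estimate by little."""
        data = scenario5_replicate
        cap = capture_from_encounters(data.encounters, data.effort)
        dens = []
        for c in (1, 2):
            ss = build_state_space(data.landscape, data.traps, coarsen=c)
            dens.append(fit_scr(cap, ss).density_per_100km2)
        assert abs(dens[1] - dens[0]) / dens[0] < 0.03

    def test_truth_beats_random_perturbations(self):
        """The NLL at generating parameters undercuts nearby random points."""
        from scrval.fit import SCRLikelihood

        wins, trials = 0, 0
        for rep in range(5):
            data = simulate_dataset(ScenarioSpec.from_id(5), 555, rep)
            ss = build_state_space(data.landscape, data.traps, coarsen=2)
            cap = capture_from_encounters(data.encounters, data.effort)
            nll = SCRLikelihood(cap, ss)
            mu_per_cell = 16 * np.exp(-4.0)  # coarse 4x4 km cell at H = 0
            truth = np.array(
                [-5, 1, -0.65, -0.85, np.log(mu_per_cell), 0.5, 0.0]
            )
            base = nll(truth)
            rng = np.random.default_rng(rep)
            for _ in range(20):
                trials += 1
                if base < nll(truth + rng.standard_normal(7)):
                    wins += 1
        assert wins / trials >= 0.95
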