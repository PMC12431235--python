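"""eCAP assembly: scaling/exposure functions, additivity, population-level
cancellation and partial-recruitment effects, sweeps, clustering."""

import copy

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

import nervecap as nc
from nervecap.ecap import DiameterGrid, ECAPResult, FiberType, _second_derivative_on, scaling_function
from nervecap.fiber import FiberKind
from nervecap.recruitment import RecruitmentCurve


def _full_recruitment(d0=4e-6):
    return RecruitmentCurve([0.0, 1e-9], [1.0, 1.0], d0)


def _step_recruitment(t0, d0=4e-6):
    return RecruitmentCurve([0.0, t0 * (1 - 1e-9), t0, 10 * t0], [0.0, 0.0, 1.0, 1.0], d0)


def _myel_afferent_only(fasc, recruitment=None):
    f = copy.copy(fasc)
    f.populations = {FiberType.MYELINATED_AFFERENT: fasc.populations[FiberType.MYELINATED_AFFERENT]}
    if recruitment is not None:
        f.recruitment = {FiberType.MYELINATED_AFFERENT: recruitment}
    return f


class TestScalingFunction:
    def test_zero_current(self, default_nerve):
        _, nerve = default_nerve
        fasc = nerve.fascicles[0]
        pop = fasc.populations[FiberType.MYELINATED_AFFERENT]
        w = scaling_function(pop, fasc.recruitment[FiberType.MYELINATED_AFFERENT], 0.0, DiameterGrid())
        assert np.all(w == 0.0)

    def test_full_recruitment_myelinated_scaling(self, default_nerve):
        """With R == 1, myelinated weights reduce to N p(d) dd (pi sigma/4a) d."""
        _, nerve = default_nerve
        pop = nerve.fascicles[0].populations[FiberType.MYELINATED_AFFERENT]
        g = DiameterGrid()
        w = scaling_function(pop, _full_recruitment(), 1.0, g)
        expected = pop.count * pop.density(g) * g.delta * (np.pi * g.diameters / (4 * 4.3e6))
        assert np.allclose(w, expected, rtol=1e-12)
        assert np.all(w >= 0.0)


class TestExposureFunction:
    def test_single_bin_reduces_to_reparameterized_lead_field(self, default_nerve):
        _, nerve = default_nerve
        fasc = nerve.fascicles[0]
        g = DiameterGrid(count=200)
        j = 120
        weights = np.zeros(g.count)
        weights[j] = 1.0
        t = 1e-5 * np.arange(2001)
        xf = nc.exposure_function(fasc, FiberType.MYELINATED_AFFERENT, 1.0, t, g, weights=weights)
        v = nc.conduction_velocity(nc.ConductionLaw.myelinated(), g.diameters[j])
        _, expected = nc.time_reparameterize(fasc.sensitivity, v, 0.0, t)
        assert np.allclose(xf.values, expected)

    def test_sharp_cutoff_produces_kink(self, default_nerve):
        """Full recruitment gives a smooth exposure; a sharp diameter cutoff
        leaves a visible discontinuity in its derivative."""
        _, nerve = default_nerve
        fasc = _myel_afferent_only(nerve.fascicles[3])
        g = DiameterGrid(count=1000)
        t = 1e-5 * np.arange(2501)
        full = nc.exposure_function(
            _myel_afferent_only(fasc, _full_recruitment()), FiberType.MYELINATED_AFFERENT, 1.0, t, g
        )
        part = nc.exposure_function(
            _myel_afferent_only(fasc, _step_recruitment(3.125e-5)), FiberType.MYELINATED_AFFERENT, 3.125e-5, t, g
        )
        def max_curvature(x):
            interior = slice(50, 2450)  # away from the window-edge onset
            return np.max(np.abs(np.diff(x[interior], 2))) / np.max(np.abs(x))
        assert max_curvature(part.values) > 2 * max_curvature(full.values)

    def test_grid_doubling_stable(self, default_nerve):
        """Doubling the diameter sampling (2000 -> 4000) barely moves the signal."""
        _, nerve = default_nerve
        spec = default_nerve[0]
        fasc = nerve.fascicles[2]
        aps = nc.default_ap_waveforms()
        r1 = nc.compute_ecap([fasc], aps, spec.partial_current, grid=DiameterGrid(count=2000))
        r2 = nc.compute_ecap([fasc], aps, spec.partial_current, grid=DiameterGrid(count=4000))
        rel = np.max(np.abs(r1.total - r2.total)) / np.max(np.abs(r1.total))
        assert rel < 0.01


class TestComputeEcap:
    def test_additivity_exact(self, default_nerve, ap_waveforms):
        spec, nerve = default_nerve
        res = nc.compute_ecap(nerve.fascicles[:4], ap_waveforms, spec.partial_current, grid=DiameterGrid(count=500))
        total = np.zeros_like(res.total)
        for vals in res.contributions.values():
            total += vals
        assert np.max(np.abs(res.total - total)) <= 1e-12 * np.max(np.abs(res.total))

    def test_zero_stimulus_zero_signal(self, default_nerve, ap_waveforms):
        _, nerve = default_nerve
        res = nc.compute_ecap(nerve.fascicles[:2], ap_waveforms, 0.0, grid=DiameterGrid(count=200))
        assert np.all(res.total == 0.0)

    def test_linear_in_fiber_counts(self, default_nerve, ap_waveforms):
        spec, nerve = default_nerve
        fasc = nerve.fascicles[1]
        res1 = nc.compute_ecap([fasc], ap_waveforms, spec.partial_current, grid=DiameterGrid(count=300))
        scaled = copy.copy(fasc)
        scaled.populations = {
            ft: nc.FiberPopulation(p.fiber_type, 3.0 * p.count, p.gamma_shape, p.gamma_scale, p.axial_conductivity)
            for ft, p in fasc.populations.items()
        }
        res3 = nc.compute_ecap([scaled], ap_waveforms, spec.partial_current, grid=DiameterGrid(count=300))
        assert np.allclose(res3.total, 3.0 * res1.total, rtol=1e-12)

    def test_single_bin_reduces_to_sfap(self, default_nerve, ap_waveforms):
        """One diameter bin with unit population weight reproduces the
        single-fiber reciprocity signal on the shared grid points."""
        _, nerve = default_nerve
        fasc = nerve.fascicles[0]
        g = DiameterGrid(count=200)
        j, dt = 150, 1e-5
        d = g.diameters[j]
        v = nc.conduction_velocity(nc.ConductionLaw.myelinated(), d)
        eta = nc.axial_prefactor(d=d)
        # exposure with the single-fiber weight eta/v, convolved exactly as compute_ecap does
        weights = np.zeros(g.count)
        weights[j] = eta / v
        t_x = dt * np.arange(2501)
        xf = nc.exposure_function(fasc, FiberType.MYELINATED_AFFERENT, 1.0, t_x, g, weights=weights)
        ap = ap_waveforms[FiberKind.MYELINATED]
        t_ap, d2 = _second_derivative_on(ap, dt)
        ecap_vals = np.convolve(d2, xf.values) * dt
        ecap_time = (t_ap[0] + t_x[0]) + dt * np.arange(ecap_vals.size)

        ap_dt = nc.gaussian_ap(ap.peak, ap.width, dt=dt)
        sfap = nc.sfap_reciprocity(ap_dt, fasc.sensitivity, v, eta)
        common = (ecap_time >= sfap.time[0]) & (ecap_time <= sfap.time[-1])
        pred = sfap.sample(ecap_time[common])
        assert np.allclose(ecap_vals[common], pred, atol=1e-6 * np.max(np.abs(pred)))


class TestPopulationCancellation:
    def test_full_recruitment_cancels(self, default_nerve, ap_waveforms):
        """Peak eCAP of a smooth fully recruited population is >= 10x smaller
        than the sum of its per-diameter |SFAP| peaks."""
        _, nerve = default_nerve
        fasc = _myel_afferent_only(nerve.fascicles[3], _full_recruitment())
        g = DiameterGrid(count=400)
        res = nc.compute_ecap([fasc], ap_waveforms, 1.0, grid=g)
        w = scaling_function(
            fasc.populations[FiberType.MYELINATED_AFFERENT], _full_recruitment(), 1.0, g
        )
        dt = 1e-5
        t_x = dt * np.arange(2501)
        sp = CubicSpline(fasc.sensitivity.arclength, fasc.sensitivity.values, extrapolate=False)
        t_ap, d2 = _second_derivative_on(ap_waveforms[FiberKind.MYELINATED], dt)
        law = nc.ConductionLaw.myelinated()
        peak_sum = 0.0
        for i, d in enumerate(g.diameters):
            if w[i] <= 0:
                continue
            phi = sp(nc.conduction_velocity(law, d) * t_x)
            phi = np.where(np.isnan(phi), 0.0, phi)
            peak_sum += np.max(np.abs(np.convolve(d2, w[i] * phi) * dt))
        assert peak_sum / np.max(np.abs(res.total)) >= 10.0

    def test_partial_recruitment_enhances_amplitude(self, default_nerve, ap_waveforms):
        """A sharp diameter cutoff breaks cancellation and raises the
        peak-to-peak amplitude above the fully recruited case."""
        _, nerve = default_nerve
        base = nerve.fascicles[3]
        g = DiameterGrid(count=400)
        i = 5e-4
        full = nc.compute_ecap([_myel_afferent_only(base, _full_recruitment())], ap_waveforms, i, grid=g)
        part = nc.compute_ecap([_myel_afferent_only(base, _step_recruitment(i))], ap_waveforms, i, grid=g)
        assert part.total_signal().peak_to_peak() > full.total_signal().peak_to_peak()


class TestAmplitudeSweep:
    def test_recruited_fraction_monotone(self, myelinated_nerve, ap_waveforms):
        spec, nerve = myelinated_nerve
        tab = nc.amplitude_sweep(
            nerve.fascicles, ap_waveforms, [3.125e-5, 1e-4, 5e-4], grid=DiameterGrid(count=300)
        )
        assert np.all(np.diff(tab["recruited_fraction"]) >= -1e-12)

    def test_fascicle_amplitude_plateaus_at_full_recruitment(self, myelinated_nerve, ap_waveforms):
        """Once a fascicle's recruitment saturates, its amplitude-vs-current
        curve flattens to < 1% relative change."""
        spec, nerve = myelinated_nerve
        tab = nc.amplitude_sweep(
            nerve.fascicles, ap_waveforms, [4e-4, 5e-4], grid=DiameterGrid(count=500)
        )
        fp = tab["fascicle_peak_to_peak"]
        rel_change = np.abs(fp[1] - fp[0]) / fp[1]
        assert np.all(rel_change < 0.01)

    def test_sharp_threshold_fascicle_non_monotonic(self, myelinated_nerve, ap_waveforms):
        """With a sharp titration threshold the fascicle amplitude rises to a
        maximum while partially recruited, then falls toward the
        full-recruitment plateau."""
        _, nerve = myelinated_nerve
        t0 = 3.125e-5
        fasc = _myel_afferent_only(nerve.fascicles[3], _step_recruitment(t0))
        # cutoff diameters d0*t0/I sweep from above the grid ceiling down to ~0
        currents = t0 * np.array([0.25, 0.4, 0.6, 1.0, 2.0, 4.0, 16.0, 256.0])
        tab = nc.amplitude_sweep([fasc], ap_waveforms, currents, grid=DiameterGrid(count=400))
        amp = tab["fascicle_peak_to_peak"][:, 0]
        imax = int(np.argmax(amp))
        assert 0 < imax < len(currents) - 1
        assert amp[imax] > 1.5 * amp[-1]

    def test_unsorted_currents_rejected(self, myelinated_nerve, ap_waveforms):
        _, nerve = myelinated_nerve
        with pytest.raises(ValueError):
            nc.amplitude_sweep(nerve.fascicles[:1], ap_waveforms, [2e-4, 1e-4])


class TestContributionCorrelation:
    def _result_from_rows(self, rows):
        t = np.linspace(0, 1e-2, rows[0].size)
        contributions = {(i, FiberType.MYELINATED_AFFERENT): r for i, r in enumerate(rows)}
        total = np.sum(rows, axis=0)
        return ECAPResult(t, total, contributions)

    def test_identical_and_opposite_contributions(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=500)
        res = self._result_from_rows([a, a.copy(), -a])
        out = nc.contribution_correlation(res, k=2, seed=0)
        c = out["correlation"]
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(-1.0)

    def test_zero_contribution_excluded(self):
        rng = np.random.default_rng(1)
        rows = [rng.normal(size=300), rng.normal(size=300), np.zeros(300)]
        res = self._result_from_rows(rows)
        with pytest.warns(UserWarning):
            out = nc.contribution_correlation(res, k=2, seed=0)
        assert out["fascicle_ids"] == [0, 1]

    def test_similar_fascicles_share_cluster(self):
        """Fascicles with matched recruitment/geometry (identical traces up to
        noise) land in the same k-means cluster."""
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=400), rng.normal(size=400)
        rows = [a + 0.01 * rng.normal(size=400) for _ in range(3)]
        rows += [b + 0.01 * rng.normal(size=400) for _ in range(3)]
        res = self._result_from_rows(rows)
        out = nc.contribution_correlation(res, k=2, seed=0)
        labels = out["labels"]
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
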