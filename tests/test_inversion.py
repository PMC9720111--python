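"""Constrained least-squares retrieval: feasibility, recovery, determinism."""
import numpy as np
import pytest

from leafspec.inversion import (
    InversionConfig,
    invert_batch,
    invert_spectrum,
    residuals,
    results_to_frame,
)
from leafspec.radiative_transfer import forward_model
from leafspec.types import LeafBiophysics, MeasuredSpectrumRecord


def record_from(p: LeafBiophysics, lib, sample_id="leaf") -> MeasuredSpectrumRecord:
    spec = forward_model(p, lib)
    return MeasuredSpectrumRecord(
        sample_id=sample_id, side="averaged", grid=lib.grid,
        reflectance=spec.reflectance, transmittance=spec.transmittance,
    )


TRUTH = LeafBiophysics(
    n=1.7, cab=42.0, ccar=42.0 / 5.2, canth=3.0, cx=0.45,
    cbrown=0.05, cw=0.012, cm=0.0045,
)


class TestResiduals:
    def test_self_consistency_and_length(self, library):
        obs = record_from(TRUTH, library)
        res = residuals(TRUTH, obs, library)
        n_window = int(np.count_nonzero(library.grid.window_mask(400.0, 900.0)))
        assert res.shape == (2 * n_window,)
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_known_offset_appears_in_reflectance_half(self, library):
        obs = record_from(TRUTH, library)
        obs.reflectance = obs.reflectance + 0.01  # shift R only
        res = residuals(TRUTH, obs, library)
        half = res.size // 2
        np.testing.assert_allclose(res[:half], -0.01, atol=1e-12)
        np.testing.assert_allclose(res[half:], 0.0, atol=1e-12)

    def test_fit_window_must_be_covered(self, library):
        obs = record_from(TRUTH, library)
        cfg = InversionConfig(fit_window=(350.0, 900.0))
        with pytest.raises(ValueError):
            residuals(TRUTH, obs, library, cfg)


class TestInvertSpectrum:
    def test_noiseless_round_trip(self, library):
        rng = np.random.default_rng(5)
        for _ in range(3):
            cab = rng.uniform(20.0, 60.0)
            truth = LeafBiophysics(
                n=rng.uniform(1.2, 2.5), cab=cab, ccar=cab / rng.uniform(4.6, 6.2),
                canth=rng.uniform(0.0, 8.0), cx=rng.uniform(0.1, 0.9),
                cbrown=rng.uniform(0.0, 0.3), cw=rng.uniform(0.005, 0.02),
                cm=rng.uniform(0.002, 0.008),
            )
            res = invert_spectrum(record_from(truth, library), library)
            assert res.converged
            est = res.estimate
            for name in ("cab", "ccar", "canth"):
                true = getattr(truth, name)
                tol = max(abs(true) * 0.01, 1e-3)
                assert abs(getattr(est, name) - true) <= tol
            assert abs(est.cx - truth.cx) < 0.02

    def test_ratio_constraint_binds_and_matches_grid_oracle(self, library):
        """A leaf with true chl/car = 8 must come back clipped to 6.4."""
        truth = LeafBiophysics(n=1.6, cab=40.0, ccar=5.0, canth=2.0, cx=0.4,
                               cw=0.01, cm=0.004)
        obs = record_from(truth, library)
        res = invert_spectrum(obs, library)
        assert res.estimate.chl_car_ratio == pytest.approx(6.4, abs=1e-6)
        assert res.ratio_active

        # dense-grid oracle over the feasible (cab, rho) plane, other
        # parameters held at truth: the best feasible ratio is the bound
        cfg = InversionConfig()
        best = (np.inf, None)
        for rho in np.linspace(4.4, 6.4, 21):
            for cab in np.linspace(35.0, 45.0, 41):
                p = LeafBiophysics(n=truth.n, cab=cab, ccar=cab / rho,
                                   canth=truth.canth, cx=truth.cx,
                                   cw=truth.cw, cm=truth.cm)
                ssr = float(np.sum(residuals(p, obs, library, cfg) ** 2))
                if ssr < best[0]:
                    best = (ssr, rho)
        assert best[1] == pytest.approx(6.4)

    def test_feasibility_always_holds(self, library):
        rng = np.random.default_rng(21)
        for _ in range(4):
            cab = rng.uniform(20.0, 60.0)
            truth = LeafBiophysics(cab=cab, ccar=cab / rng.uniform(3.0, 9.0))
            res = invert_spectrum(record_from(truth, library), library)
            est = res.estimate
            assert 4.4 - 1e-9 <= est.chl_car_ratio <= 6.4 + 1e-9
            assert 1.0 <= est.n <= 3.5
            assert 0.1 <= est.cab <= 120.0

    def test_penalty_method_also_feasible(self, library):
        truth = LeafBiophysics(cab=40.0, ccar=5.0)  # ratio 8
        cfg = InversionConfig(ratio_method="penalty")
        res = invert_spectrum(record_from(truth, library), library, cfg)
        assert 4.4 - 1e-9 <= res.estimate.chl_car_ratio <= 6.4 + 1e-9

    def test_estimate_beats_every_start(self, library):
        res = invert_spectrum(record_from(TRUTH, library), library)
        assert res.residual_norm <= min(res.start_costs) + 1e-12

    def test_deterministic_given_seed(self, library):
        obs = record_from(TRUTH, library)
        r1 = invert_spectrum(obs, library, InversionConfig(seed=7))
        r2 = invert_spectrum(obs, library, InversionConfig(seed=7))
        assert r1.estimate.as_dict() == r2.estimate.as_dict()
        assert r1.residual_norm == r2.residual_norm
        assert r1.start_index == r2.start_index

    def test_degenerate_spectrum_rejected(self, library):
        dark = MeasuredSpectrumRecord(
            sample_id="dark", side="averaged", grid=library.grid,
            reflectance=np.zeros(len(library.grid)),
            transmittance=np.zeros(len(library.grid)),
        )
        with pytest.raises(ValueError, match="degenerate"):
            invert_spectrum(dark, library)


class TestInvertBatch:
    def test_batch_matches_elementwise_and_flags_failures(self, library):
        rng = np.random.default_rng(3)
        records = [
            record_from(
                LeafBiophysics(cab=c, ccar=c / 5.0), library, sample_id=f"s{i}"
            )
            for i, c in enumerate(rng.uniform(25.0, 55.0, size=2))
        ]
        records.append(
            MeasuredSpectrumRecord(
                sample_id="dark", side="averaged", grid=library.grid,
                reflectance=np.zeros(len(library.grid)),
                transmittance=np.zeros(len(library.grid)),
            )
        )
        results = invert_batch(records, library)
        assert [r.sample_id for r in results] == ["s0", "s1", "dark"]
        assert results[0].converged and results[1].converged
        assert not results[2].converged and results[2].estimate is None
        # consistency with single-record inversion
        single = invert_spectrum(records[0], library)
        assert single.estimate.as_dict() == results[0].estimate.as_dict()
        frame = results_to_frame(results, records)
        assert len(frame) == 3
        assert frame.loc[2, "converged"] == False  # noqa: E712

    def test_empty_batch_rejected(self, library):
        with pytest.raises(ValueError):
            invert_batch([], library)
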