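"""qPCR quantification: calibration, ratios, calibrator, aggregation, FPKM."""

import math

import numpy as np
import pytest

from transeval.expression import (
    aggregate_sample,
    calibrator_normalize,
    cdna_rescale,
    fit_calibration,
    fpkm,
    relative_ratio,
)
from transeval.simulate import QpcrTruth, simulate_qpcr


class TestFitCalibration:
    def test_perfect_doubling_series(self):
        curve = fit_calibration([1, 0.1, 0.01], [20.0, 23.3219, 26.6439])
        assert curve.slope == pytest.approx(-3.3219, abs=1e-4)
        assert curve.efficiency == pytest.approx(2.000, abs=1e-3)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-6)
        assert curve.valid

    def test_flat_series_invalid(self):
        curve = fit_calibration([1, 0.1, 0.01], [25.0, 25.0, 25.0])
        assert not curve.valid
        assert math.isnan(curve.efficiency)

    def test_too_few_dilutions_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_calibration([1, 1, 0.1], [20, 20, 23])

    def test_noisy_recovery(self):
        # E=1.9 with Gaussian Cp noise: mean recovered efficiency near truth
        rng = np.random.default_rng(0)
        slope_true = -1.0 / math.log10(1.9)
        recovered = []
        for _ in range(100):
            dils = [1, 0.1, 0.01, 0.001, 0.0001]
            cps = [
                25.0 + slope_true * math.log10(d) + rng.normal(0, 0.1) for d in dils
            ]
            recovered.append(fit_calibration(dils, cps).efficiency)
        assert np.mean(recovered) == pytest.approx(1.9, abs=0.05)

    def test_noiseless_recovery_sharpens_with_points(self):
        slope_true = -1.0 / math.log10(1.85)
        for n in (3, 5, 7):
            dils = [10.0**-k for k in range(n)]
            cps = [25.0 + slope_true * math.log10(d) for d in dils]
            curve = fit_calibration(dils, cps)
            assert curve.efficiency == pytest.approx(1.85, abs=1e-10)


class TestRelativeRatio:
    def test_symmetry_is_one(self):
        assert relative_ratio(2.0, 25.0, 2.0, 25.0) == pytest.approx(1.0)

    def test_powers_of_two(self):
        assert relative_ratio(2.0, 20.0, 2.0, 18.0) == pytest.approx(4.0)

    def test_general_closed_form(self):
        expected = math.exp(22.0 * math.log(1.95) - 24.5 * math.log(1.90))
        assert relative_ratio(1.95, 22.0, 1.90, 24.5) == pytest.approx(
            expected, rel=1e-12
        )

    def test_doubling_limit_matches_delta_cp(self):
        for cp_ref, cp_t in [(20, 18), (30, 33.5), (25, 25)]:
            assert relative_ratio(2.0, cp_ref, 2.0, cp_t) == pytest.approx(
                2.0 ** (cp_ref - cp_t)
            )

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError):
            relative_ratio(1.0, 25, 2.0, 25)


class TestCalibratorNormalize:
    def test_identical_calibrator_identity(self):
        assert calibrator_normalize(3.0, 1.5, 1.5) == pytest.approx(3.0)

    def test_doubled_calibrator_halves(self):
        assert calibrator_normalize(3.0, 2.0, 1.0) == pytest.approx(1.5)

    def test_invariant_to_joint_rescaling(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            s, a, b, k = rng.lognormal(0, 1, size=4)
            assert calibrator_normalize(s, a * k, b * k) == pytest.approx(
                calibrator_normalize(s, a, b)
            )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            calibrator_normalize(0.0, 1.0, 1.0)


def _curves(efficiencies):
    from transeval.expression import CalibrationCurve

    return {
        g: CalibrationCurve(g, -1.0 / math.log10(e), 20.0, e, 1.0, 3)
        for g, e in efficiencies.items()
    }


class TestAggregateSample:
    def test_noiseless_exact_inversion(self):
        design = QpcrTruth(
            efficiencies={"actin": 2.0, "g1": 1.9, "g2": 2.05},
            ratios={("s1", "g1"): 5.0, ("s1", "g2"): 0.25, ("s2", "g1"): 1.0},
            noise_sd=0.0,
            run_offsets=(0.0, 0.8),
        )
        table = simulate_qpcr(design, n_rt=2, n_tech=2, seed=1)
        out = aggregate_sample(table, _curves(design.efficiencies), "actin")
        got = {(r.sample_id, r.gene_id): r for r in out}
        for key, truth in design.ratios.items():
            assert got[key].ratio == pytest.approx(truth, rel=1e-9)
            assert got[key].sd == pytest.approx(0.0, abs=1e-9)
            assert got[key].n_rt_replicates == 2

    def test_target_one_cycle_below_reference_gives_two(self, tmp_path):
        import pandas as pd

        from transeval.io import CpTable

        rows = []
        for gene, role, cp in [("actin", "reference", 25.0), ("g1", "target", 24.0)]:
            for rt in (1, 2):
                for tech in (1, 2):
                    rows.append(
                        dict(
                            sample_id="s1", gene_id=gene, run_id="run1",
                            rt_replicate=rt, tech_replicate=tech, cp=cp,
                            role=role, dilution=float("nan"),
                        )
                    )
        table = CpTable(pd.DataFrame(rows))
        out = aggregate_sample(table, _curves({"actin": 2.0, "g1": 2.0}), "actin")
        assert out[0].ratio == pytest.approx(2.0)
        assert out[0].sd == 0.0

    def test_replicate_order_invariance(self):
        design = QpcrTruth(
            efficiencies={"actin": 2.0, "g1": 1.95},
            ratios={("s1", "g1"): 3.0},
            noise_sd=0.2,
        )
        table = simulate_qpcr(design, n_rt=3, n_tech=2, seed=9)
        out1 = aggregate_sample(table, _curves(design.efficiencies), "actin")
        shuffled = table.__class__(table.frame.sample(frac=1.0, random_state=4))
        out2 = aggregate_sample(shuffled, _curves(design.efficiencies), "actin")
        assert out1[0].ratio == pytest.approx(out2[0].ratio)
        assert out1[0].sd == pytest.approx(out2[0].sd)

    def test_missing_reference_gene_reported(self):
        import pandas as pd

        from transeval.io import CpTable

        rows = [
            dict(
                sample_id="s1", gene_id="g1", run_id="runX", rt_replicate=1,
                tech_replicate=1, cp=24.0, role="target", dilution=float("nan"),
            )
        ]
        table = CpTable(pd.DataFrame(rows))
        with pytest.raises(ValueError, match="runX"):
            aggregate_sample(table, _curves({"actin": 2.0, "g1": 2.0}), "actin")

    def test_noisy_recovery_within_ten_percent(self):
        # designed ratio 5.0, Cp noise sd 0.15: mean over seeds within 10%
        recovered = []
        for seed in range(200):
            design = QpcrTruth(
                efficiencies={"actin": 2.0, "g1": 1.9},
                ratios={("s1", "g1"): 5.0},
                noise_sd=0.15,
            )
            table = simulate_qpcr(design, n_rt=2, n_tech=2, seed=seed)
            out = aggregate_sample(table, _curves(design.efficiencies), "actin")
            recovered.append(out[0].ratio)
        assert np.mean(recovered) == pytest.approx(5.0, rel=0.10)


class TestCdnaRescale:
    def test_bridge_doubles(self):
        assert cdna_rescale([1.0, 2.0], [(1.0, 2.0)]) == pytest.approx([2.0, 4.0])

    def test_unit_bridge_identity(self):
        assert cdna_rescale([1.5, 0.4], [(2.0, 2.0), (5.0, 5.0)]) == pytest.approx(
            [1.5, 0.4]
        )

    def test_geometric_mean_of_bridges(self):
        # factors 2 and 8 -> geometric mean 4
        out = cdna_rescale([1.0], [(1.0, 2.0), (1.0, 8.0)])
        assert out == pytest.approx([4.0])

    def test_no_bridge_rejected(self):
        with pytest.raises(ValueError):
            cdna_rescale([1.0], [])


class TestFpkm:
    @pytest.mark.parametrize(
        "frags, length, total, expected",
        [
            (1000, 1000, 10**6, 1000.0),
            (0, 1000, 10**6, 0.0),
            (250, 2000, 5 * 10**6, 25.0),
        ],
    )
    def test_values(self, frags, length, total, expected):
        assert fpkm(frags, length, total) == pytest.approx(expected)

    def test_linearity(self):
        base = fpkm(100, 500, 10**6)
        assert fpkm(300, 500, 10**6) == pytest.approx(3 * base)
        assert fpkm(100, 1500, 10**6) == pytest.approx(base / 3)
        assert fpkm(100, 500, 2 * 10**6) == pytest.approx(base / 2)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            fpkm(1, 0, 10**6)
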