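"""Probe-consistency f-ratio: closed forms, invariances, filtering, export."""

import numpy as np
import pandas as pd
import pytest

from probescreen import ProbeLevelMatrix, SimulationConfig, compute_f_ratios, \
    consistency_filter, export_probe_trajectories, f_ratio, generate_dataset, zscore_probes
from probescreen.fratio import FRatioFilter, _f_ratio_batch


def _plm(values, probe_map):
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=[f"p{i}" for i in range(len(values))],
                      columns=[f"s{i}" for i in range(np.shape(values)[1])])
    return ProbeLevelMatrix(df, pd.Series(probe_map, index=df.index),
                            pd.Series("u", index=df.columns))


def _std_rows(rows):
    z = np.asarray(rows, dtype=float)
    return (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)


class TestZScore:
    def test_closed_form_1_2_3(self):
        data = _plm([[1, 2, 3], [3, 1, 2]], ["a", "a"])
        z, dropped = zscore_probes(data, "a")
        assert np.allclose(z.loc["p0"], [-1.0, 0.0, 1.0])
        assert dropped == []

    def test_constant_probe_dropped_and_recorded(self):
        data = _plm([[1, 2, 3], [5, 5, 5], [3, 1, 2]], ["a"] * 3)
        z, dropped = zscore_probes(data, "a")
        assert dropped == ["p1"] and list(z.index) == ["p0", "p2"]

    def test_rows_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        data = _plm(rng.normal(10, 3, (6, 8)), ["a"] * 6)
        z, _ = zscore_probes(data, "a")
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_too_few_usable_probes_error_names_set(self):
        data = _plm([[1, 2, 3], [5, 5, 5]], ["a", "a"])
        with pytest.raises(ValueError, match="'a'"):
            zscore_probes(data, "a")


class TestFRatio:
    def test_perfect_coherence_is_infinite(self):
        row = _std_rows([[1.0, 3.0, 2.0, 5.0]])[0]
        assert np.isposinf(f_ratio(np.tile(row, (5, 1))))

    def test_exact_anticorrelation_is_zero(self):
        row = _std_rows([[1.0, 3.0, 2.0, 5.0]])[0]
        assert f_ratio(np.vstack([row, -row])) == 0.0

    def test_independent_noise_rarely_exceeds_one(self):
        rng = np.random.default_rng(2)
        z = _std_rows(rng.normal(0, 1, (2000 * 16, 12))).reshape(2000, 16, 12)
        f = _f_ratio_batch(z)
        assert (f > 1.0).mean() < 0.01
        assert abs(np.mean(f) - 1 / 16) < 0.05  # null expectation ~ 1/J

    def test_affine_per_probe_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 2, (6, 9))
        data = _plm(x, ["a"] * 6)
        z, _ = zscore_probes(data, "a")
        f0 = f_ratio(z)
        x2 = x.copy()
        x2[2] = -1.5 * x2[2] + 40.0  # c != 0 allows sign flips too
        x2[4] = 0.3 * x2[4] + 7.0
        z2, _ = zscore_probes(_plm(x2, ["a"] * 6), "a")
        f2 = f_ratio(z2)
        # positive-scale affine maps leave z rows identical; the flipped row
        # changes z sign only
        x3 = x.copy()
        x3[4] = 0.3 * x3[4] + 7.0
        z3, _ = zscore_probes(_plm(x3, ["a"] * 6), "a")
        assert f_ratio(z3) == pytest.approx(f0, rel=1e-12)
        assert f2 >= 0.0

    def test_probe_and_sample_permutation_invariance(self):
        rng = np.random.default_rng(4)
        z = _std_rows(rng.normal(0, 1, (8, 10)))
        f0 = f_ratio(z)
        assert f_ratio(z[rng.permutation(8)]) == pytest.approx(f0, rel=1e-12)
        assert f_ratio(z[:, rng.permutation(10)]) == pytest.approx(f0, rel=1e-12)

    def test_monotone_in_noise_level(self):
        fs = []
        for noise in (0.4, 0.2, 0.1, 0.05):
            cfg = SimulationConfig(n_probesets=60, de_fraction=1.0, de_fold=4.0,
                                   noise_sd=noise, inconsistent_fraction=0.0, seed=5)
            data, _ = generate_dataset(cfg)
            fs.append(compute_f_ratios(data)["f_ratio"].median())
        assert all(a < b for a, b in zip(fs, fs[1:]))

    def test_classical_scaling_is_j_times_plain(self):
        rng = np.random.default_rng(6)
        z = _std_rows(rng.normal(0, 1, (7, 9)))
        assert f_ratio(z, scaling="classical") == pytest.approx(7 * f_ratio(z), rel=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            f_ratio(np.ones((4, 2)))

    def test_batch_agrees_with_scalar_path(self):
        rng = np.random.default_rng(7)
        z = _std_rows(rng.normal(0, 1, (5 * 6, 8))).reshape(5, 6, 8)
        batch = _f_ratio_batch(z)
        single = [f_ratio(z[i]) for i in range(5)]
        assert np.allclose(batch, single, rtol=1e-12)


class TestFilter:
    def test_boundary_is_strict_and_infinity_passes(self):
        f = pd.Series([1.0, 1.0001, np.inf, 0.5], index=list("abcd"))
        assert consistency_filter(f, cutoff=1.0) == ["b", "c"]

    def test_empty_input(self):
        assert consistency_filter(pd.Series(dtype=float)) == []

    def test_separates_coherent_from_inconsistent_sets(self):
        # coherent = truly differential sets (their theta varies across groups);
        # inconsistent = half of member probes follow an independent profile
        cfg = SimulationConfig(n_probesets=400, de_fraction=0.5, de_fold=3.0,
                               noise_sd=0.2, inconsistent_fraction=0.5,
                               discordant_probe_fraction=0.5, seed=8)
        data, truth = generate_dataset(cfg)
        fr = FRatioFilter(cutoff=1.0).fit(data)
        f = fr.f_ratios_["f_ratio"]
        sensitivity = (f[truth.table["is_de"]] > 1.0).mean()
        specificity = (f[truth.table["is_inconsistent"]] <= 1.0).mean()
        assert sensitivity >= 0.95 and specificity >= 0.95
        assert fr.transform(list(truth.probeset_ids)) == fr.passing_ids_


class TestTrajectoryExport:
    def test_cardinality_and_blocks(self):
        data = _plm([[1, 2, 3, 4], [2, 3, 4, 5]], ["a", "a"])
        out = export_probe_trajectories(data, "a", group_boundaries=(2,))
        assert len(out) == 8
        assert sorted(out["block"].unique()) == [0, 1]

    def test_twelve_samples_three_boundaries_four_blocks(self, small_sim):
        _, data, truth = small_sim
        out = export_probe_trajectories(data, truth.probeset_ids[0],
                                        group_boundaries=(3, 6, 9))
        assert sorted(out["block"].unique()) == [0, 1, 2, 3]

    def test_raw_mode_round_trips_exactly(self):
        data = _plm([[1.25, 2.5, 3.125], [4.0, 5.0, 6.0]], ["a", "a"])
        out = export_probe_trajectories(data, "a", values="raw")
        wide = out.pivot(index="probe_id", columns="sample_id", values="value")
        assert wide.loc[data.probes, data.samples].equals(data.intensities)

    def test_unknown_sample_rejected(self):
        data = _plm([[1, 2, 3], [2, 3, 4]], ["a", "a"])
        with pytest.raises(ValueError, match="nope"):
            export_probe_trajectories(data, "a", sample_order=["s0", "nope"])
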