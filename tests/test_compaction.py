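import numpy as np
import pandas as pd
import pytest

import knotfiber as kf
from knotfiber.errors import (ExtrapolationError, InvalidParametersError,
                              NonMonotoneTableError)
from knotfiber.ring_model import Ensemble


def _label_ensemble(labels, rg=None, writhe=None):
    """Minimal annotated ensemble for estimator tests."""
    labels = np.array(labels, dtype=object)
    n = len(labels)
    params = kf.ModelParams.from_ratio(25, 0.47)
    rg = np.ones(n) if rg is None else np.asarray(rg, dtype=float)
    ens = Ensemble(params=params, coords=np.zeros((n, 25, 3)), rg=rg,
                   seed=0, burn_in_sweeps=0, decorrelation_sweeps=1,
                   acceptance_rate=0.5, tau_int_sweeps=1.0)
    ens.knot_labels = labels
    if writhe is not None:
        ens.writhe = np.asarray(writhe, dtype=float)
    return ens


class TestKnotProbability:
    def test_all_unknots(self):
        kp = kf.knot_probability(_label_ensemble(["0_1"] * 100))
        assert kp.p == 0.0
        assert kp.ci_low == 0.0

    def test_direct_fraction_with_wilson_interval(self):
        kp = kf.knot_probability(_label_ensemble(["0_1"] * 98 + ["3_1"] * 2))
        assert kp.p == pytest.approx(0.02)
        assert kp.ci_low <= kp.p <= kp.ci_high
        assert 0.0 < kp.ci_low < kp.ci_high < 1.0

    def test_unresolved_counts_as_knotted(self):
        kp = kf.knot_probability(
            _label_ensemble(["0_1"] * 8 + ["unresolved", "3_1"]))
        assert kp.p == pytest.approx(0.2)

    def test_unannotated_ensemble_rejected(self, ens_small):
        ens = Ensemble(params=ens_small.params, coords=ens_small.coords,
                       rg=ens_small.rg, seed=0, burn_in_sweeps=0,
                       decorrelation_sweeps=1, acceptance_rate=0.5,
                       tau_int_sweeps=1.0)
        with pytest.raises(InvalidParametersError):
            kf.knot_probability(ens)

    def test_oracle_recount_from_serialized_file(self, ens_047_20k, tmp_path):
        path = tmp_path / "ens.xyz"
        kf.write_ensemble_xyz(path, ens_047_20k)
        n_knot = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("frame") and "knot" in line:
                    if line.rsplit("knot", 1)[1].strip() != "0_1":
                        n_knot += 1
        assert n_knot == kf.knot_probability(ens_047_20k).n_knotted


class TestPknVsRatio:
    def test_empty_ratio_list(self):
        table = kf.pkn_vs_ratio([], 100, seed=1)
        assert len(table) == 0

    def test_single_ratio_consistent_with_direct_estimate(self):
        table = kf.pkn_vs_ratio([0.47], 2000, seed=5)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["n_total"] == 2000
        assert row["p"] == row["n_knotted"] / row["n_total"]
        assert 0.0 < row["p"] < 0.1


class TestCalibrateDl:
    @pytest.fixture()
    def synthetic_table(self):
        # log-linear P_kn(D/L), the shape calibrate_dl assumes
        dl = np.array([0.3, 0.4, 0.5, 0.65])
        p = 0.1 * np.exp(-5.0 * (dl - 0.3))
        return pd.DataFrame({"dl_ratio": dl, "p": p,
                             "n_total": [10 ** 6] * 4,
                             "n_knotted": (p * 10 ** 6).astype(int)})

    def test_grid_point_returned_exactly(self, synthetic_table):
        target = synthetic_table["p"].iloc[2]
        assert kf.calibrate_dl(target, synthetic_table) == 0.5

    def test_loglinear_interpolation_recovers_ratio(self, synthetic_table):
        # P(dl) = 0.1 exp(-5 (dl - 0.3)) -> P = 0.02 at dl = 0.3 + ln(5)/5
        target_dl = 0.3 + np.log(5.0) / 5.0
        assert kf.calibrate_dl(0.02, synthetic_table) == pytest.approx(
            target_dl, abs=1e-9)

    def test_non_monotone_table_rejected(self, synthetic_table):
        bad = synthetic_table.copy()
        bad.loc[2, "p"] = 0.2
        bad.loc[2, "n_knotted"] = 200_000
        with pytest.raises(NonMonotoneTableError):
            kf.calibrate_dl(0.02, bad)

    def test_target_outside_range_rejected(self, synthetic_table):
        with pytest.raises(ExtrapolationError):
            kf.calibrate_dl(0.5, synthetic_table)


class TestCompactionProfile:
    def test_infinite_cutoff_recovers_unconstrained(self, ens_047_20k):
        prof = kf.compaction_profile(ens_047_20k, [np.inf])
        row = prof.iloc[0]
        assert row["n_kept"] == ens_047_20k.n
        assert row["pkn"] == kf.knot_probability(ens_047_20k).p
        for cls in ("3_1", "4_1", "5_1_5_2"):
            assert row[f"enh_{cls}"] == pytest.approx(1.0)

    def test_kept_counts_non_increasing(self, ens_047_20k):
        prof = kf.compaction_profile(ens_047_20k,
                                     [1.0, 0.9, 0.8, 0.7], min_kept=10)
        assert (np.diff(prof["n_kept"]) <= 0).all()

    def test_small_kept_rows_flagged(self, ens_047_20k):
        prof = kf.compaction_profile(ens_047_20k, [0.55], min_kept=200)
        assert bool(prof.iloc[0]["flagged"])

    def test_conditional_pkn_rises_under_compaction(self, ens_047_20k):
        prof = kf.compaction_profile(ens_047_20k,
                                     [np.inf, 0.9, 0.8], min_kept=10)
        p = prof["pkn"].to_numpy()
        assert p[0] < p[1] < p[2]


class TestKnotSpectrum:
    def test_all_unknot_spectrum_is_zero(self):
        spec = kf.knot_spectrum(_label_ensemble(["0_1"] * 50))
        assert (spec["probability"] == 0).all()

    def test_spectrum_partitions_pkn(self):
        labels = (["0_1"] * 80 + ["3_1"] * 10 + ["4_1"] * 4 + ["5_2"] * 2 +
                  ["3_1#3_1"] * 2 + ["unresolved"] * 2)
        ens = _label_ensemble(labels)
        spec = kf.knot_spectrum(ens)
        kp = kf.knot_probability(ens)
        assert spec["probability"].sum() + spec.attrs["unresolved_fraction"] \
            == pytest.approx(kp.p)
        # composites binned by total crossing number
        assert spec.loc[spec["kn"] == 6, "count"].item() == 2

    def test_trefoil_dominates_spectrum(self, ens_047_20k):
        spec = kf.knot_spectrum(ens_047_20k)
        p = spec["probability"].to_numpy()
        assert p[0] == max(p) and p[0] > 0


class TestWritheRgTable:
    def test_bins_partition_the_ensemble(self, ens_047_20k):
        table = kf.writhe_rg_table(ens_047_20k, bin_width=1.0)
        assert table["n"].sum() == ens_047_20k.n
        assert (table["wr_hi"] - table["wr_lo"]).round(12).eq(1.0).all()

    def test_mean_rel_rg_decreases_with_writhe(self, ens_047_20k):
        table = kf.writhe_rg_table(ens_047_20k, bin_width=1.0)
        well = table[table["n"] >= 50]
        means = well["mean_rg_rel"].to_numpy()
        # non-increasing within 2 SE of each bin mean
        rel = ens_047_20k.rg / ens_047_20k.rms_rg
        aw = np.abs(ens_047_20k.writhe)
        for a, b in zip(range(len(well) - 1), range(1, len(well))):
            lo_a, lo_b = well.iloc[a]["wr_lo"], well.iloc[b]["wr_lo"]
            sa = rel[(aw >= lo_a) & (aw < lo_a + 1)].std()
            sb = rel[(aw >= lo_b) & (aw < lo_b + 1)].std()
            se = np.hypot(sa / np.sqrt(well.iloc[a]["n"]),
                          sb / np.sqrt(well.iloc[b]["n"]))
            assert means[b] <= means[a] + 2 * se

    def test_writhe_annotation_required(self):
        with pytest.raises(InvalidParametersError):
            kf.writhe_rg_table(_label_ensemble(["0_1"] * 10))
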