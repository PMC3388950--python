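import numpy as np
import pandas as pd
import pytest

from modaccess.access import (
    accessibility_table,
    count_accessible,
    population_adjust,
    quintile_summary,
)
from modaccess.config import AnalysisConfig
from modaccess.facilities import Facility
from modaccess.journeys import TravelTimeMatrix


def facs(intensities):
    return [
        Facility(f"f{i}", "x", 0.0, 0.0, 5.0, lab) for i, lab in enumerate(intensities)
    ]


def matrix(minutes, fids, zones=("z0",)):
    return TravelTimeMatrix(
        mode="walk", origins=list(zones), destinations=list(fids),
        minutes=np.asarray(minutes, float),
    )


class TestCountAccessible:
    def test_threshold_and_unreachable(self):
        """Times {5, 19, 21, inf} against threshold 20 count exactly 2."""
        fl = facs(["moderate"] * 4)
        m = matrix([[5.0, 19.0, 21.0, np.inf]], [f.facility_id for f in fl])
        out = count_accessible(m, fl, "moderate", 20.0)
        assert out["z0"] == 2

    def test_exact_threshold_is_inclusive(self):
        fl = facs(["moderate"])
        m = matrix([[20.0]], ["f0"])
        assert count_accessible(m, fl, "moderate", 20.0)["z0"] == 1

    def test_intensity_filter(self):
        fl = facs(["moderate", "vigorous", "light"])
        m = matrix([[1.0, 1.0, 1.0]], [f.facility_id for f in fl])
        assert count_accessible(m, fl, "vigorous", 20.0)["z0"] == 1
        assert count_accessible(m, fl, "light", 20.0)["z0"] == 1

    def test_unknown_intensity_rejected(self):
        fl = facs(["moderate"])
        m = matrix([[1.0]], ["f0"])
        with pytest.raises(ValueError):
            count_accessible(m, fl, "extreme", 20.0)

    def test_matches_brute_force_row_scan(self):
        rng = np.random.default_rng(0)
        labs = ["moderate", "vigorous", "light"]
        fl = facs([labs[i % 3] for i in range(12)])
        mins = rng.uniform(0, 40, size=(5, 12))
        mins[rng.random((5, 12)) < 0.2] = np.inf
        m = matrix(mins, [f.facility_id for f in fl], [f"z{i}" for i in range(5)])
        for lab in labs:
            for thr in (10.0, 20.0, 30.0):
                out = count_accessible(m, fl, lab, thr)
                for i, z in enumerate(m.origins):
                    brute = sum(
                        1
                        for j, f in enumerate(fl)
                        if f.intensity == lab and np.isfinite(mins[i, j])
                        and mins[i, j] <= thr
                    )
                    assert out[z] == brute


class TestPopulationAdjust:
    def test_arithmetic(self):
        """2 facilities in a zone of 500 residents is 4 per 1,000."""
        assert population_adjust(2, 500) == pytest.approx(4.0)

    def test_zero_count(self):
        assert population_adjust(0, 750) == 0.0

    def test_linearity_in_count(self):
        rng = np.random.default_rng(1)
        c = rng.integers(0, 50, 10)
        p = rng.integers(500, 1001, 10)
        assert np.allclose(population_adjust(3 * c, p), 3 * population_adjust(c, p))

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            population_adjust(1, 0)


class TestQuintileSummary:
    def zones(self):
        return pd.DataFrame(
            {
                "zone_id": [f"z{i}" for i in range(6)],
                "population": [600] * 6,
                "quintile": [1, 1, 1, 2, 3, 3],
            }
        )

    def table(self):
        rows = []
        for z, c in zip([f"z{i}" for i in range(6)], [1, 2, 9, 4, 5, 7]):
            rows.append(
                {"zone_id": z, "mode": "walk", "intensity": "moderate",
                 "threshold": 20.0, "count": c, "adjusted_count": c * 1000 / 600}
            )
        return pd.DataFrame(rows)

    def test_median_min_max(self):
        """Counts {1, 2, 9} in a quintile: median 2, min 1, max 9."""
        out = quintile_summary(self.table(), self.zones())
        q1 = out[out["quintile"] == 1].iloc[0]
        assert (q1["median"], q1["min"], q1["max"]) == (2.0, 1.0, 9.0)

    def test_single_zone_quintile_median_equals_extremes(self):
        out = quintile_summary(self.table(), self.zones())
        q2 = out[out["quintile"] == 2].iloc[0]
        assert q2["median"] == q2["min"] == q2["max"] == 4.0

    def test_empty_quintile_emitted_with_missing_markers(self):
        out = quintile_summary(self.table(), self.zones())
        q5 = out[out["quintile"] == 5].iloc[0]
        assert q5["n_zones"] == 0
        assert np.isnan(q5["median"])

    def test_all_five_quintile_rows_always_present(self):
        out = quintile_summary(self.table(), self.zones())
        assert list(out["quintile"]) == [1, 2, 3, 4, 5]

    def test_median_matches_order_statistics_oracle(self):
        rng = np.random.default_rng(2)
        zones = pd.DataFrame(
            {
                "zone_id": [f"z{i}" for i in range(20)],
                "population": rng.integers(500, 1001, 20),
                "quintile": rng.integers(1, 6, 20),
            }
        )
        counts = rng.integers(0, 30, 20)
        table = pd.DataFrame(
            {
                "zone_id": zones["zone_id"], "mode": "bus", "intensity": "vigorous",
                "threshold": 30.0, "count": counts,
                "adjusted_count": counts * 1000 / zones["population"],
            }
        )
        out = quintile_summary(table, zones)
        for q in range(1, 6):
            vals = sorted(counts[(zones["quintile"] == q).to_numpy()])
            row = out[out["quintile"] == q].iloc[0]
            if not vals:
                assert row["n_zones"] == 0
                continue
            k = len(vals)
            med = vals[k // 2] if k % 2 else (vals[k // 2 - 1] + vals[k // 2]) / 2
            assert row["median"] == med
            assert row["min"] == vals[0] and row["max"] == vals[-1]


def test_accessibility_table_threshold_monotone_and_consistent():
    """count(20) <= count(30) per zone; adjusted = count * 1000 / pop."""
    rng = np.random.default_rng(3)
    labs = ["moderate", "vigorous"]
    fl = facs([labs[i % 2] for i in range(10)])
    mins = rng.uniform(0, 45, size=(6, 10))
    m = matrix(mins, [f.facility_id for f in fl], [f"z{i}" for i in range(6)])
    zones = pd.DataFrame(
        {"zone_id": [f"z{i}" for i in range(6)],
         "population": rng.integers(500, 1001, 6)}
    )
    table = accessibility_table({"walk": m}, fl, zones, AnalysisConfig())
    wide = table.pivot_table(
        index=["zone_id", "intensity"], columns="threshold", values="count"
    )
    assert (wide[20.0] <= wide[30.0]).all()
    pops = zones.set_index("zone_id")["population"]
    assert np.allclose(
        table["adjusted_count"],
        table["count"] * 1000.0 / table["zone_id"].map(pops),
    )
    # light excluded by default
    assert set(table["intensity"]) == {"moderate", "vigorous"}
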