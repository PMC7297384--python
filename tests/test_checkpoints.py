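"""The TC+DR decision cascade and its audit trail."""

import numpy as np
import pytest

from coopdiscern import (
    IBParams,
    NCParams,
    Thresholds,
    discriminate,
    lhs_scan,
    nc_to_ib,
    simulate_ode,
)
from coopdiscern.checkpoints import (
    analyze,
    checkpoint1,
    checkpoint2,
    checkpoint3,
    decide_from_analysis,
)

THR = Thresholds(dynr0_nc=0.2, dynr0_ib=0.2, tip=0.5)


class TestStageRules:
    @pytest.mark.parametrize(
        "shape, expected",
        [
            ("decreasing", "IB"),
            ("biphasic", "IB"),
            ("increasing", "continue"),
            (None, "undecided"),
        ],
    )
    def test_checkpoint1(self, shape, expected):
        assert checkpoint1(shape) == expected

    def test_checkpoint2_band_order(self):
        # outside the NC band -> IB, regardless of the IB band
        assert checkpoint2(0.5, 0.0, True, THR) == "IB"
        # inside NC band, outside IB band -> NC
        assert checkpoint2(0.1, 0.5, True, THR) == "NC"
        # inside both -> continue
        assert checkpoint2(0.1, 0.1, True, THR) == "continue"
        # unreliable early estimate -> skip
        assert checkpoint2(0.5, 0.5, False, THR) == "skip"
        assert checkpoint2(float("nan"), 0.1, True, THR) == "skip"

    def test_checkpoint3_terminal(self):
        assert checkpoint3(2.0, THR) == "IB"
        assert checkpoint3(0.1, THR) == "NC"
        assert checkpoint3(float("nan"), THR) == "undecided"


class TestDiscriminate:
    def test_noiseless_nc_verdicts(self, small_db, wide_det_grid):
        wrong = 0
        for pair in lhs_scan(12, seed=31):
            data = simulate_ode(pair.nc, wide_det_grid)
            decision = discriminate(data, small_db)
            if decision.verdict != "NC":
                wrong += 1
        assert wrong <= 1  # near-perfect in the deterministic limit

    def test_noiseless_ib_with_distinct_rates(self, small_db, wide_det_grid):
        K10, K01 = nc_to_ib(1.0, 0.05)
        ib = IBParams(k10=30.0 / K10, k01=0.03 / K01, l10=30.0, l01=0.03)
        decision = discriminate(simulate_ode(ib, wide_det_grid), small_db)
        assert decision.verdict == "IB"
        # strongly distinct kinetics resolve at the TC stage already
        assert decision.path[-1]["stage"] == "tc"

    def test_equal_sites_corner_reports_omega_near_one(
        self, small_db, wide_det_grid
    ):
        data = simulate_ode(IBParams(1, 1, 1, 1), wide_det_grid)
        decision = discriminate(data, small_db)
        assert decision.analysis.tc.omega_hat == pytest.approx(1.0, abs=0.05)
        assert decision.verdict in ("NC", "IB", "undecided")

    def test_determinism_and_audit_trail(self, small_db, wide_det_grid):
        data = simulate_ode(NCParams(2.0, 0.5, 0.2), wide_det_grid)
        d1 = discriminate(data, small_db)
        d2 = discriminate(data, small_db)
        assert d1.verdict == d2.verdict
        assert d1.path == d2.path
        stages = [p["stage"] for p in d1.path]
        assert stages[0] == "tc"
        assert stages == sorted(stages, key=["tc", "cp1", "cp2", "cp3"].index)
        assert all("verdict" in p for p in d1.path)

    def test_cascade_order_and_short_circuit(self, small_db):
        # a decreasing target curve must stop at checkpoint 1 with IB
        a = analyze_stub(shape="decreasing")
        decision = decide_from_analysis(a, small_db, THR)
        assert decision.verdict == "IB"
        assert [p["stage"] for p in decision.path] == ["tc", "cp1"]

    def test_undefined_tip_gives_explained_undecided(self, small_db):
        a = analyze_stub(shape="increasing", d_tip=float("nan"))
        decision = decide_from_analysis(a, small_db, THR)
        assert decision.verdict == "undecided"
        assert decision.path[-1]["stage"] == "cp3"


def analyze_stub(shape, d_nc=0.05, d_ib=0.05, d_tip=0.1, C=0.5):
    """Hand-built Analysis for exercising the cascade routing."""
    from coopdiscern.checkpoints import Analysis
    from coopdiscern.metrics import TargetCurve
    from coopdiscern.tc import TCFitResult

    tc = TCFitResult(
        K_hat=1.0, omega_hat=0.5, K10_hat=3.41, K01_hat=0.59,
        l_hat=1.0, l10_hat=1.0, l01_hat=1.0,
        sse_nc=1.0, sse_ib=1.0, n_obs=100, C=C,
    )
    t = np.logspace(-3, 3, 20)
    curve = TargetCurve(
        times=t, dynr=np.full(20, 2.0), valid=np.ones(20, bool),
        dynr_initial=2.0, dynr_initial_reliable=True,
        dynr_final=2.5, t_ip=1.0, shape=shape,
    )
    return Analysis(
        tc=tc, curve=curve, d_dynr0_nc=d_nc, d_dynr0_ib=d_ib, d_log_tip=d_tip
    )
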