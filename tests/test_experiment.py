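"""Grid enumeration, batch accounting and the knotting statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from knotloop.experiment import (
    SitePlacement,
    enumerate_grid,
    fcsl,
    ftrsl,
    knot_spectrum,
    persistence_length,
    rkp,
    run_batch,
    summarize,
)
from knotloop.io import RunRecord
from knotloop.params import ModelParams, RunProtocol


class TestGrid:
    def test_paper_grid_has_twenty_placements(self):
        grid = enumerate_grid(500, 50)
        assert len(grid) == 20
        pairs = {(p.l_x, p.l_y) for p in grid}
        assert (50, 300) in pairs

    def test_coarse_grid_brute_force(self):
        grid = {(p.l_x, p.l_y) for p in enumerate_grid(500, 100)}
        assert grid == {(100, 100), (100, 200), (100, 300), (200, 200)}

    def test_canonical_and_idempotent(self):
        grid = enumerate_grid(500, 50)
        for p in grid:
            assert p.l_x <= p.l_y
            assert p.loop_length >= 50
            # re-canonicalization is a no-op
            assert SitePlacement(p.l_x, p.l_y, 500) == p
        assert len({(p.l_x, p.l_y) for p in grid}) == len(grid)

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            enumerate_grid(500, 0)
        with pytest.raises(ValueError):
            enumerate_grid(500, 250)

    def test_site_indices(self):
        p = SitePlacement(50, 300, 500)
        assert p.x_index == 50
        assert p.y_index == 199
        assert p.loop_length == 150  # beads X..Y inclusive


def _rec(i, knot="0_1", closed=None, relevant=None, censored=False):
    return RunRecord(
        run_id=f"r{i}",
        config_hash="h",
        seed=i,
        placement="lx20-ly60",
        circularized=not censored,
        censored=censored,
        steps=10,
        knot_label=None if censored else knot,
        det_minus1=None if censored else 1,
        det_minus2=None if censored else 1,
        loop_closed=closed if not censored else None,
        relevant=relevant,
    )


class TestStatistics:
    def test_rkp_arithmetic(self):
        assert rkp(4, 1000, 2, 1000).value == pytest.approx(2.0)
        assert rkp(2, 1000, 2, 1000).value == pytest.approx(1.0)

    def test_rkp_zero_reference_errors(self):
        with pytest.raises(ValueError):
            rkp(3, 100, 0, 100)

    def test_rkp_interval_brackets_estimate(self):
        r = rkp(8, 400, 4, 800)
        assert r.ci_low < r.value < r.ci_high

    def test_rkp_zero_numerator_has_upper_bound(self):
        r = rkp(0, 400, 4, 800)
        assert r.value == 0.0
        assert r.ci_high > 0.0

    def test_fcsl_ftrsl_counting(self):
        recs = (
            [_rec(i, "3_1", closed=True, relevant=True) for i in range(6)]
            + [_rec(i + 6, "3_1", closed=True, relevant=False) for i in range(2)]
            + [_rec(i + 8, "3_1", closed=False) for i in range(2)]
            + [_rec(i + 10, "0_1", closed=False) for i in range(30)]
        )
        assert fcsl(recs) == pytest.approx(0.8)
        assert ftrsl(recs) == pytest.approx(0.6)

    def test_all_loops_open(self):
        recs = [_rec(i, "3_1", closed=False) for i in range(5)]
        assert fcsl(recs) == 0.0
        assert ftrsl(recs) == 0.0

    def test_no_knots_errors(self):
        recs = [_rec(i, "0_1") for i in range(5)]
        with pytest.raises(ValueError):
            fcsl(recs)
        with pytest.raises(ValueError):
            knot_spectrum(recs)

    @given(
        st.lists(
            st.tuples(st.sampled_from(["0_1", "3_1", "4_1"]), st.booleans(), st.booleans()),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_ftrsl_never_exceeds_fcsl(self, rows):
        recs = []
        for i, (knot, closed, rel) in enumerate(rows):
            relevant = (rel if (knot != "0_1" and closed) else None)
            recs.append(_rec(i, knot, closed=closed, relevant=relevant))
        if not any(r.knot_label != "0_1" for r in recs):
            return
        assert ftrsl(recs) <= fcsl(recs) + 1e-12

    def test_spectrum_fractions(self):
        recs = [_rec(i, "3_1", closed=False) for i in range(3)] + [
            _rec(3, "4_1", closed=False)
        ]
        spec = knot_spectrum(recs)
        assert spec == {"3_1": 0.75, "4_1": 0.25}
        assert sum(spec.values()) == pytest.approx(1.0)

    def test_summary_accounting(self):
        recs = (
            [_rec(i, "3_1", closed=True, relevant=True) for i in range(2)]
            + [_rec(i + 2, "0_1", closed=False) for i in range(6)]
            + [_rec(i + 8, censored=True) for i in range(2)]
        )
        s = summarize(recs)
        # knotted + unknotted + censored = total
        assert s.n_knotted + (8 - s.n_knotted) + s.n_censored == 10
        assert s.p_k == pytest.approx(2 / 8)
        assert s.p_k_ci[0] < s.p_k < s.p_k_ci[1]


class TestRunBatchAccounting:
    def test_determinism_and_row_count(self, tmp_path):
        params = ModelParams.chain(20)
        protocol = RunProtocol(gamma=0.1, max_steps=2_000_000)
        a = run_batch(None, params, protocol, 3, 777, ledger_path=tmp_path / "a.csv")
        b = run_batch(None, params, protocol, 3, 777, ledger_path=tmp_path / "b.csv")
        assert len(a) == len(b) == 3
        for ra, rb in zip(a, b):
            assert (ra.run_id, ra.steps, ra.knot_label) == (
                rb.run_id,
                rb.steps,
                rb.knot_label,
            )

    def test_resume_skips_completed_runs(self, tmp_path):
        params = ModelParams.chain(20)
        protocol = RunProtocol(gamma=0.1, max_steps=2_000_000)
        path = tmp_path / "ledger.csv"
        first = run_batch(None, params, protocol, 2, 500, ledger_path=path)
        again = run_batch(None, params, protocol, 4, 500, ledger_path=path)
        assert len(again) == 4
        # the first two rows are byte-identical reuses, not recomputations
        assert [r.run_id for r in again[:2]] == [r.run_id for r in first]

    def test_reference_batch_has_no_loop_flags(self, tmp_path):
        params = ModelParams.chain(20)
        protocol = RunProtocol(gamma=0.1, max_steps=2_000_000)
        recs = run_batch(None, params, protocol, 2, 321)
        for r in recs:
            assert r.loop_closed is None
            assert r.relevant is None


class TestPersistenceLengthFit:
    def test_exponential_profile_recovered(self):
        lp, b = 10.0, 0.97
        s = np.arange(0, 30)
        corr = np.exp(-s * b / lp)
        assert persistence_length(corr, b) == pytest.approx(lp, rel=1e-6)

    def test_rigid_rod_rejected(self):
        corr = np.ones(30)
        with pytest.raises(ValueError):
            persistence_length(corr, 0.97)
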