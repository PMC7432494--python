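import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ubshift.projection import (
    ReferencePair,
    collinearity_report,
    composite_coords,
    project_fraction,
    unit_open_fractions,
    PeakProjector,
)
from ubshift.peaklist import Peak, PeakList


def grid_search_fraction(open_ref, closed_ref, observed, alpha_N=0.14, step=1e-6):
    """Independent oracle: dividing ratio by brute-force minimization of the
    distance from the observed point to the parameterized reference line."""
    o = np.array(composite_coords(open_ref, alpha_N))
    c = np.array(composite_coords(closed_ref, alpha_N))
    x = np.array(composite_coords(observed, alpha_N))
    ts = np.arange(-0.5, 1.5 + step / 2, step)
    pts = o[None, :] + ts[:, None] * (c - o)[None, :]
    d2 = ((pts - x) ** 2).sum(axis=1)
    i = int(np.argmin(d2))
    return float(ts[i]), float(np.sqrt(d2[i]))


class TestCompositeCoords:
    def test_scales_nitrogen_axis(self):
        assert composite_coords((9.05, 127.1), 0.14) == pytest.approx((9.05, 17.794))

    def test_unit_weight_is_identity(self):
        assert composite_coords((9.05, 127.1), 1.0) == (9.05, 127.1)

    def test_origin_fixed(self):
        assert composite_coords((0.0, 0.0), 0.37) == (0.0, 0.0)

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(ValueError):
            composite_coords((9.0, 120.0), 0.0)


OPEN = (8.50, 120.00)
CLOSED = (8.00, 118.00)


class TestProjectFraction:
    def test_exact_collinear_division(self):
        observed = (8.50 + 0.24 * (8.00 - 8.50), 120.00 + 0.24 * (118.00 - 120.00))
        r = project_fraction(OPEN, CLOSED, observed)
        assert r.f_closed == pytest.approx(0.24, abs=1e-12)
        assert r.f_open == pytest.approx(0.76, abs=1e-12)
        assert r.perp_deviation == pytest.approx(0.0, abs=1e-12)
        assert r.flag == "ok"

    def test_observed_at_open_reference(self):
        r = project_fraction(OPEN, CLOSED, OPEN)
        assert r.f_open == pytest.approx(1.0)
        assert r.f_closed == pytest.approx(0.0, abs=1e-15)

    def test_matches_grid_search_oracle_frozen(self):
        # Oracle values computed by grid_search_fraction, step 1e-6.
        r = project_fraction(OPEN, CLOSED, (8.38, 119.60), alpha_N=0.14)
        assert r.f_closed == pytest.approx(0.2304507, abs=1e-5)
        assert r.perp_deviation == pytest.approx(0.0097721, abs=1e-5)

    def test_coincident_references_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            project_fraction(OPEN, OPEN, (8.4, 119.0))

    def test_tiny_separation_flagged_uninformative(self):
        close = (OPEN[0] + 1e-4, OPEN[1] + 1e-4)
        r = project_fraction(OPEN, close, OPEN)
        assert r.flag == "uninformative"

    def test_out_of_range_flag(self):
        beyond = (8.50 + 1.5 * (8.00 - 8.50), 120.00 + 1.5 * (118.00 - 120.00))
        r = project_fraction(OPEN, CLOSED, beyond)
        assert r.flag == "out_of_range"
        assert r.f_closed == pytest.approx(1.5, abs=1e-12)  # raw, not clamped


@settings(max_examples=100, deadline=None)
@given(
    t=st.floats(0.0, 1.0),
    oh=st.floats(7.0, 9.5), on=st.floats(105.0, 130.0),
    dh=st.floats(0.1, 0.5), dn=st.floats(0.5, 2.0),
    sh=st.sampled_from([-1.0, 1.0]), sn=st.sampled_from([-1.0, 1.0]),
)
def test_exact_collinear_recovery(t, oh, on, dh, dn, sh, sn):
    """Any internally dividing point returns its construction parameter."""
    open_ref = (oh, on)
    closed_ref = (oh + sh * dh, on + sn * dn)
    observed = (oh + t * sh * dh, on + t * sn * dn)
    r = project_fraction(open_ref, closed_ref, observed)
    assert abs(r.f_closed - t) < 1e-12
    assert r.f_open + r.f_closed == pytest.approx(1.0, abs=0)


@settings(max_examples=100, deadline=None)
@given(
    t=st.floats(0.0, 1.0),
    scale_h=st.floats(0.5, 2.0), scale_n=st.floats(0.5, 2.0),
    shift_h=st.floats(-1.0, 1.0), shift_n=st.floats(-5.0, 5.0),
)
def test_affine_invariance_on_collinear_triples(t, scale_h, scale_n, shift_h, shift_n):
    """Anisotropic rescaling plus translation leaves the dividing ratio fixed."""
    open_ref, closed_ref = OPEN, CLOSED
    observed = (
        open_ref[0] + t * (closed_ref[0] - open_ref[0]),
        open_ref[1] + t * (closed_ref[1] - open_ref[1]),
    )

    def warp(p):
        return (scale_h * p[0] + shift_h, scale_n * p[1] + shift_n)

    r0 = project_fraction(open_ref, closed_ref, observed)
    r1 = project_fraction(warp(open_ref), warp(closed_ref), warp(observed))
    assert abs(r0.f_closed - r1.f_closed) < 1e-10


@settings(max_examples=20, deadline=None)
@given(
    oh=st.floats(7.5, 9.0), on=st.floats(108.0, 128.0),
    dh=st.floats(-0.5, 0.5), dn=st.floats(-2.0, 2.0),
    xh=st.floats(-0.3, 0.3), xn=st.floats(-1.5, 1.5),
)
def test_projection_agrees_with_grid_search(oh, on, dh, dn, xh, xn):
    """Closed-form orthogonal projection vs brute-force line search."""
    open_ref = (oh, on)
    closed_ref = (oh + dh + (0.12 if abs(dh) < 0.1 else 0.0),
                  on + dn + (0.6 if abs(dn) < 0.5 else 0.0))
    observed = ((open_ref[0] + closed_ref[0]) / 2 + xh,
                (open_ref[1] + closed_ref[1]) / 2 + xn)
    t_oracle, perp_oracle = grid_search_fraction(open_ref, closed_ref, observed)
    r = project_fraction(open_ref, closed_ref, observed,
                         rel_deviation_threshold=np.inf)
    if -0.45 < t_oracle < 1.45:  # oracle grid interior only
        assert r.f_closed == pytest.approx(t_oracle, abs=1e-5)
        assert r.perp_deviation == pytest.approx(perp_oracle, abs=1e-5)


@settings(max_examples=50, deadline=None)
@given(t1=st.floats(0.0, 1.0), t2=st.floats(0.0, 1.0))
def test_monotonic_along_reference_line(t1, t2):
    """Moving toward the closed reference never decreases f_closed."""
    def obs(t):
        return (OPEN[0] + t * (CLOSED[0] - OPEN[0]), OPEN[1] + t * (CLOSED[1] - OPEN[1]))

    lo, hi = sorted([t1, t2])
    r_lo = project_fraction(OPEN, CLOSED, obs(lo))
    r_hi = project_fraction(OPEN, CLOSED, obs(hi))
    assert r_hi.f_closed >= r_lo.f_closed - 1e-12


def _results_for_ratios(ratios_by_unit, residue=70):
    """Exact collinear peaks dividing the segment at the given ratios."""
    out = []
    for unit, t in ratios_by_unit.items():
        observed = (
            OPEN[0] + t * (CLOSED[0] - OPEN[0]),
            OPEN[1] + t * (CLOSED[1] - OPEN[1]),
        )
        out.append(
            project_fraction(OPEN, CLOSED, observed,
                             residue_number=residue, unit_label=unit)
        )
    return out


class TestUnitAggregation:
    def test_single_probe_recovers_published_triub_fractions(self):
        # Val70 peaks dividing the segment at 0.24 / 0.67 / 0.53 give the
        # published per-unit open fractions 0.76 / 0.33 / 0.47.
        results = _results_for_ratios({"Ub1": 0.24, "Ub2": 0.67, "Ub3": 0.53})
        uf = unit_open_fractions(results, policy="single_probe", probe_residue=70)
        assert uf.table["Ub1"][0] == pytest.approx(0.76, abs=1e-12)
        assert uf.table["Ub2"][0] == pytest.approx(0.33, abs=1e-12)
        assert uf.table["Ub3"][0] == pytest.approx(0.47, abs=1e-12)

    def test_single_residue_has_zero_uncertainty(self):
        results = _results_for_ratios({"Ub1": 0.5})
        uf = unit_open_fractions(results)
        f, se, n = uf.table["Ub1"]
        assert f == pytest.approx(0.5, abs=1e-12)
        assert se == 0.0 and n == 1

    def test_weighted_mean_of_constants(self):
        pairs = [
            ((8.5, 120.0), (8.0, 118.0)),
            ((7.8, 112.0), (8.2, 113.5)),  # different separation
        ]
        results = []
        for k, (o, c) in enumerate(pairs):
            obs = (o[0] + 0.4 * (c[0] - o[0]), o[1] + 0.4 * (c[1] - o[1]))
            results.append(
                project_fraction(o, c, obs, residue_number=8 + k, unit_label="Ub1")
            )
        uf = unit_open_fractions(results, policy="weighted_mean")
        assert uf.table["Ub1"][0] == pytest.approx(0.6, abs=1e-12)
        assert uf.table["Ub1"][2] == 2

    def test_off_line_results_never_aggregated(self):
        good = _results_for_ratios({"Ub1": 0.3})
        mid = (
            (OPEN[0] + CLOSED[0]) / 2,
            (OPEN[1] + CLOSED[1]) / 2 + 5.0,  # far off the line
        )
        bad = project_fraction(OPEN, CLOSED, mid, residue_number=70, unit_label="Ub2")
        assert bad.flag == "off_line"
        with pytest.raises(ValueError, match="Ub2|usable|probe"):
            unit_open_fractions(good + [bad])

    def test_missing_probe_is_an_error(self):
        results = _results_for_ratios({"Ub1": 0.3}, residue=44)
        with pytest.raises(ValueError, match="probe"):
            unit_open_fractions(results, probe_residue=70)


class TestCollinearityReport:
    def test_collinear_input_nothing_excluded(self):
        results = _results_for_ratios({"Ub1": 0.2, "Ub2": 0.8})
        rep = collinearity_report(results, threshold=0.1)
        assert (rep["rel_deviation"] < 1e-10).all()
        assert not rep["excluded"].any()

    def test_half_separation_offset_excluded(self):
        sep = ReferencePair(70, OPEN, CLOSED).separation()
        from ubshift.simulate import simulate_offline_peak

        obs = simulate_offline_peak(ReferencePair(70, OPEN, CLOSED), 0.5 * sep)
        r = project_fraction(OPEN, CLOSED, obs, residue_number=70, unit_label="Ub1")
        rep = collinearity_report([r], threshold=0.1)
        assert rep.loc[0, "rel_deviation"] == pytest.approx(0.5, abs=1e-10)
        assert bool(rep.loc[0, "excluded"])

    def test_threshold_one_excludes_nothing(self):
        sep = ReferencePair(70, OPEN, CLOSED).separation()
        from ubshift.simulate import simulate_offline_peak

        obs = simulate_offline_peak(ReferencePair(70, OPEN, CLOSED), 0.9 * sep)
        r = project_fraction(OPEN, CLOSED, obs, residue_number=70, unit_label="Ub1")
        rep = collinearity_report([r], threshold=1.0)
        assert not rep["excluded"].any()


class TestPeakProjector:
    def test_fit_transform_on_peaklists(self):
        open_list = PeakList(peaks=[Peak(70, "V", *OPEN)])
        closed_list = PeakList(peaks=[Peak(70, "V", *CLOSED)])
        obs = PeakList(peaks=[Peak(
            70, "V",
            OPEN[0] + 0.24 * (CLOSED[0] - OPEN[0]),
            OPEN[1] + 0.24 * (CLOSED[1] - OPEN[1]),
        )])
        proj = PeakProjector().fit(open_list, closed_list)
        (r,) = proj.transform({"Ub1": obs})
        assert r.f_open == pytest.approx(0.76, abs=1e-12)

    def test_sklearn_params_roundtrip(self):
        proj = PeakProjector(alpha_N=0.2)
        assert proj.get_params()["alpha_N"] == 0.2
        proj.set_params(min_separation=0.05)
        assert proj.min_separation == 0.05

    def test_transform_before_fit_raises(self):
        with pytest.raises(RuntimeError, match="fitted"):
            PeakProjector().transform({})
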