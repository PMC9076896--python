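"""Sensitivities, niche/fitness differences and outcome classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rangecoex import coexistence as cx


def _nd_rfd_rule(S_ij, S_ji):
    """Independent oracle: outcome from the ND/RFD inequalities with the
    fitness difference oriented >= 1.  Under that orientation coexistence
    requires RFD < 1/(1-ND) (with ND > 0) and a priority effect requires
    RFD < 1-ND (with ND < 0); anything else is exclusion."""
    nd = 1 - np.sqrt(S_ij * S_ji)
    rfd = max(np.sqrt(S_ji / S_ij), np.sqrt(S_ij / S_ji))
    if nd > 0 and rfd < 1 / (1 - nd):
        return "stable_coexistence"
    if nd < 0 and rfd < 1 - nd:
        return "priority_effect"
    return "competitive_exclusion"


class TestSensitivity:
    def test_no_competitive_effect_gives_zero(self):
        s, flags = cx.sensitivity(0.7, 0.7)
        assert s == pytest.approx(0.0) and not flags

    def test_invasion_boundary_gives_one(self):
        s, _ = cx.sensitivity(0.0, 0.7)
        assert s == pytest.approx(1.0)

    def test_halved_growth_gives_half(self):
        s, _ = cx.sensitivity(0.35, 0.7)
        assert s == pytest.approx(0.5)

    def test_facilitation_is_negative(self):
        s, _ = cx.sensitivity(0.9, 0.7)
        assert s < 0

    def test_zero_intrinsic_rate_flagged_undefined(self):
        s, flags = cx.sensitivity(0.2, 0.0)
        assert np.isnan(s) and "sensitivity_undefined" in flags

    def test_negative_intrinsic_rate_flagged(self):
        _, flags = cx.sensitivity(0.2, -0.3)
        assert "intrinsic_nonpersistent" in flags


class TestNicheFitness:
    def test_symmetric_half_sensitivities(self):
        nd, rfd, metric = cx.niche_fitness(0.5, 0.5)
        assert (nd, rfd, metric) == pytest.approx((0.5, 1.0, 2.0))

    def test_knife_edge(self):
        nd, rfd, metric = cx.niche_fitness(1.0, 1.0)
        assert (nd, rfd, metric) == pytest.approx((0.0, 1.0, 1.0))

    def test_asymmetric_pair(self):
        nd, rfd, metric = cx.niche_fitness(0.5, 0.8)
        assert nd == pytest.approx(1 - np.sqrt(0.4))
        assert rfd == pytest.approx(np.sqrt(1.6))
        assert metric == pytest.approx(1.25)

    def test_nonpositive_sensitivity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cx.niche_fitness(-0.1, 0.5)

    @given(
        s1=st.floats(1e-3, 2.0, exclude_min=True),
        s2=st.floats(1e-3, 2.0, exclude_min=True),
    )
    @settings(deadline=None, max_examples=200)
    def test_metric_identity_and_exchange_symmetry(self, s1, s2):
        nd, rfd, metric = cx.niche_fitness(s1, s2)
        assert metric == pytest.approx(1.0 / max(s1, s2), rel=1e-12)
        nd2, rfd2, metric2 = cx.niche_fitness(s2, s1)
        assert nd2 == pytest.approx(nd, rel=1e-12)
        assert rfd2 == pytest.approx(1.0 / rfd, rel=1e-12)
        assert metric2 == pytest.approx(metric, rel=1e-12)

    def test_metric_decreases_in_max_sensitivity(self):
        metrics = [cx.niche_fitness(0.3, s)[2] for s in (0.4, 0.6, 0.9, 1.3)]
        assert all(a > b for a, b in zip(metrics, metrics[1:]))


class TestClassify:
    def test_mutual_invasion_is_coexistence(self):
        assert cx.classify(0.5, 0.8) == "stable_coexistence"

    def test_no_invasion_is_priority_effect(self):
        assert cx.classify(1.2, 1.4) == "priority_effect"

    def test_one_sided_invasion_is_exclusion(self):
        assert cx.classify(0.5, 1.4) == "competitive_exclusion"

    def test_agrees_with_nd_rfd_rule_on_grid(self):
        grid = np.linspace(0.01, 1.99, 60)
        for s1 in grid:
            for s2 in grid:
                if abs(s1 - 1) < 1e-9 or abs(s2 - 1) < 1e-9:
                    continue  # measure-zero boundary
                assert cx.classify(s1, s2) == _nd_rfd_rule(s1, s2)

    def test_negative_intrinsic_uses_invasion_sign(self):
        # ln lambda_i < 0: S < 1 no longer means invasion; the sign of
        # ln lambda_invasion decides
        out = cx.classify(0.5, 0.5, ln_intrinsic_i=-0.2, ln_invasion_i=-0.1,
                          ln_intrinsic_j=0.4, ln_invasion_j=0.2)
        assert out == "competitive_exclusion"


class TestPairTable:
    def _lambdas(self, entries):
        return pd.DataFrame(
            entries, columns=["species", "site_elevation_m", "background", "ln_lambda"]
        )

    def test_symmetric_pair_quantities(self):
        lam = self._lambdas(
            [
                ("A", 890.0, "none", 0.8),
                ("B", 890.0, "none", 0.8),
                ("A", 890.0, "B", 0.4),
                ("B", 890.0, "A", 0.4),
            ]
        )
        out = cx.pair_table(lam, {"A": "lowland", "B": "lowland"})
        row = out.iloc[0]
        assert row["outcome"] == "stable_coexistence"
        assert row["metric"] == pytest.approx(2.0)
        assert row["pair_type"] == "lowland-lowland"

    def test_facilitative_pair_excluded_from_nd_rfd_only(self):
        lam = self._lambdas(
            [
                ("A", 890.0, "none", 0.5),
                ("B", 890.0, "none", 0.5),
                ("A", 890.0, "B", 0.6),  # facilitation: invasion > intrinsic
                ("B", 890.0, "A", 0.2),
            ]
        )
        out = cx.pair_table(lam, {"A": "lowland", "B": "lowland"})
        row = out.iloc[0]
        assert "facilitative_excluded" in row["flags"]
        assert np.isnan(row["ND"]) and np.isnan(row["metric"])
        assert row["outcome"] == "stable_coexistence"  # still classified

    def test_nonpersistent_intrinsic_keeps_nd_rfd_with_flag(self):
        lam = self._lambdas(
            [
                ("A", 890.0, "none", -0.1),
                ("B", 890.0, "none", 0.5),
                ("A", 890.0, "B", -0.05),
                ("B", 890.0, "A", 0.25),
            ]
        )
        out = cx.pair_table(lam, {"A": "lowland", "B": "lowland"})
        row = out.iloc[0]
        assert "intrinsic_nonpersistent" in row["flags"]
        assert np.isfinite(row["ND"]) and np.isfinite(row["RFD"])

    def test_mixed_pair_oriented_highland_first(self):
        lam = self._lambdas(
            [
                ("Alow", 890.0, "none", 0.6),
                ("Bhigh", 890.0, "none", 0.6),
                ("Alow", 890.0, "Bhigh", 0.3),
                ("Bhigh", 890.0, "Alow", 0.1),
            ]
        )
        out = cx.pair_table(lam, {"Alow": "lowland", "Bhigh": "highland"})
        row = out.iloc[0]
        assert row["species_i"] == "Bhigh" and row["species_j"] == "Alow"
        # highland suffers more (S_ij larger) -> RFD > 1 would mean j dominant;
        # here ln_RFD < 0 iff the lowland species is dominant
        assert row["S_ij"] > row["S_ji"]
        assert row["ln_RFD"] < 0

    def test_missing_context_skips_pair(self):
        lam = self._lambdas([("A", 890.0, "none", 0.5), ("B", 890.0, "none", 0.5)])
        out = cx.pair_table(lam, {"A": "lowland", "B": "lowland"})
        assert out.empty

    def test_replicate_column_preserved(self):
        base = [
            ("A", 890.0, "none", 0.8),
            ("B", 890.0, "none", 0.8),
            ("A", 890.0, "B", 0.4),
            ("B", 890.0, "A", 0.4),
        ]
        lam = pd.concat(
            [self._lambdas(base).assign(replicate=r) for r in (1, 2)], ignore_index=True
        )
        out = cx.pair_table(lam, {"A": "lowland", "B": "lowland"})
        assert sorted(out["replicate"]) == [1, 2]
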