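"""Ultra-deep validation: control null arithmetic, Z rule, coverage filter,
adjudication statuses, and the branched-to-truncal upgrade."""

import math

import numpy as np
import pytest

from ithkit.io import Site, SiteCounts
from ithkit.validation import (
    ValidationConfig,
    adjudicate,
    build_control_null,
    depth_filter,
    validate_panel,
    z_score,
)

from conftest import make_panel, tier2_site_rows

CFG = ValidationConfig()
SECTORS = list("ABCDE")


def _counts_map(sector_vars, normal_var=0, control_vars=(0, 0, 0), depth=16000):
    counts = {s: SiteCounts(v, depth, depth) for s, v in zip(SECTORS, sector_vars)}
    counts["N"] = SiteCounts(normal_var, depth, depth)
    for j, v in enumerate(control_vars):
        counts[f"CTRL{j+1}"] = SiteCounts(v, depth, depth)
    return counts


SITE = Site("chr7", 100, "G", "A")
CTRL_IDS = ["CTRL1", "CTRL2", "CTRL3"]


class TestControlNull:
    def test_pseudocount_smoothing_arithmetic(self):
        # normal + 3 clean controls at depth 10 000 each
        clean = SiteCounts(0, 10_000, 10_000)
        null = build_control_null(clean, [clean] * 3, CFG)
        assert null.pooled_error == pytest.approx(1 / 40_002)
        assert null.sd_vaf > 0  # binomial floor engaged
        assert null.mean_vaf == 0.0
        assert null.n_controls == 3

    def test_identical_controls_have_zero_raw_sd(self):
        c = SiteCounts(5, 10_000, 10_000)
        null = build_control_null(c, [c] * 3, CFG)
        # raw sd is zero; what remains is exactly the binomial floor
        pooled = (20 + 1) / (40_000 + 2)
        floor = math.sqrt(1 + 1 / 4) * math.sqrt(pooled * (1 - pooled) / 10_000)
        assert null.sd_vaf == pytest.approx(floor)

    def test_germline_het_normal_shifts_mean(self):
        normal = SiteCounts(3000, 10_000, 10_000)  # VAF 0.3
        clean = SiteCounts(0, 10_000, 10_000)
        null = build_control_null(normal, [clean] * 3, CFG)
        assert null.mean_vaf == pytest.approx(0.075)

    def test_too_few_controls_rejected(self):
        clean = SiteCounts(0, 10_000, 10_000)
        with pytest.raises(ValueError):
            build_control_null(clean, [clean] * 2, CFG)


class TestZScore:
    def test_zero_at_null_mean(self):
        clean = SiteCounts(16, 16_000, 16_000)
        null = build_control_null(clean, [clean] * 3, CFG)
        assert z_score(SiteCounts(16, 16_000, 16_000), null, CFG) == pytest.approx(0.0)

    def test_definition_with_zero_mean(self):
        clean = SiteCounts(0, 16_000, 16_000)
        null = build_control_null(clean, [clean] * 3, CFG)
        v = SiteCounts(160, 16_000, 16_000)
        assert z_score(v, null, CFG) == pytest.approx(v.vaf / null.sd_vaf)

    def test_zero_depth_is_nan(self):
        clean = SiteCounts(0, 16_000, 16_000)
        null = build_control_null(clean, [clean] * 3, CFG)
        assert math.isnan(z_score(SiteCounts(0, 0, 0), null, CFG))

    def test_sign_preserved_below_null(self):
        ref = SiteCounts(160, 16_000, 16_000)
        null = build_control_null(ref, [ref] * 3, CFG)
        assert z_score(SiteCounts(0, 16_000, 16_000), null, CFG) < 0


class TestDepthFilter:
    def test_boundary_pass(self):
        counts = {s: SiteCounts(0, 100, 100) for s in SECTORS + ["N"]}
        ok, why = depth_filter(counts, SECTORS, "N", CFG)
        assert ok and why == ""

    def test_one_shallow_sector_fails(self):
        counts = {s: SiteCounts(0, 100, 100) for s in SECTORS + ["N"]}
        counts["C"] = SiteCounts(0, 99, 99)
        ok, why = depth_filter(counts, SECTORS, "N", CFG)
        assert not ok and why == "low_coverage:C"

    def test_missing_sector_is_missing_data(self):
        counts = {s: SiteCounts(0, 100, 100) for s in SECTORS[:-1] + ["N"]}
        ok, why = depth_filter(counts, SECTORS, "N", CFG)
        assert not ok and why == "missing_data"

    def test_assayable_accounting_with_engineered_failures(self):
        """121 designed sites of which exactly 5 fail coverage leaves 116."""
        rows = []
        for i in range(121):
            depth = 99 if i < 5 else 16_000
            pos = 1000 + i
            for s in SECTORS:
                rows.append((s, "sector", "tier2", pos, 0 if depth < 100 else 160, depth, depth))
            rows.append(("N", "normal", "tier2", pos, 0, 16_000, 16_000))
            for j in range(3):
                rows.append((f"CTRL{j+1}", "control", "tier2", pos, 0, 16_000, 16_000))
        results, log = validate_panel(make_panel(rows))
        n_na = sum(1 for r in results.values() if r.status == "not_assessable")
        assert len(results) == 121 and n_na == 5
        assert sum(1 for r in results.values() if r.status != "not_assessable") == 116


class TestAdjudicate:
    def test_het_germline_variant_rejected(self):
        counts = _counts_map([7000] * 5, normal_var=7680)  # normal VAF 0.48
        res = adjudicate(SITE, counts, SECTORS, "N", CTRL_IDS, CFG)
        assert res.status == "germline_like"
        assert "N" in res.provenance
        assert not any(res.present.values())

    def test_control_carrier_rejected(self):
        counts = _counts_map([7000] * 5, control_vars=(5300, 0, 0))
        res = adjudicate(SITE, counts, SECTORS, "N", CTRL_IDS, CFG)
        assert res.status == "germline_like"
        assert "CTRL1" in res.provenance

    def test_variant_seen_nowhere_is_absent(self):
        counts = _counts_map([0] * 5)
        res = adjudicate(SITE, counts, SECTORS, "N", CTRL_IDS, CFG)
        assert res.status == "absent"

    def test_branched_to_truncal_upgrade(self):
        """Discovery saw 4/5 sectors; ultra-deep shows the fifth at low but
        unambiguous VAF, so the mutation is present in all five."""
        counts = _counts_map([5600, 5400, 5800, 5500, 180])  # E at ~1.1% VAF
        res = adjudicate(SITE, counts, SECTORS, "N", CTRL_IDS, CFG)
        assert res.status == "confirmed"
        assert res.present_sectors == SECTORS

    def test_confirmed_requires_some_sector(self):
        # sectors and references all at the ~1e-3 error level
        counts = _counts_map([16, 20, 12, 18, 15], normal_var=17, control_vars=(16, 18, 15))
        res = adjudicate(SITE, counts, SECTORS, "N", CTRL_IDS, CFG)
        assert res.status in {"absent", "germline_like"}

    def test_raising_z_threshold_is_monotone(self):
        counts = _counts_map([60, 45, 30, 20, 10])
        n_present = []
        for z in (2.0, 3.0, 5.0, 10.0):
            cfg = ValidationConfig(z_threshold=z)
            res = adjudicate(SITE, counts, SECTORS, "N", CTRL_IDS, cfg)
            n_present.append(sum(res.present.values()))
        assert n_present == sorted(n_present, reverse=True)

    def test_determinism(self):
        counts = _counts_map([500, 0, 20, 90, 4])
        a = adjudicate(SITE, counts, SECTORS, "N", CTRL_IDS, CFG)
        b = adjudicate(SITE, counts, SECTORS, "N", CTRL_IDS, CFG)
        assert a.status == b.status and a.present == b.present and a.sector_z == b.sector_z

    def test_vaf_floor_gates_presence(self):
        cfg = ValidationConfig(min_vaf_floor=0.02)
        counts = _counts_map([180, 0, 0, 0, 0])  # 1.1% VAF, huge Z
        res = adjudicate(SITE, counts, SECTORS, "N", CTRL_IDS, cfg)
        assert not res.present["A"]


class TestValidatePanel:
    def test_requested_sites_only(self):
        rows = tier2_site_rows(100, [160] * 5) + tier2_site_rows(200, [160] * 5)
        panel = make_panel(rows)
        results, _ = validate_panel(panel, sites=[Site("chr7", 100, "G", "A")])
        assert list(results) == [Site("chr7", 100, "G", "A")]

    def test_log_accounts_for_removals(self):
        rows = tier2_site_rows(100, [160] * 5) + tier2_site_rows(200, [0] * 5)
        results, log = validate_panel(make_panel(rows))
        assert any("absent" in line for line in log)
        assert log[-1].startswith("#")

    def test_missing_normal_is_hard_error(self):
        rows = [(s, "sector", "tier2", 100, 0, 16000, 16000) for s in SECTORS]
        with pytest.raises(ValueError, match="normal"):
            validate_panel(make_panel(rows))


class TestIntermixedMinorClonePower:
    def test_tier2_sees_ubiquitous_minor_clone_tier1_does_not(self):
        """A mutation at CCF ~0.02 in every sector is invisible at discovery
        depth but recovered as truncal by ultra-deep validation in >= 95%
        of replicates."""
        from ithkit.discovery import CallerConfig, call_site

        rng = np.random.default_rng(77)
        p = 0.7 * 0.02 / 2  # purity 0.7, CCF 0.02, diploid
        e = 1e-3
        p_eff = p * (1 - e) + (1 - p) * e
        n_rep = 60
        tier2_truncal = 0
        tier1_any_truncal = 0
        for _ in range(n_rep):
            d2 = np.round(0.95 * rng.poisson(17075, size=9)).astype(int)
            vars2 = rng.binomial(d2[:5], p_eff)
            refs2 = rng.binomial(d2[5:], e)
            counts = {s: SiteCounts(int(v), int(d), int(d)) for s, v, d in zip(SECTORS, vars2, d2)}
            counts["N"] = SiteCounts(int(refs2[0]), int(d2[5]), int(d2[5]))
            for j in range(3):
                counts[f"CTRL{j+1}"] = SiteCounts(int(refs2[j + 1]), int(d2[6 + j]), int(d2[6 + j]))
            res = adjudicate(SITE, counts, SECTORS, "N", CTRL_IDS, CFG)
            if res.status == "confirmed" and len(res.present_sectors) == 5:
                tier2_truncal += 1
            d1 = np.round(0.95 * rng.poisson(384, size=5)).astype(int)
            vars1 = rng.binomial(d1, p_eff)
            normal1 = SiteCounts(0, 365, 384)
            calls = [
                call_site(SiteCounts(int(v), int(d), int(d)), normal1, CallerConfig()).called
                for v, d in zip(vars1, d1)
            ]
            if all(calls):
                tier1_any_truncal += 1
        assert tier2_truncal / n_rep >= 0.95
        assert tier1_any_truncal == 0
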