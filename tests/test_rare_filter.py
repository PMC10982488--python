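import numpy as np
import pytest

from cnvburden import (
    CnvCall,
    SampleRecord,
    build_cnv_regions,
    drop_panel_samples,
    remove_common,
    select_reference_panel,
)
from cnvburden.rare_filter import ReferencePanel


def control(sid, country="NO", sex="M"):
    return SampleRecord(sid, "control", country, sex, 0.1, 0.001, 0.0)


def call(sid, start, end, chrom=1, cnv_type="DEL"):
    cn = 1 if cnv_type == "DEL" else 3
    return CnvCall(sid, chrom, start, end, cnv_type, cn, 10)


def make_panel(ids):
    return ReferencePanel(sample_ids=frozenset(ids))


class TestSelectReferencePanel:
    @pytest.fixture
    def controls(self):
        out = []
        for country in ("NO", "SE"):
            for sex in ("M", "F"):
                out += [control(f"{country}{sex}{i}", country, sex) for i in range(100)]
        return out

    def test_stratified_50_per_stratum(self, controls):
        panel = select_reference_panel(controls, size=200, seed=1)
        assert panel.size == 200
        assert all(v == 50 for v in panel.strata.values())
        for country in ("NO", "SE"):
            for sex in ("M", "F"):
                n = sum(1 for sid in panel.sample_ids if sid.startswith(country + sex))
                assert n == 50

    def test_deterministic_given_seed(self, controls):
        p1 = select_reference_panel(controls, 200, seed=9)
        p2 = select_reference_panel(controls, 200, seed=9)
        p3 = select_reference_panel(controls, 200, seed=10)
        assert p1.sample_ids == p2.sample_ids
        assert p1.sample_ids != p3.sample_ids

    def test_exhausting_strata_returns_full_set(self):
        four = [control("a", "NO", "M"), control("b", "NO", "F"),
                control("c", "SE", "M"), control("d", "SE", "F")]
        panel = select_reference_panel(four, size=4, seed=0)
        assert panel.sample_ids == {"a", "b", "c", "d"}

    def test_insufficient_stratum_names_it(self, controls):
        depleted = [s for s in controls if not (s.country == "SE" and s.sex == "F")]
        with pytest.raises(ValueError, match="SE.*F"):
            select_reference_panel(depleted, 200, seed=0)


class TestBuildCnvRegions:
    def test_identical_calls_one_region_frequency(self):
        panel = make_panel([f"P{i}" for i in range(200)])
        calls = [call(f"P{i}", 1_000_000, 1_100_000) for i in range(4)]
        regions = build_cnv_regions(calls, panel)
        assert len(regions) == 1
        assert regions[0].carrier_frequency == pytest.approx(0.02)
        assert regions[0].carrier_ids == frozenset(f"P{i}" for i in range(4))

    def test_low_mutual_overlap_stays_separate(self):
        panel = make_panel(["P0", "P1"])
        a = call("P0", 0, 100_000)
        b = call("P1", 90_000, 190_000)  # 10% mutual overlap
        assert len(build_cnv_regions([a, b], panel)) == 2

    def test_types_cluster_separately(self):
        panel = make_panel(["P0", "P1"])
        a = call("P0", 0, 100_000, cnv_type="DEL")
        b = call("P1", 0, 100_000, cnv_type="DUP")
        regions = build_cnv_regions([a, b], panel)
        assert {r.cnv_type for r in regions} == {"DEL", "DUP"}

    def test_duplicate_carrier_counts_once(self):
        panel = make_panel(["P0", "P1"])
        calls = [call("P0", 0, 100_000), call("P0", 10_000, 110_000),
                 call("P1", 0, 100_000)]
        (region,) = build_cnv_regions(calls, panel)
        assert region.carrier_frequency == pytest.approx(1.0)

    def test_matches_graph_closure_oracle(self, rng):
        import networkx as nx

        from cnvburden.intervals import reciprocal_overlap

        panel = make_panel([f"P{i}" for i in range(30)])
        for _ in range(200):
            calls = []
            for i in range(int(rng.integers(2, 15))):
                start = int(rng.integers(0, 50_000))
                length = int(rng.integers(1_000, 30_000))
                calls.append(call(f"P{i % 30}", start, start + length))
            regions = build_cnv_regions(calls, panel)

            g = nx.Graph()
            g.add_nodes_from(range(len(calls)))
            for i in range(len(calls)):
                for j in range(i + 1, len(calls)):
                    if reciprocal_overlap(calls[i].interval(), calls[j].interval()) >= 0.5:
                        g.add_edge(i, j)
            expected = sorted(
                tuple(sorted((calls[i].start, calls[i].end) for i in comp))
                for comp in nx.connected_components(g)
            )
            got = []
            for r in regions:
                members = [c for c in calls if any(
                    c.sample_id == m and r.start <= c.start and c.end <= r.end
                    for m in r.carrier_ids)]
                got.append(tuple(sorted((c.start, c.end) for c in members)))
            assert len(regions) == nx.number_connected_components(g)
            # spans agree with the closure components
            spans = sorted((r.start, r.end) for r in regions)
            exp_spans = sorted(
                (min(s for s, _ in comp), max(e for _, e in comp)) for comp in expected
            )
            assert spans == exp_spans


class TestRemoveCommon:
    def make_region(self, freq, cnv_type="DEL", start=0, end=100_000):
        from cnvburden import CnvRegion

        return CnvRegion(1, start, end, cnv_type, frozenset(), freq)

    def test_threshold_on_call_coverage(self):
        region = self.make_region(0.05)
        kept_call = call("S1", 51_000, 151_000)  # 49% covered
        removed_call = call("S2", 0, 100_000)  # 100% covered
        rare, removed = remove_common([kept_call, removed_call], [region])
        assert rare == [kept_call] and removed == [removed_call]

    def test_type_matched(self):
        dup_region = self.make_region(0.05, cnv_type="DUP")
        del_call = call("S1", 0, 100_000, cnv_type="DEL")
        rare, removed = remove_common([del_call], [dup_region])
        assert rare == [del_call]

    def test_rare_region_not_used(self):
        rare_region = self.make_region(0.01)
        c = call("S1", 0, 100_000)
        rare, removed = remove_common([c], [rare_region], min_freq=0.02)
        assert rare == [c]

    def test_monotone_in_min_freq(self, rng):
        regions = [self.make_region(float(f), start=s, end=s + 50_000)
                   for f, s in zip(rng.uniform(0, 0.2, 10),
                                   range(0, 1_000_000, 100_000))]
        calls = [call(f"S{i}", int(p), int(p) + 60_000)
                 for i, p in enumerate(rng.integers(0, 900_000, 50))]
        kept_ids = {}
        for mf in (0.01, 0.05, 0.10, 0.50):
            rare, _ = remove_common(calls, regions, min_freq=mf)
            kept_ids[mf] = {c.sample_id for c in rare}
        assert kept_ids[0.01] <= kept_ids[0.05] <= kept_ids[0.10] <= kept_ids[0.50]


class TestDropPanelSamples:
    def test_panel_members_and_calls_removed(self):
        samples = [control(f"S{i}") for i in range(10)]
        calls = [call(f"S{i}", 0, 60_000) for i in range(10)]
        panel = make_panel({"S0", "S5"})
        kept_s, kept_c = drop_panel_samples(samples, calls, panel)
        assert len(kept_s) == 8 and len(kept_c) == 8
        assert not any(c.sample_id in panel.sample_ids for c in kept_c)

    def test_empty_panel_is_identity(self):
        samples = [control("A")]
        calls = [call("A", 0, 60_000)]
        kept_s, kept_c = drop_panel_samples(samples, calls, make_panel(set()))
        assert kept_s == samples and kept_c == calls


def test_planted_common_region_frequency_recovered(small_cohort):
    """Estimated panel carrier frequencies sit within binomial error of the
    planted truth (leakage-free by construction)."""
    from cnvburden import QcThresholds, filter_samples

    bundle = small_cohort
    samples, calls, _ = filter_samples(list(bundle.samples), list(bundle.calls),
                                       QcThresholds())
    controls = [s for s in samples if s.phenotype == "control"]
    panel = select_reference_panel(controls, size=200, seed=5)
    panel_calls = [c for c in calls if c.sample_id in panel.sample_ids]
    regions = build_cnv_regions(panel_calls, panel)
    # every planted common region of true frequency f should be recovered
    # by a clustered region with |f_hat - f| within ~4 binomial SEs
    found_common = [r for r in regions if r.carrier_frequency >= 0.02]
    assert len(found_common) >= bundle.spec.common_region_count * 0.5
    for r in found_common[:10]:
        se = np.sqrt(r.carrier_frequency * (1 - r.carrier_frequency) / panel.size)
        assert r.carrier_frequency <= 0.20 + 4 * se + 0.05
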