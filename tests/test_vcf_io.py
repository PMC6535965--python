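"""VCF reading, the hard-filter thread, and BED output."""

import numpy as np
import pytest

from budsport import synthetic_data as sd
from budsport.loh_scan import LohSegment
from budsport.vcf_io import (
    FILTER_RULES,
    HardFilterThresholds,
    SiteRecord,
    apply_hard_filters,
    read_pair_vcf,
    read_scaffold_table,
    read_segments_bed,
    records_to_frame,
    write_segments_bed,
)
from conftest import make_small_config, write_vcf_text

NOMINAL_INFO = {
    "QD": 20.0,
    "MQ": 60.0,
    "FS": 0.0,
    "MQRankSum": 0.0,
    "ReadPosRankSum": 0.0,
    "SOR": 1.0,
    "ClippingRankSum": 0.0,
}


def site(pos=100, info=None, gq=(99, 99), gt_sport=(0, 0), **kw):
    merged = dict(NOMINAL_INFO)
    merged.update(info or {})
    return SiteRecord(
        scaffold="chrA",
        pos=pos,
        ref_allele="A",
        alt_allele="G",
        gt_wild=(0, 1),
        gt_sport=gt_sport,
        dp_wild=30,
        dp_sport=28,
        gq_wild=gq[0],
        gq_sport=gq[1],
        info=merged,
        **kw,
    )


class TestHardFilters:
    def test_nominal_site_passes(self):
        passing, fails = apply_hard_filters([site()])
        assert len(passing) == 1 and not fails

    @pytest.mark.parametrize(
        "info,rule",
        [
            ({"QD": 9.9}, "QD"),
            ({"MQ": 59.8}, "MQ_low"),
            ({"MQ": 60.2}, "MQ_high"),
            ({"FS": 15.1}, "FS"),
            ({"MQRankSum": 0.05}, "MQRankSum"),
            ({"MQRankSum": -0.05}, "MQRankSum"),
            ({"ReadPosRankSum": -1.6}, "ReadPosRankSum"),
            ({"SOR": 2.5}, "SOR"),
            ({"ClippingRankSum": 0.31}, "ClippingRankSum"),
            ({"ClippingRankSum": -0.31}, "ClippingRankSum"),
        ],
    )
    def test_single_rule_violations(self, info, rule):
        passing, fails = apply_hard_filters([site(info=info)])
        assert not passing
        assert fails == {rule: 1}

    def test_first_failure_attribution_order(self):
        # QD and SOR both fire; the earlier rule takes the count
        _, fails = apply_hard_filters([site(info={"QD": 1.0, "SOR": 9.0})])
        assert fails == {"QD": 1}

    def test_gq_and_missing_gates(self):
        _, fails = apply_hard_filters([site(gq=(99, 19))])
        assert fails == {"GQ": 1}
        _, fails = apply_hard_filters([site(gt_sport=None)])
        assert fails == {"missing_genotype": 1}
        passing, _ = apply_hard_filters(
            [site(gt_sport=None)], HardFilterThresholds(require_complete=False)
        )
        assert len(passing) == 1

    def test_rprs_upper_bound_configurable(self):
        rec = site(info={"ReadPosRankSum": 1.6})
        passing, _ = apply_hard_filters([rec])  # one-sided default: passes
        assert len(passing) == 1
        _, fails = apply_hard_filters([rec], HardFilterThresholds(rprs_one_sided=False))
        assert fails == {"ReadPosRankSum": 1}

    def test_absent_metric_is_lenient(self):
        rec = site(info={"QD": None})
        rec.info.pop("QD")
        passing, _ = apply_hard_filters([rec])
        assert len(passing) == 1

    def test_brute_force_over_random_sites(self):
        # draw 1,000 sites with random metrics and re-evaluate every condition
        # independently; per-rule counts must agree and sum to the rejects
        rng = np.random.default_rng(42)
        thr = HardFilterThresholds()
        sites = []
        for i in range(1000):
            info = {
                "QD": rng.uniform(5, 35),
                "MQ": rng.uniform(59.8, 60.2),
                "FS": rng.uniform(0, 20),
                "MQRankSum": rng.uniform(-0.08, 0.08),
                "ReadPosRankSum": rng.uniform(-2.5, 2.5),
                "SOR": rng.uniform(0, 3),
                "ClippingRankSum": rng.uniform(-0.5, 0.5),
            }
            gq = (int(rng.integers(10, 100)), int(rng.integers(10, 100)))
            sites.append(site(pos=i + 1, info=info, gq=gq))
        passing, fails = apply_hard_filters(sites, thr)

        def oracle_passes(rec):
            i = rec.info
            return not (
                i["QD"] < 10.0
                or i["MQ"] < 59.9
                or i["MQ"] > 60.1
                or i["FS"] > 15.0
                or i["MQRankSum"] < -0.04
                or i["MQRankSum"] > 0.04
                or i["ReadPosRankSum"] < -1.5
                or i["SOR"] > 2.0
                or i["ClippingRankSum"] < -0.3
                or i["ClippingRankSum"] > 0.3
                or rec.gq_wild < 20
                or rec.gq_sport < 20
            )

        expected_pass = [s for s in sites if oracle_passes(s)]
        assert [s.pos for s in passing] == [s.pos for s in expected_pass]
        assert sum(fails.values()) == len(sites) - len(passing)
        assert set(fails) <= set(FILTER_RULES)

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(3)
        sites = [
            site(pos=i + 1, info={"QD": rng.uniform(5, 35), "SOR": rng.uniform(0, 3)})
            for i in range(200)
        ]
        once, _ = apply_hard_filters(sites)
        twice, fails = apply_hard_filters(once)
        assert [s.pos for s in twice] == [s.pos for s in once]
        assert not fails


class TestReadPairVcf:
    def test_biallelic_snp_selection(self, tmp_path):
        rows = [
            ("chrA", 100, "A", "G", "0/1", "0/0"),
            ("chrA", 200, "A", "AT", "0/1", "0/1"),  # indel
            "chrA\t300\t.\tC\tG,T\t50\tPASS\tQD=20.0\tGT:DP:GQ\t0/1:30:99\t0/2:30:99",
            ("chrA", 400, "T", "C", "1/1", "1/1"),
            ("chrA", 500, "G", "C", "0/1", "0/1"),
        ]
        path = write_vcf_text(tmp_path / "pair.vcf", rows)
        records, skips = read_pair_vcf(path, ("WILD", "SPORT"))
        assert [r.pos for r in records] == [100, 400, 500]
        assert skips["indel"] == 1 and skips["multiallelic"] == 1

    def test_two_single_sample_files_intersect(self, tmp_path):
        wild = write_vcf_text(
            tmp_path / "w.vcf",
            [("chrA", 100, "A", "G", "0/1"), ("chrA", 200, "C", "T", "0/1")],
            samples=("WILD",),
        )
        sport = write_vcf_text(
            tmp_path / "s.vcf",
            [
                ("chrA", 200, "C", "T", "1/1"),
                ("chrA", 200 + 100, "G", "A", "0/0"),
                ("chrA", 400, "C", "T", "0/1"),  # same pos would be 400 only here
            ],
            samples=("SPORT",),
        )
        records, skips = read_pair_vcf([wild, sport], ("WILD", "SPORT"))
        assert [r.pos for r in records] == [200]
        assert records[0].gt_wild == (0, 1) and records[0].gt_sport == (1, 1)
        assert skips["wild_only"] == 1 and skips["sport_only"] == 2

    def test_allele_mismatch_dropped_and_counted(self, tmp_path):
        wild = write_vcf_text(tmp_path / "w.vcf", [("chrA", 100, "A", "G", "0/1")], samples=("WILD",))
        sport = write_vcf_text(tmp_path / "s.vcf", [("chrA", 100, "A", "T", "0/1")], samples=("SPORT",))
        records, skips = read_pair_vcf([wild, sport], ("WILD", "SPORT"))
        assert not records
        assert skips["allele_mismatch"] == 1

    def test_missing_sample_names_available(self, tmp_path):
        path = write_vcf_text(tmp_path / "p.vcf", [("chrA", 1, "A", "G", "0/1", "0/1")])
        with pytest.raises(ValueError, match="WILD"):
            read_pair_vcf(path, ("NOPE", "SPORT"))

    def test_unsorted_input_rejected(self, tmp_path):
        path = write_vcf_text(
            tmp_path / "p.vcf",
            [("chrA", 500, "A", "G", "0/1", "0/1"), ("chrA", 100, "C", "T", "0/1", "0/1")],
        )
        with pytest.raises(ValueError, match="unsorted"):
            read_pair_vcf(path, ("WILD", "SPORT"))

    def test_synthetic_roundtrip(self, tmp_path):
        cfg = make_small_config(seed=9)
        result = sd.simulate(cfg)
        out = sd.simulate_pair(cfg, tmp_path, split=True)
        records, _ = read_pair_vcf(
            [out["paths"]["wild_vcf"], out["paths"]["sport_vcf"]], ("WILD", "SPORT")
        )
        frame = records_to_frame(records)
        expected = result.sites.sort_values(["scaffold", "pos"]).reset_index(drop=True)
        for col in ["pos", "code_wild", "code_sport", "dp_wild", "dp_sport"]:
            np.testing.assert_array_equal(frame[col].to_numpy(), expected[col].to_numpy())
        # INFO metrics survive the round trip too
        assert records[0].info["MQ"] == pytest.approx(60.0)


class TestScaffoldTable:
    def test_read_and_validate(self, tmp_path):
        p = tmp_path / "sc.tsv"
        p.write_text("chrA\t1000\nchrB\t2000\n")
        df = read_scaffold_table(p)
        assert df["length"].tolist() == [1000, 2000]
        p.write_text("chrA\t1000\nchrA\t2000\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_scaffold_table(p)


class TestBedOutput:
    def seg(self, scaffold, start, end):
        return LohSegment(scaffold, start, end, 10, 0, 0, 10)

    def test_coordinate_conversion(self, tmp_path):
        out = tmp_path / "segs.bed"
        write_segments_bed([self.seg("Pp06", 22_202_387, 30_767_194)], out)
        assert out.read_text().startswith("Pp06\t22202386\t30767194\tloh")

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        segs = [self.seg("Pp01", 5, 10), self.seg("Pp06", 100, 900), self.seg("Pp06", 1000, 2000)]
        out = tmp_path / "segs.bed"
        write_segments_bed(segs, out)
        back = read_segments_bed(out)
        assert back["start"].tolist() == [5, 100, 1000]
        assert back["end"].tolist() == [10, 900, 2000]

    def test_empty_segment_list(self, tmp_path):
        out = tmp_path / "empty.bed"
        write_segments_bed([], out)
        assert out.read_text() == ""

    def test_overlap_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="overlap"):
            write_segments_bed(
                [self.seg("Pp06", 100, 900), self.seg("Pp06", 800, 2000)],
                tmp_path / "x.bed",
            )
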