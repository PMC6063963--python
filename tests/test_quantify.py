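"""Quantification pipeline: read parsing, whitelisting, indel calling,
rates, ratios, aggregations and replicate concordance."""

import numpy as np
import pandas as pd
import pytest

from pairscreen import design as D
from pairscreen import model as M
from pairscreen import quantify as Q
from pairscreen import simulate as S
from pairscreen.dna import revcomp

LAYOUT = D.CassetteLayout()


def read_pair_for(cassette: str, read_length: int = 150):
    return cassette[:read_length], revcomp(cassette)[:read_length]


class TestParse:
    def test_error_free_reads_parse_exactly(self, clean_sim, design_index, small_design):
        obs, log = clean_sim["obs"], clean_sim["log"]
        assert clean_sim["accounting"]["n_anchor_fail"] == 0
        assert (obs["hamming_status"] == "exact").all()
        # every read maps back to the member that generated it
        per_member_obs = obs.groupby(obs["member_id"].astype(int)).size()
        reads_per_rbc = int(clean_sim["config"].reads_per_rbc)
        per_member_truth = log.groupby("member_id").size() * reads_per_rbc
        pd.testing.assert_series_equal(
            per_member_obs, per_member_truth, check_names=False
        )
        by_member = {int(r.member_id): r for r in small_design.itertuples(index=False)}
        sample = obs.head(50)
        for row in sample.itertuples(index=False):
            ref = by_member[int(row.member_id)]
            assert row.spacer_obs == ref.spacer

    def test_barcode_substitution_recovered_as_corrected(self, design_index, small_design):
        ref = small_design.iloc[5]
        cassette = LAYOUT.cassette(ref.spacer, ref.target, ref.barcode, "ACGTACGT")
        bc_start = cassette.index(ref.barcode)
        mutated = list(cassette)
        mutated[bc_start + 7] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[bc_start + 7]]
        r1, r2 = read_pair_for("".join(mutated))
        got = Q.parse_read_pair(r1, r2, design_index)
        assert got["hamming_status"] == "corrected"
        assert got["member_id"] == ref.member_id
        assert got["rbc"] == "ACGTACGT"

    def test_scrambled_anchors_unmatched(self, design_index, small_design):
        ref = small_design.iloc[0]
        cassette = LAYOUT.cassette(ref.spacer, ref.target, ref.barcode, "AAAATTTT")
        r1, r2 = read_pair_for(cassette)
        got = Q.parse_read_pair("N" * len(r1), r2, design_index)
        assert not got["anchors_ok"]
        assert pd.isna(got["member_id"])

    def test_anchor_tolerates_one_substitution(self, design_index, small_design):
        ref = small_design.iloc[3]
        cassette = LAYOUT.cassette(ref.spacer, ref.target, ref.barcode, "ACGTACGT")
        broken = "T" + cassette[1:]  # one substitution in the prefix anchor
        if cassette[0] == "T":
            broken = "A" + cassette[1:]
        r1, r2 = read_pair_for(broken)
        got = Q.parse_read_pair(r1, r2, design_index)
        assert got["anchors_ok"]
        assert got["member_id"] == ref.member_id

    def test_find_approx(self):
        assert Q.find_approx("AAACGTAAA", "ACGT", 0) == 2
        assert Q.find_approx("AAACCTAAA", "ACGT", 1) == 2
        assert Q.find_approx("AAACCTAAA", "ACGT", 0) == -1
        assert Q.find_approx("AAA", "ACGT", 1) == -1


@pytest.fixture(scope="module")
def noisy_day0(small_design, design_index, tmp_path_factory):
    """Day-0 reads with synthesis errors on (no sequencing error)."""
    out = tmp_path_factory.mktemp("noisy_day0")
    cfg = S.SimConfig(
        seed=19, synthesis_error_rate=0.05, synthesis_indel_rate=0.1,
        sequencing_error_rate=0.0, integrations_per_member=8, reads_per_rbc=3,
    )
    design = small_design.head(120).reset_index(drop=True)
    truth = S.simulate_truth(design, cfg)
    log = S.simulate_integrations(design, cfg)
    r1, r2 = out / "R1.fastq.gz", out / "R2.fastq.gz"
    S.simulate_reads(log, truth, design, 0, cfg, r1, r2)
    idx = Q.DesignIndex(design)
    obs, _ = Q.parse_fastq_pair(r1, r2, idx)
    return {"design": design, "index": idx, "log": log, "obs": obs}


class TestWhitelist:
    def test_whitelist_equals_error_free_truth(self, noisy_day0):
        wl = Q.build_whitelist(noisy_day0["obs"], noisy_day0["index"])
        got = set(zip(wl.member_id, wl.rbc))
        log = noisy_day0["log"]
        want = set(
            zip(log[log.error_free].member_id, log[log.error_free].rbc)
        )
        assert got == want

    def test_min_read_support_enforced(self, noisy_day0):
        wl = Q.build_whitelist(noisy_day0["obs"], noisy_day0["index"], min_reads_per_rbc=4)
        assert wl.empty  # every rBC has exactly 3 reads

    def test_conflicting_rbc_rejected(self, design_index, small_design):
        rows = []
        for member in (small_design.iloc[0], small_design.iloc[1]):
            for _ in range(2):
                rows.append(
                    {
                        "member_id": int(member.member_id),
                        "rbc": "AAAACCCC",
                        "spacer_obs": member.spacer,
                        "target_obs": design_index.expected_region(int(member.member_id)),
                        "anchors_ok": True,
                        "hamming_status": "exact",
                    }
                )
        obs = pd.DataFrame(rows)
        wl = Q.build_whitelist(obs, design_index)
        assert wl.empty

    def test_corrected_barcode_not_whitelisted(self, design_index, small_design):
        member = small_design.iloc[0]
        rows = [
            {
                "member_id": int(member.member_id),
                "rbc": "GGGGTTTT",
                "spacer_obs": member.spacer,
                "target_obs": design_index.expected_region(int(member.member_id)),
                "anchors_ok": True,
                "hamming_status": status,
            }
            for status in ("corrected", "corrected")
        ]
        wl = Q.build_whitelist(pd.DataFrame(rows), design_index)
        assert wl.empty  # a corrected barcode implies a cassette error

    def test_empty_input_warns(self, design_index):
        with pytest.warns(UserWarning, match="empty"):
            wl = Q.build_whitelist(pd.DataFrame(columns=["member_id"]), design_index)
        assert wl.empty


class TestCallIndel:
    EXPECTED = "GATTACAGATTACAGATTAC" + LAYOUT.pam + LAYOUT.post_pam

    def test_identical_is_intact(self):
        assert Q.call_indel(self.EXPECTED, self.EXPECTED) == "intact"

    def test_deletion_at_cut_is_indel(self):
        cut = len(self.EXPECTED) - 16
        obs = self.EXPECTED[: cut - 2] + self.EXPECTED[cut + 1 :]
        assert Q.call_indel(obs, self.EXPECTED) == "indel"

    def test_insertion_at_cut_is_indel(self):
        cut = len(self.EXPECTED) - 16
        obs = self.EXPECTED[:cut] + "CC" + self.EXPECTED[cut:]
        assert Q.call_indel(obs, self.EXPECTED) == "indel"

    def test_substitution_is_discard(self):
        obs = "C" + self.EXPECTED[1:]
        assert obs != self.EXPECTED
        assert Q.call_indel(obs, self.EXPECTED) == "discard"

    def test_indel_far_from_cut_is_discard(self):
        obs = self.EXPECTED[2:]  # deletion at the very 5' end, outside the window
        assert Q.call_indel(obs, self.EXPECTED, Q.IndelPolicy(window=5)) == "discard"

    def test_deletion_reaching_into_pam_still_called(self):
        cut = len(self.EXPECTED) - 16
        obs = self.EXPECTED[: cut - 3] + self.EXPECTED[cut + 5 :]  # spans cut and PAM start
        assert Q.call_indel(obs, self.EXPECTED) == "indel"


class TestRates:
    def test_rates_match_truth_on_clean_simulation(self, clean_sim, design_index, small_design):
        rec = Q.compute_indel_rates(clean_sim["obs"], design_index, min_rbc=0)
        truth = clean_sim["truth"]
        expected = {
            int(r.member_id): S.expected_rate(r._asdict(), truth)
            for r in small_design.itertuples(index=False)
        }
        merged = rec[rec.n_rbc > 0]
        resid = [
            row.indel_rate - expected[row.member_id] for row in merged.itertuples(index=False)
        ]
        assert abs(np.mean(resid)) < 0.01  # unbiased
        assert np.percentile(np.abs(resid), 95) < 0.25  # binomial noise at n_rbc ~ 25

    def test_conservation_of_reads(self, clean_sim, design_index):
        rec = Q.compute_indel_rates(clean_sim["obs"], design_index, min_rbc=0)
        obs = clean_sim["obs"]
        mapped = int(obs["member_id"].notna().sum())
        assert (rec.n_indel_reads + rec.n_intact + rec.n_discarded).sum() == rec.n_reads.sum()
        assert rec.n_reads.sum() == mapped

    def test_whitelisting_never_increases_counts(self, clean_sim, design_index):
        wl = pd.DataFrame(
            {
                "member_id": clean_sim["log"].member_id,
                "rbc": clean_sim["log"].rbc,
                "day0_read_count": 3,
            }
        ).head(2000)
        full = Q.compute_indel_rates(clean_sim["obs"], design_index, min_rbc=0)
        filt = Q.compute_indel_rates(clean_sim["obs"], design_index, whitelist=wl, min_rbc=0)
        assert (filt.n_reads <= full.n_reads).all()
        total_seen = filt.n_reads.sum() + filt.attrs["n_non_whitelisted_reads"]
        assert total_seen == full.n_reads.sum()

    def test_min_rbc_exclusion_flag(self, clean_sim, design_index):
        rec = Q.compute_indel_rates(clean_sim["obs"], design_index, min_rbc=20)
        assert (rec.excluded == (rec.n_rbc < 20)).all()

    def test_unobserved_member_is_dropout(self, design_index, small_design):
        empty = pd.DataFrame(
            columns=["member_id", "rbc", "spacer_obs", "target_obs", "anchors_ok", "hamming_status"]
        )
        empty["anchors_ok"] = empty["anchors_ok"].astype(bool)
        rec = Q.compute_indel_rates(empty, design_index, min_rbc=0)
        assert len(rec) == len(small_design)
        assert (rec.n_reads == 0).all()
        assert rec.indel_rate.isna().all()


class TestOffOnRatios:
    def _records(self, small_design, rates: dict):
        rec = pd.DataFrame(
            {
                "member_id": list(rates),
                "n_rbc": 30,
                "n_reads": 100,
                "n_indel_reads": 0,
                "n_intact": 0,
                "n_discarded": 0,
                "indel_rate": list(rates.values()),
                "excluded": False,
            }
        )
        return rec

    def test_ratio_arithmetic(self, small_design):
        matched = small_design[small_design.category == "matched"].iloc[0]
        off = small_design[
            (small_design.category == "single_mismatch")
            & (small_design.spacer_length == matched.spacer_length)
        ].iloc[0]
        rec = self._records(
            small_design, {int(matched.member_id): 0.25, int(off.member_id): 0.05}
        )
        out = Q.off_on_ratios(rec, small_design)
        by = out.set_index("member_id")
        assert by.loc[int(off.member_id), "off_on_ratio"] == pytest.approx(0.20)
        assert by.loc[int(matched.member_id), "off_on_ratio"] == 1.0

    def test_low_on_target_group_gets_no_ratio(self, small_design):
        matched = small_design[small_design.category == "matched"].iloc[0]
        off = small_design[
            (small_design.category == "single_mismatch")
            & (small_design.spacer_length == matched.spacer_length)
        ].iloc[0]
        rec = self._records(
            small_design, {int(matched.member_id): 0.01, int(off.member_id): 0.005}
        )
        out = Q.off_on_ratios(rec, small_design)
        assert out["off_on_ratio"].isna().all()


@pytest.fixture(scope="module")
def dipped_screen(barcode_pool, tmp_path_factory):
    """Forward simulation where only position 5 is penalised (f = 0.5)."""
    out = tmp_path_factory.mktemp("dipped")
    groups = D.generate_spacer_groups(1, seed=21, lengths=(21,))
    lib = D.assemble_library(
        groups, D.uniform_plan(groups, ["matched", "single_mismatch"]), barcode_pool[:200], seed=21
    )
    design = D.library_to_frame(lib)
    L = 21
    f = np.ones((L, 12))
    f[4, :] = 0.5  # position 5, every mismatch type
    truth = S.GroundTruth(
        guide_activity={(0, L): 0.8},
        penalty={L: M.PenaltyMatrix(L, f)},
        bulge_penalty={"proximal": 0.05, "distal": 0.9},
    )
    cfg = S.SimConfig(
        seed=6, synthesis_error_rate=0, synthesis_indel_rate=0,
        sequencing_error_rate=0, integrations_per_member=150,
        integration_distribution="fixed", reads_per_rbc=1,
    )
    log = S.simulate_integrations(design, cfg)
    r1, r2 = out / "R1.fq.gz", out / "R2.fq.gz"
    S.simulate_reads(log, truth, design, 3, cfg, r1, r2)
    idx = Q.DesignIndex(design)
    obs, _ = Q.parse_fastq_pair(r1, r2, idx)
    rec = Q.compute_indel_rates(obs, idx, min_rbc=0)
    return design, Q.off_on_ratios(rec, design)


class TestAggregation:
    def test_dip_localised_to_penalised_position(self, dipped_screen):
        design, rates = dipped_screen
        agg = Q.aggregate_tolerance(rates, design, by=("position",))
        by_pos = agg.set_index("position")["mean_ratio"]
        assert by_pos.loc[5.0] == pytest.approx(0.5, abs=0.1)
        others = by_pos.drop(index=5.0)
        assert (others > 0.85).all()

    def test_counts_are_conserved(self, dipped_screen):
        design, rates = dipped_screen
        agg = Q.aggregate_tolerance(rates, design, by=("position", "length"))
        contributing = rates[
            rates.off_on_ratio.notna() & (rates.category == "single_mismatch")
        ]
        assert agg["n"].sum() == len(contributing)

    def test_single_member_stratum_mean(self, dipped_screen):
        design, rates = dipped_screen
        agg = Q.aggregate_tolerance(rates, design, by=("position", "mismatch_type"))
        ones = agg[agg.n == 1]
        assert not ones.empty
        assert ones.ci95_lo.isna().all()

    def test_unknown_key_rejected(self, dipped_screen):
        design, rates = dipped_screen
        with pytest.raises(ValueError):
            Q.aggregate_tolerance(rates, design, by=("chromosome",))


class TestReplicateConcordance:
    def _fake_records(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "member_id": np.arange(n),
                "n_rbc": rng.integers(1, 40, n),
                "indel_rate": rng.uniform(0, 1, n),
            }
        )

    def test_identical_replicates_have_unit_r2(self):
        rec = self._fake_records()
        out = Q.replicate_concordance(rec, rec)
        np.testing.assert_allclose(out.r_squared.dropna(), 1.0, atol=1e-9)

    def test_retained_fraction_non_increasing(self):
        a, b = self._fake_records(seed=1), self._fake_records(seed=2)
        out = Q.replicate_concordance(a, b)
        assert (out.retained_fraction.diff().dropna() <= 1e-12).all()

    def test_too_few_shared_members_absent(self):
        a, b = self._fake_records(n=2, seed=1), self._fake_records(n=2, seed=2)
        out = Q.replicate_concordance(a, b, thresholds=(1,))
        assert out.r_squared.isna().all()
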