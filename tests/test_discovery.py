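"""Tests of the five-filter cascade: audit trail, filter order, recovery."""

import numpy as np
import pandas as pd
import pytest

import methsig as m
from methsig.discovery import CascadeParams, FILTER_ORDER
from conftest import exact_ranksum_p


def _manifest(rows):
    return pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "gene", "gene_group",
                       "island_relation"]
    )


@pytest.fixture()
def threshold_fixture():
    """Three probes: one passes everything, one fails delta, one fails region."""
    manifest = _manifest(
        [
            ("cgA1", "chr1", 100, "GA", "TSS200", "Island"),
            ("cgA2", "chr1", 200, "GA", "TSS200", "Island"),
            ("cgA3", "chr1", 300, "GA", "TSS1500", "N_Shore"),
            ("cgB1", "chr2", 100, "GB", "TSS200", "Island"),
            ("cgC1", "chr3", 100, "GC", "Body", "OpenSea"),
        ]
    )
    r = {"cgA1": 0.10, "cgA2": 0.12, "cgA3": 0.11, "cgB1": 0.40, "cgC1": 0.10}
    nr = {"cgA1": 0.50, "cgA2": 0.55, "cgA3": 0.52, "cgB1": 0.50, "cgC1": 0.55}
    rng = np.random.default_rng(0)
    cols = {}
    for i in range(6):
        cols[f"R{i}"] = {p: np.clip(v + rng.normal(0, 0.02), 0, 1) for p, v in r.items()}
    for i in range(6):
        cols[f"N{i}"] = {p: np.clip(v + rng.normal(0, 0.02), 0, 1) for p, v in nr.items()}
    beta = pd.DataFrame(cols)
    beta.index.name = "probe_id"
    samples = pd.DataFrame(
        {
            "sample_id": list(cols),
            "cohort": "discovery",
            "rcb_class": [0] * 6 + [2] * 6,
            "response": ["R"] * 6 + ["NR"] * 6,
        }
    )
    return manifest, beta, samples


class TestProbeRecords:
    def test_constructed_means_and_direction(self, threshold_fixture):
        manifest, beta, samples = threshold_fixture
        rec = m.test_all_probes(beta, samples).set_index("probe_id")
        row = rec.loc["cgA1"]
        assert row["delta_beta"] == pytest.approx(
            row["mean_nr"] - row["mean_r"]
        )
        assert row["delta_beta"] == pytest.approx(0.40, abs=0.05)
        assert row["direction"] == "hyper_in_NR"

    def test_identical_groups_null(self):
        beta = pd.DataFrame(
            {f"S{i}": [0.5, 0.2] for i in range(8)},
            index=pd.Index(["p1", "p2"], name="probe_id"),
        )
        samples = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(8)], "cohort": "discovery",
             "rcb_class": [0] * 4 + [1] * 4,
             "response": ["R"] * 4 + ["NR"] * 4}
        )
        rec = m.test_all_probes(beta, samples)
        assert (rec["p_value"] == 1.0).all()
        assert (rec["delta_beta"] == 0.0).all()

    def test_p_matches_exact_enumeration(self, threshold_fixture):
        manifest, beta, samples = threshold_fixture
        rec = m.test_all_probes(beta, samples).set_index("probe_id")
        r_cols = samples.loc[samples["response"] == "R", "sample_id"]
        nr_cols = samples.loc[samples["response"] == "NR", "sample_id"]
        a = beta.loc["cgB1", r_cols].tolist()
        b = beta.loc["cgB1", nr_cols].tolist()
        assert rec.at["cgB1", "p_value"] == pytest.approx(exact_ranksum_p(a, b))

    def test_probe_missing_in_group_excluded(self, threshold_fixture):
        manifest, beta, samples = threshold_fixture
        beta = beta.copy()
        beta.loc["cgB1", samples.loc[samples["response"] == "R", "sample_id"]] = np.nan
        rec = m.test_all_probes(beta, samples).set_index("probe_id")
        assert not rec.at["cgB1", "tested"]
        assert rec.at["cgB1", "exclude_reason"] == "missing_in_entire_group"


class TestCascade:
    def test_first_failed_filter_tags(self, threshold_fixture):
        manifest, beta, samples = threshold_fixture
        rec = m.test_all_probes(beta, samples)
        res = m.apply_cascade(rec, manifest)
        tags = res.records.set_index("probe_id")["first_failed_filter"]
        assert (tags[["cgA1", "cgA2", "cgA3"]] == "none").all()
        assert tags["cgB1"] == "delta"  # |delta| = 0.10
        assert tags["cgC1"] == "region"  # OpenSea body probe
        assert res.candidates["gene"].tolist() == ["GA"]

    def test_counts_monotone_and_reconciled(self, threshold_fixture):
        manifest, beta, samples = threshold_fixture
        res = m.apply_cascade(m.test_all_probes(beta, samples), manifest)
        counts = [res.step_counts["tested"]] + [
            res.step_counts[s] for s in FILTER_ORDER
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        # every non-survivor carries exactly its first failing step
        tags = res.records["first_failed_filter"]
        assert (tags.isin(("none", "not_tested") + FILTER_ORDER)).all()
        assert (tags == "none").sum() == res.step_counts["consistency"]

    def test_degenerate_thresholds_keep_every_probe(self, threshold_fixture):
        manifest, beta, samples = threshold_fixture
        params = CascadeParams(
            p_alpha=1.0, delta_min=0.0, sd_max=np.inf,
            promoter_groups=frozenset(
                {"TSS1500", "TSS200", "5UTR", "1stExon", "Body"}
            ),
            island_relations=frozenset(
                {"Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"}
            ),
            min_concordant=0, zero_neighbors_pass=True,
        )
        rec = m.test_all_probes(beta, samples, params=params)
        res = m.apply_cascade(rec, manifest, params)
        assert res.step_counts["consistency"] == res.step_counts["tested"]

    def test_disabling_a_filter_never_loses_survivors(self, threshold_fixture):
        manifest, beta, samples = threshold_fixture
        rec = m.test_all_probes(beta, samples)
        strict = m.apply_cascade(rec, manifest)
        relaxed = m.apply_cascade(rec, manifest, CascadeParams(delta_min=0.0))
        assert relaxed.step_counts["consistency"] >= strict.step_counts["consistency"]

    def test_invariant_to_probe_and_sample_order(self, threshold_fixture):
        manifest, beta, samples = threshold_fixture
        rec1 = m.test_all_probes(beta, samples)
        shuffled = beta.iloc[::-1, ::-1]
        rec2 = m.test_all_probes(shuffled, samples.iloc[::-1])
        res1 = m.apply_cascade(rec1, manifest)
        res2 = m.apply_cascade(rec2, manifest)
        assert res1.step_counts == res2.step_counts
        pd.testing.assert_frame_equal(res1.candidates, res2.candidates)

    def test_multi_gene_probe_supports_both_genes(self):
        manifest = _manifest(
            [
                ("cg1", "chr1", 100, "LOCX;LEFY", "TSS200;TSS1500", "Island"),
                ("cg2", "chr1", 200, "LOCX;LEFY", "TSS200;TSS1500", "Island"),
                ("cg3", "chr1", 300, "LOCX;LEFY", "TSS200", "Island"),
            ]
        )
        rng = np.random.default_rng(1)
        cols = {
            **{f"R{i}": 0.1 + rng.normal(0, 0.02, 3) for i in range(6)},
            **{f"N{i}": 0.5 + rng.normal(0, 0.02, 3) for i in range(6)},
        }
        beta = pd.DataFrame(cols, index=pd.Index(["cg1", "cg2", "cg3"], name="probe_id"))
        samples = pd.DataFrame(
            {"sample_id": list(cols), "cohort": "discovery",
             "rcb_class": [0] * 6 + [1] * 6, "response": ["R"] * 6 + ["NR"] * 6}
        )
        res = m.apply_cascade(m.test_all_probes(beta, samples), manifest)
        assert sorted(res.candidates["gene"]) == ["LEFY", "LOCX"]
        assert (res.candidates["direction"] == "hyper_in_NR").all()


class TestConsistency:
    def _records(self, deltas):
        return pd.DataFrame(
            {
                "probe_id": list(deltas),
                "delta_beta": list(deltas.values()),
                "tested": True,
                "p_value": 0.01,
            }
        )

    def test_all_concordant_neighbors_pass(self):
        manifest = _manifest(
            [(f"cg{i}", "chr1", 100 + 100 * i, "G", "TSS200", "Island")
             for i in range(4)]
        )
        records = self._records(
            {"cg0": 0.30, "cg1": 0.25, "cg2": 0.18, "cg3": 0.12}
        )
        ok, report = m.consecutive_consistency("cg0", manifest, records)
        assert ok and len(report) == 3 and report["concordant"].all()

    def test_discordant_neighbors_fail(self):
        manifest = _manifest(
            [(f"cg{i}", "chr1", 100 + 100 * i, "G", "TSS200", "Island")
             for i in range(3)]
        )
        records = self._records({"cg0": 0.30, "cg1": -0.05, "cg2": 0.02})
        ok, report = m.consecutive_consistency("cg0", manifest, records)
        assert not ok and not report["concordant"].any()

    def test_zero_neighbors_fail_by_default(self):
        manifest = _manifest([("cg0", "chr1", 100, "G", "TSS200", "Island")])
        records = self._records({"cg0": 0.30})
        ok, report = m.consecutive_consistency("cg0", manifest, records)
        assert not ok and report.empty
        ok2, _ = m.consecutive_consistency(
            "cg0", manifest, records, CascadeParams(zero_neighbors_pass=True)
        )
        assert ok2

    def test_window_excludes_distant_probes(self):
        manifest = _manifest(
            [
                ("cg0", "chr1", 100, "G", "TSS200", "Island"),
                ("cg1", "chr1", 300, "G", "TSS200", "Island"),
                ("cg2", "chr1", 5000, "G", "Body", "OpenSea"),
            ]
        )
        records = self._records({"cg0": 0.30, "cg1": 0.25, "cg2": 0.30})
        _, report = m.consecutive_consistency("cg0", manifest, records)
        assert report["probe_id"].tolist() == ["cg1"]
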