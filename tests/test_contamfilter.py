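"""Cross-contamination filter: hand-computed cases and invariants."""

import numpy as np
import pandas as pd
import pytest

from pterochron.contamfilter import (
    FilterReport,
    TranscriptTable,
    apply_filter,
    enrichment_ratio,
    summarize_exclusions,
)
from pterochron.synthdata import ContaminationSpec, gen_contaminated_expression


def table(rows):
    return TranscriptTable(pd.DataFrame(
        rows,
        columns=["transcript_id", "dataset_id", "lane_id", "est_count", "tpm"],
    ))


TOY = table([
    ("T1", "A", 1, 9, 10.0), ("T1", "B", 1, 50, 30.0),
    ("T2", "A", 1, 1, 8.0), ("T2", "B", 1, 10, 4.0),
    ("T3", "A", 1, 9, 8.0), ("T3", "B", 1, 10, 4.0),
])


class TestEnrichmentRatio:
    def test_max_over_lane_mates(self):
        t = table([
            ("X", "A", 1, 5, 10.0), ("X", "B", 1, 5, 30.0), ("X", "C", 1, 5, 5.0),
        ])
        assert enrichment_ratio("X", "A", t) == pytest.approx(3.0)

    def test_no_lane_mates_zero(self):
        t = table([("W", "A", 1, 5, 3.0)])
        assert enrichment_ratio("W", "A", t) == 0.0

    def test_zero_focal_tpm_infinite(self):
        t = table([("Z", "A", 1, 0, 0.0), ("Z", "B", 1, 5, 2.0)])
        assert enrichment_ratio("Z", "A", t) == np.inf

    def test_absent_transcript_raises(self):
        with pytest.raises(KeyError):
            enrichment_ratio("nope", "A", TOY)


class TestApplyFilter:
    def test_toy_partition(self):
        reps = {r.dataset_id: r for r in apply_filter(TOY)}
        a = reps["A"]
        assert a.excluded_by_enrichment == ["T1"]  # 3-fold enriched in B
        assert a.excluded_by_count == ["T2"]  # count 1 < 2
        assert a.kept == ["T3"]

    def test_disabled_filter_keeps_all(self):
        reps = apply_filter(TOY, fold_threshold=np.inf, min_count=0)
        for r in reps:
            assert not r.excluded_by_enrichment and not r.excluded_by_count

    def test_lone_dataset_criterion1_vacuous(self):
        t = table([("T1", "A", 1, 5, 10.0), ("T2", "A", 1, 9, 2.0)])
        (r,) = apply_filter(t)
        assert not r.excluded_by_enrichment and r.n_total == 2

    def test_double_failure_attributed_to_enrichment(self):
        t = table([("T1", "A", 1, 0.5, 1.0), ("T1", "B", 1, 90, 50.0)])
        reps = {r.dataset_id: r for r in apply_filter(t)}
        assert reps["A"].excluded_by_enrichment == ["T1"]
        assert reps["A"].excluded_by_count == []

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_and_monotonicity_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        rows = []
        for d, lane in [("A", 1), ("B", 1), ("C", 2), ("D", 2)]:
            tpm = rng.lognormal(1, 1.5, n)
            ids = rng.choice(3 * n, size=n, replace=False)
            for i in range(n):
                rows.append((f"t{ids[i]}", d, lane, rng.exponential(5), tpm[i]))
        t = table(rows)
        reps = apply_filter(t)
        for r in reps:
            assert r.n_total == len(r.kept) + len(r.excluded_by_enrichment) + len(
                r.excluded_by_count
            )
        # raising the fold threshold never adds an enrichment exclusion
        strict = {r.dataset_id: set(r.excluded_by_enrichment) for r in reps}
        loose = {
            r.dataset_id: set(r.excluded_by_enrichment)
            for r in apply_filter(t, fold_threshold=5.0)
        }
        for d in strict:
            assert loose[d] <= strict[d]

    def test_synthetic_no_contamination_no_enrichment_exclusions(self):
        df = gen_contaminated_expression(
            ContaminationSpec(seed=4, n_datasets=4, n_transcripts=200,
                              library_size=100_000, contamination=0.0)
        )
        for r in apply_filter(TranscriptTable(df)):
            assert not r.excluded_by_enrichment


class TestSummaries:
    def test_median(self):
        def rep(d, k, e1, e2):
            return FilterReport(d, [f"k{i}" for i in range(k)],
                                [f"a{i}" for i in range(e1)],
                                [f"b{i}" for i in range(e2)])

        reps = [rep("A", 9, 1, 0), rep("B", 8, 2, 0), rep("C", 7, 3, 0)]
        m1, _ = summarize_exclusions(reps)
        assert m1 == pytest.approx(0.2)

    def test_single_report_is_identity(self):
        def rep(d, k, e1, e2):
            return FilterReport(d, ["x"] * k, ["y"] * e1, ["z"] * e2)

        m1, m2 = summarize_exclusions([rep("A", 6, 2, 2)])
        assert (m1, m2) == (0.2, 0.2)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_exclusions([])

    def test_synthetic_contamination_recall(self):
        """With 5% leakage the enrichment criterion recovers most injected
        contaminant rows (ground-truth labels are the oracle)."""
        df = gen_contaminated_expression(
            ContaminationSpec(seed=11, n_datasets=4, n_transcripts=400,
                              library_size=400_000, contamination=0.05)
        )
        reps = apply_filter(TranscriptTable(df))
        flagged = {
            (t, r.dataset_id)
            for r in reps
            for t in r.excluded_by_enrichment + r.excluded_by_count
        }
        contam = {
            (row.transcript_id, row.dataset_id)
            for row in df[df.is_contaminant].itertuples()
        }
        recall = len(flagged & contam) / len(contam)
        assert recall > 0.9
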