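"""Synthetic-data generator: determinism, sampling model, pipeline recovery."""
import logging

import numpy as np
import pytest

from fibropanel.classify import classify_variants
from fibropanel.io import read_annotations, read_variant_table, write_annotations, write_variant_table
from fibropanel.model import GENES, Population
from fibropanel.prevalence import panel_summaries
from fibropanel.simulate import (
    FounderSpec,
    GeneSiteCounts,
    SyntheticConfig,
    simulate_dataset,
)

P = Population


def _founder_only_config(seed, freq=0.004, n=10_000):
    return SyntheticConfig(
        seed=seed,
        populations={P.NFE: n},
        call_rate_range=(1.0, 1.0),
        genes={g: GeneSiteCounts(0, 0, 0, 0, 0, 0, 0) for g in GENES},
        founders=[FounderSpec("FGG", (P.NFE,), freq)],
    )


def test_same_seed_gives_identical_output():
    a = simulate_dataset(SyntheticConfig(seed=42))
    b = simulate_dataset(SyntheticConfig(seed=42))
    assert a[0] == b[0] and a[1] == b[1]
    c = simulate_dataset(SyntheticConfig(seed=43))
    assert c[0] != a[0]


def test_output_round_trips_through_io_without_warnings(tmp_path, caplog):
    records, annotations, _ = simulate_dataset(SyntheticConfig(seed=7))
    vpath, apath = tmp_path / "v.tsv", tmp_path / "a.tsv"
    write_variant_table(records, vpath)
    write_annotations(annotations, apath)
    with caplog.at_level(logging.WARNING, logger="fibropanel"):
        assert read_variant_table(vpath) == records
        assert read_annotations(apath) == annotations
    assert caplog.text == ""


def test_zero_deleterious_sites_give_zero_prevalence():
    config = SyntheticConfig(
        seed=1,
        genes={g: GeneSiteCounts(0, 0, 0, 0, 0, 0, benign=5) for g in GENES},
        founders=[],
        benign_consensus_rate=0.0,
    )
    records, annotations, truth = simulate_dataset(config)
    assert all(q == 0.0 for q in truth.dominant_q.values())
    summaries = panel_summaries(classify_variants(records, annotations))
    assert all(
        s.recessive_prevalence_per_1e6 == 0 and s.dominant_prevalence_per_1e3 == 0
        for s in summaries.values()
    )


def test_founder_allele_count_matches_binomial_mean():
    """E[ac] = 2N * f for a founder at frequency f with full call rate."""
    n, freq, n_seeds = 10_000, 0.004, 300
    acs = []
    for seed in range(n_seeds):
        records, _, _ = simulate_dataset(_founder_only_config(seed, freq, n))
        acs.append(records[0].counts[P.NFE].ac if records else 0)
    mean = np.mean(acs)
    expected = 2 * n * freq
    se = np.sqrt(2 * n * freq * (1 - freq) / n_seeds)
    assert abs(mean - expected) <= 3 * se


def test_allele_numbers_follow_call_rate():
    config = SyntheticConfig(seed=5, call_rate_range=(0.9, 0.95))
    records, _, _ = simulate_dataset(config)
    for r in records:
        for pop, n in config.populations.items():
            assert 2 * int(0.85 * n) <= r.counts[pop].an <= 2 * n


def test_common_allele_frequency_is_rejected():
    with pytest.raises(ValueError, match="0.5"):
        simulate_dataset(
            SyntheticConfig(seed=0, founders=[FounderSpec("FGG", (P.NFE,), 0.6)])
        )
    with pytest.raises(ValueError, match="0.5"):
        simulate_dataset(SyntheticConfig(seed=0, background_freq=0.7))


def test_truth_all_group_is_sample_size_weighted():
    config = SyntheticConfig(seed=2)
    _, _, truth = simulate_dataset(config)
    weights = {p: 2 * n for p, n in config.populations.items()}
    wsum = sum(weights.values())
    for gene in GENES:
        manual = sum(
            weights[p] * truth.recessive_q[(gene, p)] for p in config.populations
        ) / wsum
        assert truth.recessive_q[(gene, P.ALL)] == pytest.approx(manual, rel=1e-12)


def test_pipeline_recovers_true_collective_frequency():
    """With perfect predictor concordance, q-hat is the binomial MLE of q*."""
    config = SyntheticConfig(
        seed=9,
        populations={P.NFE: 100_000},
        call_rate_range=(1.0, 1.0),
        genes={"FGA": GeneSiteCounts(0, 0, 0, 0, 5, 0, 0),
               "FGB": GeneSiteCounts(0, 0, 0, 0, 0, 0, 0),
               "FGG": GeneSiteCounts(0, 0, 0, 0, 0, 0, 0)},
        background_freq=2e-4,
        founders=[],
        predictor_consensus_rate=1.0,
    )
    records, annotations, truth = simulate_dataset(config)
    classified = classify_variants(records, annotations)
    q_hat = sum(v.record.counts[P.NFE].ac for v in classified if v.recessive_eligible) / 200_000
    q_true = truth.recessive_q[("FGA", P.NFE)]
    assert q_true == pytest.approx(1e-3)
    # within 5 binomial standard deviations of the truth
    sd = np.sqrt(q_true / 200_000)
    assert abs(q_hat - q_true) < 5 * sd
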