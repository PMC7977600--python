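import numpy as np
import pandas as pd
import pytest

from mirarray import de_screen, normalization
from mirarray.errors import ConfigurationError, InputError
from mirarray.synthetic_data import (
    ArraySimConfig,
    DESpec,
    EnrichedTermSpec,
    QpcrDesign,
    generate_annotation_tables,
    generate_array_experiment,
    generate_prediction_tables,
    generate_qpcr_plate,
)
from mirarray.function_annotation import consensus_targets, enrich, normalize_symbol
from mirarray.qpcr import delta_delta_ct


class TestArrayGenerator:
    def test_seed_determinism(self):
        cfg = ArraySimConfig(seed=7)
        s1, t1 = generate_array_experiment(cfg)
        s2, t2 = generate_array_experiment(ArraySimConfig(seed=7))
        pd.testing.assert_frame_equal(s1, s2)
        assert t1.expressed_probes == t2.expressed_probes
        assert t1.de_status == t2.de_status
        assert t1.true_fold_change == t2.true_fold_change

    def test_no_signal_case(self):
        cfg = ArraySimConfig(n_probes=50, frac_expressed=0.0, seed=0)
        spots, truth = generate_array_experiment(cfg)
        matrix = normalization.collapse_replicates(spots)
        assert truth.expressed_probes == frozenset()
        assert (matrix < 50).all().all()
        acc = de_screen.accept_probes(matrix, "CR", "AL")
        assert len(acc.accepted) == 0

    def test_truth_consistency(self, default_experiment):
        cfg, _, truth = default_experiment
        for trt in cfg.treatments:
            for probe, status in truth.de_status[trt].items():
                assert probe in truth.expressed_probes
                fc = truth.fold_change(trt, probe)
                if status == "up":
                    assert fc >= 1.5
                else:
                    assert fc <= 2 / 3
            nulls = truth.expressed_probes - truth.de_probes(trt)
            assert all(truth.fold_change(trt, p) == 1.0 for p in nulls)

    def test_detection_consistency_noise_free(self):
        cfg = ArraySimConfig(
            n_probes=80,
            seed=3,
            background_sd=0.0,
            spot_noise_log2_sd=0.0,
            foreground_noise_sd=0.0,
        )
        spots, truth = generate_array_experiment(cfg)
        matrix = normalization.collapse_replicates(spots)
        detected = matrix.index[(matrix >= 50).any(axis=1)]
        assert set(detected) == set(truth.expressed_probes)

    def test_accepted_count_matches_configured_expectation(self, default_experiment):
        """Accepted probes ~ n_probes * frac_expressed (the study-like 330)."""
        cfg, spots, _ = default_experiment
        matrix = normalization.collapse_replicates(spots)
        accepted = matrix.index[(matrix >= 50).any(axis=1)]
        expectation = cfg.n_probes * cfg.frac_expressed  # ~330.6
        sd = np.sqrt(cfg.n_probes * cfg.frac_expressed * (1 - cfg.frac_expressed))
        assert abs(len(accepted) - expectation) <= 3 * sd

    def test_replicate_count_and_coverage(self, default_experiment):
        cfg, spots, _ = default_experiment
        counts = spots.groupby(["probe_id", "sample"]).size()
        assert (counts == cfg.n_replicate_spots).all()
        assert set(spots["sample"]) == set(cfg.groups)
        assert spots["probe_id"].nunique() == cfg.n_probes

    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_probes", 4),
            ("n_replicate_spots", 0),
            ("frac_expressed", 1.2),
            ("abundance_bias", 2.0),  # valid field, invalid companion below
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        if field == "abundance_bias":
            cfg = ArraySimConfig(de_spec={"CR": DESpec(frac_de=1.5, frac_up=0.5)})
            with pytest.raises(ConfigurationError, match="frac_de"):
                cfg.validate()
            return
        cfg = ArraySimConfig(**{field: value})
        with pytest.raises(ConfigurationError, match=field):
            cfg.validate()

    def test_de_concentrates_at_low_abundance(self):
        """With a strong bias weight, planted DE probes sit well below the
        abundance ranks of a no-bias run."""
        base = dict(n_probes=400, frac_expressed=0.8, seed=5)
        spec = {"HF": DESpec(frac_de=0.3, frac_up=0.5)}
        ranks = {}
        for bias in (0.0, 6.0):
            cfg = ArraySimConfig(abundance_bias=bias, de_spec=spec, **base)
            _, truth = generate_array_experiment(cfg)
            signal = pd.Series(truth.base_signal)
            expressed = sorted(truth.expressed_probes)
            order = signal[expressed].rank(pct=True)
            ranks[bias] = order[sorted(truth.de_probes("HF"))].mean()
        assert ranks[6.0] < ranks[0.0] - 0.1


class TestPredictionTables:
    mirnas = [f"mmu-miR-{i}" for i in range(1, 7)]
    genes = [f"Gene{i:03d}" for i in range(1, 121)]

    def test_forced_full_support_recovers_truth(self):
        tables, truth = generate_prediction_tables(self.mirnas, self.genes, {4: 1.0}, seed=2)
        consensus = consensus_targets(tables, min_support=3)
        expected = {m: {normalize_symbol(g) for g in gs} for m, gs in truth.items()}
        assert consensus == expected

    def test_forced_low_support_gives_empty_consensus(self):
        tables, _ = generate_prediction_tables(self.mirnas, self.genes, {2: 1.0}, seed=2)
        assert consensus_targets(tables, min_support=3) == {}

    def test_mixed_rates_match_brute_force_pair_counting(self):
        tables, truth = generate_prediction_tables(
            self.mirnas, self.genes, {4: 0.4, 3: 0.3, 2: 0.2, 1: 0.1}, seed=9
        )
        consensus = consensus_targets(tables, min_support=3)
        # oracle: count support for every (mirna, gene) pair exhaustively
        oracle: dict[str, set[str]] = {}
        for m in self.mirnas:
            for g in self.genes:
                support = sum((m, g) in t for t in tables.values())
                if support >= 3:
                    oracle.setdefault(m, set()).add(normalize_symbol(g))
        assert consensus == oracle
        # precision/recall vs planted truth, by the same exhaustive counting
        truth_pairs = {(m, normalize_symbol(g)) for m, gs in truth.items() for g in gs}
        called = {(m, g) for m, gs in consensus.items() for g in gs}
        assert called <= truth_pairs  # decoys never reach 3-of-4 support
        expected_recall = 0.7  # P(support >= 3) under the configured rates
        recall = len(called & truth_pairs) / len(truth_pairs)
        assert abs(recall - expected_recall) < 0.15

    def test_determinism_and_errors(self):
        t1, m1 = generate_prediction_tables(self.mirnas, self.genes, seed=4)
        t2, m2 = generate_prediction_tables(self.mirnas, self.genes, seed=4)
        assert t1 == t2 and m1 == m2
        with pytest.raises(InputError):
            generate_prediction_tables([], self.genes, seed=0)
        with pytest.raises(ConfigurationError):
            generate_prediction_tables(self.mirnas, self.genes, {5: 1.0}, seed=0)


class TestAnnotationTables:
    genes = [f"Gene{i:03d}" for i in range(1, 201)]

    def test_determinism(self):
        a1, t1 = generate_annotation_tables(self.genes, 8, seed=6)
        a2, t2 = generate_annotation_tables(self.genes, 8, seed=6)
        pd.testing.assert_frame_equal(a1, a2)
        assert t1 == t2

    def test_term_size_validation(self):
        with pytest.raises(InputError):
            generate_annotation_tables(self.genes, 3, term_size_range=(10, 500), seed=0)
        with pytest.raises(InputError):
            generate_annotation_tables(self.genes, 0, seed=0)

    def test_extreme_enrichment_attains_min_p(self):
        """A term equal to the selection itself beats every null term."""
        table, truth = generate_annotation_tables(self.genes, 10, seed=1, selection_size=30)
        sel = truth["selection"]
        extra = pd.DataFrame(
            {"term_id": "T9999", "term_name": "exact", "category": "BP", "gene": sel}
        )
        rows = enrich(sel, self.genes, pd.concat([table, extra], ignore_index=True))
        best = rows.loc[rows["p_value"].idxmin(), "term_id"]
        assert best == "T9999"

    def test_planted_term_is_overrepresented(self):
        table, truth = generate_annotation_tables(
            self.genes, 6, [EnrichedTermSpec(size=40, odds_ratio=12.0)], seed=3,
            selection_size=40,
        )
        rows = enrich(truth["selection"], self.genes, table).set_index("term_id")
        planted = truth["enriched_terms"][0]
        assert rows.loc[planted, "p_value"] == rows["p_value"].min()


class TestQpcrPlate:
    def design(self, fc, noise=0.0):
        return QpcrDesign(
            genes=("miR-x",),
            true_fold_change={"miR-x": fc},
            ct_noise_sd=noise,
        )

    def test_null_fold_changes_give_unit_rq(self):
        plate = generate_qpcr_plate(self.design({}), seed=0)
        rq = delta_delta_ct(plate, "miR-x", "U6", "AL")
        assert np.allclose(rq["rq"], 1.0)

    def test_planted_fc2_exact_without_noise(self):
        plate = generate_qpcr_plate(self.design({"CR": 2.0}), seed=0)
        rq = delta_delta_ct(plate, "miR-x", "U6", "AL")
        assert np.allclose(rq.loc[rq["group"] == "CR", "rq"], 2.0)
        assert np.allclose(rq.loc[rq["group"] == "AL", "rq"], 1.0)

    def test_noisy_plates_recover_fc_in_expectation(self):
        """noise sd 0.2, n=5: mean estimated RQ within 15% of the planted 2."""
        means = []
        for seed in range(200):
            plate = generate_qpcr_plate(self.design({"CR": 2.0}, noise=0.2), seed=seed)
            rq = delta_delta_ct(plate, "miR-x", "U6", "AL")
            means.append(rq.loc[rq["group"] == "CR", "rq"].mean())
        assert abs(np.mean(means) - 2.0) / 2.0 < 0.15

    def test_reference_validation(self):
        with pytest.raises(InputError):
            QpcrDesign(genes=("miR-x",), reference_gene="").validate()
        with pytest.raises(InputError):
            QpcrDesign(genes=("U6",), reference_gene="U6").validate()

    def test_determinism(self):
        d = self.design({"CR": 1.5}, noise=0.3)
        pd.testing.assert_frame_equal(
            generate_qpcr_plate(d, seed=5), generate_qpcr_plate(d, seed=5)
        )
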