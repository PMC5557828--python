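"""Synthetic genome/count generator and recovery scoring."""

import numpy as np
import pytest

from fragratio import (
    compute_ratios,
    enrich_scaffolds,
    masked_fraction,
    select_candidates,
    split_softmasked,
)
from fragratio.simulate import (
    SimConfig,
    SimTruth,
    evaluate_recovery,
    simulate_experiment,
    simulate_genome,
    simulate_pool_counts,
)


def class_means(records, truth):
    out = {}
    for cls in "AXY":
        vals = [r.r_norm for r in records
                if truth.fragment_class[r.fragment] == cls
                and r.r_norm is not None]
        out[cls] = float(np.mean(vals))
    return out


class TestSimulateGenome:
    def test_identical_seed_identical_genome(self):
        a, _ = simulate_genome(SimConfig(seed=42, n_auto=3, n_x=1, n_y=1))
        b, _ = simulate_genome(SimConfig(seed=42, n_auto=3, n_x=1, n_y=1))
        assert [(s.id, s.seq) for s in a] == [(s.id, s.seq) for s in b]

    def test_different_seed_different_genome(self):
        a, _ = simulate_genome(SimConfig(seed=1, n_auto=2, n_x=0, n_y=0))
        b, _ = simulate_genome(SimConfig(seed=2, n_auto=2, n_x=0, n_y=0))
        assert any(x.seq != y.seq for x, y in zip(a, b))

    def test_zero_repeat_density_means_single_fragment_scaffolds(self):
        cfg = SimConfig(seed=3, n_auto=4, n_x=0, n_y=0, repeat_density=0.0)
        scaffolds, _ = simulate_genome(cfg)
        for sc in scaffolds:
            frags = split_softmasked(sc)
            assert len(frags) == 1
            assert frags[0].length == len(sc.seq)

    def test_y_scaffolds_carry_more_repeats(self, default_sim):
        truth = default_sim["truth"]
        by_class = {c: [s for s in default_sim["scaffolds"]
                        if truth.scaffold_class[s.id] == c] for c in "AY"}
        y_frac = masked_fraction(by_class["Y"])
        genome_frac = masked_fraction(default_sim["scaffolds"])
        assert y_frac > genome_frac
        # densities land near their configured targets
        assert y_frac == pytest.approx(0.3071, abs=0.05)
        assert genome_frac == pytest.approx(0.19, abs=0.05)

    def test_class_labels_cover_all_scaffolds(self, default_sim):
        truth = default_sim["truth"]
        counts = {c: sum(v == c for v in truth.scaffold_class.values())
                  for c in "AXY"}
        assert counts == {"A": 50, "X": 5, "Y": 5}

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(scaffold_len_range=(100, 150))
        with pytest.raises(ValueError):
            SimConfig(leakage=1.5)


class TestSimulatePoolCounts:
    def test_y_fragments_get_no_female_reads_without_leakage(self, default_sim):
        truth, table = default_sim["truth"], default_sim["table"]
        y_rows = [n for n, c in truth.fragment_class.items() if c == "Y"]
        assert int(table.rows.loc[y_rows, "F"].sum()) == 0

    def test_leakage_raises_y_ratio(self):
        base = SimConfig(seed=11, n_auto=20, n_x=2, n_y=5)
        leaky = SimConfig(seed=11, n_auto=20, n_x=2, n_y=5, leakage=0.5)
        means = {}
        for cfg in (base, leaky):
            _, _, truth, table = simulate_experiment(cfg)
            recs = compute_ratios(table)
            means[cfg.leakage] = class_means(recs, truth)["Y"]
        assert means[0.5] > means[0.0]

    def test_expected_counts_conserve_total_depth(self, default_sim):
        """Sum of generative means equals depth x copy-weighted fragment
        mass / read length for each pool."""
        cfg, truth = default_sim["config"], default_sim["truth"]
        frags = default_sim["fragments"]
        copies_m = {"A": 2, "X": 1, "Y": 1}
        copies_f = {"A": 2, "X": 2, "Y": 0}
        want_f = want_m = 0.0
        for f in frags:
            cls = truth.scaffold_class[f.scaffold_id]
            want_m += cfg.depth_m * copies_m[cls] / 2 * f.length / cfg.read_len
            want_f += cfg.depth_f * copies_f[cls] / 2 * f.length / cfg.read_len
        got_f = sum(v[0] for v in truth.expected_counts.values())
        got_m = sum(v[1] for v in truth.expected_counts.values())
        assert got_f == pytest.approx(want_f, rel=1e-9)
        assert got_m == pytest.approx(want_m, rel=1e-9)

    def test_overdispersion_inflates_variance(self):
        cfg_p = SimConfig(seed=5, n_auto=30, n_x=0, n_y=0)
        cfg_nb = SimConfig(seed=5, n_auto=30, n_x=0, n_y=0,
                           overdispersion=0.5)
        var = {}
        for cfg in (cfg_p, cfg_nb):
            _, _, truth, table = simulate_experiment(cfg)
            resid = (table.rows["M"] - np.array(
                [truth.expected_counts[n][1] for n in table.rows.index]))
            var[cfg.overdispersion] = float(np.var(resid))
        assert var[0.5] > 2 * var[None]

    def test_count_determinism_end_to_end(self):
        t1 = simulate_experiment(SimConfig(seed=9, n_auto=5, n_x=1, n_y=1))
        t2 = simulate_experiment(SimConfig(seed=9, n_auto=5, n_x=1, n_y=1))
        assert t1[3].rows.equals(t2[3].rows)


class TestRecovery:
    def test_perfect_separation_regime(self, default_pipeline):
        report = evaluate_recovery(default_pipeline["enrichments"],
                                   default_pipeline["candidates"],
                                   default_pipeline["truth"])
        assert report.scaffold_sensitivity == 1.0
        assert report.scaffold_fdr == 0.0
        assert report.fragment_confusion["A"]["called_y"] == 0
        assert report.fragment_sensitivity() == 1.0

    def test_leakage_lowers_fragment_sensitivity(self):
        sens = {}
        for leakage in (0.0, 0.5):
            cfg = SimConfig(seed=21, n_auto=20, n_x=2, n_y=5, leakage=leakage)
            _, _, truth, table = simulate_experiment(cfg)
            recs = compute_ratios(table)
            cands = select_candidates(recs)
            enr = enrich_scaffolds(recs, cands)
            sens[leakage] = evaluate_recovery(
                enr, cands, truth).fragment_sensitivity()
        assert sens[0.5] < sens[0.0]

    def test_sensitivity_non_increasing_as_alpha_shrinks(self, default_pipeline):
        enr = default_pipeline["enrichments"]
        cands = default_pipeline["candidates"]
        truth = default_pipeline["truth"]
        sens = [evaluate_recovery(enr, cands, truth, alpha=a)
                .scaffold_sensitivity
                for a in (1e-2, 1e-5, 1e-30, 1e-300)]
        assert sens == sorted(sens, reverse=True)

    def test_truth_universe_mismatch_rejected(self, default_pipeline):
        truth = SimTruth(scaffold_class={"Sca1": "A"},
                         fragment_class={"Sca1_1_300": "A"})
        with pytest.raises(ValueError, match="not covered"):
            evaluate_recovery(default_pipeline["enrichments"],
                              default_pipeline["candidates"], truth)
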