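import io as stdio

import numpy as np
import pandas as pd
import pytest

from grnpipe import design, qpcr, synthetic
from grnpipe.motifs import PWM


class TestGeneratePlantedNetwork:
    def test_minimal_network(self):
        net = synthetic.generate_planted_network(1, 1, 0, 1.0, seed=7)
        assert len(net.edges) == 1
        assert net.edges[0].sign in (-1, 1)
        again = synthetic.generate_planted_network(1, 1, 0, 1.0, seed=7)
        assert net.edges == again.edges

    def test_cardinality_contract(self):
        net = synthetic.generate_planted_network(3, 12, 20, 1.0, seed=42)
        assert len(net.tf_ids) == 3
        assert len(net.target_ids) == 12
        assert len(net.null_ids) == 20
        regulated = {e.target for e in net.edges}
        assert regulated == set(net.target_ids)

    def test_determinism(self):
        a = synthetic.generate_planted_network(2, 5, 3, 1.5, seed=9)
        b = synthetic.generate_planted_network(2, 5, 3, 1.5, seed=9)
        assert a.edges == b.edges and a.tf_region_effect == b.tf_region_effect

    def test_at_least_one_repressive_edge(self):
        net = synthetic.generate_planted_network(3, 12, 0, 1.0, seed=5)
        assert any(e.sign == -1 for e in net.edges)
        assert len(net.repressed_targets) >= 1

    @pytest.mark.parametrize(
        "args", [(0, 1, 0, 1.0), (1, 0, 0, 1.0), (1, 1, -1, 1.0), (1, 1, 0, 0.0)]
    )
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            synthetic.generate_planted_network(*args, seed=1)

    def test_overlapping_regulation_mode(self):
        net = synthetic.generate_planted_network(3, 12, 0, 1.0, seed=1, reg_prob=0.8)
        per_target = pd.Series([e.target for e in net.edges]).value_counts()
        assert per_target.max() > 1  # at least one multiply-regulated target


class TestSimulateExpression:
    def test_degenerate_no_noise_no_effect(self):
        net = synthetic.generate_planted_network(1, 2, 1, 1.0, seed=1)
        for tf in net.tf_region_effect:
            net.tf_region_effect[tf] = {
                k: 0.0 for k in net.tf_region_effect[tf]
            }
        cfg = synthetic.SimulationConfig(
            seed=1, expr_noise_sd=0.0, replicate_sd=0.0
        )
        expr = synthetic.simulate_expression(net, cfg)
        for _gene, sub in expr.groupby("gene"):
            assert sub["log2_expr"].nunique() == 1

    def test_single_edge_effect_is_exact(self):
        net = synthetic.generate_planted_network(1, 1, 0, 1.0, seed=2)
        cfg = synthetic.SimulationConfig(seed=2, expr_noise_sd=0.0, replicate_sd=0.0)
        expr = synthetic.simulate_expression(net, cfg)
        edge = net.edges[0]
        sub = expr[expr["gene"] == edge.target]
        is_l = sub["region"].map(design.is_l_region)
        diff = sub[is_l]["log2_expr"].mean() - sub[~is_l]["log2_expr"].mean()
        assert diff == pytest.approx(edge.sign * edge.weight, abs=1e-12)

    def test_null_genes_carry_no_region_effect(self):
        net = synthetic.generate_planted_network(2, 3, 2, 2.0, seed=4)
        cfg = synthetic.SimulationConfig(seed=4, expr_noise_sd=0.0, replicate_sd=0.0)
        expr = synthetic.simulate_expression(net, cfg)
        for null in net.null_ids:
            assert expr[expr["gene"] == null]["log2_expr"].nunique() == 1

    def test_monte_carlo_mean_matches_planted_effect(self):
        """Empirical L-S mean of regulated targets within 3 SE of the effect."""
        diffs = []
        for seed in range(20):
            net = synthetic.generate_planted_network(2, 4, 0, 1.0, seed=seed)
            cfg = synthetic.SimulationConfig(seed=seed, expr_noise_sd=0.3)
            expr = synthetic.simulate_expression(net, cfg)
            for edge in net.edges:
                sub = expr[expr["gene"] == edge.target]
                is_l = sub["region"].map(design.is_l_region)
                d = sub[is_l]["log2_expr"].mean() - sub[~is_l]["log2_expr"].mean()
                diffs.append(d * edge.sign)  # orient repressed targets
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - 1.0) <= 3 * se


class TestExpressionToCq:
    def test_doubling_expression_lowers_cq_by_one(self, ref_genes):
        net = synthetic.generate_planted_network(1, 1, 0, 1.0, seed=6)
        cfg = synthetic.SimulationConfig(
            seed=6, noise_sd_cq=0.0, expr_noise_sd=0.0,
            replicate_sd=0.0, ref_noise_sd=0.0,
        )
        expr = synthetic.simulate_expression(net, cfg)
        doubled = expr.copy()
        doubled["log2_expr"] += 1.0
        p0 = synthetic.expression_to_cq(expr, cfg, ref_genes)
        p1 = synthetic.expression_to_cq(doubled, cfg, ref_genes)
        t0 = p0[~p0["is_reference"]]["cq"].to_numpy()
        t1 = p1[~p1["is_reference"]]["cq"].to_numpy()
        np.testing.assert_allclose(t0 - t1, 1.0, atol=1e-12)

    def test_requires_reference_genes(self):
        net = synthetic.generate_planted_network(1, 1, 0, 1.0, seed=6)
        cfg = synthetic.SimulationConfig(seed=6)
        expr = synthetic.simulate_expression(net, cfg)
        with pytest.raises(ValueError):
            synthetic.expression_to_cq(expr, cfg, [])

    def test_twofold_effect_recovered_at_default_noise(self, ref_genes):
        """Median RQ estimate of a planted 2-fold L/S effect in [1.8, 2.2]."""
        ratios = []
        for seed in range(20):
            net = synthetic.generate_planted_network(1, 3, 0, 1.0, seed=seed)
            cfg = synthetic.SimulationConfig(seed=seed)
            expr = synthetic.simulate_expression(net, cfg)
            plate = synthetic.expression_to_cq(expr, cfg, ref_genes)
            rq = qpcr.relative_quantities(plate, ref_genes)
            for edge in net.edges:
                if edge.sign < 0:
                    continue
                sub = rq[rq["gene"] == edge.target]
                is_l = sub["region"].map(design.is_l_region)
                ratios.append(
                    2.0 ** (sub[is_l]["log_rq"].mean() - sub[~is_l]["log_rq"].mean())
                )
        assert 1.8 <= float(np.median(ratios)) <= 2.2


class TestGeneratePwmLibrary:
    def test_high_ic_gives_near_consensus_columns(self):
        lib = synthetic.generate_pwm_library(5, (8, 10), 2.0, seed=1)
        for pwm in lib:
            assert pwm.matrix.max(axis=1).min() > 0.99

    def test_zero_ic_gives_near_uniform_columns(self):
        lib = synthetic.generate_pwm_library(5, (8, 10), 0.0, seed=1)
        for pwm in lib:
            np.testing.assert_allclose(pwm.matrix, 0.25, atol=0.01)

    def test_columns_sum_to_one(self):
        lib = synthetic.generate_pwm_library(10, (6, 12), 1.5, seed=2)
        for pwm in lib:
            np.testing.assert_allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_requested_information_content_is_hit(self):
        lib = synthetic.generate_pwm_library(5, (8, 8), 1.5, seed=3)
        for pwm in lib:
            raw = PWM(id=pwm.id, matrix=pwm.matrix, pseudocount=0.0)
            assert raw.information_content() == pytest.approx(1.5, abs=0.02)

    def test_tf_ids_lead_the_library(self):
        lib = synthetic.generate_pwm_library(5, (8, 10), 1.8, seed=4,
                                             tf_ids=("tf01", "tf02"))
        assert [p.id for p in lib[:2]] == ["tf01", "tf02"]
        assert len(lib) == 5

    def test_width_range_validated(self):
        with pytest.raises(ValueError):
            synthetic.generate_pwm_library(5, (2, 10), 1.8, seed=1)
        with pytest.raises(ValueError):
            synthetic.generate_pwm_library(5, (8, 30), 1.8, seed=1)


class TestGeneratePromoters:
    def _setup(self, seed=1, **cfg_kwargs):
        net = synthetic.generate_planted_network(1, 1, 1, 1.0, seed=seed)
        cfg = synthetic.SimulationConfig(seed=seed, promoter_length=500, **cfg_kwargs)
        lib = synthetic.generate_pwm_library(3, (8, 8), 1.9, seed=seed,
                                             tf_ids=tuple(net.tf_ids))
        return net, cfg, lib

    def test_planted_site_scores_at_least_as_well_as_sampled_site(self):
        net, cfg, lib = self._setup(seed=8)
        records, planted = synthetic.generate_promoters(net, lib, cfg, plant_rate=1.0)
        assert len(planted) == len(net.edges)
        pwm = lib[0]
        seqs = {r.id: str(r.seq) for r in records}
        for row in planted.itertuples(index=False):
            target_score = pwm.score_word(row.site)
            best = max(
                pwm.score_word(seqs[row.gene][i : i + pwm.width])
                for i in range(len(seqs[row.gene]) - pwm.width + 1)
            )
            best_rc = max(
                pwm.reverse_complement().score_word(
                    seqs[row.gene][i : i + pwm.width]
                )
                for i in range(len(seqs[row.gene]) - pwm.width + 1)
            )
            assert max(best, best_rc) >= target_score - 1e-9

    def test_plant_rate_zero_is_pure_background(self):
        net, cfg, lib = self._setup(seed=9)
        records, planted = synthetic.generate_promoters(net, lib, cfg, plant_rate=0.0)
        assert planted.empty
        assert len(records) == len(net.genes)

    def test_record_count_covers_all_genes(self):
        net = synthetic.generate_planted_network(2, 5, 7, 1.0, seed=10)
        cfg = synthetic.SimulationConfig(seed=10, promoter_length=300)
        lib = synthetic.generate_pwm_library(4, (8, 8), 1.8, seed=10,
                                             tf_ids=tuple(net.tf_ids))
        records, _ = synthetic.generate_promoters(net, lib, cfg)
        assert len(records) == 2 + 5 + 7
        assert all(len(r.seq) == 300 for r in records)

    def test_missing_tf_pwm_is_configuration_error(self):
        net, cfg, _ = self._setup(seed=11)
        distractors = synthetic.generate_pwm_library(2, (8, 8), 1.8, seed=11)
        with pytest.raises(KeyError, match="tf01"):
            synthetic.generate_promoters(net, distractors, cfg)


class TestBuildCoexpressionDb:
    def test_compendium_too_small_rejected(self):
        net = synthetic.generate_planted_network(1, 2, 0, 1.0, seed=1)
        cfg = synthetic.SimulationConfig(seed=1, compendium_size=49)
        with pytest.raises(ValueError, match="compendium"):
            synthetic.build_coexpression_db(net, cfg)

    def test_shared_tf_targets_are_mutual_top_neighbors(self):
        # one TF, two activated targets, low noise: brute-force check
        net = synthetic.generate_planted_network(1, 3, 4, 1.0, seed=2)
        cfg = synthetic.SimulationConfig(seed=2, compendium_noise_sd=0.2)
        db = synthetic.build_coexpression_db(net, cfg)
        activated = [t for t in net.target_ids if t not in net.repressed_targets]
        a, b = activated[:2]
        nb = {x.gene: x for x in db.neighbors(a)}
        assert nb[b].correlation > 0.5
        assert db.neighbors(a)[0].gene in (b, net.tf_ids[0])
        assert nb[b].supportability >= 1

    def test_supportability_bounded_by_batches(self):
        net = synthetic.generate_planted_network(2, 4, 4, 1.0, seed=3)
        cfg = synthetic.SimulationConfig(seed=3, compendium_batches=4)
        db = synthetic.build_coexpression_db(net, cfg)
        for gene in db.genes():
            for nb in db.neighbors(gene):
                assert 0 <= nb.supportability <= 4

    def test_null_supportability_is_zero(self):
        """A null gene never earns supportability with regulated genes."""
        clean = 0
        n_seeds = 20
        for seed in range(n_seeds):
            net = synthetic.generate_planted_network(2, 6, 8, 1.0, seed=seed)
            cfg = synthetic.SimulationConfig(seed=seed)
            db = synthetic.build_coexpression_db(net, cfg)
            regulated = set(net.tf_ids) | set(net.target_ids)
            null = net.null_ids[0]
            supports = [
                nb.supportability for nb in db.neighbors(null) if nb.gene in regulated
            ]
            if max(supports) == 0:
                clean += 1
        assert clean >= 0.9 * n_seeds

    def test_correlations_match_brute_force_recomputation(self):
        """Neighbor correlations equal an independent corrcoef on the compendium."""
        net = synthetic.generate_planted_network(1, 2, 2, 1.0, seed=5)
        cfg = synthetic.SimulationConfig(seed=5)
        db = synthetic.build_coexpression_db(net, cfg)
        # reproduce the compendium from the same seeded stream
        rng = np.random.default_rng([5, cfg.seed])
        genes = net.genes
        w = np.zeros((len(genes), len(net.tf_ids)))
        pos = {g: i for i, g in enumerate(genes)}
        for i, tf in enumerate(net.tf_ids):
            w[pos[tf], i] = 1.0
        for e in net.edges:
            w[pos[e.target], i] += e.sign * e.weight
        acts = rng.normal(0.0, 1.0, size=(len(net.tf_ids), cfg.compendium_size))
        noise = rng.normal(0.0, cfg.compendium_noise_sd,
                           size=(len(genes), cfg.compendium_size))
        corr = np.corrcoef(w @ acts + noise)
        for gene in genes:
            for nb in db.neighbors(gene):
                assert nb.correlation == pytest.approx(
                    corr[pos[gene], pos[nb.gene]], abs=1e-12
                )


class TestDeterminism:
    def test_identical_seeds_give_identical_artifacts(self, ref_genes):
        outputs = []
        for _ in range(2):
            net = synthetic.generate_planted_network(2, 4, 3, 1.0, seed=77)
            cfg = synthetic.SimulationConfig(seed=77, promoter_length=200)
            expr = synthetic.simulate_expression(net, cfg)
            plate = synthetic.expression_to_cq(expr, cfg, ref_genes)
            lib = synthetic.generate_pwm_library(4, (8, 8), 1.8, seed=77,
                                                 tf_ids=tuple(net.tf_ids))
            records, planted = synthetic.generate_promoters(net, lib, cfg)
            db = synthetic.build_coexpression_db(net, cfg)
            buf = stdio.StringIO()
            plate.to_csv(buf, sep="\t", index=False)
            db.to_frame().to_csv(buf, sep="\t", index=False)
            planted.to_csv(buf, sep="\t", index=False)
            for rec in records:
                buf.write(f">{rec.id}\n{rec.seq}\n")
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]
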