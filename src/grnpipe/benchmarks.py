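"""Recovery benchmarks on planted synthetic data.

Each function runs the relevant pipeline stages from scratch on freshly
generated synthetic inputs and measures how well the planted ground truth
is recovered. They are used by the acceptance test-suite and by
``scripts/acceptance.py``; all randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import design, synthetic
from .consistency import consistency_call, paired_lvs_tests
from .motifs import (
    discover_motifs,
    filter_shared_motifs,
    match_motif_to_library,
    nominate_tfs,
)
from .network import build_network, pairwise_correlations
from .qpcr import relative_quantities
from .stepwise import run_stepwise

REF_GENES = ["ref1", "ref2"]


def _verdict_for(direction: str) -> str:
    return design.CONSISTENT_L if direction == design.HIGHER_L else design.CONSISTENT_S


def _quantify(net, cfg):
    expr = synthetic.simulate_expression(net, cfg)
    plate = synthetic.expression_to_cq(expr, cfg, REF_GENES)
    rq = relative_quantities(plate, REF_GENES)
    return plate, rq


# ---------------------------------------------------------------------------
# criterion: type-I control of the screen


def null_screen_rates(n_null: int = 500, seed: int = 0) -> dict:
    """Paired-t rejection rate and consistency false-call rate on null genes."""
    net = synthetic.generate_planted_network(1, 1, n_null, 1.0, seed=seed)
    cfg = synthetic.SimulationConfig(seed=seed)
    _plate, rq = _quantify(net, cfg)
    rq_null = rq[rq["gene"].isin(net.null_ids)]
    sig = paired_lvs_tests(rq_null)
    report = consistency_call(sig)
    return {
        "paired_t_rejection_rate": float((sig["p"] < 0.05).mean()),
        "null_consistent_fraction": float(
            (report["verdict"] != design.INCONSISTENT).mean()
        ),
        "n_tests": int(len(sig)),
        "n_genes": int(len(report)),
    }


# ---------------------------------------------------------------------------
# criterion: screen power at the pinned parameters


def screen_power(
    n_seeds: int = 20,
    effect: float = 1.0,
    noise_sd_cq: float = 0.25,
    seed: int = 0,
) -> dict:
    """Fraction of regulated targets called consistent with planted direction."""
    called = total = 0
    for k in range(n_seeds):
        net = synthetic.generate_planted_network(3, 12, 5, effect, seed=seed + k)
        cfg = synthetic.SimulationConfig(seed=seed + k, noise_sd_cq=noise_sd_cq)
        _plate, rq = _quantify(net, cfg)
        sig = paired_lvs_tests(rq[rq["gene"].isin(net.target_ids)])
        report = consistency_call(sig)
        verdicts = dict(zip(report["gene"], report["verdict"]))
        for target in net.target_ids:
            planted = net.planted_direction(target)
            if planted is None:
                continue
            total += 1
            if verdicts.get(target) == _verdict_for(planted):
                called += 1
    return {"recovery": called / total, "n_targets": total}


# ---------------------------------------------------------------------------
# criterion: stepwise extension


def stepwise_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Target recovery and decoy admission of the full stepwise procedure."""
    recovered = target_total = admitted = decoy_total = 0
    for k in range(n_seeds):
        net = synthetic.generate_planted_network(3, 12, 20, 2.0, seed=seed + k)
        cfg = synthetic.SimulationConfig(seed=seed + k)
        expr = synthetic.simulate_expression(net, cfg)
        plate = synthetic.expression_to_cq(expr, cfg, REF_GENES)
        db = synthetic.build_coexpression_db(net, cfg)
        by_tf: dict[str, str] = {}
        for e in net.edges:
            if e.sign > 0 and e.tf not in by_tf:
                by_tf[e.tf] = e.target
        seeds = [by_tf[tf] for tf in sorted(by_tf)]
        result = run_stepwise(seeds, db, plate)
        final = set(result.final["gene"])
        recovered += len(final & set(net.target_ids))
        target_total += len(net.target_ids)
        admitted += len(final & set(net.null_ids))
        decoy_total += len(net.null_ids)
    return {
        "target_recovery": recovered / target_total,
        "decoy_admission": admitted / decoy_total,
        "n_targets": target_total,
        "n_decoys": decoy_total,
    }


# ---------------------------------------------------------------------------
# criterion: motif recovery and null control


def _planted_promoter_set(seed: int, n: int = 12, length: int = 600,
                          site_in: int = 11):
    lib = synthetic.generate_pwm_library(
        6, (8, 8), info_content=1.9, seed=seed, tf_ids=("planted",)
    )
    pwm = lib[0]
    rng = np.random.default_rng([7, seed])
    from .motifs import BASES, reverse_complement

    seqs = {}
    for i in range(n):
        seq = list(rng.choice(list(BASES), size=length))
        if i < site_in:
            pos = int(rng.integers(0, length - pwm.width))
            site = pwm.sample_site(rng)
            if rng.random() < 0.5:
                site = reverse_complement(site)
            seq[pos : pos + pwm.width] = list(site)
        seqs[f"g{i}"] = "".join(seq)
    return seqs, pwm, lib


def motif_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Planted 8-mer discovery rate and the null (background-only) clean rate."""
    hits = 0
    for k in range(n_seeds):
        seqs, pwm, lib = _planted_promoter_set(seed + k)
        found = discover_motifs(seqs, widths=range(6, 11), top_m=10)
        shared = filter_shared_motifs(found, len(seqs), 0.5)
        ok = False
        for motif in shared:
            preds = match_motif_to_library(motif.pwm, lib)
            planted_score = next(p.score for p in preds if p.tf_id == "planted")
            if planted_score >= 0.8:
                ok = True
                break
        hits += ok

    clean = 0
    for k in range(n_seeds):
        rng = np.random.default_rng([8, seed + k])
        seqs = {
            f"g{i}": "".join(rng.choice(list("ACGT"), size=600)) for i in range(12)
        }
        found = discover_motifs(seqs, widths=range(6, 11), top_m=10)
        shared = filter_shared_motifs(found, 12, 0.5)
        clean += not shared
    return {
        "planted_recovery_rate": hits / n_seeds,
        "null_clean_rate": clean / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# criterion: end-to-end TF nomination


def end_to_end_nomination(n_seeds: int = 10, seed: int = 0) -> dict:
    """TF shortlist recovery and the repressed-target binding-site report."""
    tf_hits = tf_total = 0
    repressed_reported = repressed_total = 0
    for k in range(n_seeds):
        net = synthetic.generate_planted_network(
            3, 12, 6, 2.0, seed=seed + k, reg_prob=0.9
        )
        cfg = synthetic.SimulationConfig(
            seed=seed + k, promoter_length=1000, plant_rate=0.95, sites_per_edge=3
        )
        library = synthetic.generate_pwm_library(
            20, (8, 10), info_content=1.9, seed=seed + k, tf_ids=tuple(net.tf_ids)
        )
        promoters, _planted = synthetic.generate_promoters(net, library, cfg)
        _plate, rq = _quantify(net, cfg)
        sig = paired_lvs_tests(rq)
        report = consistency_call(sig)
        verdicts = dict(zip(report["gene"], report["verdict"]))
        seqs = {r.id: str(r.seq) for r in promoters}
        l_up = [
            g for g, v in verdicts.items()
            if v == design.CONSISTENT_L and g in seqs
        ]
        found = discover_motifs({g: seqs[g] for g in l_up},
                                widths=range(6, 11), top_m=10)
        shared = filter_shared_motifs(found, len(l_up), 0.5)
        nomination = nominate_tfs(shared, library, report, promoters=seqs)
        shortlist = set(nomination.shortlist["tf"])
        for tf in net.tf_ids:
            tf_total += 1
            tf_hits += tf in shortlist
        for target in net.repressed_targets:
            regulator = {e.tf for e in net.edges if e.target == target}
            repressed_total += 1
            sites = nomination.repressed_gene_sites
            mask = (sites["gene"] == target) & sites["tf"].isin(regulator)
            repressed_reported += bool(mask.any())
    return {
        "tf_shortlist_rate": tf_hits / tf_total,
        "repressed_site_rate": repressed_reported / max(repressed_total, 1),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# criterion: network recovery


def network_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Power and sign accuracy for co-regulated pairs; decoy false-edge rate."""
    pair_hits = pair_total = 0
    false_edges = decoy_pairs = 0
    alpha = 0.01
    for k in range(n_seeds):
        net = synthetic.generate_planted_network(3, 12, 10, 2.0, seed=seed + k)
        cfg = synthetic.SimulationConfig(seed=seed + k)
        _plate, rq = _quantify(net, cfg)
        genes = net.target_ids + net.null_ids
        pooled = pairwise_correlations(rq, genes, scope="pooled")
        per_fin = pairwise_correlations(rq, genes, scope="per-fin")
        edges = build_network(pooled, per_fin, alpha, alpha)
        edge_sign = {
            (e.gene_a, e.gene_b): e.sign for e in edges
        }

        sign_of = {}
        for e in net.edges:
            sign_of.setdefault(e.target, {})[e.tf] = e.sign
        targets = net.target_ids
        for i, a in enumerate(targets):
            for b in targets[i + 1 :]:
                shared = set(sign_of.get(a, {})) & set(sign_of.get(b, {}))
                if not shared:
                    continue
                tf = sorted(shared)[0]
                expected = sign_of[a][tf] * sign_of[b][tf]
                pair_total += 1
                key = (min(a, b), max(a, b))
                if key in edge_sign and edge_sign[key] == expected:
                    pair_hits += 1
        nulls = net.null_ids
        for i, a in enumerate(nulls):
            for b in nulls[i + 1 :]:
                decoy_pairs += 1
                if (min(a, b), max(a, b)) in edge_sign:
                    false_edges += 1
    return {
        "pair_power": pair_hits / pair_total,
        "false_edge_rate": false_edges / decoy_pairs,
        "false_edge_bound": alpha * 3,
        "n_pairs": pair_total,
        "n_decoy_pairs": decoy_pairs,
    }
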