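"""Synthetic inputs generated from a planted TF -> target network.

Every downstream stage of the pipeline (quantification, consistency
screening, stepwise selection, motif/TF prediction, network assembly) can be
tested by recovery against the ground truth emitted here: a planted
regulatory network, a log2-linear expression model over fins x regions x
stages x replicates, Cq plates derived by inverting the quantification
model, promoters with planted binding sites, a PWM library containing the
planted regulators, and a co-expression compendium simulated from the same
network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design
from .motifs import BASES, PWM, reverse_complement
from .stepwise import CoexpressionDB, Neighbor

# rng stream tags, so each generator draws from an independent stream
_STREAM_EXPR = 1
_STREAM_CQ = 2
_STREAM_PWM = 3
_STREAM_PROM = 4
_STREAM_COMP = 5


@dataclass(frozen=True)
class Edge:
    tf: str
    target: str
    sign: int  # +1 activating, -1 repressing
    weight: float  # log2-fold units per unit of TF activity


@dataclass
class PlantedNetwork:
    """Ground-truth regulatory structure behind all synthetic inputs."""

    tf_ids: list[str]
    target_ids: list[str]
    null_ids: list[str]
    edges: list[Edge]
    #: per TF: L-minus-S activity difference (log2 units) per (fin, stage)
    tf_region_effect: dict[str, dict[tuple[str, int], float]]

    def __post_init__(self) -> None:
        tfs, targets, nulls = set(self.tf_ids), set(self.target_ids), set(self.null_ids)
        if tfs & targets or tfs & nulls or targets & nulls:
            raise ValueError("tf, target and null gene sets must be disjoint")
        for e in self.edges:
            if e.tf not in tfs:
                raise ValueError(f"edge TF {e.tf} not in tf_ids")
            if e.target not in targets:
                raise ValueError(f"edge target {e.target} not in target_ids")
            if not np.isfinite(e.weight) or e.weight == 0:
                raise ValueError(f"edge {e.tf}->{e.target} has invalid weight")
            if e.sign not in (-1, 1):
                raise ValueError("edge sign must be +1 or -1")

    @property
    def genes(self) -> list[str]:
        return list(self.tf_ids) + list(self.target_ids) + list(self.null_ids)

    def regulators_of(self, target: str) -> list[Edge]:
        return [e for e in self.edges if e.target == target]

    @property
    def repressed_targets(self) -> list[str]:
        """Targets whose regulation is exclusively repressive."""
        out = []
        for t in self.target_ids:
            regs = self.regulators_of(t)
            if regs and all(e.sign < 0 for e in regs):
                out.append(t)
        return out

    def planted_direction(self, gene: str) -> str | None:
        """Expected L/S direction of a gene under positive TF activity in L."""
        if gene in self.tf_ids:
            return design.HIGHER_L
        if gene in self.null_ids:
            return None
        total = sum(
            e.sign * e.weight * np.mean(list(self.tf_region_effect[e.tf].values()))
            for e in self.regulators_of(gene)
        )
        if total == 0:
            return None
        return design.HIGHER_L if total > 0 else design.HIGHER_S


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study design; defaults mirror the real one."""

    fins: tuple[str, ...] = design.FINS
    stages: tuple[int, ...] = design.STAGES
    n_replicates: int = 3
    noise_sd_cq: float = 0.25
    expr_noise_sd: float = 0.0
    replicate_sd: float = 0.05
    ref_noise_sd: float = 0.05
    ref_level: float = 10.0
    promoter_length: int = 4000
    plant_rate: float = 0.9
    sites_per_edge: int = 1
    compendium_size: int = 200
    compendium_batches: int = 4
    mutual_rank_top_n: int = 10
    support_alpha: float = 0.001
    compendium_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for name in ("noise_sd_cq", "expr_noise_sd", "replicate_sd",
                     "ref_noise_sd", "compendium_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.promoter_length < 1:
            raise ValueError("promoter_length must be >= 1")
        if not 0 <= self.plant_rate <= 1:
            raise ValueError("plant_rate must be in [0, 1]")
        if self.compendium_batches < 1:
            raise ValueError("compendium_batches must be >= 1")

    def samples(self):
        """Every (fin, region, stage, replicate) cell of the design."""
        for fin in self.fins:
            for region in design.regions_of(fin):
                for stage in self.stages:
                    for rep in range(1, self.n_replicates + 1):
                        yield fin, region, stage, rep


def _rng(tag: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([tag, seed])


# ---------------------------------------------------------------------------
# Network


def generate_planted_network(
    n_tfs: int,
    n_targets: int,
    n_nulls: int,
    effect_size: float,
    seed: int,
    reg_prob: float | None = None,
    n_repressed: int = 1,
    fins: tuple[str, ...] = design.FINS,
    stages: tuple[int, ...] = design.STAGES,
) -> PlantedNetwork:
    """Plant a TF -> target network with one exclusively repressed target.

    With ``reg_prob=None`` each target gets exactly one activating regulator
    (round-robin over TFs in a seeded random target order); with a float,
    every TF->target edge is drawn independently with that probability and
    lonely targets get one regulator assigned. At least one target (the last
    ``n_repressed``) carries a single repressive edge instead.
    """
    if n_tfs < 1 or n_targets < 1 or n_nulls < 0:
        raise ValueError("need n_tfs >= 1, n_targets >= 1, n_nulls >= 0")
    if effect_size <= 0:
        raise ValueError("effect_size must be > 0")
    rng = np.random.default_rng(seed)
    tfs = [f"tf{i:02d}" for i in range(1, n_tfs + 1)]
    targets = [f"tg{i:02d}" for i in range(1, n_targets + 1)]
    nulls = [f"null{i:02d}" for i in range(1, n_nulls + 1)]

    n_repressed = max(1, min(n_repressed, n_targets))
    repressed = set(targets[-n_repressed:])
    activated = [t for t in targets if t not in repressed]

    edges: list[Edge] = []
    if reg_prob is None:
        order = rng.permutation(len(activated))
        for slot, idx in enumerate(order):
            edges.append(Edge(tfs[slot % n_tfs], activated[idx], +1, 1.0))
    else:
        for t in activated:
            picked = [tf for tf in tfs if rng.random() < reg_prob]
            if not picked:
                picked = [tfs[rng.integers(n_tfs)]]
            for tf in picked:
                edges.append(Edge(tf, t, +1, 1.0))
    for t in sorted(repressed):
        edges.append(Edge(tfs[rng.integers(n_tfs)], t, -1, 1.0))

    effect = {
        tf: {(fin, stage): float(effect_size) for fin in fins for stage in stages}
        for tf in tfs
    }
    return PlantedNetwork(tfs, targets, nulls, edges, effect)


# ---------------------------------------------------------------------------
# Expression and Cq plates


def simulate_expression(net: PlantedNetwork, cfg: SimulationConfig) -> pd.DataFrame:
    """Long table of log2 abundance per gene and design cell.

    log2 expr = baseline + sum_edges sign*weight*tf_activity + replicate
    effect + Gaussian noise; TF genes track their own activity, null genes
    receive no TF term. TF activity is +effect/2 in L regions and -effect/2
    in S regions, so the planted L-minus-S difference of a single-edge
    target equals sign*weight*effect exactly.
    """
    rng = _rng(_STREAM_EXPR, cfg.seed)
    genes = net.genes
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    baselines = rng.normal(8.0, 1.0, size=n_genes)
    rep_effects = rng.normal(0.0, cfg.replicate_sd, size=cfg.n_replicates)

    sample_list = list(cfg.samples())
    n_samples = len(sample_list)

    # TF activity per sample
    act = np.zeros((len(net.tf_ids), n_samples))
    for j, (fin, region, stage, _rep) in enumerate(sample_list):
        half = 0.5 if design.is_l_region(region) else -0.5
        for i, tf in enumerate(net.tf_ids):
            act[i, j] = half * net.tf_region_effect[tf][(fin, stage)]

    # regulatory weights: rows genes, cols TFs
    w = np.zeros((n_genes, len(net.tf_ids)))
    tf_pos = {tf: i for i, tf in enumerate(net.tf_ids)}
    for i, tf in enumerate(net.tf_ids):
        w[gene_pos[tf], i] = 1.0  # a TF gene's expression tracks its activity
    for e in net.edges:
        w[gene_pos[e.target], tf_pos[e.tf]] += e.sign * e.weight

    noise = (
        rng.normal(0.0, cfg.expr_noise_sd, size=(n_genes, n_samples))
        if cfg.expr_noise_sd > 0
        else np.zeros((n_genes, n_samples))
    )
    rep_idx = np.array([rep - 1 for _, _, _, rep in sample_list])
    expr = baselines[:, None] + w @ act + rep_effects[rep_idx][None, :] + noise

    rows = []
    for i, gene in enumerate(genes):
        for j, (fin, region, stage, rep) in enumerate(sample_list):
            rows.append((gene, fin, region, stage, rep, expr[i, j]))
    return pd.DataFrame(
        rows, columns=["gene", "fin", "region", "stage", "replicate", "log2_expr"]
    )


def expression_to_cq(
    expr: pd.DataFrame,
    cfg: SimulationConfig,
    ref_gene_ids: list[str],
) -> pd.DataFrame:
    """Invert the quantification model: Cq = offset - log2 expr + noise.

    Reference genes are appended with constant expression (``cfg.ref_level``)
    plus their own, typically smaller, noise. With all noise terms at zero
    the plate round-trips: quantification recovers every pairwise expression
    ratio exactly.
    """
    if not ref_gene_ids:
        raise ValueError("need at least one reference gene")
    rng = _rng(_STREAM_CQ, cfg.seed)
    genes = list(dict.fromkeys(expr["gene"]))
    offsets = dict(zip(genes, rng.normal(30.0, 1.0, size=len(genes))))
    ref_offsets = dict(
        zip(ref_gene_ids, rng.normal(25.0, 1.0, size=len(ref_gene_ids)))
    )

    out = expr.copy()
    out["cq"] = (
        out["gene"].map(offsets).to_numpy()
        - out["log2_expr"].to_numpy()
        + rng.normal(0.0, cfg.noise_sd_cq, size=len(out))
    )
    out["is_reference"] = False
    out = out.drop(columns=["log2_expr"])

    samples = out[["fin", "region", "stage", "replicate"]].drop_duplicates()
    ref_rows = []
    for ref in ref_gene_ids:
        base = ref_offsets[ref] - cfg.ref_level
        noise = rng.normal(0.0, cfg.ref_noise_sd, size=len(samples))
        for (row, eps) in zip(samples.itertuples(index=False), noise):
            ref_rows.append(
                (ref, row.fin, row.region, row.stage, row.replicate,
                 base + eps, True)
            )
    plate = pd.concat(
        [out, pd.DataFrame(ref_rows, columns=out.columns)], ignore_index=True
    )
    return plate


# ---------------------------------------------------------------------------
# PWM library and promoters


def _dominant_prob_for_ic(ic: float) -> float:
    """Dominant-base probability giving the requested per-column IC (bits)."""
    ic = min(max(ic, 0.0), 2.0)

    def f(p: float) -> float:
        rest = (1.0 - p) / 3.0
        h = 0.0
        if p > 0:
            h += p * np.log2(p)
        if rest > 0:
            h += 3 * rest * np.log2(rest)
        return 2.0 + h

    lo, hi = 0.25, 1.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if f(mid) < ic:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def generate_pwm_library(
    n_pwms: int,
    width_range: tuple[int, int] = (8, 10),
    info_content: float = 1.8,
    seed: int = 0,
    tf_ids: tuple[str, ...] = (),
) -> list[PWM]:
    """PWMs with the requested average column information content.

    The first ``len(tf_ids)`` matrices carry the TF ids (the planted
    regulators' binding models); the remainder are distractors.
    """
    wmin, wmax = width_range
    if not (4 <= wmin <= wmax <= 20):
        raise ValueError("width_range must satisfy 4 <= min <= max <= 20")
    if n_pwms < len(tf_ids):
        raise ValueError("n_pwms smaller than the number of TF ids")
    rng = _rng(_STREAM_PWM, seed)
    p_dom = _dominant_prob_for_ic(info_content)

    pwms = []
    for i in range(n_pwms):
        name = tf_ids[i] if i < len(tf_ids) else f"pwm{i - len(tf_ids) + 1:02d}"
        width = int(rng.integers(wmin, wmax + 1))
        mat = np.full((width, 4), (1.0 - p_dom) / 3.0)
        for j in range(width):
            mat[j, rng.integers(4)] = p_dom
        pwms.append(PWM(id=name, matrix=mat))
    return pwms


def generate_promoters(
    net: PlantedNetwork,
    library: list[PWM],
    cfg: SimulationConfig,
    plant_rate: float | None = None,
):
    """Order-0 background promoters with sites planted per regulatory edge.

    Returns (records, planted) where records are Biopython ``SeqRecord``
    objects (one per gene, length ``cfg.promoter_length``) and planted is the
    ground-truth site table (gene, pwm, position, strand, site). Null genes
    receive pure background.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if plant_rate is None:
        plant_rate = cfg.plant_rate
    lib_by_id = {p.id: p for p in library}
    needed_tfs = sorted({e.tf for e in net.edges})
    for tf in needed_tfs:
        if tf not in lib_by_id:
            raise KeyError(f"no PWM in library for planted TF {tf}")
    if cfg.promoter_length < max(lib_by_id[tf].width for tf in needed_tfs):
        raise ValueError("promoter_length shorter than a planted PWM width")

    rng = _rng(_STREAM_PROM, cfg.seed)
    length = cfg.promoter_length
    seqs = {
        g: rng.choice(list(BASES), size=length) for g in net.genes
    }

    planted_rows = []
    for e in sorted(net.edges, key=lambda e: (e.target, e.tf)):
        pwm = lib_by_id[e.tf]
        for _k in range(cfg.sites_per_edge):
            if rng.random() >= plant_rate:
                continue
            site = pwm.sample_site(rng)
            strand = "+" if rng.random() < 0.5 else "-"
            pos = int(rng.integers(0, length - pwm.width + 1))
            inserted = site if strand == "+" else reverse_complement(site)
            seqs[e.target][pos : pos + pwm.width] = list(inserted)
            planted_rows.append((e.target, e.tf, pos, strand, site))

    records = [
        SeqRecord(Seq("".join(seqs[g])), id=g, description="") for g in net.genes
    ]
    planted = pd.DataFrame(
        planted_rows, columns=["gene", "pwm", "position", "strand", "site"]
    )
    return records, planted


# ---------------------------------------------------------------------------
# Co-expression compendium


def _critical_r(n: int, alpha: float = 0.01) -> float:
    """Pearson r above which the two-tailed p falls below alpha at n obs."""
    from scipy import stats

    if n < 3:
        return 1.0
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def build_coexpression_db(net: PlantedNetwork, cfg: SimulationConfig) -> CoexpressionDB:
    """Simulate a random-condition compendium and derive ranked neighbor lists.

    Neighbors are ranked by full-compendium Pearson correlation. The
    supportability score of a pair counts the compendium batches (default 4)
    in which the genes fall into each other's top-N ranks with a batch
    correlation exceeding the two-tailed ``support_alpha`` significance
    threshold; the gate keeps chance mutual ranks of unregulated genes at 0.
    """
    if cfg.compendium_size < 50:
        raise ValueError("compendium_size must be >= 50")
    rng = _rng(_STREAM_COMP, cfg.seed)
    genes = net.genes
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    tf_pos = {tf: i for i, tf in enumerate(net.tf_ids)}

    w = np.zeros((n_genes, len(net.tf_ids)))
    for i, tf in enumerate(net.tf_ids):
        w[gene_pos[tf], i] = 1.0
    for e in net.edges:
        w[gene_pos[e.target], tf_pos[e.tf]] += e.sign * e.weight

    acts = rng.normal(0.0, 1.0, size=(len(net.tf_ids), cfg.compendium_size))
    noise = rng.normal(0.0, cfg.compendium_noise_sd, size=(n_genes, cfg.compendium_size))
    expr = w @ acts + noise

    corr_full = np.corrcoef(expr)

    n_b = cfg.compendium_batches
    bounds = np.linspace(0, cfg.compendium_size, n_b + 1).astype(int)
    support = np.zeros((n_genes, n_genes), dtype=int)
    top_n = min(cfg.mutual_rank_top_n, n_genes - 1)
    for b in range(n_b):
        block = expr[:, bounds[b] : bounds[b + 1]]
        if block.shape[1] < 3:
            continue
        corr_b = np.corrcoef(block)
        r_crit = _critical_r(block.shape[1], cfg.support_alpha)
        np.fill_diagonal(corr_b, -np.inf)
        # top-N neighbor sets per gene within this batch
        order = np.argsort(-corr_b, axis=1, kind="stable")
        in_top = np.zeros((n_genes, n_genes), dtype=bool)
        rows = np.repeat(np.arange(n_genes), top_n)
        in_top[rows, order[:, :top_n].ravel()] = True
        mutual = in_top & in_top.T & (corr_b > r_crit)
        support += mutual.astype(int)

    neighbors: dict[str, list[Neighbor]] = {}
    for i, g in enumerate(genes):
        entries = [
            Neighbor(genes[j], float(corr_full[i, j]), int(support[i, j]))
            for j in range(n_genes)
            if j != i
        ]
        entries.sort(key=lambda nb: (-nb.correlation, nb.gene))
        neighbors[g] = entries
    return CoexpressionDB(neighbors)
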