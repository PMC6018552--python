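"""Iterative candidate selection and co-expression module extension.

Round 1 selects strongly co-expressed neighbors of the seed genes from a
local co-expression database (supportability-filtered), quantifies and
tests them, and groups seeds with their consistent same-direction hits into
modules. Round 2 extends each multi-gene module with genes co-expressed
with *all* of its members and tests those. No gene is ever tested twice:
the exclusion set grows monotonically across rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import design
from .consistency import consistency_call, paired_lvs_tests
from .qpcr import relative_quantities

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Neighbor:
    gene: str
    correlation: float
    supportability: int


class CoexpressionDB:
    """Per-gene neighbor lists ranked by descending correlation.

    Ties are broken lexicographically by gene id; self-neighbors are
    rejected. Construct from a mapping gene -> iterable of
    :class:`Neighbor`, or load from the tab-separated neighbor file.
    """

    def __init__(self, neighbors: dict[str, list[Neighbor]]):
        self._neighbors: dict[str, list[Neighbor]] = {}
        for gene, entries in neighbors.items():
            entries = sorted(entries, key=lambda nb: (-nb.correlation, nb.gene))
            for nb in entries:
                if nb.gene == gene:
                    raise ValueError(f"self-neighbor for gene {gene}")
                if nb.supportability < 0:
                    raise ValueError("supportability must be >= 0")
            self._neighbors[gene] = entries

    def __contains__(self, gene: str) -> bool:
        return gene in self._neighbors

    def genes(self) -> list[str]:
        return sorted(self._neighbors)

    def neighbors(self, gene: str) -> list[Neighbor]:
        if gene not in self._neighbors:
            raise KeyError(f"gene {gene} absent from co-expression database")
        return list(self._neighbors[gene])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, nb.gene, nb.correlation, nb.supportability)
            for g in sorted(self._neighbors)
            for nb in self._neighbors[g]
        ]
        return pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "correlation", "supportability"]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CoexpressionDB":
        neighbors: dict[str, list[Neighbor]] = {}
        for row in frame.itertuples(index=False):
            neighbors.setdefault(row.gene_a, []).append(
                Neighbor(row.gene_b, float(row.correlation), int(row.supportability))
            )
        return cls(neighbors)


@dataclass
class GeneModule:
    members: list[str]
    direction: str | None  # 'higher-L' / 'higher-S' / None for unresolved seeds
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def seed(self) -> str:
        return self.members[0]


@dataclass
class SelectionResult:
    per_seed: dict[str, list[str]]
    candidates: list[str]  # deduplicated, in first-seen order
    provenance: dict[str, list[str]]  # candidate -> seeds that proposed it


def select_candidates(
    seeds: list[str],
    db: CoexpressionDB,
    k: int = 9,
    min_support: int = 1,
    exclude: set[str] | None = None,
) -> SelectionResult:
    """Top-k supportability-filtered neighbors per seed, deduplicated.

    Already-tested genes (``exclude``) and the seeds themselves are skipped;
    a candidate proposed by several seeds is returned once with full
    provenance.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    exclude = set(exclude or ())
    exclude |= set(seeds)

    per_seed: dict[str, list[str]] = {}
    provenance: dict[str, list[str]] = {}
    ordered: list[str] = []
    for seed in seeds:
        picked = []
        for nb in db.neighbors(seed):  # KeyError names an absent seed
            if len(picked) >= k:
                break
            if nb.gene in exclude or nb.supportability < min_support:
                continue
            picked.append(nb.gene)
        if not picked:
            logger.warning("seed %s: no neighbor passed the filters", seed)
        per_seed[seed] = picked
        for gene in picked:
            if gene not in provenance:
                provenance[gene] = []
                ordered.append(gene)
            provenance[gene].append(seed)
    return SelectionResult(per_seed=per_seed, candidates=ordered, provenance=provenance)


def assemble_modules(
    seeds: list[str],
    report: pd.DataFrame,
    provenance: dict[str, list[str]],
) -> list[GeneModule]:
    """Group each seed with its consistent, same-direction co-selected genes.

    Inconsistent genes are dropped everywhere; a candidate proposed by
    several seeds joins the first seed's module only. Seeds without
    consistent hits yield singleton modules.
    """
    verdicts = dict(zip(report["gene"], report["verdict"]))
    verdict_dir = {
        design.CONSISTENT_L: design.HIGHER_L,
        design.CONSISTENT_S: design.HIGHER_S,
    }
    assigned: set[str] = set()
    modules = []
    for seed in seeds:
        direction = verdict_dir.get(verdicts.get(seed))
        members = [seed]
        prov = {seed: [seed]}
        if direction is not None:
            for gene, origin in provenance.items():
                if seed not in origin or gene in assigned:
                    continue
                if verdict_dir.get(verdicts.get(gene)) == direction:
                    members.append(gene)
                    prov[gene] = list(origin)
                    assigned.add(gene)
        modules.append(GeneModule(members=members, direction=direction, provenance=prov))
    return modules


def extend_module(
    module: GeneModule,
    db: CoexpressionDB,
    k: int = 5,
    exclude: set[str] | None = None,
    min_support: int = 1,
) -> list[str]:
    """Genes co-expressed with every module member, most conservative first.

    Candidates are the intersection of all members' supportability-filtered
    neighbor sets minus the exclusion set, ranked by their minimum pairwise
    correlation across members (ties lexicographic). An empty intersection
    is a warning, not an error.
    """
    if not module.members:
        raise ValueError("cannot extend an empty module")
    if k < 1:
        raise ValueError("k must be >= 1")
    exclude = set(exclude or ()) | set(module.members)

    min_corr: dict[str, float] | None = None
    for member in module.members:
        corrs = {
            nb.gene: nb.correlation
            for nb in db.neighbors(member)
            if nb.supportability >= min_support and nb.gene not in exclude
        }
        if min_corr is None:
            min_corr = corrs
        else:
            min_corr = {
                g: min(c, corrs[g]) for g, c in min_corr.items() if g in corrs
            }
    assert min_corr is not None
    if not min_corr:
        logger.warning("module %s: empty neighbor intersection", module.seed)
        return []
    ranked = sorted(min_corr.items(), key=lambda item: (-item[1], item[0]))
    return [g for g, _c in ranked[:k]]


@dataclass
class StepwiseConfig:
    ref_genes: tuple[str, ...] = ("ref1", "ref2")
    k: int = 9
    min_support: int = 1
    extend_k: int = 5
    min_module_size_to_extend: int = 2
    rounds: int = 2
    alpha: float = 0.05
    min_stages: int = 2
    min_fins: int = 2
    caudal_rule: str = "any"
    amplification_base: float = 2.0


@dataclass
class StepwiseResult:
    final: pd.DataFrame  # gene, direction, round, provenance
    modules: list[GeneModule]
    log: list[dict]
    reports: dict[int, pd.DataFrame]  # round -> consistency report


def _test_genes(
    genes: list[str], plate: pd.DataFrame, cfg: StepwiseConfig
) -> pd.DataFrame:
    subset = plate[
        plate["gene"].isin(list(genes) + list(cfg.ref_genes))
    ].reset_index(drop=True)
    missing = set(genes) - set(subset["gene"])
    if missing:
        raise ValueError(f"genes absent from plate: {sorted(missing)}")
    rq = relative_quantities(subset, list(cfg.ref_genes), e=cfg.amplification_base)
    sig = paired_lvs_tests(rq, alpha=cfg.alpha)
    return consistency_call(
        sig,
        alpha=cfg.alpha,
        min_stages=cfg.min_stages,
        min_fins=cfg.min_fins,
        caudal_rule=cfg.caudal_rule,
    )


def run_stepwise(
    seeds: list[str],
    db: CoexpressionDB,
    plate: pd.DataFrame,
    config: StepwiseConfig | None = None,
) -> StepwiseResult:
    """The full select -> quantify -> test -> assemble -> extend procedure.

    Returns the final gene set (seeds plus every consistent gene, with
    directions), the modules, and an auditable per-round log in which every
    tested gene appears exactly once.
    """
    if not seeds:
        raise ValueError("seed gene list must not be empty")
    cfg = config or StepwiseConfig()
    log: list[dict] = []
    reports: dict[int, pd.DataFrame] = {}

    # round 1: select, test seeds + candidates, assemble modules
    selection = select_candidates(
        seeds, db, k=cfg.k, min_support=cfg.min_support, exclude=set()
    )
    tested_r1 = list(seeds) + selection.candidates
    report1 = _test_genes(tested_r1, plate, cfg)
    reports[1] = report1
    modules = assemble_modules(seeds, report1, selection.provenance)
    exclude = set(tested_r1)
    log.append(
        {
            "round": 1,
            "stage": "select+test",
            "tested": list(tested_r1),
            "candidates": list(selection.candidates),
            "modules": [list(m.members) for m in modules],
        }
    )

    # round 2+: extend modules, test extensions
    verdict_dir = {
        design.CONSISTENT_L: design.HIGHER_L,
        design.CONSISTENT_S: design.HIGHER_S,
    }
    round_provenance: dict[str, int] = {g: 1 for g in tested_r1}
    for rnd in range(2, cfg.rounds + 1):
        extension_of: dict[str, GeneModule] = {}
        ext_order: list[str] = []
        for module in modules:
            if len(module.members) < cfg.min_module_size_to_extend:
                continue
            for gene in extend_module(
                module, db, k=cfg.extend_k, exclude=exclude,
                min_support=cfg.min_support,
            ):
                if gene not in extension_of:
                    extension_of[gene] = module
                    ext_order.append(gene)
        if not ext_order:
            log.append({"round": rnd, "stage": "extend+test", "tested": [],
                        "candidates": [], "modules": [list(m.members) for m in modules]})
            break
        report = _test_genes(ext_order, plate, cfg)
        reports[rnd] = report
        verdicts = dict(zip(report["gene"], report["verdict"]))
        for gene in ext_order:
            module = extension_of[gene]
            if verdict_dir.get(verdicts.get(gene)) == module.direction:
                module.members.append(gene)
                module.provenance[gene] = [module.seed]
        exclude |= set(ext_order)
        for gene in ext_order:
            round_provenance[gene] = rnd
        log.append(
            {
                "round": rnd,
                "stage": "extend+test",
                "tested": list(ext_order),
                "candidates": list(ext_order),
                "modules": [list(m.members) for m in modules],
            }
        )

    all_verdicts: dict[str, str] = {}
    for rep in reports.values():
        all_verdicts.update(zip(rep["gene"], rep["verdict"]))
    module_of: dict[str, GeneModule] = {}
    for module in modules:
        for gene in module.members:
            module_of.setdefault(gene, module)

    # final set: the seeds plus every consistent tested gene
    rows = []
    for gene in round_provenance:
        verdict = all_verdicts.get(gene, "untested")
        if gene not in seeds and verdict not in verdict_dir:
            continue
        module = module_of.get(gene)
        rows.append(
            {
                "gene": gene,
                "direction": verdict_dir.get(verdict, "none"),
                "verdict": verdict,
                "round": round_provenance.get(gene, 1),
                "module_seed": module.seed if module else "",
                "provenance": ";".join(
                    module.provenance.get(gene, [gene]) if module else [gene]
                ),
            }
        )
    final = pd.DataFrame(
        rows,
        columns=["gene", "direction", "verdict", "round", "module_seed", "provenance"],
    )
    return StepwiseResult(final=final, modules=modules, log=log, reports=reports)
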