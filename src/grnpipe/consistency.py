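"""L/S differential testing and the cross-fin / cross-stage consistency rule.

Per gene, two-tailed paired t-tests compare log RQ between each elongated
(L) region and the fin's short (S) region, separately per fin and stage,
pairing by biological replicate. A gene is called consistent in a direction
when at least ``min_stages`` stages are significant in that direction in at
least ``min_fins`` fins, with no significant cell in the opposite
direction. A mixed linear model with a random intercept per biological
replicate serves as a per-gene gate; singular fits fall back to the
fixed-effects model and are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import design


class PairingError(ValueError):
    """L and S observations cannot be paired by replicate."""


def bonferroni(p, m: int):
    """Bonferroni adjustment: multiply by the family size, cap at 1."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


# ---------------------------------------------------------------------------
# Paired L-vs-S tests


def paired_lvs_tests(rq_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Two-tailed paired t-tests on log RQ for every gene x fin x L-region x stage.

    The caudal fin contributes two comparisons per stage (dcL vs cS and vcL
    vs cS). Differences with zero variance are reported with p = 0 and a
    degenerate flag (p = 1 if the differences are all zero). Unpaired
    replicates raise :class:`PairingError`.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    needed = {"gene", "fin", "region", "stage", "replicate", "log_rq"}
    if not needed <= set(rq_table.columns):
        raise ValueError(f"rq_table missing columns {needed - set(rq_table.columns)}")

    s_map = design.S_REGION
    lpart = rq_table[rq_table["region"].map(design.is_l_region)].copy()
    spart = rq_table[~rq_table["region"].map(design.is_l_region)].copy()
    spart = spart.rename(columns={"log_rq": "log_rq_s", "region": "s_region"})

    merged = lpart.merge(
        spart[["gene", "fin", "stage", "replicate", "log_rq_s"]],
        on=["gene", "fin", "stage", "replicate"],
        how="left",
    )
    if merged["log_rq_s"].isna().any():
        bad = merged[merged["log_rq_s"].isna()][
            ["gene", "fin", "region", "stage", "replicate"]
        ].drop_duplicates()
        raise PairingError(
            f"unpaired L observations (no matching S replicate):\n{bad.to_string(index=False)}"
        )
    # the reverse direction: every S replicate needs an L partner
    cnt_l = lpart.groupby(["gene", "fin", "region", "stage"])["replicate"].count()
    cnt_s = spart.groupby(["gene", "fin", "stage"])["replicate"].count()
    for (gene, fin, region, stage), n_l in cnt_l.items():
        n_s = cnt_s.get((gene, fin, stage), 0)
        if n_s != n_l:
            raise PairingError(
                f"gene {gene} fin {fin} stage {stage}: {n_l} L vs {n_s} S replicates"
            )

    merged["diff"] = merged["log_rq"] - merged["log_rq_s"]
    grouped = merged.groupby(["gene", "fin", "region", "stage"], sort=True)["diff"]
    agg = grouped.agg(n="count", mean_diff="mean", sd=lambda x: x.std(ddof=1))
    if (agg["n"] < 2).any():
        raise PairingError("paired t-test needs at least 2 replicate pairs")

    n = agg["n"].to_numpy(dtype=float)
    mean = agg["mean_diff"].to_numpy()
    sd = agg["sd"].to_numpy()

    degenerate = sd <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    # zero-variance differences: identical nonzero diffs -> p=0, all-zero -> t=0, p=1
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(mean) * np.inf, t)
    t = np.where(degenerate & (mean == 0), 0.0, t)
    p = np.where(degenerate, np.where(mean == 0, 1.0, 0.0), p)

    out = agg.reset_index()
    out["t"] = t
    out["p"] = p
    out["direction"] = np.where(
        mean > 0, design.HIGHER_L, np.where(mean < 0, design.HIGHER_S, "none")
    )
    out["degenerate"] = degenerate
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# Consistency call


@dataclass
class ConsistencyParams:
    alpha: float = 0.05
    min_stages: int = 2
    min_fins: int = 2
    #: 'any': a caudal fin x stage cell counts when either L-region test is
    #: significant (and no opposing significant test in the cell);
    #: 'both': both dcL and vcL comparisons must agree and pass alpha.
    caudal_rule: str = "any"


def _cell_direction(cell: pd.DataFrame, alpha: float, rule: str) -> str | None:
    """Direction of one fin x stage cell, or None if not significant."""
    sig = cell[(cell["p"] < alpha) & (cell["direction"] != "none")]
    if sig.empty:
        return None
    dirs = set(sig["direction"])
    if len(dirs) > 1:
        return "conflict"
    if rule == "both" and len(sig) < len(cell):
        return None
    return dirs.pop()


def consistency_call(
    sig_matrix: pd.DataFrame,
    alpha: float = 0.05,
    min_stages: int = 2,
    min_fins: int = 2,
    caudal_rule: str = "any",
) -> pd.DataFrame:
    """Apply the >= min_stages stages in >= min_fins fins rule per gene.

    Genes with significant cells in opposing directions across the design
    are called inconsistent regardless of counts.
    """
    if caudal_rule not in ("any", "both"):
        raise ValueError("caudal_rule must be 'any' or 'both'")
    rows = []
    for gene, sub in sig_matrix.groupby("gene", sort=True):
        cell_dirs: dict[tuple[str, int], str] = {}
        conflict = False
        for (fin, stage), cell in sub.groupby(["fin", "stage"], sort=True):
            rule = caudal_rule if len(cell) > 1 else "any"
            d = _cell_direction(cell, alpha, rule)
            if d == "conflict":
                conflict = True
            elif d is not None:
                cell_dirs[(fin, stage)] = d
        directions = set(cell_dirs.values())
        if conflict or len(directions) > 1:
            verdict, cells = design.INCONSISTENT, []
        elif not directions:
            verdict, cells = design.INCONSISTENT, []
        else:
            d = directions.pop()
            per_fin: dict[str, list[int]] = {}
            for (fin, stage) in cell_dirs:
                per_fin.setdefault(fin, []).append(stage)
            qualifying = [f for f, ss in per_fin.items() if len(ss) >= min_stages]
            if len(qualifying) >= min_fins:
                verdict = (
                    design.CONSISTENT_L if d == design.HIGHER_L else design.CONSISTENT_S
                )
                cells = sorted(cell_dirs)
            else:
                verdict, cells = design.INCONSISTENT, []
        rows.append(
            {
                "gene": gene,
                "verdict": verdict,
                "n_supporting": len(cells),
                "supporting_cells": ";".join(f"{f}:{s}" for f, s in cells),
            }
        )
    report = pd.DataFrame(
        rows, columns=["gene", "verdict", "n_supporting", "supporting_cells"]
    )
    report.attrs["params"] = {
        "alpha": alpha,
        "min_stages": min_stages,
        "min_fins": min_fins,
        "caudal_rule": caudal_rule,
    }
    return report


# ---------------------------------------------------------------------------
# Mixed linear model gate


def fit_region_model(
    rq_table: pd.DataFrame,
    genes: list[str] | None = None,
    bonferroni_family: int | None = None,
) -> pd.DataFrame:
    """Per-gene linear model of log RQ with a random intercept per replicate.

    Fixed effects: region (L vs S), fin, stage and the region x fin and
    region x stage interactions (sum coding for fin and stage, so the region
    coefficient is its main effect). Returns the region main-effect p, the
    smallest interaction p, convergence flags, and the Bonferroni-adjusted
    region p over the tested gene batch.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    needed = {"gene", "fin", "region", "stage", "replicate", "log_rq"}
    if not needed <= set(rq_table.columns):
        raise ValueError(f"rq_table missing columns {needed - set(rq_table.columns)}")
    if genes is None:
        genes = sorted(rq_table["gene"].unique())
    family = bonferroni_family if bonferroni_family is not None else len(genes)

    formula = (
        "log_rq ~ C(region_type, Treatment('S')) * C(fin, Sum)"
        " + C(region_type, Treatment('S')) * C(stage, Sum)"
    )
    rows = []
    for gene in genes:
        sub = rq_table[rq_table["gene"] == gene].copy()
        if sub.empty:
            raise ValueError(f"gene {gene} absent from rq_table")
        sub["region_type"] = np.where(
            sub["region"].map(design.is_l_region), "L", "S"
        )
        if sub["replicate"].nunique() < 2:
            raise ValueError("mixed model needs >= 2 biological replicates")
        cells = sub.groupby(["region_type", "fin", "stage"]).size()
        expected = sub["fin"].nunique() * sub["stage"].nunique() * 2
        if len(cells) < expected:
            raise ValueError(
                f"gene {gene}: singular design, empty region x fin x stage cell"
            )

        fallback = False
        params = pvalues = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                fit = smf.mixedlm(formula, sub, groups=sub["replicate"]).fit(reml=True)
                if not np.all(np.isfinite(fit.bse.iloc[:-1])):
                    raise np.linalg.LinAlgError("non-finite standard errors")
                params, pvalues = fit.params, fit.pvalues
            except Exception:
                fallback = True
                fit = smf.ols(formula, sub).fit()
                params, pvalues = fit.params, fit.pvalues

        region_term = next(
            name for name in params.index
            if name.startswith("C(region_type") and ":" not in name
        )
        inter_ps = {
            name: float(pvalues[name]) for name in params.index if ":" in name
        }
        region_p = float(pvalues[region_term])
        rows.append(
            {
                "gene": gene,
                "region_p": region_p,
                "region_coef": float(params[region_term]),
                "min_interaction_p": min(inter_ps.values()) if inter_ps else np.nan,
                "singular_fallback": fallback,
                "region_p_bonferroni": float(bonferroni(region_p, family)),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_family"] = family
    return out
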