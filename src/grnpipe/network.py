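"""Correlation-network assembly from quantified expression tables.

Pairwise Pearson correlations are computed on log RQ over all design cells
shared by two genes, pooled across fins and per fin. Edges are pairs with
pooled two-tailed p below ``alpha_pooled`` (default 0.01, uncorrected); an
edge is additionally flagged when it is significant in every fin
separately. TF roles are summarised descriptively from edge signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NetworkEdge:
    gene_a: str
    gene_b: str
    r_pooled: float
    p_pooled: float
    sign: int
    per_fin: dict[str, tuple[float, float, bool]] = field(default_factory=dict)
    all_fins_flag: bool = False


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Product-moment r and two-tailed p via the t transform (n-2 df)."""
    n = len(x)
    sx = x - x.mean()
    sy = y - y.mean()
    denom = np.sqrt(float(sx @ sx) * float(sy @ sy))
    if denom == 0:
        return np.nan, np.nan, n
    r = float(sx @ sy) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p), n


def pairwise_correlations(
    rq_table: pd.DataFrame,
    genes: list[str] | None = None,
    scope: str = "pooled",
    value_column: str = "log_rq",
    min_obs: int = 4,
    center_per_fin: bool = True,
) -> pd.DataFrame:
    """All-pairs Pearson r and two-tailed p on shared observations.

    ``scope`` is 'pooled' (all fins mixed) or 'per-fin'. Pairs with fewer
    than ``min_obs`` shared observations are reported with NaN r/p rather
    than raising. Correlations default to the log scale; pass
    ``value_column='rq'`` for raw RQ.

    Because every fin is normalised against its own calibrator sample, the
    absolute log RQ levels of different fins are not comparable: the
    calibrator's measurement noise becomes a random per-gene, per-fin
    offset. Pooled correlations therefore center each gene within each fin
    by default (``center_per_fin``), pooling the within-fin covariance
    structure; the raw pooled estimator is available by switching it off.
    """
    if scope not in ("pooled", "per-fin"):
        raise ValueError("scope must be 'pooled' or 'per-fin'")
    if genes is None:
        genes = sorted(rq_table["gene"].unique())

    sub = rq_table[rq_table["gene"].isin(genes)].copy()
    if scope == "pooled" and center_per_fin:
        sub[value_column] = sub[value_column] - sub.groupby(["gene", "fin"])[
            value_column
        ].transform("mean")
    wide = sub.pivot_table(
        index=["fin", "region", "stage", "replicate"],
        columns="gene",
        values=value_column,
        aggfunc="mean",
        sort=True,
    )

    def _pairs(frame: pd.DataFrame, fin: str | None) -> list[dict]:
        rows = []
        present = [g for g in genes if g in frame.columns]
        for i, a in enumerate(present):
            xa = frame[a].to_numpy()
            for b in present[i + 1 :]:
                xb = frame[b].to_numpy()
                ok = np.isfinite(xa) & np.isfinite(xb)
                n = int(ok.sum())
                if n < min_obs:
                    r = p = np.nan
                else:
                    r, p, n = _pearson_with_p(xa[ok], xb[ok])
                rows.append(
                    {"gene_a": a, "gene_b": b, "fin": fin, "n": n, "r": r, "p": p}
                )
        return rows

    if scope == "pooled":
        rows = _pairs(wide, None)
    else:
        rows = []
        for fin in sorted(sub["fin"].unique()):
            rows.extend(_pairs(wide.loc[fin], fin))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "fin", "n", "r", "p"])


def build_network(
    pooled: pd.DataFrame,
    per_fin: pd.DataFrame,
    alpha_pooled: float = 0.01,
    alpha_fin: float = 0.01,
) -> list[NetworkEdge]:
    """Edges for pairs with pooled p < alpha_pooled; per-fin flags attached.

    No multiple-testing correction is applied. ``all_fins_flag`` is set when
    the pair is significant in every fin present in the per-fin table.
    """
    if not 0 < alpha_pooled <= 1 or not 0 < alpha_fin <= 1:
        raise ValueError("alpha levels must be in (0, 1]")
    fins = sorted(per_fin["fin"].dropna().unique())
    fin_lookup: dict[tuple[str, str], dict[str, tuple[float, float, bool]]] = {}
    for row in per_fin.itertuples(index=False):
        key = (row.gene_a, row.gene_b)
        ok = bool(np.isfinite(row.p) and row.p < alpha_fin)
        fin_lookup.setdefault(key, {})[row.fin] = (row.r, row.p, ok)

    edges = []
    for row in pooled.sort_values(["gene_a", "gene_b"]).itertuples(index=False):
        if not np.isfinite(row.p) or row.p >= alpha_pooled:
            continue
        per = fin_lookup.get((row.gene_a, row.gene_b), {})
        all_fins = bool(fins) and all(
            fin in per and per[fin][2] for fin in fins
        )
        edges.append(
            NetworkEdge(
                gene_a=row.gene_a,
                gene_b=row.gene_b,
                r_pooled=float(row.r),
                p_pooled=float(row.p),
                sign=1 if row.r > 0 else -1,
                per_fin=per,
                all_fins_flag=all_fins,
            )
        )
    return edges


def classify_tf_roles(
    edges: list[NetworkEdge],
    tf_ids: list[str],
    network_gene_ids: list[str],
) -> pd.DataFrame:
    """Descriptive per-TF counts of signed edges to network genes.

    Activator-candidate when positive edges strictly dominate,
    repressor-candidate when negative dominate, ambiguous on ties.
    """
    net_genes = set(network_gene_ids)
    rows = []
    for tf in tf_ids:
        pos = neg = 0
        for e in edges:
            other = None
            if e.gene_a == tf and e.gene_b in net_genes:
                other = e.gene_b
            elif e.gene_b == tf and e.gene_a in net_genes:
                other = e.gene_a
            if other is None:
                continue
            if e.sign > 0:
                pos += 1
            else:
                neg += 1
        if pos > neg:
            role = "activator-candidate"
        elif neg > pos:
            role = "repressor-candidate"
        else:
            role = "ambiguous"
        rows.append({"tf": tf, "n_positive": pos, "n_negative": neg, "role": role})
    return pd.DataFrame(rows, columns=["tf", "n_positive", "n_negative", "role"])


# ---------------------------------------------------------------------------
# Export / import


def edges_to_frame(edges: list[NetworkEdge]) -> pd.DataFrame:
    rows = []
    for e in edges:
        row = {
            "gene_a": e.gene_a,
            "gene_b": e.gene_b,
            "r": e.r_pooled,
            "p": e.p_pooled,
            "sign": e.sign,
            "all_fins": e.all_fins_flag,
        }
        for fin, (r, p, ok) in sorted(e.per_fin.items()):
            row[f"r_{fin}"] = r
            row[f"p_{fin}"] = p
            row[f"sig_{fin}"] = ok
        rows.append(row)
    return pd.DataFrame(rows)


def export_network(
    edges: list[NetworkEdge],
    path,
    fmt: str = "graphml",
    force: bool = False,
) -> None:
    """Write the edge list as SIF, GraphML or TSV.

    GraphML and TSV carry r, p, sign and the all-fins flag as attributes and
    round-trip losslessly through :func:`read_network`; SIF records the edge
    sign only. An empty network is an error unless ``force``.
    """
    if not edges and not force:
        raise ValueError("refusing to export an empty network (use force=True)")
    path = str(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for e in edges:
                rel = "pos" if e.sign > 0 else "neg"
                fh.write(f"{e.gene_a}\t{rel}\t{e.gene_b}\n")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.Graph()
        for e in edges:
            g.add_edge(
                e.gene_a,
                e.gene_b,
                r=float(e.r_pooled),
                p=float(e.p_pooled),
                sign=int(e.sign),
                all_fins=bool(e.all_fins_flag),
            )
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        edges_to_frame(edges).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, fmt: str = "graphml") -> list[NetworkEdge]:
    """Read a network written by :func:`export_network` (graphml or tsv)."""
    edges: list[NetworkEdge] = []
    if fmt == "graphml":
        import networkx as nx

        g = nx.read_graphml(str(path))
        for a, b, data in g.edges(data=True):
            edges.append(
                NetworkEdge(
                    gene_a=min(a, b),
                    gene_b=max(a, b),
                    r_pooled=float(data["r"]),
                    p_pooled=float(data["p"]),
                    sign=int(data["sign"]),
                    all_fins_flag=bool(data["all_fins"]),
                )
            )
    elif fmt == "tsv":
        frame = pd.read_csv(str(path), sep="\t")
        for row in frame.itertuples(index=False):
            edges.append(
                NetworkEdge(
                    gene_a=row.gene_a,
                    gene_b=row.gene_b,
                    r_pooled=float(row.r),
                    p_pooled=float(row.p),
                    sign=int(row.sign),
                    all_fins_flag=bool(row.all_fins),
                )
            )
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    edges.sort(key=lambda e: (e.gene_a, e.gene_b))
    return edges
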