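"""Relative quantification of raw Cq plates (ddCq method).

A plate is a long-format table with columns gene, fin, region, stage,
replicate, cq, is_reference. Quantification follows the classic scheme:
dCq = Cq_target - mean(Cq of reference genes in the same sample), ddCq =
dCq - dCq of the fin's calibrator sample, RQ = E**-ddCq (E defaults to 2),
log RQ in log2 units. The calibrator is one biological replicate of the
fin's first L region at the first stage; its RQ is exactly 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import design

PLATE_COLUMNS = ["gene", "fin", "region", "stage", "replicate", "cq", "is_reference"]
SAMPLE_KEY = ["fin", "region", "stage", "replicate"]


class PlateIntegrityError(ValueError):
    """A plate violates a structural invariant (missing references etc.)."""


def validate_plate(plate: pd.DataFrame) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise PlateIntegrityError(f"plate missing columns: {missing}")
    cq = plate["cq"].to_numpy(dtype=float)
    if not np.all(np.isfinite(cq)) or np.any(cq <= 0):
        raise PlateIntegrityError("all Cq values must be finite and > 0")
    for fin, region in plate[["fin", "region"]].drop_duplicates().itertuples(index=False):
        if fin not in design.FINS or region not in design.regions_of(fin):
            raise PlateIntegrityError(f"region {region!r} not legal for fin {fin!r}")


def reference_cq(plate: pd.DataFrame, ref_genes: list[str]) -> pd.DataFrame:
    """Arithmetic mean of the reference genes' Cq per sample.

    Raises :class:`PlateIntegrityError` naming every sample that lacks one of
    the reference genes.
    """
    if not ref_genes:
        raise ValueError("need at least one reference gene")
    refs = plate[plate["gene"].isin(ref_genes)]
    counts = refs.groupby(SAMPLE_KEY, sort=False)["gene"].nunique()
    samples = plate[SAMPLE_KEY].drop_duplicates()
    bad = []
    for row in samples.itertuples(index=False):
        key = (row.fin, row.region, row.stage, row.replicate)
        if counts.get(key, 0) != len(ref_genes):
            bad.append(key)
    if bad:
        raise PlateIntegrityError(
            "reference gene(s) missing in sample(s): "
            + ", ".join(f"(fin={f}, region={r}, stage={s}, replicate={n})"
                        for f, r, s, n in bad)
        )
    out = refs.groupby(SAMPLE_KEY, as_index=False, sort=False)["cq"].mean()
    return out.rename(columns={"cq": "ref_cq"})


def default_calibrators(fins=design.FINS, stage: int | None = None,
                        replicate: int = 1) -> dict[str, tuple[str, int, int]]:
    """One calibrator per fin: first L region, first stage, replicate 1.

    The study picked an arbitrary biological replicate; a fixed replicate is
    used here for reproducibility and can be overridden.
    """
    stage = design.STAGES[0] if stage is None else stage
    return {fin: (design.L_REGIONS[fin][0], stage, replicate) for fin in fins}


def relative_quantities(
    plate: pd.DataFrame,
    ref_genes: list[str],
    calibrators: dict[str, tuple[str, int, int]] | None = None,
    e: float = 2.0,
) -> pd.DataFrame:
    """ddCq relative quantification of every target-gene well.

    Returns a table with the full lineage (delta_cq, delta_delta_cq, rq,
    log_rq); ``log_rq`` is log2(RQ). The amplification base ``e`` must
    exceed 1.
    """
    if e <= 1:
        raise ValueError("amplification base E must be > 1")
    validate_plate(plate)
    if calibrators is None:
        calibrators = default_calibrators(
            fins=tuple(dict.fromkeys(plate["fin"]))
        )

    ref = reference_cq(plate, ref_genes)
    targets = plate[~plate["gene"].isin(ref_genes)].copy()
    targets = targets.merge(ref, on=SAMPLE_KEY, how="left")
    targets["delta_cq"] = targets["cq"] - targets["ref_cq"]

    cal_rows = []
    for fin, (region, stage, rep) in calibrators.items():
        sel = targets[
            (targets["fin"] == fin)
            & (targets["region"] == region)
            & (targets["stage"] == stage)
            & (targets["replicate"] == rep)
        ]
        cal_rows.append(sel[["gene", "fin", "delta_cq"]])
    cal = pd.concat(cal_rows, ignore_index=True).rename(
        columns={"delta_cq": "cal_delta_cq"}
    )

    out = targets.merge(cal, on=["gene", "fin"], how="left")
    missing = out[out["cal_delta_cq"].isna()][["gene", "fin"]].drop_duplicates()
    if len(missing):
        pairs = ", ".join(f"({g}, {f})" for g, f in missing.itertuples(index=False))
        raise PlateIntegrityError(f"calibrator sample absent for gene/fin: {pairs}")

    out["delta_delta_cq"] = out["delta_cq"] - out["cal_delta_cq"]
    out["rq"] = np.power(float(e), -out["delta_delta_cq"].to_numpy())
    out["log_rq"] = np.log2(out["rq"].to_numpy())
    out = out[
        ["gene", "fin", "region", "stage", "replicate",
         "delta_cq", "delta_delta_cq", "rq", "log_rq"]
    ].reset_index(drop=True)
    out.attrs["amplification_base"] = float(e)
    out.attrs["ref_genes"] = list(ref_genes)
    return out


def qc_efficiencies(
    efficiencies: dict[str, float],
    bounds: tuple[float, float] = (89.0, 111.0),
) -> pd.DataFrame:
    """Flag genes whose percent amplification efficiency leaves the bounds.

    Bounds are inclusive; the report is informational and never mutates data.
    """
    low, high = bounds
    rows = []
    for gene, eff in efficiencies.items():
        if eff <= 0:
            raise ValueError(f"efficiency for {gene} must be positive")
        rows.append(
            {
                "gene": gene,
                "efficiency_pct": float(eff),
                "status": "pass" if low <= eff <= high else "flag",
            }
        )
    return pd.DataFrame(rows, columns=["gene", "efficiency_pct", "status"])
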