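"""Relative-growth-rate inference from barcode count tables.

Pipeline (per pool, condition and biological replicate):

1. TPM normalization: counts are divided by the per-sample total (separately
   per barcode position and technical replicate) and multiplied by 1e6.
2. Technical replicates are averaged *after* the log transform:
   a = mean over technical replicates of log2(TPM + 1).
3. Strains enter the fit only if their raw read count at the first time point
   (summed over technical replicates) exceeds ``min_reads`` (default 30),
   independently per barcode position.
4. A robust (Huber M-estimator) linear model a ~ generations yields a slope
   per barcode position; the strain's growth rate is the mean of the B1 and
   B2 slopes when both are defined, otherwise the defined one.
5. Growth rates are Z-standardized within each (condition, background,
   biological replicate) stratum; a strain is called a hit when Z < -1.5 in
   every biological replicate, and an ethanol "survivor" when
   log2(TPM + 1) > 2 at the last two time points in every replicate.

Missing intermediates stay missing (NaN) all the way down — a dropped strain
never masquerades as neutral.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

SAMPLE_COLS = [
    "pool",
    "background",
    "condition",
    "bio_rep",
    "tech_rep",
    "timepoint_index",
    "generations",
    "barcode_position",
]

#: Huber tuning constant: 95% Gaussian efficiency.
HUBER_C = 1.345
#: MAD-to-sigma consistency factor for the normal distribution.
MAD_SCALE = 0.6745


# ---------------------------------------------------------------------------
# Normalization and technical-replicate collapse
# ---------------------------------------------------------------------------


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Append a TPM column: count / per-sample total * 1e6.

    Totals are computed separately per (pool, condition, bio_rep, tech_rep,
    time point, barcode position).  A sample whose explicit counts sum to
    zero is an error (it cannot be normalized).
    """
    totals = counts.groupby(SAMPLE_COLS, observed=True)["count"].transform("sum")
    if (totals == 0).any():
        bad = counts.loc[totals == 0, SAMPLE_COLS].drop_duplicates().iloc[0].to_dict()
        raise ValueError(f"sample has zero total reads: {bad}")
    out = counts.copy()
    out["tpm"] = out["count"] / totals * 1e6
    return out


def collapse_technical(tpm: pd.DataFrame) -> pd.DataFrame:
    """Average log2(TPM + 1) over technical replicates on a full strain grid.

    Strains absent from a sample count as TPM 0 (contributing log2(1) = 0),
    so the output holds one abundance value for every strain observed in the
    experiment at every sample, per barcode position.

    Returns a long table with columns: strain_id, pool, background,
    condition, bio_rep, barcode_position, timepoint_index, generations, a.
    """
    group_cols = ["pool", "background", "condition", "bio_rep", "barcode_position", "timepoint_index"]
    wide = tpm.pivot_table(
        index="strain_id",
        columns=group_cols + ["tech_rep"],
        values="tpm",
        fill_value=0.0,
        aggfunc="sum",
    )
    log_a = np.log2(wide + 1.0)
    collapsed = log_a.T.groupby(level=group_cols, observed=True).mean().T

    gen_map = tpm[group_cols + ["generations"]].drop_duplicates().set_index(group_cols)["generations"]
    long = collapsed.stack(group_cols, future_stack=True).rename("a").reset_index()
    long["generations"] = pd.MultiIndex.from_frame(long[group_cols]).map(gen_map)
    return long


def filter_low(counts: pd.DataFrame, min_reads: int = 30) -> pd.DataFrame:
    """Strains passing the first-time-point read filter.

    A (strain, pool, condition, bio_rep, barcode_position) series is usable
    iff its raw count at the earliest time point, summed over technical
    replicates, is strictly greater than ``min_reads``.

    Returns the passing keys as a DataFrame.
    """
    t0 = counts.groupby(["pool", "condition", "bio_rep"], observed=True)["timepoint_index"].transform("min")
    first = counts[counts["timepoint_index"] == t0]
    key_cols = ["strain_id", "pool", "condition", "bio_rep", "barcode_position"]
    sums = first.groupby(key_cols, observed=True)["count"].sum()
    return sums[sums > min_reads].reset_index()[key_cols]


# ---------------------------------------------------------------------------
# Robust slope fitting
# ---------------------------------------------------------------------------


def huber_slopes(
    x: np.ndarray,
    Y: np.ndarray,
    c: float = HUBER_C,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> np.ndarray:
    """Huber M-estimated slopes for many series sharing the design ``x``.

    IRLS with the Huber weight function w = min(1, c*s/|r|); the scale ``s``
    is the median absolute residual rescaled by 1/0.6745 and re-estimated at
    every iteration.  Iteration stops when no coefficient moves by more than
    ``tol`` or after ``max_iter`` rounds.  A series whose scale estimate hits
    zero (at least half the points fit exactly) keeps its current fit.

    Parameters
    ----------
    x : (n_points,) generations.
    Y : (n_series, n_points) abundances.

    Returns
    -------
    (n_series,) slopes.  With n_points == 2 this is the exact two-point
    slope; with fewer than 2 points the caller should not be here.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least two points to fit a slope")
    if np.ptp(x) == 0:
        raise ValueError("generations are constant; slope undefined")

    xc = x - x.mean()
    denom = float(xc @ xc)
    b = (Y @ xc) / denom
    a = Y.mean(axis=1) - b * x.mean()
    if n == 2:
        return b

    tiny = np.finfo(float).tiny
    for _ in range(max_iter):
        resid = Y - a[:, None] - b[:, None] * x
        scale = np.median(np.abs(resid), axis=1) / MAD_SCALE
        active = scale > 0
        if not active.any():
            break
        w = np.minimum(1.0, (c * scale[:, None]) / np.maximum(np.abs(resid), tiny))
        sw = w.sum(axis=1)
        swx = w @ x
        swxx = w @ (x * x)
        swy = (w * Y).sum(axis=1)
        swxy = (w * Y) @ x
        det = sw * swxx - swx * swx
        with np.errstate(invalid="ignore", divide="ignore"):
            # inactive rows (scale 0, perfect fit) keep their coefficients
            b_new = np.where(active, (sw * swxy - swx * swy) / det, b)
            a_new = np.where(active, (swy - b_new * swx) / sw, a)
        delta = np.maximum(np.abs(b_new - b), np.abs(a_new - a))
        a, b = a_new, b_new
        if delta.max() < tol:
            break
    return b


def fit_slope(generations, abundance) -> float:
    """Huber slope of one (generations, log2(TPM+1)) series.

    Returns NaN when fewer than two points are available.
    """
    g = np.asarray(generations, dtype=float)
    a = np.asarray(abundance, dtype=float)
    keep = ~(np.isnan(g) | np.isnan(a))
    if keep.sum() < 2:
        return float("nan")
    return float(huber_slopes(g[keep], a[keep][None, :])[0])


def combine_barcodes(slope_b1: float, slope_b2: float) -> float:
    """Mean of the defined barcode slopes; NaN if neither is defined."""
    vals = [s for s in (slope_b1, slope_b2) if s is not None and not np.isnan(s)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def standardize(slopes: pd.Series, ddof: int = 1) -> pd.Series:
    """Z-standardize the defined slopes of one stratum (sample sd, n-1).

    Raises on degenerate strata (fewer than two defined slopes or zero
    spread); missing slopes stay missing.
    """
    defined = slopes.dropna()
    if len(defined) < 2:
        raise ValueError("stratum has fewer than two defined growth rates")
    sd = defined.std(ddof=ddof)
    if sd == 0:
        raise ValueError("degenerate stratum: zero standard deviation of growth rates")
    return (slopes - defined.mean()) / sd


# ---------------------------------------------------------------------------
# Assembled growth-rate table
# ---------------------------------------------------------------------------


def fit_growth_rates(
    counts: pd.DataFrame,
    min_reads: int = 30,
    truncate: Mapping[str, int] | None = None,
    abundance: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """CountTable -> per-strain growth rates and Z-scores.

    Parameters
    ----------
    counts : long CountTable (see ``poolfit.simulate.COUNT_COLUMNS``).
    min_reads : first-time-point raw-read threshold (strict >).
    truncate : condition name -> number of leading time points to use, for
        conditions (8% ethanol in the screen) where the population stops
        turning over later in the experiment.
    abundance : pre-computed output of ``collapse_technical`` (recomputed
        from ``counts`` when omitted).

    Returns
    -------
    DataFrame with one row per (strain, pool, condition, bio_rep):
    slope_B1, slope_B2, slope, n_points, z.
    """
    truncate = dict(truncate or {})
    if abundance is None:
        abundance = collapse_technical(normalize(counts))
    passing = filter_low(counts, min_reads=min_reads)
    pass_idx = set(map(tuple, passing.to_numpy()))

    rows = []
    for (pool, cond, rep, pos), grp in abundance.groupby(
        ["pool", "condition", "bio_rep", "barcode_position"], observed=True, sort=True
    ):
        wide = grp.pivot_table(index="strain_id", columns="timepoint_index", values="a")
        gens = (
            grp[["timepoint_index", "generations"]]
            .drop_duplicates()
            .set_index("timepoint_index")["generations"]
            .reindex(wide.columns)
            .to_numpy(dtype=float)
        )
        if cond in truncate:
            k = truncate[cond]
            wide = wide.iloc[:, :k]
            gens = gens[:k]
        usable = [s for s in wide.index if (s, pool, cond, rep, pos) in pass_idx]
        if not usable or wide.shape[1] < 2:
            continue
        Y = wide.loc[usable].to_numpy(dtype=float)
        ok = ~np.isnan(Y).any(axis=1)
        # strains with missing cells (time points absent from the grid) are
        # fitted individually on their observed points
        slopes = np.full(len(usable), np.nan)
        if ok.any():
            slopes[ok] = huber_slopes(gens, Y[ok])
        for i in np.nonzero(~ok)[0]:
            slopes[i] = fit_slope(gens, Y[i])
        n_pts = (~np.isnan(Y)).sum(axis=1)
        for sid, sl, npt in zip(usable, slopes, n_pts):
            rows.append(
                {
                    "strain_id": sid,
                    "pool": pool,
                    "condition": cond,
                    "bio_rep": rep,
                    "barcode_position": pos,
                    "slope": sl,
                    "n_points": int(npt),
                }
            )
    per_pos = pd.DataFrame(rows)
    if per_pos.empty:
        return pd.DataFrame(
            columns=["strain_id", "pool", "condition", "bio_rep", "slope_B1", "slope_B2", "slope", "n_points", "z"]
        )

    table = per_pos.pivot_table(
        index=["strain_id", "pool", "condition", "bio_rep"],
        columns="barcode_position",
        values=["slope", "n_points"],
        aggfunc="first",
    )
    slope_b1 = table.get(("slope", "B1"))
    slope_b2 = table.get(("slope", "B2"))
    out = pd.DataFrame(index=table.index)
    out["slope_B1"] = slope_b1 if slope_b1 is not None else np.nan
    out["slope_B2"] = slope_b2 if slope_b2 is not None else np.nan
    out["slope"] = out[["slope_B1", "slope_B2"]].mean(axis=1, skipna=True)
    npts = table["n_points"] if "n_points" in table.columns.levels[0] else None
    out["n_points"] = npts.max(axis=1).astype(int) if npts is not None else 0
    out = out.reset_index()

    out["z"] = np.nan
    for _, idx in out.groupby(["pool", "condition", "bio_rep"], observed=True).groups.items():
        out.loc[idx, "z"] = standardize(out.loc[idx, "slope"])
    return out


# ---------------------------------------------------------------------------
# Hit and survivor calling
# ---------------------------------------------------------------------------


def call_hits(growth: pd.DataFrame, z_threshold: float = -1.5) -> pd.DataFrame:
    """Reduced-growth hit calls: Z strictly below threshold in *every* bio rep.

    Returns one row per (strain, pool, condition) with columns ``is_hit`` and
    ``evaluable`` (False when the Z-score is missing in any replicate; such
    strains are never hits).
    """
    z = growth.pivot_table(
        index=["strain_id", "pool", "condition"], columns="bio_rep", values="z", aggfunc="first"
    )
    n_reps = growth.groupby(["pool", "condition"], observed=True)["bio_rep"].nunique()
    out = pd.DataFrame(index=z.index)
    expected = pd.MultiIndex.from_frame(
        z.index.to_frame(index=False)[["pool", "condition"]]
    ).map(n_reps)
    defined = z.notna().sum(axis=1)
    out["evaluable"] = defined.values == expected.to_numpy()
    out["is_hit"] = ((z < z_threshold).sum(axis=1) == expected.to_numpy()) & out["evaluable"]
    return out.reset_index()


def strain_abundance(abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-strain abundance per time point: mean of a over barcode positions."""
    cols = ["strain_id", "pool", "condition", "bio_rep", "timepoint_index", "generations"]
    return abundance.groupby(cols, observed=True)["a"].mean().reset_index()


def call_survivors(
    abundance: pd.DataFrame,
    pool: str,
    condition: str,
    threshold: float = 2.0,
    last_k: int = 2,
) -> pd.DataFrame:
    """Takeover survivors: strains abundant at the end of the experiment.

    A strain is a survivor iff log2(TPM+1) > ``threshold`` (strict) at each of
    the last ``last_k`` time points in *every* biological replicate of the
    given pool and condition.  Abundance per strain is the mean of the B1 and
    B2 values.
    """
    ab = strain_abundance(abundance)
    ab = ab[(ab["pool"] == pool) & (ab["condition"] == condition)]
    if ab.empty:
        raise ValueError(f"no abundance data for pool={pool!r}, condition={condition!r}")
    rep_flags = []
    for rep, grp in ab.groupby("bio_rep", observed=True):
        tps = np.sort(grp["timepoint_index"].unique())
        if len(tps) < last_k:
            raise ValueError(f"replicate {rep!r} has fewer than {last_k} time points")
        last = set(tps[-last_k:])
        sub = grp[grp["timepoint_index"].isin(last)]
        ok = (sub.groupby("strain_id")["a"].agg(lambda v: bool((v > threshold).all()))) & (
            sub.groupby("strain_id")["a"].size() == last_k
        )
        rep_flags.append(ok.rename(rep))
    flags = pd.concat(rep_flags, axis=1).fillna(False)
    out = pd.DataFrame(
        {
            "strain_id": flags.index,
            "pool": pool,
            "condition": condition,
            "is_survivor": flags.all(axis=1).values,
        }
    )
    return out.reset_index(drop=True)


def hybrid_specific_set(
    hits: pd.DataFrame,
    hybrid_pool: str = "hybrid",
    reference_pool: str = "cerevisiae",
    mode: str = "no_condition",
) -> set[str]:
    """Strains with hybrid-specific dosage sensitivity.

    ``mode='no_condition'`` (default): hit in the hybrid pool in at least one
    condition AND hit in the reference pool in no condition at all.
    ``mode='per_condition'``: hit in the hybrid in some condition in which the
    reference pool is not hit.
    """
    hyb = hits[(hits["pool"] == hybrid_pool) & hits["is_hit"]]
    ref = hits[(hits["pool"] == reference_pool) & hits["is_hit"]]
    if mode == "no_condition":
        return set(hyb["strain_id"]) - set(ref["strain_id"])
    if mode == "per_condition":
        ref_by_cond = ref.groupby("condition")["strain_id"].apply(set).to_dict()
        out = set()
        for cond, grp in hyb.groupby("condition"):
            out |= set(grp["strain_id"]) - ref_by_cond.get(cond, set())
        return out
    raise ValueError(f"unknown mode {mode!r}")


def count_identified(counts: pd.DataFrame, min_reads: int = 30) -> tuple[pd.Series, pd.DataFrame]:
    """Screen yield summaries based on the read-count threshold.

    Returns
    -------
    per_pool : number of distinct strains passing the first-time-point filter
        in at least one (condition, bio_rep, barcode position), per pool.
    per_timepoint : strains with > min_reads (summed over technical
        replicates, in at least one barcode position) at each time point, per
        (pool, condition, bio_rep) — the takeover-collapse time series.
    """
    passing = filter_low(counts, min_reads=min_reads)
    per_pool = passing.groupby("pool")["strain_id"].nunique()

    sums = counts.groupby(
        ["pool", "condition", "bio_rep", "timepoint_index", "strain_id", "barcode_position"],
        observed=True,
    )["count"].sum()
    detected = sums[sums > min_reads].reset_index()
    per_tp = (
        detected.groupby(["pool", "condition", "bio_rep", "timepoint_index"], observed=True)["strain_id"]
        .nunique()
        .rename("n_identified")
        .reset_index()
    )
    return per_pool, per_tp


def summarize_hits(hits: pd.DataFrame, gene_map: Mapping[str, str] | None = None) -> dict[str, int]:
    """Allele-level and gene-collapsed counts of strains hit anywhere.

    ``n_alleles``: strains with is_hit in >= 1 (pool, condition);
    ``n_genes``: same after collapsing strain ids through ``gene_map``
    (equal to ``n_alleles`` when no map is given).
    """
    hit_strains = set(hits.loc[hits["is_hit"], "strain_id"])
    n_alleles = len(hit_strains)
    if gene_map:
        n_genes = len({gene_map.get(s, s) for s in hit_strains})
    else:
        n_genes = n_alleles
    return {"n_alleles": n_alleles, "n_genes": n_genes}
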