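"""Relative qPCR quantification (2^-ddCt) and mRNA half-life estimation.

Transcription is arrested with actinomycin D and cells harvested over a
0-48 h grid; abundance follows first-order decay, so ln(abundance) is linear
in time and one halving corresponds to +1 Ct at perfect amplification
efficiency (fixed at 2.0; the assay applies no efficiency correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CT_COLUMNS = ["gene", "fraction", "condition", "timepoint_h", "replicate", "ct"]
#: harvest grid (hours post actinomycin D)
TIMEPOINTS_H = (0, 1, 2, 4, 8, 12, 18, 24, 36, 48)
#: internal control genes used for ddCt normalization
REFERENCE_GENES = ("HPRT1", "SNRNP200", "ZMYM4")


@dataclass
class HalfLife:
    """First-order decay estimate for one (gene, fraction, condition)."""

    gene: str
    fraction: str
    condition: str
    k: float            # decay rate, 1/h
    se: float           # standard error of k
    r2: float
    n_points: int
    flag: str = "ok"    # ok | stable | unestimable

    @property
    def t_half_h(self) -> float:
        return np.log(2) / self.k if self.k > 0 else np.inf


def relative_abundance(
    ct_table: pd.DataFrame, reference_genes=REFERENCE_GENES
) -> pd.DataFrame:
    """Per-row 2^-ddCt abundance relative to the reference genes and t=0.

    dCt subtracts the arithmetic mean reference Ct within the same
    (fraction, condition, timepoint, replicate); ddCt subtracts the mean
    dCt at t=0 of the same (gene, fraction, condition). Rows lacking a
    reference measurement are dropped with a log message.
    """
    df = ct_table.copy()
    if (df["ct"] <= 0).any() or (df["ct"] >= 45).any():
        raise ValueError("Ct values must lie in (0, 45)")
    refs = df[df["gene"].isin(reference_genes)]
    if refs.empty:
        raise ValueError("no reference-gene rows in the Ct table")
    key = ["fraction", "condition", "timepoint_h", "replicate"]
    ref_mean = refs.groupby(key)["ct"].mean().rename("ref_ct")
    targets = df[~df["gene"].isin(reference_genes)].merge(
        ref_mean, left_on=key, right_index=True, how="left"
    )
    missing = targets["ref_ct"].isna()
    if missing.any():
        log.warning("dropping %d rows without a reference Ct", int(missing.sum()))
        targets = targets[~missing]
    targets["dct"] = targets["ct"] - targets["ref_ct"]
    base = (
        targets[targets["timepoint_h"] == 0]
        .groupby(["gene", "fraction", "condition"])["dct"]
        .mean()
        .rename("dct0")
    )
    targets = targets.merge(base, left_on=["gene", "fraction", "condition"], right_index=True)
    targets["ddct"] = targets["dct"] - targets["dct0"]
    targets["abundance"] = 2.0 ** (-targets["ddct"])
    return targets.drop(columns=["ref_ct", "dct", "dct0"])


def fit_halflife(
    timepoints_h,
    abundances,
    min_points: int = 4,
    floor: float = 0.01,
    gene: str = "",
    fraction: str = "",
    condition: str = "",
) -> HalfLife:
    """Least-squares fit of ln(abundance) on time; t1/2 = ln2 / (-slope).

    Points at or below ``floor`` times the t=0 level are excluded (late
    timepoints plateau at the qPCR noise floor). Fewer than ``min_points``
    usable points flags the estimate unestimable; a non-positive rate is
    flagged stable with infinite half-life.
    """
    t = np.asarray(timepoints_h, dtype=float)
    a = np.asarray(abundances, dtype=float)
    if t.shape != a.shape:
        raise ValueError("timepoints and abundances differ in length")
    level0 = a[t == 0].mean() if (t == 0).any() else a.max()
    usable = a > floor * level0
    t, a = t[usable], a[usable]
    if t.size < min_points or np.ptp(t) == 0:
        return HalfLife(gene, fraction, condition, np.nan, np.nan, np.nan, int(t.size),
                        flag="unestimable")
    res = stats.linregress(t, np.log(a))
    k = -res.slope
    flag = "ok" if k > 0 else "stable"
    return HalfLife(gene, fraction, condition, float(k), float(res.stderr),
                    float(res.rvalue**2), int(t.size), flag=flag)


def fit_halflives(rel: pd.DataFrame, min_points: int = 4, floor: float = 0.01) -> pd.DataFrame:
    """Fit every (gene, fraction, condition) series of a relative-abundance table."""
    rows = []
    for (gene, frac, cond), sub in rel.groupby(["gene", "fraction", "condition"]):
        hl = fit_halflife(
            sub["timepoint_h"].values, sub["abundance"].values,
            min_points=min_points, floor=floor, gene=gene, fraction=frac, condition=cond,
        )
        rows.append(
            dict(gene=gene, fraction=frac, condition=cond, k=hl.k,
                 t_half_h=hl.t_half_h, se=hl.se, r2=hl.r2, n=hl.n_points, flag=hl.flag)
        )
    return pd.DataFrame(rows)


def compare_halflife(a: HalfLife, b: HalfLife) -> dict:
    """Half-life ratio b/a and a z-test on the decay rates."""
    if a.flag == "unestimable" or b.flag == "unestimable":
        raise ValueError("cannot compare unestimable half-lives")
    if not np.isfinite(a.t_half_h) or not np.isfinite(b.t_half_h):
        return dict(ratio=np.nan, z=np.nan, p=np.nan, flag="infinite_halflife")
    z = (a.k - b.k) / np.sqrt(a.se**2 + b.se**2) if (a.se or b.se) else 0.0
    p = 1.0 if z == 0 else float(2 * stats.norm.sf(abs(z)))
    return dict(ratio=b.t_half_h / a.t_half_h, z=float(z), p=min(1.0, p), flag="ok")


def check_transcription_arrest(
    rel_premrna: pd.DataFrame, max_residual: float = 0.5, checkpoint_h: float | None = None
) -> dict[str, bool]:
    """Verify actinomycin D stopped transcription in each condition.

    Uses nuclear pre-mRNA relative abundance: arrest passes for a condition
    when the mean abundance at the first post-treatment timepoint (or
    ``checkpoint_h``) has dropped below ``max_residual`` of baseline.
    """
    out: dict[str, bool] = {}
    for cond, sub in rel_premrna.groupby("condition"):
        post = sorted(t for t in sub["timepoint_h"].unique() if t > 0)
        if not post:
            out[cond] = False
            continue
        t_check = checkpoint_h if checkpoint_h is not None else post[0]
        level = sub.loc[sub["timepoint_h"] == t_check, "abundance"].mean()
        out[cond] = bool(level < max_residual)
    return out
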