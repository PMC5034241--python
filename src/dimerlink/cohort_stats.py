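"""Cohort-level statistics of the Gaussian entanglement G'.

Operates on a table with one row per dimer (pdb_id, g_prime, g_mean,
n_residues, human).  A transcription of the published 110-dimer
domain-swapped cohort ships with the package
(:func:`load_packaged_cohort`) so the statistics can be reproduced
without recomputing any structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import erf

COHORT_COLUMNS = ["pdb_id", "g_prime", "g_mean", "n_residues", "human"]

_SQRT2 = float(np.sqrt(2.0))


def load_cohort(path: str | Path, provenance: str = "user") -> pd.DataFrame:
    """Load a cohort TSV (columns pdb_id, g_prime, g_mean, n_residues, human)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if df["pdb_id"].duplicated().any():
        dupes = df.loc[df["pdb_id"].duplicated(), "pdb_id"].tolist()
        raise ValueError(f"duplicate pdb_ids in cohort table: {dupes}")
    if (df["n_residues"] <= 0).any():
        raise ValueError("n_residues must be positive")
    df = df.copy()
    df["human"] = df["human"].astype(bool)
    df.attrs["provenance"] = provenance
    return df


def load_packaged_cohort() -> pd.DataFrame:
    """The packaged 110-dimer domain-swapped cohort (published values)."""
    ref = resources.files("dimerlink.data") / "swapped_dimer_cohort.tsv"
    with resources.as_file(ref) as path:
        return load_cohort(path, provenance="published_cohort_table")


@dataclass(frozen=True)
class ThresholdCounts:
    """Counts of dimers in the extreme- and negative-G' classes.

    All comparisons are strict, so the boundary values G' = ±1 fall in
    the middle class.  Percentages are rounded to the nearest integer.
    """

    n_total: int
    n_human: int
    n_below_minus1: int
    n_above_plus1: int
    n_negative: int
    pct_negative: int
    pct_negative_human: int
    pct_negative_nonhuman: int
    pct_extreme: int  # |G'| > 1


def threshold_counts(table: pd.DataFrame) -> ThresholdCounts:
    if len(table) == 0:
        raise ValueError("empty cohort table")
    gp = table["g_prime"].to_numpy(float)
    human = table["human"].to_numpy(bool)
    neg = gp < 0

    def pct(mask_num, mask_den) -> int:
        den = int(mask_den.sum())
        return int(round(100.0 * int((mask_num & mask_den).sum()) / den)) if den else 0

    return ThresholdCounts(
        n_total=len(table),
        n_human=int(human.sum()),
        n_below_minus1=int((gp < -1).sum()),
        n_above_plus1=int((gp > 1).sum()),
        n_negative=int(neg.sum()),
        pct_negative=pct(neg, np.ones_like(neg)),
        pct_negative_human=pct(neg, human),
        pct_negative_nonhuman=pct(neg, ~human),
        pct_extreme=pct(np.abs(gp) > 1, np.ones_like(neg)),
    )


@dataclass(frozen=True)
class DistributionFit:
    """Location/width fit of the G' distribution.

    ``erf_width`` is the width parameter Δ of the error-function CDF
    F(x) = ½[1 + erf((x − m)/Δ)]; the equivalent Gaussian standard
    deviation is ``sd`` = Δ/√2.  For histogram fits ``sd`` is the
    fitted Gaussian σ and ``erf_width`` = √2·σ.
    """

    mean: float
    sd: float
    fit_kind: str  # "erf_cdf" or "gaussian_histogram"
    residual: float
    bin_width: float | None = None

    @property
    def erf_width(self) -> float:
        return self.sd * _SQRT2


def _erf_cdf(x, m, delta):
    return 0.5 * (1.0 + erf((x - m) / delta))


def fit_gprime_distribution(
    values,
    fit_kind: str = "erf_cdf",
    bin_width: float = 0.25,
) -> DistributionFit:
    """Fit the empirical distribution of G' values.

    erf_cdf:
        Least squares of F(x) = ½[1 + erf((x − m)/Δ)] against the ECDF
        F(x) = #{values ≤ x}/n evaluated at the sorted sample points.
        This is bin-free and is the headline width estimate.
    gaussian_histogram:
        Least-squares Gaussian fit to a density histogram with bins of
        ``bin_width`` aligned so a bin edge sits at 0.  Bin-dependent;
        provided for qualitative comparison.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ValueError("need at least 10 values to fit a distribution")
    if np.ptp(v) == 0:
        raise ValueError("degenerate sample: all values equal")

    if fit_kind == "erf_cdf":
        x = np.sort(v)
        ecdf = np.arange(1, x.size + 1) / x.size
        p0 = [float(v.mean()), float(v.std() * _SQRT2)]
        popt, _ = curve_fit(_erf_cdf, x, ecdf, p0=p0)
        m, delta = float(popt[0]), abs(float(popt[1]))
        resid = float(np.sqrt(np.mean((_erf_cdf(x, m, delta) - ecdf) ** 2)))
        return DistributionFit(mean=m, sd=delta / _SQRT2, fit_kind=fit_kind, residual=resid)

    if fit_kind == "gaussian_histogram":
        lo = np.floor(v.min() / bin_width) * bin_width
        hi = np.ceil(v.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        density, edges = np.histogram(v, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def gauss(x, m, s):
            return np.exp(-0.5 * ((x - m) / s) ** 2) / (s * _SQRT2 * np.sqrt(np.pi))

        popt, _ = curve_fit(gauss, centers, density, p0=[float(v.mean()), float(v.std())])
        m, s = float(popt[0]), abs(float(popt[1]))
        resid = float(np.sqrt(np.mean((gauss(centers, m, s) - density) ** 2)))
        return DistributionFit(mean=m, sd=s, fit_kind=fit_kind, residual=resid, bin_width=bin_width)

    raise ValueError(f"unknown fit_kind {fit_kind!r}")


def length_trend(table: pd.DataFrame, window: int = 21) -> pd.DataFrame:
    """Running mean of |G'| against chain length N.

    Rows are sorted by n_residues (ties by pdb_id); a centred moving
    average of window ``window`` (odd) is applied, truncating the
    window at the edges.  A window larger than the table collapses to
    the global mean.  Returns columns n_residues, abs_g_prime,
    running_mean.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    df = table.sort_values(["n_residues", "pdb_id"], kind="stable").reset_index(drop=True)
    abs_gp = df["g_prime"].abs().to_numpy(float)
    if window >= abs_gp.size:
        run = np.full(abs_gp.size, abs_gp.mean())
    else:
        run = (
            pd.Series(abs_gp)
            .rolling(window=window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    return pd.DataFrame(
        {"n_residues": df["n_residues"], "pdb_id": df["pdb_id"],
         "abs_g_prime": abs_gp, "running_mean": run}
    )
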