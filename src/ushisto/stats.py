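"""Agreement and correlation between US-based and histology-based measurements.

Two annotation sources in ultrasound (manual US_M and registered US_Reg)
are each compared against the whole-slide-image measurement of the same
slide and region.  Agreement is summarized Bland-Altman style (mean
difference and 1.96-SD limits of agreement) and association by
Spearman's rank correlation, overall and within magnitude categories of
the two-modality mean (< 5, 5 < 10, > 10 mm) — short margins are the
clinically critical stratum.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .margins import MeasurementRecord

__all__ = [
    "PairedMeasurement",
    "BlandAltmanResult",
    "CorrelationResult",
    "CATEGORIES",
    "spearman_correlation",
    "bland_altman",
    "bland_altman_from_diffs",
    "split_categories",
    "pair_measurements",
    "agreement_report",
    "bland_altman_plot",
]

CATEGORIES = ("<5", "5<10", ">10")
_LOA_MULTIPLIER = 1.96  # normal-theory 95% limits of agreement


@dataclass(frozen=True)
class PairedMeasurement:
    slide_id: str
    region: str
    wsi_mm: float
    us_mm: float
    us_source: str  # US_M | US_Reg

    @property
    def mean_mm(self) -> float:
        return 0.5 * (self.us_mm + self.wsi_mm)

    @property
    def diff_mm(self) -> float:
        return self.us_mm - self.wsi_mm

    @property
    def category(self) -> str:
        return _category_of(self.mean_mm)


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    mean_diff_mm: float
    sd_diff_mm: float
    loa_lower_mm: float
    loa_upper_mm: float


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def _category_of(mean_mm: float) -> str:
    """Left-closed category boundaries: [0,5), [5,10), [10,inf)."""
    if mean_mm < 0:
        raise ValueError(f"negative mean measurement {mean_mm}")
    if mean_mm < 5.0:
        return "<5"
    if mean_mm < 10.0:
        return "5<10"
    return ">10"


def spearman_correlation(x, y, exact_max_n: int = 9) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on ties).
    For n <= ``exact_max_n`` the p-value is the exact permutation
    probability P(|rho_perm| >= |rho_obs|) over all n! orderings;
    otherwise the usual t-approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        num = pc @ rxc
        den = np.sqrt((pc**2).sum(axis=1) * (rxc**2).sum())
        rho_perm = num / den
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=p, n=n)


def bland_altman_from_diffs(diffs) -> BlandAltmanResult:
    d = np.asarray(diffs, dtype=float)
    if len(d) < 2:
        raise ValueError("Bland-Altman needs at least 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        n=len(d),
        mean_diff_mm=mean,
        sd_diff_mm=sd,
        loa_lower_mm=mean - _LOA_MULTIPLIER * sd,
        loa_upper_mm=mean + _LOA_MULTIPLIER * sd,
    )


def bland_altman(pairs: list[PairedMeasurement]) -> BlandAltmanResult:
    """Mean difference and 95% limits of agreement for paired values."""
    return bland_altman_from_diffs([p.diff_mm for p in pairs])


def split_categories(pairs: list[PairedMeasurement]) -> dict[str, list[PairedMeasurement]]:
    """Partition pairs by the magnitude category of their two-modality mean."""
    out: dict[str, list[PairedMeasurement]] = {c: [] for c in CATEGORIES}
    for p in pairs:
        out[p.category].append(p)
    return out


def pair_measurements(
    measurements: list[MeasurementRecord], us_source: str
) -> list[PairedMeasurement]:
    """Join one US source against WSI on (slide_id, region)."""
    wsi = {
        (m.slide_id, m.region): m.value_mm for m in measurements if m.source == "WSI"
    }
    pairs = []
    for m in measurements:
        if m.source != us_source:
            continue
        key = (m.slide_id, m.region)
        if key in wsi:
            pairs.append(
                PairedMeasurement(
                    slide_id=m.slide_id,
                    region=m.region,
                    wsi_mm=wsi[key],
                    us_mm=m.value_mm,
                    us_source=us_source,
                )
            )
    # deterministic order regardless of input record order
    pairs.sort(key=lambda p: (p.slide_id, p.region))
    return pairs


def agreement_report(
    measurements: list[MeasurementRecord], us_sources: tuple[str, ...] = ("US_M", "US_Reg")
) -> pd.DataFrame:
    """Correlation + agreement table per US source and magnitude stratum.

    One row per (us_source, stratum) with stratum in All, <5, 5<10, >10.
    Strata with fewer than 3 pairs are flagged ``computed = False`` and
    carry NaN statistics.  The result is a pure function of the record
    list (row order is fixed by source and stratum, not input order).

    Note: slides from the same patient are pooled without a clustering
    adjustment; treat per-stratum p-values accordingly.
    """
    if not any(m.source == "WSI" for m in measurements):
        raise ValueError("no WSI measurements to compare against")
    rows = []
    for source in us_sources:
        pairs = pair_measurements(measurements, source)
        strata: list[tuple[str, list[PairedMeasurement]]] = [("All", pairs)]
        strata += [(c, v) for c, v in split_categories(pairs).items()]
        for name, sel in strata:
            row: dict = {"us_source": source, "stratum": name, "n": len(sel)}
            if len(sel) >= 3:
                us = [p.us_mm for p in sel]
                wsi = [p.wsi_mm for p in sel]
                try:
                    corr = spearman_correlation(us, wsi)
                    row.update(rho=corr.rho, p=corr.p_value)
                except ValueError:
                    row.update(rho=np.nan, p=np.nan)
                ba = bland_altman(sel)
                row.update(
                    mean_diff_mm=ba.mean_diff_mm,
                    loa_lower_mm=ba.loa_lower_mm,
                    loa_upper_mm=ba.loa_upper_mm,
                    computed=True,
                )
            else:
                row.update(
                    rho=np.nan,
                    p=np.nan,
                    mean_diff_mm=np.nan,
                    loa_lower_mm=np.nan,
                    loa_upper_mm=np.nan,
                    computed=False,
                )
            rows.append(row)
    cols = [
        "us_source",
        "stratum",
        "n",
        "rho",
        "p",
        "mean_diff_mm",
        "loa_lower_mm",
        "loa_upper_mm",
        "computed",
    ]
    return pd.DataFrame(rows)[cols]


def bland_altman_plot(pairs: list[PairedMeasurement], path, title: str = "") -> None:
    """Difference-vs-mean plot with category coloring and LoA lines (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"<5": "tab:red", "5<10": "tab:green", ">10": "tab:blue"}
    fig, ax = plt.subplots(figsize=(6, 4))
    by_cat = split_categories(pairs)
    for cat, sel in by_cat.items():
        if sel:
            ax.scatter(
                [p.mean_mm for p in sel],
                [p.diff_mm for p in sel],
                s=14,
                color=colors[cat],
                label=f"{cat} mm (n={len(sel)})",
            )
    ba = bland_altman(pairs)
    ax.axhline(ba.mean_diff_mm, color="tab:blue", lw=1.2)
    for y in (ba.loa_lower_mm, ba.loa_upper_mm):
        ax.axhline(y, color="tab:red", ls="--", lw=1.0)
    for x in (5.0, 10.0):
        ax.axvline(x, color="k", ls=":", lw=0.8)
    ax.set_xlabel("mean of modalities (mm)")
    ax.set_ylabel("US - WSI difference (mm)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
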