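"""Per-parcel areal metrics and interspecies statistics.

Absolute cortical measurements scale with brain size, so interspecies
comparison uses relative quantities: each parcel's surface area (sum of
barycentric vertex areas on the mid-thickness surface), mean thickness,
and wedge volume are expressed as fractions of the hemisphere totals.
Group differences are tested with a two-way fixed-effects ANOVA (factors:
species and cortical parcel, with interaction; Type III sums of squares
under sum-to-zero contrasts, appropriate for the unbalanced species
design), followed by per-parcel pairwise Welch t tests with Bonferroni
correction over (species pairs × parcels) comparisons.  Hemispheres are
treated as independent observations, matching the hemisphere-count
accounting of comparative-anatomy studies (e.g. 64/18/40 hemispheres and
interaction df (6, 476) for three species × four parcels).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import (
    MetricMap,
    SurfacePair,
    compute_midthickness,
    correspondence_thickness,
    vertex_areas,
    wedge_volumes,
)
from .parcellation import ParcelLabelMap

__all__ = [
    "METRICS_COLUMNS",
    "AnovaResult",
    "parcel_metrics",
    "relative_fraction",
    "two_way_anova",
    "posthoc_bonferroni",
    "summary_report",
]

METRICS_COLUMNS = [
    "subject_id",
    "hemisphere",
    "species",
    "parcel",
    "area_mm2",
    "mean_thickness_mm",
    "volume_mm3",
    "total_area_mm2",
    "total_volume_mm3",
    "rel_area",
    "rel_volume",
]

RESPONSES = ("rel_area", "mean_thickness_mm", "rel_volume")


def parcel_metrics(
    pair: SurfacePair,
    labels: ParcelLabelMap,
    thickness: MetricMap | None = None,
    subject_id: str = "",
    hemisphere: str = "",
    species: str = "",
    area_weighted_thickness: bool = False,
) -> pd.DataFrame:
    """Per-parcel area, mean thickness, and wedge volume in native space.

    Areas are sums of barycentric vertex areas on the mid-thickness
    surface; volumes are sums of vertexwise wedge volumes between white
    and pial; mean thickness is the plain (unweighted) vertex average by
    default, with an area-weighted variant behind a flag.  Totals run over
    all vertices, labelled or not.  Empty parcels yield a zero row with a
    warning.
    """
    mid = compute_midthickness(pair)
    va = vertex_areas(mid).values
    wv = wedge_volumes(pair).values
    th = (thickness or correspondence_thickness(pair)).values
    total_area = float(va.sum())
    total_vol = float(wv.sum())
    rows = []
    for lab in sorted(labels.names):
        name = labels.names[lab]
        sel = labels.labels == lab
        n = int(np.count_nonzero(sel))
        if n == 0:
            warnings.warn(f"parcel {name!r} is empty", stacklevel=2)
            area = vol = mean_th = 0.0
        else:
            area = float(va[sel].sum())
            vol = float(wv[sel].sum())
            if area_weighted_thickness:
                mean_th = float(np.average(th[sel], weights=va[sel]))
            else:
                mean_th = float(np.mean(th[sel]))
        rows.append(
            dict(
                subject_id=subject_id,
                hemisphere=hemisphere,
                species=species,
                parcel=name,
                area_mm2=area,
                mean_thickness_mm=mean_th,
                volume_mm3=vol,
                total_area_mm2=total_area,
                total_volume_mm3=total_vol,
                rel_area=area / total_area,
                rel_volume=vol / total_vol,
            )
        )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def relative_fraction(area_mm2: float, total_mm2: float) -> float:
    """Percentage 100·area/total, rounded half-up to one decimal place.

    This is the printed-report convention (e.g. 47.9/2030 → 2.4).
    """
    if total_mm2 <= 0:
        raise ValueError("total must be > 0")
    pct = Decimal(100.0 * area_mm2 / total_mm2)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Two-way ANOVA factor table plus (optional) post hoc table."""

    anova: pd.DataFrame                 # effect, F, df1, df2, p, ss
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)
    zero_residual_variance: bool = False


def _sum_contrast(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding: (n, n_levels-1) columns."""
    X = np.zeros((len(codes), n_levels - 1))
    for j in range(n_levels - 1):
        X[codes == j, j] = 1.0
    X[codes == n_levels - 1, :] = -1.0
    return X


def _check_cells(df: pd.DataFrame) -> tuple[list, list]:
    species = sorted(df["species"].unique())
    parcels = sorted(df["parcel"].unique())
    if len(species) < 2 or len(parcels) < 1:
        raise ValueError("need >= 2 species levels and >= 1 parcel level")
    counts = df.groupby(["species", "parcel"]).size()
    for s in species:
        for p in parcels:
            if (s, p) not in counts.index:
                raise ValueError(f"empty design cell: species={s!r}, parcel={p!r}")
    return species, parcels


def two_way_anova(table: pd.DataFrame, response: str = "rel_area") -> AnovaResult:
    """Fixed-effects two-way ANOVA: species, parcel, species×parcel.

    Type III sums of squares with sum-to-zero contrasts (each effect is
    tested after all others including the interaction — the standard
    choice for unbalanced designs); residual df = N − a·b.  A response
    with zero residual variance is flagged and reported with F = 0.

    A single-level parcel factor degrades gracefully to the one-way model
    (parcel and interaction rows omitted), where the species F statistic
    on two balanced groups reduces exactly to the squared pooled t.
    """
    if response not in table.columns:
        raise KeyError(response)
    species, parcels = _check_cells(table)
    y = table[response].to_numpy(dtype=np.float64)
    s_codes = pd.Categorical(table["species"], categories=species).codes.astype(int)
    p_codes = pd.Categorical(table["parcel"], categories=parcels).codes.astype(int)
    a, b = len(species), len(parcels)
    n = len(y)
    Xs = _sum_contrast(s_codes, a)
    Xp = _sum_contrast(p_codes, b)
    Xi = np.einsum("ni,nj->nij", Xs, Xp).reshape(n, (a - 1) * (b - 1))
    ones = np.ones((n, 1))

    def rss(X: np.ndarray) -> float:
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    X_full = np.hstack([ones, Xs, Xp, Xi])
    rss_full = rss(X_full)
    df2 = n - a * b
    blocks = {
        "species": (np.hstack([ones, Xp, Xi]), a - 1),
    }
    if b > 1:
        blocks["parcel"] = (np.hstack([ones, Xs, Xi]), b - 1)
        blocks["species:parcel"] = (np.hstack([ones, Xs, Xp]), (a - 1) * (b - 1))
    zero_var = rss_full <= max(1e-12 * float(y @ y), 1e-300)
    rows = []
    for effect, (X_red, df1) in blocks.items():
        ss = max(rss(X_red) - rss_full, 0.0)
        if zero_var:
            F, p = 0.0, 1.0
        else:
            F = (ss / df1) / (rss_full / df2)
            p = float(sps.f.sf(F, df1, df2))
        rows.append(dict(effect=effect, F=F, df1=df1, df2=df2, p=p, ss=ss))
    return AnovaResult(
        anova=pd.DataFrame(rows), zero_residual_variance=bool(zero_var)
    )


def posthoc_bonferroni(table: pd.DataFrame, response: str = "rel_area") -> pd.DataFrame:
    """Per-parcel pairwise Welch t tests, Bonferroni-corrected.

    The correction count m = (species pairs) × (parcels) spans the whole
    comparison family (e.g. 3 × 4 = 12 for three species and four
    parcels); p_bonferroni = min(1, m·p_raw).  Groups with n < 2 are
    flagged and not tested.
    """
    if response not in table.columns:
        raise KeyError(response)
    species = sorted(table["species"].unique())
    parcels = sorted(table["parcel"].unique())
    pairs = list(itertools.combinations(species, 2))
    m = len(pairs) * len(parcels)
    rows = []
    for parcel in parcels:
        sub = table[table["parcel"] == parcel]
        for s1, s2 in pairs:
            g1 = sub.loc[sub["species"] == s1, response].to_numpy(dtype=float)
            g2 = sub.loc[sub["species"] == s2, response].to_numpy(dtype=float)
            if len(g1) < 2 or len(g2) < 2:
                rows.append(
                    dict(parcel=parcel, species_pair=f"{s1} vs {s2}", t=np.nan,
                         df=np.nan, p_raw=np.nan, p_bonferroni=np.nan, m=m,
                         n1=len(g1), n2=len(g2), flag="n<2")
                )
                continue
            if np.allclose(g1, g1[0]) and np.allclose(g2, g2[0]) and g1[0] == g2[0]:
                t, p, df = 0.0, 1.0, float(len(g1) + len(g2) - 2)
            else:
                res = sps.ttest_ind(g1, g2, equal_var=False)
                t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
            rows.append(
                dict(parcel=parcel, species_pair=f"{s1} vs {s2}", t=t, df=df,
                     p_raw=p, p_bonferroni=min(1.0, m * p), m=m,
                     n1=len(g1), n2=len(g2), flag="")
            )
    return pd.DataFrame(rows)


def summary_report(table: pd.DataFrame) -> pd.DataFrame:
    """Species × parcel group means ± sd and n for each response.

    Deterministic (species, parcel) ordering; groups with a single
    observation report sd 0 and are flagged.
    """
    if table.empty:
        raise ValueError("empty metrics table")
    rows = []
    for (species, parcel), g in table.groupby(["species", "parcel"], sort=True):
        row = dict(species=species, parcel=parcel, n=len(g),
                   flag="n=1" if len(g) == 1 else "")
        for resp in RESPONSES:
            vals = g[resp].to_numpy(dtype=float)
            row[f"{resp}_mean"] = float(vals.mean())
            row[f"{resp}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
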