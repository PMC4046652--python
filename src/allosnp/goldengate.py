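"""Two-channel genotyping analysis: theta clustering and assay QC.

Each (sample, assay) pair contributes a point with
``theta = (2/pi) * arctan(Cy5/Cy3)`` in [0, 1] and ``normR = Cy3 + Cy5``.
A homozygote for allele A sits near theta 0, a homozygote for allele B
near 1, and a heterozygote near 0.5.  Per assay, a one-dimensional
cluster model is fitted to the theta values for each candidate cluster
count k (deterministic quantile initialisation, Lloyd iterations,
equal-variance Gaussian BIC selection with ties broken toward smaller k);
genotype calls are cluster memberships, with no-calls for points of low
total intensity or far from every centre.  An assay whose pooled
two-population fit needs four or more clusters is flagged as a hemi-SNP:
a single-locus (simple) SNP can produce at most three genotype groups, so
a fourth group betrays signal summed from a second locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ThetaPoint:
    sample: str
    assay: str
    theta: float
    norm_r: float
    no_signal: bool = False


def theta_transform(cy3: float, cy5: float) -> tuple[float, float]:
    """(theta, normR) for one intensity pair; both zero -> no-signal."""
    if cy3 < 0 or cy5 < 0:
        raise ValueError("intensities must be non-negative")
    if cy3 == 0 and cy5 == 0:
        return float("nan"), 0.0
    theta = 2.0 / np.pi * np.arctan2(cy5, cy3)
    return float(theta), float(cy3 + cy5)


def theta_frame(intensities: pd.DataFrame) -> pd.DataFrame:
    """Vectorised transform of a (sample, assay, Cy3, Cy5) table."""
    out = intensities.copy()
    cy3 = out["Cy3"].to_numpy(float)
    cy5 = out["Cy5"].to_numpy(float)
    if (cy3 < 0).any() or (cy5 < 0).any():
        raise ValueError("intensities must be non-negative")
    theta = 2.0 / np.pi * np.arctan2(cy5, cy3)
    theta[(cy3 == 0) & (cy5 == 0)] = np.nan
    out["theta"] = theta
    out["normR"] = cy3 + cy5
    return out


# --------------------------------------------------------------------------
# 1-D cluster model


@dataclass
class ClusterModel:
    assay: str
    k: int
    centers: np.ndarray          # sorted ascending
    assignments: np.ndarray      # cluster index per point (-1 for excluded)
    bic_by_k: dict[int, float] = field(default_factory=dict)


def _lloyd_1d(values: np.ndarray, k: int, max_iter: int = 100):
    """Deterministic 1-D k-means: centres start at evenly spaced quantiles."""
    qs = (np.arange(k) + 0.5) / k
    centers = np.quantile(values, qs)
    for _ in range(max_iter):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(k):
            sel = values[assign == j]
            if sel.size:
                new[j] = sel.mean()
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    order = np.argsort(centers, kind="stable")
    centers = centers[order]
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    assign = remap[np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)]
    return centers, assign


def fit_clusters(
    values: np.ndarray,
    k_max: int = 6,
    assay: str = "",
    min_separation: float = 0.12,
    min_cluster_size: int | None = None,
    var_floor: float = 1e-6,
) -> ClusterModel:
    """Select k by equal-variance Gaussian BIC over k = 1..k_max.

    Fits with fewer points than centres are skipped; candidate fits whose
    adjacent centres sit closer than ``min_separation`` are rejected
    (a split tighter than the noise scale is never a real genotype group),
    as are fits assigning fewer than ``min_cluster_size`` points to any
    cluster — by default 5% of the points (at least 3), because a genuine
    genotype group in a mapping population is never a handful of outliers,
    while theta (a ratio of noisy channels) has heavier-than-Gaussian
    tails that would otherwise split off spurious groups.  BIC ties go to
    the smaller k.
    """
    values = np.sort(np.asarray(values, dtype=float))
    values = values[~np.isnan(values)]
    n = values.size
    if n < 2:
        raise ValueError("need at least two points to fit clusters")
    if min_cluster_size is None:
        min_cluster_size = max(3, int(round(0.05 * n)))
    best: tuple[float, int] | None = None
    fits: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    bics: dict[int, float] = {}
    for k in range(1, k_max + 1):
        if n < k:
            break
        centers, assign = _lloyd_1d(values, k)
        if k > 1 and np.diff(centers).min() < min_separation:
            continue
        if k > 1 and np.bincount(assign, minlength=k).min() < min_cluster_size:
            continue
        wcss = float(((values - centers[assign]) ** 2).sum())
        sigma2 = max(wcss / n, var_floor)
        bic = n * np.log(sigma2) + 2 * k * np.log(n)
        fits[k] = (centers, assign)
        bics[k] = bic
        if best is None or bic < best[0] - 1e-12:  # strict: ties keep smaller k
            best = (bic, k)
    assert best is not None
    k = best[1]
    centers, assign = fits[k]
    return ClusterModel(assay, k, centers, assign, bics)


# --------------------------------------------------------------------------
# genotype calls and call rates


@dataclass
class CallSet:
    calls: pd.DataFrame          # sample, assay, cluster (-1 = no-call), theta
    assay_call_rate: pd.Series
    sample_call_rate: pd.Series
    excluded_samples: list[str]


def call_genotypes(
    theta_df: pd.DataFrame,
    models: dict[str, ClusterModel],
    min_intensity: float = 1000.0,
    max_center_distance: float = 0.15,
    sample_call_rate_min: float = 0.8,
) -> CallSet:
    """Assign points to clusters; drop samples calling < 80% of assays.

    A point is a no-call when its summed intensity is below the floor or
    its theta lies farther than ``max_center_distance`` from every centre.
    Sample call rates are computed across assays, failing samples dropped,
    and assay call rates recomputed once over the remaining samples.
    """
    rows = []
    for assay, grp in theta_df.groupby("assay", sort=True):
        model = models[assay]
        theta = grp["theta"].to_numpy(float)
        norm_r = grp["normR"].to_numpy(float)
        dist = np.abs(theta[:, None] - model.centers[None, :])
        nearest = dist.argmin(axis=1)
        nocall = (
            np.isnan(theta) | (norm_r < min_intensity)
            | (dist.min(axis=1) > max_center_distance)
        )
        cluster = np.where(nocall, -1, nearest)
        for sample, cl, th in zip(grp["sample"], cluster, theta):
            rows.append((sample, assay, int(cl), th))
    calls = pd.DataFrame(rows, columns=["sample", "assay", "cluster", "theta"])

    called = calls["cluster"] >= 0
    sample_rate = called.groupby(calls["sample"]).mean()
    excluded = sorted(sample_rate.index[sample_rate < sample_call_rate_min])
    kept = calls[~calls["sample"].isin(excluded)]
    assay_rate = (kept["cluster"] >= 0).groupby(kept["assay"]).mean()
    return CallSet(calls, assay_rate, sample_rate, excluded)


# --------------------------------------------------------------------------
# segregation, hemi detection, reproducibility, designability


@dataclass
class SegregationResult:
    statistic: float
    df: int
    p_value: float
    distorted: bool
    inconsistent: bool = False  # e.g. heterozygote class in a DH population


def segregation_test(counts, design: str) -> SegregationResult:
    """Pearson chi-squared against 1:1 (DH) or 1:2:1 (F2) expectations.

    ``counts`` are genotype-class counts ordered by theta (AA, [AB,] BB).
    A heterozygote class in a DH design is flagged inconsistent and the
    test is run on the two homozygote classes.
    """
    counts = [int(c) for c in counts]
    inconsistent = False
    if design == "DH":
        if len(counts) == 3:
            inconsistent = True
            counts = [counts[0], counts[2]]
        if len(counts) != 2:
            raise ValueError("DH design expects two genotype classes")
        ratio = np.array([1.0, 1.0])
    elif design == "F2":
        if len(counts) != 3:
            raise ValueError("F2 design expects three genotype classes")
        ratio = np.array([1.0, 2.0, 1.0])
    else:
        raise ValueError(f"unknown design {design!r}")
    obs = np.asarray(counts, dtype=float)
    total = obs.sum()
    if total == 0:
        return SegregationResult(0.0, len(counts) - 1, 1.0, False, inconsistent)
    exp = ratio / ratio.sum() * total
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(counts) - 1
    p = float(stats.chi2.sf(stat, df))
    return SegregationResult(stat, df, p, p <= 0.05, inconsistent)


def hemi_snp_flag(pooled_model: ClusterModel) -> str:
    """'hemi' iff the pooled two-population fit has >= 4 clusters."""
    return "hemi" if pooled_model.k >= 4 else "simple"


def reproducibility_check(replicate_calls) -> bool:
    """True iff all replicate calls agree (no-calls ignored when >= 2 remain)."""
    calls = [c for c in replicate_calls if c is not None and c != -1]
    if len(calls) < 2:
        return True  # nothing contradictory observable
    return len(set(calls)) == 1


DESIGNABILITY_BANDS = ((0.4, "low"), (0.6, "moderate"), (1.01, "high"))


def designability_class(score: float) -> str:
    """Band label: < 0.4 low, 0.4-0.6 moderate, > 0.6 high."""
    if not 0.0 <= score <= 1.0:
        raise ValueError("rank score must lie in [0, 1]")
    if score < 0.4:
        return "low"
    if score <= 0.6:
        return "moderate"
    return "high"


def designability_filter(scores: pd.DataFrame, cutoff: float = 0.85) -> pd.DataFrame:
    """Label rank scores and drop assays scoring at or below the cutoff."""
    out = scores.copy()
    out["class"] = out["rank_score"].map(designability_class)
    out["kept"] = out["rank_score"] > cutoff
    return out


def plot_assay(theta_df: pd.DataFrame, assay: str, path,
               model: ClusterModel | None = None) -> None:
    """Theta vs normalised-R scatter for one assay (GenomeStudio-style).

    Requires matplotlib (optional dependency, ``allosnp[plot]``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = theta_df[theta_df["assay"] == assay]
    fig, ax = plt.subplots(figsize=(5, 4))
    if "population" in sub:
        for pop, grp in sub.groupby("population"):
            ax.scatter(grp["theta"], grp["normR"], s=12, label=pop, alpha=0.7)
        ax.legend()
    else:
        ax.scatter(sub["theta"], sub["normR"], s=12, alpha=0.7)
    if model is not None:
        for c in model.centers:
            ax.axvline(c, color="grey", lw=0.8, ls="--")
    ax.set_xlim(-0.02, 1.02)
    ax.set_xlabel(r"normalized theta  $(2/\pi)\,\tan^{-1}(Cy5/Cy3)$")
    ax.set_ylabel("normalized R  (Cy3 + Cy5)")
    ax.set_title(assay)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# per-assay orchestration


def analyze_assays(
    intensities: pd.DataFrame,
    k_max: int = 6,
    min_intensity: float = 1000.0,
    max_center_distance: float = 0.15,
) -> pd.DataFrame:
    """Full per-assay analysis of a pooled DH + F2 intensity table.

    Returns one row per assay: cluster counts per population and pooled,
    call rate, polymorphism (parents in different clusters), segregation
    chi-squared p for the appropriate design, hemi flag, reproducibility.
    """
    df = theta_frame(intensities)
    pooled_models: dict[str, ClusterModel] = {}
    for assay, grp in df.groupby("assay", sort=True):
        pooled_models[assay] = fit_clusters(
            grp["theta"].to_numpy(float), k_max=k_max, assay=assay
        )
    callset = call_genotypes(
        df, pooled_models,
        min_intensity=min_intensity, max_center_distance=max_center_distance,
    )
    calls = callset.calls.merge(
        df[["sample", "assay", "population", "is_parent", "replicate_of"]],
        on=["sample", "assay"],
    )

    rows = []
    for assay, grp in calls.groupby("assay", sort=True):
        model = pooled_models[assay]
        pop_k = {}
        for pop in ("DH", "F2"):
            sub = df[(df["assay"] == assay) & (df["population"] == pop)]
            pop_k[pop] = fit_clusters(
                sub["theta"].to_numpy(float), k_max=k_max, assay=assay
            ).k if len(sub) >= 2 else 0

        seg_p = {}
        polymorphic = False
        for pop, design in (("DH", "DH"), ("F2", "F2")):
            sub = grp[(grp["population"] == pop) & (~grp["is_parent"])
                      & (grp["replicate_of"] == "") & (grp["cluster"] >= 0)]
            parents = grp[(grp["population"] == pop) & grp["is_parent"]
                          & (grp["cluster"] >= 0)]
            pop_poly = parents["cluster"].nunique() > 1
            polymorphic |= pop_poly
            counts = sub["cluster"].value_counts().sort_index()
            n_classes = 2 if design == "DH" else 3
            if pop_poly and len(counts) == n_classes:
                seg_p[pop] = segregation_test(counts.to_numpy(), design).p_value
            else:
                seg_p[pop] = np.nan

        reps = grp[(grp["replicate_of"] != "") | (grp["sample"] == "DH000")]
        reproducible = reproducibility_check(reps["cluster"].tolist())
        rows.append({
            "assay": assay,
            "pooled_k": model.k,
            "dh_k": pop_k["DH"], "f2_k": pop_k["F2"],
            "call_rate": float(callset.assay_call_rate.get(assay, np.nan)),
            "polymorphic": polymorphic,
            "dh_segregation_p": seg_p["DH"], "f2_segregation_p": seg_p["F2"],
            "hemi": hemi_snp_flag(model) == "hemi",
            "reproducible": reproducible,
        })
    return pd.DataFrame(rows)
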