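"""Bump-hunting detection of differentially methylated regions (DMRs).

Probes are grouped into clusters of nearby positions, per-probe
beta-scale exposure effects are smoothed by a running mean within each
cluster, candidate regions are maximal same-sign runs of smoothed
effects exceeding a beta-scale cutoff (1% by default) with at least
three CpGs, and familywise error rates come from re-running the whole
pipeline under permutations of the exposure labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dmp import build_design

__all__ = [
    "DMRResult",
    "DMRParams",
    "cluster_probes",
    "smooth_effects",
    "find_bumps",
    "assess_fwer",
    "run_dmr_ewas",
    "probe_effects",
]

MIN_PROBES_FLOOR = 3


@dataclass(frozen=True)
class DMRResult:
    chromosome: str
    start: int
    end: int
    n_probes: int
    probe_ids: tuple[str, ...]
    area: float
    avg_delta_beta: float
    fwer: float | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")
        if self.fwer is not None and not 0 <= self.fwer <= 1:
            raise ValueError("fwer outside [0, 1]")


@dataclass(frozen=True)
class DMRParams:
    cutoff: float = 0.01  # beta-scale: 1% methylation difference
    min_probes: int = 3
    window: int = 5
    max_gap: int = 500
    n_permutations: int = 500
    seed: int = 0
    model: str = "base"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_probes < MIN_PROBES_FLOOR:
            raise ValueError(
                f"min_probes={self.min_probes} below the floor of "
                f"{MIN_PROBES_FLOOR} CpG sites per region"
            )
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")


def cluster_probes(annotation: pd.DataFrame, max_gap: int = 500) -> pd.Series:
    """Assign cluster ids: consecutive probes share a cluster iff they sit
    on the same chromosome within ``max_gap`` base pairs.

    ``annotation`` needs ``chromosome`` and ``position`` columns; it is
    sorted internally.  Ids are consecutive integers in genome order, so
    they are stable across runs.
    """
    ann = annotation.sort_values(["chromosome", "position"], kind="mergesort")
    dup = ann.duplicated(subset=["chromosome", "position"])
    if dup.any():
        where = ann.loc[dup, ["chromosome", "position"]].iloc[0]
        raise ValueError(
            f"duplicate probe coordinates at {where['chromosome']}:"
            f"{where['position']}"
        )
    chrom = ann["chromosome"].to_numpy()
    pos = ann["position"].to_numpy()
    new = np.ones(len(ann), dtype=bool)
    if len(ann) > 1:
        same_chrom = chrom[1:] == chrom[:-1]
        close = np.diff(pos) <= max_gap
        new[1:] = ~(same_chrom & close)
    return pd.Series(np.cumsum(new) - 1, index=ann.index, name="cluster")


def _cluster_bounds(clusters: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe [start, end) indices of the probe's cluster run."""
    n = clusters.size
    starts = np.r_[0, np.flatnonzero(np.diff(clusters) != 0) + 1]
    ends = np.r_[starts[1:], n]
    sizes = ends - starts
    run_of = np.repeat(np.arange(starts.size), sizes)
    return starts[run_of], ends[run_of]


def smooth_effects(effect, clusters, window: int = 5) -> np.ndarray:
    """Centered running mean of per-probe effects within each cluster.

    The window is truncated at cluster edges; clusters with fewer than 3
    probes pass through unsmoothed.  Inputs must be in genome order,
    matching the cluster assignment.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    y = np.asarray(effect, dtype=float)
    cl = np.asarray(clusters)
    if y.size != cl.size:
        raise ValueError("effect and cluster vectors differ in length")
    if window == 1 or y.size == 0:
        return y.copy()
    half = window // 2
    start, end = _cluster_bounds(cl)
    idx = np.arange(y.size)
    lo = np.maximum(idx - half, start)
    hi = np.minimum(idx + half, end - 1)
    cs = np.r_[0.0, np.cumsum(y)]
    out = (cs[hi + 1] - cs[lo]) / (hi - lo + 1)
    small = (end - start) < 3
    out[small] = y[small]
    return out


def _runs(smoothed: np.ndarray, clusters: np.ndarray, cutoff: float):
    """Maximal same-cluster, same-sign runs with |smoothed| > cutoff."""
    sign = np.zeros(smoothed.size, dtype=np.int8)
    sign[smoothed > cutoff] = 1
    sign[smoothed < -cutoff] = -1
    if smoothed.size == 0:
        return []
    brk = np.ones(smoothed.size, dtype=bool)
    brk[1:] = (np.diff(clusters) != 0) | (sign[1:] != sign[:-1])
    starts = np.flatnonzero(brk)
    ends = np.r_[starts[1:], smoothed.size]
    keep = sign[starts] != 0
    return list(zip(starts[keep].tolist(), ends[keep].tolist()))


def find_bumps(
    effect,
    smoothed,
    clusters,
    annotation: pd.DataFrame,
    cutoff: float,
    min_probes: int = 3,
) -> list[DMRResult]:
    """Call candidate regions from smoothed effects (FWER left unset).

    ``annotation`` rows must align with the effect vectors (genome
    order).  Area is the sum of |smoothed effect| over the run and
    ``avg_delta_beta`` the mean raw effect.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    raw = np.asarray(effect, dtype=float)
    sm = np.asarray(smoothed, dtype=float)
    cl = np.asarray(clusters)
    chrom = annotation["chromosome"].to_numpy()
    pos = annotation["position"].to_numpy()
    gene = (
        annotation["gene"].to_numpy()
        if "gene" in annotation.columns
        else np.full(len(annotation), None)
    )
    probe_ids = annotation.index.to_numpy()

    out = []
    for s, e in _runs(sm, cl, cutoff):
        if e - s < min_probes:
            continue
        out.append(
            DMRResult(
                chromosome=str(chrom[s]),
                start=int(pos[s:e].min()),
                end=int(pos[s:e].max()),
                n_probes=e - s,
                probe_ids=tuple(str(p) for p in probe_ids[s:e]),
                area=float(np.abs(sm[s:e]).sum()),
                avg_delta_beta=float(raw[s:e].mean()),
                gene=str(gene[s]) if gene[s] is not None else None,
            )
        )
    return out


def _max_null_area(
    smoothed: np.ndarray, clusters: np.ndarray, cutoff: float, min_probes: int
) -> float:
    best = 0.0
    for s, e in _runs(smoothed, clusters, cutoff):
        if e - s >= min_probes:
            a = float(np.abs(smoothed[s:e]).sum())
            if a > best:
                best = a
    return best


def probe_effects(beta: np.ndarray, design: pd.DataFrame, exposure: str) -> np.ndarray:
    """Per-probe beta-scale exposure effect from the covariate-adjusted OLS."""
    X = design.to_numpy(dtype=float)
    j = list(design.columns).index(exposure)
    h = np.linalg.solve(X.T @ X, X.T)[j]
    return beta @ h


def assess_fwer(
    beta: np.ndarray,
    design: pd.DataFrame,
    candidates: list[DMRResult],
    clusters: np.ndarray,
    params: DMRParams,
    exposure: str = "cli_index",
) -> list[DMRResult]:
    """Attach permutation familywise error rates to candidate regions.

    Each permutation shuffles the exposure labels (covariates fixed),
    re-runs effect estimation, smoothing and bump finding, and records
    the maximum null region area.  The add-one estimator
    fwer = (1 + #{null max ≥ area}) / (1 + B) avoids zero p-values.
    """
    if not candidates:
        return []
    rng = np.random.default_rng(params.seed)
    j = list(design.columns).index(exposure)
    null_max = np.empty(params.n_permutations)
    Xp = design.to_numpy(dtype=float).copy()
    expo = Xp[:, j].copy()
    for b in range(params.n_permutations):
        Xp[:, j] = rng.permutation(expo)
        h = np.linalg.solve(Xp.T @ Xp, Xp.T)[j]
        eff = beta @ h
        sm = smooth_effects(eff, clusters, params.window)
        null_max[b] = _max_null_area(sm, clusters, params.cutoff, params.min_probes)

    out = []
    for c in candidates:
        exceed = int(np.sum(null_max >= c.area))
        out.append(replace(c, fwer=(1 + exceed) / (1 + params.n_permutations)))
    return out


def run_dmr_ewas(
    methylation,
    phenotype: pd.DataFrame,
    params: DMRParams = DMRParams(),
    exposure: str = "cli_index",
) -> list[DMRResult]:
    """Full region pipeline: effects → cluster → smooth → bumps → FWER."""
    data = methylation.sorted_by_position()
    sample_ids = list(data.sample_ids)
    if set(sample_ids) != set(phenotype.index):
        raise ValueError("sample ids differ between methylation and phenotype")
    pheno = phenotype.loc[sample_ids]
    design = build_design(
        pheno, exposure=exposure, include_bmi=params.model == "bmi_adjusted"
    )
    ann = data.annotation.loc[data.probe_ids]
    clusters = cluster_probes(ann, params.max_gap).loc[data.probe_ids].to_numpy()
    beta = data.beta.to_numpy(dtype=float)

    eff = probe_effects(beta, design, exposure)
    sm = smooth_effects(eff, clusters, params.window)
    candidates = find_bumps(eff, sm, clusters, ann, params.cutoff, params.min_probes)
    return assess_fwer(beta, design, candidates, clusters, params, exposure)


def dmr_table(dmrs: list[DMRResult]) -> pd.DataFrame:
    """Flatten DMR results into a writable table."""
    return pd.DataFrame(
        [
            {
                "chromosome": d.chromosome,
                "start": d.start,
                "end": d.end,
                "n_probes": d.n_probes,
                "gene": d.gene,
                "area": d.area,
                "avg_delta_beta": d.avg_delta_beta,
                "fwer": d.fwer,
                "probe_ids": ",".join(d.probe_ids),
            }
            for d in dmrs
        ],
        columns=[
            "chromosome",
            "start",
            "end",
            "n_probes",
            "gene",
            "area",
            "avg_delta_beta",
            "fwer",
            "probe_ids",
        ],
    )
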