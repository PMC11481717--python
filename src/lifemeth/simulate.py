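"""Synthetic phenotype, methylation and outcome generator with known truth.

Emulates the study conditions of a Ghanaian adult cohort profiled on the
Illumina 450k array: ~700 participants whose lifestyle-category
frequencies match the published population (88.6% never smokers, 61.6%
alcohol abstainers, 41.7% high physical activity), DQI-I ≈ 56 ± 6.1,
bimodal beta-value distributions across tens of thousands of probes,
spiked lifestyle-linked probes with beta-scale effects of a few percent,
one or more spiked contiguous regions, and T2DM / FBG / HbA1c outcomes
generated with configurable links to the lifestyle index and to
methylation.  Every spiked feature is recorded in a GroundTruth object
so downstream stages can be tested for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MethylationData
from .lifestyle import score_participants

__all__ = [
    "OutcomeLinks",
    "SimulationConfig",
    "GroundTruth",
    "ConfigurationError",
    "generate_participants",
    "generate_methylation",
    "generate_outcomes",
    "simulate_bundle",
]


class ConfigurationError(ValueError):
    """Raised for invalid simulation settings."""


class AlignmentError(ValueError):
    """Raised when sample identifiers of two inputs disagree."""


# Table-2-style category frequencies of the emulated population
DEFAULT_CATEGORY_FREQUENCIES: dict[str, dict[str, float]] = {
    "smoking": {"never": 0.886, "former": 0.091, "current": 0.022},
    "alcohol": {"abstainer": 0.616, "moderate": 0.355, "heavy": 0.029},
    "activity": {"high": 0.417, "moderate": 0.229, "low": 0.355},
}

DEFAULT_SITE_FREQUENCIES = {
    "rural_ghana": 0.146,
    "urban_ghana": 0.341,
    "europe": 0.513,
}

#: Dirichlet concentration for the six estimated leukocyte fractions;
#: means follow typical adult whole-blood composition (granulocytes ~55%).
CELL_TYPES = ("cell_cd4t", "cell_cd8t", "cell_nk", "cell_bcell", "cell_mono", "cell_gran")
CELL_ALPHA = np.array([0.15, 0.10, 0.05, 0.075, 0.075, 0.55]) * 40


@dataclass(frozen=True)
class OutcomeLinks:
    """Coefficients tying lifestyle and methylation to the outcomes.

    T2DM follows a logistic model on the binary high-risk index and the
    centered mean beta of the spiked probes; FBG (mmol/L) and HbA1c
    (mmol/mol) follow linear models with Gaussian noise.  Methylation
    coefficients are per beta unit, so e.g. ``fbg_meth = 29`` means
    +0.29 mmol/L per 1% methylation.
    """

    t2dm_intercept: float = -0.39  # logit of ~40% baseline prevalence
    t2dm_cli: float = 0.25
    t2dm_meth: float = -0.28
    fbg_intercept: float = 5.2
    fbg_cli: float = 0.22
    fbg_meth: float = 29.0
    hba1c_intercept: float = 38.0
    hba1c_cli: float = 0.65
    hba1c_meth: float = -290.0


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 713
    n_probes: int = 20000
    n_spiked_probes: int = 20
    spike_delta_beta: float = 0.02
    n_spiked_regions: int = 1
    region_n_probes: int = 10
    region_delta_beta: float = 0.075
    category_frequencies: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_CATEGORY_FREQUENCIES.items()
        }
    )
    dqi_mean: float = 56.0
    dqi_sd: float = 6.1
    outcome_links: OutcomeLinks = field(default_factory=OutcomeLinks)
    noise_sd_fbg: float = 1.5
    noise_sd_hba1c: float = 10.0
    # background beta mixture: low- and high-methylated Beta components
    beta_mixture: tuple = ((2.0, 10.0), (10.0, 2.0))
    beta_mixture_weight: float = 0.5
    #: per-sample Beta concentration around each probe's baseline level
    probe_concentration: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for factor, freqs in self.category_frequencies.items():
            probs = np.array(list(freqs.values()), dtype=float)
            # published frequencies are rounded; allow sums within 1% of 1
            if np.any(probs < 0) or np.any(probs > 1) or abs(probs.sum() - 1) > 0.01:
                raise ConfigurationError(
                    f"category frequencies for {factor!r} are not a "
                    f"probability vector: {freqs}"
                )
        if not 0 <= self.spike_delta_beta <= 0.2:
            raise ConfigurationError(
                f"spike_delta_beta={self.spike_delta_beta} outside [0, 0.2]"
            )
        if self.n_spiked_regions and self.region_n_probes < 3:
            raise ConfigurationError("region_n_probes must be >= 3")
        spiked = self.n_spiked_probes + self.n_spiked_regions * self.region_n_probes
        if spiked > self.n_probes:
            raise ConfigurationError(
                f"{spiked} spiked probes exceed n_probes={self.n_probes}"
            )

    def rng_streams(self) -> dict[str, np.random.Generator]:
        """Deterministic child generators for the three stages."""
        seq = np.random.SeedSequence(self.seed)
        kids = seq.spawn(3)
        return {
            "participants": np.random.default_rng(kids[0]),
            "methylation": np.random.default_rng(kids[1]),
            "outcomes": np.random.default_rng(kids[2]),
        }


@dataclass
class GroundTruth:
    """What was spiked, where, and with which coefficients."""

    spiked_probe_ids: list[str]
    true_delta_beta: dict[str, float]
    spiked_region_spans: list[dict]  # chromosome, start, end, probe_ids, delta_beta
    true_outcome_coefficients: dict[str, float]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _draw_categories(rng, freqs: dict[str, float], n: int) -> np.ndarray:
    names = list(freqs)
    p = np.array([freqs[k] for k in names], dtype=float)
    return rng.choice(names, size=n, p=p / p.sum())


def _activity_record(rng, category: str) -> dict[str, float]:
    """Draw an IPAQ-style record guaranteed to classify as ``category``."""
    if category == "high":
        d = int(rng.integers(3, 8))
        mins = float(rng.uniform(70, 120))
        return dict(
            vigorous_days=d,
            vigorous_min_per_day=mins,
            moderate_days=0.0,
            moderate_min_per_day=0.0,
            walking_days=0.0,
            walking_min_per_day=0.0,
            total_met_min_week=8.0 * d * mins,
        )
    if category == "moderate":
        d = int(rng.integers(5, 8))
        mins = float(rng.uniform(30, 60))
        return dict(
            vigorous_days=0.0,
            vigorous_min_per_day=0.0,
            moderate_days=d,
            moderate_min_per_day=mins,
            walking_days=0.0,
            walking_min_per_day=0.0,
            total_met_min_week=4.0 * d * mins,
        )
    # low: nothing, or a little walking on < 5 days
    d = int(rng.integers(0, 5))
    mins = float(rng.uniform(0, 20)) if d else 0.0
    return dict(
        vigorous_days=0.0,
        vigorous_min_per_day=0.0,
        moderate_days=0.0,
        moderate_min_per_day=0.0,
        walking_days=d,
        walking_min_per_day=mins,
        total_met_min_week=3.3 * d * mins,
    )


def generate_participants(config: SimulationConfig) -> pd.DataFrame:
    """Draw the participant table: demographics, lifestyle and covariates.

    Lifestyle categories follow ``config.category_frequencies``; the
    DQI-I is normal (``dqi_mean`` ± ``dqi_sd``) truncated to [0, 100];
    cell proportions are a Dirichlet draw per sample and batch / array
    position are categorical technical covariates.
    """
    rng = config.rng_streams()["participants"]
    n = config.n_samples
    freqs = config.category_frequencies

    sample_id = [f"S{i + 1:05d}" for i in range(n)]
    sex = np.where(rng.random(n) < 0.426, "male", "female")
    age = np.clip(rng.normal(52, 10, n), 25, 85).round(1)
    site = _draw_categories(rng, DEFAULT_SITE_FREQUENCIES, n)
    bmi = np.clip(rng.normal(27, 5.5, n), 16, 52).round(1)

    smoking = _draw_categories(rng, freqs["smoking"], n)
    alcohol_cat = _draw_categories(rng, freqs["alcohol"], n)
    limit = np.where(sex == "male", 2.0, 1.0)
    units = np.zeros(n)
    mod = alcohol_cat == "moderate"
    heavy = alcohol_cat == "heavy"
    units[mod] = rng.uniform(0.2, 1.0, mod.sum()) * limit[mod]
    units[heavy] = limit[heavy] + rng.exponential(1.0, heavy.sum()) + 0.1
    never_drinker = alcohol_cat == "abstainer"

    activity_cat = _draw_categories(rng, freqs["activity"], n)
    activity = pd.DataFrame([_activity_record(rng, c) for c in activity_cat])

    # truncated-normal DQI-I by resampling out-of-range draws
    dqi = rng.normal(config.dqi_mean, config.dqi_sd, n)
    bad = (dqi < 0) | (dqi > 100)
    while bad.any():
        dqi[bad] = rng.normal(config.dqi_mean, config.dqi_sd, bad.sum())
        bad = (dqi < 0) | (dqi > 100)

    cells = rng.dirichlet(CELL_ALPHA, size=n)
    batch = rng.integers(1, 5, n)
    array_pos = rng.integers(1, 9, n)

    df = pd.DataFrame(
        {
            "sample_id": sample_id,
            "age": age,
            "sex": sex,
            "site": site,
            "bmi": bmi,
            "smoking": smoking,
            "alcohol_units": units.round(2),
            "never_drinker": never_drinker,
            "dqi": dqi.round(1),
            "batch": [f"B{b}" for b in batch],
            "array_pos": [f"R{r:02d}" for r in array_pos],
        }
    ).set_index("sample_id")
    for j, name in enumerate(CELL_TYPES):
        df[name] = cells[:, j].round(4)
    return pd.concat([df, activity.set_index(df.index)], axis=1)


def _probe_baselines(rng, config: SimulationConfig, n: int) -> np.ndarray:
    (a1, b1), (a2, b2) = config.beta_mixture
    low = rng.random(n) < config.beta_mixture_weight
    base = np.where(low, rng.beta(a1, b1, n), rng.beta(a2, b2, n))
    return np.clip(base, 0.01, 0.99)


def generate_methylation(
    config: SimulationConfig,
    participants: pd.DataFrame,
    cli_index,
) -> tuple[MethylationData, GroundTruth]:
    """Simulate the probes × samples beta matrix and its annotation.

    Background probes draw per-sample betas from a Beta law around a
    bimodal per-probe baseline.  Spiked probes shift the high-risk
    group's baseline by ±``spike_delta_beta``; spiked regions shift runs
    of ``region_n_probes`` consecutive probes by ``region_delta_beta``.
    Positions increase strictly within each chromosome.
    """
    cli = np.asarray(cli_index)
    if cli.shape[0] != config.n_samples or len(participants) != config.n_samples:
        raise AlignmentError("cli_index length must equal n_samples")
    rng = config.rng_streams()["methylation"]
    n_probes, n_samples = config.n_probes, config.n_samples

    probe_ids = np.array([f"cg{i:08d}" for i in range(n_probes)])
    chroms = np.sort(np.array([f"chr{c}" for c in rng.integers(1, 23, n_probes)]))
    # strictly increasing positions per chromosome via cumulative gaps;
    # gaps are kept so spiked regions can tighten them in place
    gaps = rng.integers(100, 8000, n_probes)
    chrom_masks = {c: np.flatnonzero(chroms == c) for c in np.unique(chroms)}

    def _rebuild_positions() -> np.ndarray:
        pos = np.empty(n_probes, dtype=int)
        for c, idx in chrom_masks.items():
            pos[idx] = 10_000 + np.cumsum(gaps[idx])
        return pos

    positions = _rebuild_positions()

    baselines = _probe_baselines(rng, config, n_probes)

    # choose spiked singles and region runs (disjoint)
    spike_total = config.n_spiked_probes
    region_probe_count = config.n_spiked_regions * config.region_n_probes
    chosen = rng.choice(n_probes, size=spike_total + region_probe_count, replace=False)
    single_idx = np.sort(chosen[:spike_total])

    delta = np.zeros(n_probes)
    if spike_total:
        d = config.spike_delta_beta
        signs = rng.choice([-1.0, 1.0], size=spike_total)
        # keep spiked baselines mid-range so the shift survives clipping
        baselines[single_idx] = rng.uniform(0.2 + d, 0.8 - d, spike_total)
        delta[single_idx] = signs * d

    region_spans: list[dict] = []
    if config.n_spiked_regions:
        if config.region_delta_beta > 0.2:
            raise ConfigurationError(
                "region_delta_beta too large to survive clipping"
            )
        k = config.region_n_probes
        used = set(single_idx.tolist())
        for _ in range(config.n_spiked_regions):
            # place the run of k consecutive probes on one chromosome
            start = None
            for cand in rng.permutation(n_probes - k):
                idxs = np.arange(cand, cand + k)
                if chroms[cand] == chroms[cand + k - 1] and not (
                    used & set(idxs.tolist())
                ):
                    start = int(cand)
                    break
            if start is None:
                raise ConfigurationError("could not place a spiked region")
            idxs = np.arange(start, start + k)
            used |= set(idxs.tolist())
            # tighten the gaps inside the run so it clusters at
            # bump-hunting scale, then rebuild chromosome positions
            gaps[idxs[1:]] = rng.integers(50, 200, k - 1)
            d = config.region_delta_beta
            baselines[idxs] = rng.uniform(0.2 + d, 0.8 - d, k)
            delta[idxs] = d
            region_spans.append(
                {
                    "chromosome": str(chroms[start]),
                    "probe_ids": [str(p) for p in probe_ids[idxs]],
                    "delta_beta": d,
                    "_idxs": idxs,
                }
            )
        # positions are final only once every region has tightened its gaps
        positions = _rebuild_positions()
        for span in region_spans:
            idxs = span.pop("_idxs")
            span["start"] = int(positions[idxs].min())
            span["end"] = int(positions[idxs].max())

    # per-sample means: baseline plus the group shift for high-risk samples
    mean = baselines[:, None] + delta[:, None] * cli[None, :]
    mean = np.clip(mean, 1e-3, 1 - 1e-3)
    kappa = config.probe_concentration
    beta = rng.beta(mean * kappa, (1 - mean) * kappa)
    beta = np.clip(beta, 1e-6, 1 - 1e-6)

    annotation = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chroms,
            "position": positions,
            "gene": [f"GENE{i // 20:05d}" for i in range(n_probes)],
            "feature": rng.choice(
                ["TSS200", "TSS1500", "Body", "3'UTR", "Intergenic"], n_probes
            ),
        }
    ).set_index("probe_id")

    data = MethylationData(
        beta=pd.DataFrame(beta, index=probe_ids, columns=participants.index),
        annotation=annotation,
    ).sorted_by_position()
    truth = GroundTruth(
        spiked_probe_ids=[str(p) for p in probe_ids[single_idx]],
        true_delta_beta={
            str(probe_ids[i]): float(delta[i]) for i in single_idx
        },
        spiked_region_spans=region_spans,
        true_outcome_coefficients=asdict(config.outcome_links),
    )
    return data, truth


def generate_outcomes(
    config: SimulationConfig,
    participants: pd.DataFrame,
    methylation: MethylationData,
    truth: GroundTruth,
    cli_index=None,
) -> pd.DataFrame:
    """Add T2DM, FBG and HbA1c columns generated from the configured links.

    The methylation predictor is the centered mean beta across the
    spiked probes (zero when nothing was spiked), so the intercepts keep
    their marginal interpretation.
    """
    if list(methylation.sample_ids) != list(participants.index):
        raise AlignmentError("methylation columns do not match participant rows")
    rng = config.rng_streams()["outcomes"]
    links = config.outcome_links
    cli = (
        np.asarray(cli_index)
        if cli_index is not None
        else participants["cli_index"].to_numpy()
    )

    if truth.spiked_probe_ids:
        meth = methylation.beta.loc[truth.spiked_probe_ids].mean(axis=0).to_numpy()
        meth = meth - meth.mean()
    else:
        meth = np.zeros(len(participants))

    logits = links.t2dm_intercept + links.t2dm_cli * cli + links.t2dm_meth * meth
    p = 1.0 / (1.0 + np.exp(-logits))
    t2dm = (rng.random(len(p)) < p).astype(int)

    fbg = (
        links.fbg_intercept
        + links.fbg_cli * cli
        + links.fbg_meth * meth
        + rng.normal(0, config.noise_sd_fbg, len(p))
    )
    hba1c = (
        links.hba1c_intercept
        + links.hba1c_cli * cli
        + links.hba1c_meth * meth
        + rng.normal(0, config.noise_sd_hba1c, len(p))
    )

    out = participants.copy()
    out["t2dm"] = t2dm
    out["fbg"] = np.maximum(fbg, 2.0).round(3)
    out["hba1c"] = np.maximum(hba1c, 10.0).round(2)
    return out


def simulate_bundle(config: SimulationConfig):
    """Generate participants, scores, methylation and outcomes in one call.

    Returns ``(phenotype, methylation, truth)`` where the phenotype
    table already carries the lifestyle scores, the binary index and the
    outcome columns.
    """
    participants = generate_participants(config)
    scores = score_participants(participants)
    participants = pd.concat([participants, scores], axis=1)
    methylation, truth = generate_methylation(
        config, participants, participants["cli_index"].to_numpy()
    )
    phenotype = generate_outcomes(config, participants, methylation, truth)
    return phenotype, methylation, truth
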