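"""Synthetic transcriptome parameters, paired count matrices, and depth loss.

The generator emulates the empirical inputs of a two-condition bulk RNA-Seq
power study: a transcriptome-wide population of per-transcript NB parameters
``(mu_i, phi_i)`` spanning several abundance decades with a power-law
dispersion-mean trend, differential expression induced in a fraction of
transcripts by a multiplicative regulating factor ``theta_i`` (mean
``theta_i * mu_i`` in the treatment condition, dispersion unchanged), and
loss of sequencing depth simulated by sampling reads without replacement
within each lane (multivariate hypergeometric draws tracked by transcript).

Parameter populations can instead be estimated from a user-supplied
transcript-by-lane count matrix: lane totals are first equalised to the
smallest lane by without-replacement subsampling, transcripts averaging
under one read per lane are culled, and the per-transcript NB MLE is taken
over lanes treated as biological replicates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .nb_core import estimate_nb_mle

__all__ = [
    "TranscriptParams",
    "ParameterPopulation",
    "CountMatrix",
    "GeneratorConfig",
    "EFFECTIVE_DE_LOWER",
    "EFFECTIVE_DE_UPPER",
    "equalize_lane_depths",
    "cull_low_count_transcripts",
    "build_parameter_population",
    "draw_regulating_factors",
    "label_effective_de",
    "simulate_counts",
    "subsample_depth",
]

#: A regulating factor theta <= 0.83 or >= 1.20 makes a transcript
#: "effectively DE" -- the minimal fold change counted as a true positive.
EFFECTIVE_DE_LOWER = 0.83
EFFECTIVE_DE_UPPER = 1.20

LABEL_DE = "effectively-DE"
LABEL_NON_DE = "effectively-non-DE"


@dataclass(frozen=True)
class TranscriptParams:
    """Simulation parameters of a single transcript isoform."""

    transcript_id: str
    mean: float
    dispersion: float
    theta: float = 1.0
    effective_label: str | None = None


@dataclass
class ParameterPopulation:
    """Array-backed population of per-transcript simulation parameters.

    Equivalent to a list of :class:`TranscriptParams` (see
    :meth:`to_params_list`) but stored as numpy arrays so transcriptome-sized
    populations stay cheap.
    """

    transcript_ids: np.ndarray
    mean: np.ndarray
    dispersion: np.ndarray
    theta: np.ndarray = None  # type: ignore[assignment]
    effective_de: np.ndarray | None = None  # boolean once labelled

    def __post_init__(self) -> None:
        self.transcript_ids = np.asarray(self.transcript_ids)
        self.mean = np.asarray(self.mean, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        if self.theta is None:
            self.theta = np.ones_like(self.mean)
        self.theta = np.asarray(self.theta, dtype=float)
        n = len(self.transcript_ids)
        if not (len(self.mean) == len(self.dispersion) == len(self.theta) == n):
            raise ValueError("population arrays must have equal length")
        if np.any(self.mean < 0) or np.any(self.dispersion < 0):
            raise ValueError("means and dispersions must be non-negative")
        if np.any(self.theta <= 0):
            raise ValueError("regulating factors must be positive")

    def __len__(self) -> int:
        return len(self.transcript_ids)

    def copy(self) -> "ParameterPopulation":
        return ParameterPopulation(
            transcript_ids=self.transcript_ids.copy(),
            mean=self.mean.copy(),
            dispersion=self.dispersion.copy(),
            theta=self.theta.copy(),
            effective_de=None if self.effective_de is None else self.effective_de.copy(),
        )

    @property
    def effective_labels(self) -> np.ndarray:
        if self.effective_de is None:
            raise ValueError("population has not been labelled; call label_effective_de")
        return np.where(self.effective_de, LABEL_DE, LABEL_NON_DE)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "transcript_id": self.transcript_ids,
                "mean": self.mean,
                "dispersion": self.dispersion,
                "theta": self.theta,
            }
        )
        if self.effective_de is not None:
            df["effective_label"] = self.effective_labels
        return df

    def to_params_list(self) -> list[TranscriptParams]:
        labels = (
            self.effective_labels if self.effective_de is not None else [None] * len(self)
        )
        return [
            TranscriptParams(str(t), float(m), float(d), float(th), lab)
            for t, m, d, th, lab in zip(
                self.transcript_ids, self.mean, self.dispersion, self.theta, labels
            )
        ]


@dataclass
class CountMatrix:
    """Integer transcript-by-lane count matrix with optional condition labels."""

    counts: np.ndarray
    transcript_ids: np.ndarray
    lane_ids: np.ndarray
    condition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D transcripts x lanes array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.transcript_ids = np.asarray(self.transcript_ids)
        self.lane_ids = np.asarray(self.lane_ids)
        if len(self.transcript_ids) != self.counts.shape[0]:
            raise ValueError("transcript_ids length mismatch")
        if len(self.lane_ids) != self.counts.shape[1]:
            raise ValueError("lane_ids length mismatch")
        if self.condition is not None:
            self.condition = np.asarray(self.condition)
            if len(self.condition) != self.counts.shape[1]:
                raise ValueError("condition length mismatch")

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_lanes(self) -> int:
        return self.counts.shape[1]

    def lane_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.copy(),
            transcript_ids=self.transcript_ids.copy(),
            lane_ids=self.lane_ids.copy(),
            condition=None if self.condition is None else self.condition.copy(),
        )

    # -- TSV round trip ----------------------------------------------------
    def to_tsv(self, path, condition_path=None) -> None:
        df = pd.DataFrame(self.counts, columns=self.lane_ids)
        df.insert(0, "transcript_id", self.transcript_ids)
        df.to_csv(path, sep="\t", index=False)
        if condition_path is not None:
            if self.condition is None:
                raise ValueError("no condition labels to write")
            pd.DataFrame({"lane_id": self.lane_ids, "condition": self.condition}).to_csv(
                condition_path, sep="\t", index=False
            )

    @classmethod
    def from_tsv(cls, path, condition_path=None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        tids = df.iloc[:, 0].to_numpy()
        counts = df.iloc[:, 1:].to_numpy()
        lanes = np.asarray(df.columns[1:])
        condition = None
        if condition_path is not None:
            cmap = pd.read_csv(condition_path, sep="\t").set_index("lane_id")["condition"]
            condition = cmap.reindex(lanes).to_numpy()
        return cls(counts=counts, transcript_ids=tids, lane_ids=lanes, condition=condition)


@dataclass(frozen=True)
class GeneratorConfig:
    """Built-in parameter-population generator settings.

    Abundances are drawn as ``log10(mu) ~ Normal(mean_log10, sd_log10)``
    truncated to ``mu_range`` (spanning roughly four abundance decades),
    then rescaled once so the expected lane total equals ``library_size``.
    Dispersions follow the power law ``phi = c * mu**(alpha-2)`` with
    lognormal scatter of ``sigma_phi`` decades, clamped to ``phi_range``.
    """

    t: int = 20_000
    mean_log10: float = 0.9
    sd_log10: float = 0.8
    mu_range: tuple = (1.0, 1e5)
    c: float = 0.364
    alpha: float = 1.700
    sigma_phi: float = 0.35
    phi_range: tuple = (1e-4, 10.0)
    frac_up: float = 0.075
    frac_down: float = 0.075
    library_size: float | None = 1e6


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _hypergeom_lane(rng, lane_counts: np.ndarray, nsample: int) -> np.ndarray:
    """Draw ``nsample`` reads without replacement from one lane."""
    return rng.multivariate_hypergeometric(lane_counts, nsample, method="marginals")


def equalize_lane_depths(counts: CountMatrix, seed=None) -> CountMatrix:
    """Reduce every lane to the total of the smallest lane.

    Reads are removed by without-replacement subsampling tracked by
    transcript (a multivariate hypergeometric draw per lane); lanes already
    at the minimum are left untouched and consume no randomness.
    """
    if counts.n_lanes < 1 or counts.n_transcripts < 1:
        raise ValueError("count matrix must be non-empty")
    rng = _rng(seed)
    totals = counts.lane_totals()
    target = int(totals.min())
    out = counts.counts.copy()
    for j in range(counts.n_lanes):
        if totals[j] > target:
            out[:, j] = _hypergeom_lane(rng, counts.counts[:, j], target)
    return dataclasses.replace(counts, counts=out)


def cull_low_count_transcripts(counts: CountMatrix, min_total: int) -> CountMatrix:
    """Drop transcripts whose total count over all lanes is below ``min_total``.

    With ``min_total`` equal to the number of lanes this removes transcripts
    averaging under one read per lane.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = counts.counts.sum(axis=1) >= min_total
    if not keep.any():
        import warnings

        warnings.warn("all transcripts fall below min_total; returning empty matrix")
    return dataclasses.replace(
        counts, counts=counts.counts[keep], transcript_ids=counts.transcript_ids[keep]
    )


def build_parameter_population(source, seed=None, min_total=None) -> ParameterPopulation:
    """Build a per-transcript (mu, phi) population.

    From a :class:`CountMatrix` (lanes treated as biological replicates of a
    single condition): equalise lane depths, cull transcripts averaging under
    one read per lane (``min_total`` defaults to the lane count), then take
    the per-transcript NB MLE.  From a :class:`GeneratorConfig`: draw the
    built-in abundance law and power-law dispersion trend.  All regulating
    factors start at 1.
    """
    rng = _rng(seed)
    if isinstance(source, GeneratorConfig):
        cfg = source
        lo, hi = (np.log10(cfg.mu_range[0]) - cfg.mean_log10) / cfg.sd_log10, (
            np.log10(cfg.mu_range[1]) - cfg.mean_log10
        ) / cfg.sd_log10
        log10_mu = truncnorm.rvs(
            lo, hi, loc=cfg.mean_log10, scale=cfg.sd_log10, size=cfg.t, random_state=rng
        )
        mu = 10.0 ** log10_mu
        if cfg.library_size is not None:
            mu *= cfg.library_size / mu.sum()
        eps = rng.normal(0.0, cfg.sigma_phi, size=cfg.t)
        phi = cfg.c * mu ** (cfg.alpha - 2.0) * 10.0 ** eps
        phi = np.clip(phi, cfg.phi_range[0], cfg.phi_range[1])
        ids = np.array([f"T{i:06d}" for i in range(cfg.t)])
        return ParameterPopulation(transcript_ids=ids, mean=mu, dispersion=phi)

    if isinstance(source, CountMatrix):
        if source.n_lanes < 2:
            raise ValueError("need >= 2 lanes to estimate dispersions")
        eq = equalize_lane_depths(source, rng)
        if min_total is None:
            min_total = eq.n_lanes
        culled = cull_low_count_transcripts(eq, min_total)
        if culled.n_transcripts == 0:
            raise ValueError("no transcripts survive culling")
        means = np.empty(culled.n_transcripts)
        phis = np.empty(culled.n_transcripts)
        for i in range(culled.n_transcripts):
            est = estimate_nb_mle(culled.counts[i])
            means[i] = est.mean
            phis[i] = est.dispersion
        keep = means > 0
        return ParameterPopulation(
            transcript_ids=culled.transcript_ids[keep],
            mean=means[keep],
            dispersion=phis[keep],
        )

    raise TypeError("source must be a CountMatrix or GeneratorConfig")


def draw_regulating_factors(
    population: ParameterPopulation,
    frac_up: float = 0.075,
    frac_down: float = 0.075,
    seed=None,
) -> ParameterPopulation:
    """Assign regulating factors: theta = 1 + X up, (1 + X)^-1 down, X ~ Exp(1).

    ``floor(frac_up * t)`` randomly chosen transcripts are up-regulated and a
    disjoint ``floor(frac_down * t)`` down-regulated; the rest keep theta = 1.
    Returns a new population; labels are reset (call
    :func:`label_effective_de` afterwards).
    """
    if frac_up < 0 or frac_down < 0 or frac_up + frac_down > 1:
        raise ValueError("fractions must be non-negative and sum to at most 1")
    rng = _rng(seed)
    t = len(population)
    n_up = int(np.floor(frac_up * t))
    n_down = int(np.floor(frac_down * t))
    out = population.copy()
    out.theta = np.ones(t)
    out.effective_de = None
    if n_up + n_down > 0:
        chosen = rng.choice(t, size=n_up + n_down, replace=False)
        up, down = chosen[:n_up], chosen[n_up:]
        out.theta[up] = 1.0 + rng.exponential(1.0, size=n_up)
        out.theta[down] = 1.0 / (1.0 + rng.exponential(1.0, size=n_down))
    return out


def label_effective_de(
    population: ParameterPopulation,
    lower: float = EFFECTIVE_DE_LOWER,
    upper: float = EFFECTIVE_DE_UPPER,
) -> ParameterPopulation:
    """Label transcripts effectively DE iff theta <= lower or theta >= upper.

    Both boundaries are inclusive on the DE side; transcripts with
    ``lower < theta < upper`` (including unregulated theta = 1) are
    effectively non-DE.
    """
    out = population.copy()
    out.effective_de = (out.theta <= lower) | (out.theta >= upper)
    return out


def simulate_counts(
    population: ParameterPopulation, n_reps: int, seed=None
) -> CountMatrix:
    """Draw a paired control/treatment count matrix.

    Control lanes are NB(mu_i, phi_i) and treatment lanes
    NB(theta_i * mu_i, phi_i), independent across transcripts and lanes,
    sampled through the gamma-Poisson hierarchy (Poisson when phi_i is
    numerically zero).
    """
    if int(n_reps) != n_reps or n_reps < 1:
        raise ValueError("n_reps must be a positive integer")
    if np.any(population.mean <= 0):
        raise ValueError("population contains degenerate (mean 0) transcripts")
    rng = _rng(seed)
    t = len(population)
    phi = population.dispersion

    def _draw(mean_vec: np.ndarray, n: int) -> np.ndarray:
        mean = np.repeat(mean_vec[:, None], n, axis=1)
        out = np.empty((t, n), dtype=np.int64)
        poiss = phi < 1e-12
        if poiss.any():
            out[poiss] = rng.poisson(mean[poiss])
        nb = ~poiss
        if nb.any():
            r = 1.0 / phi[nb]
            lam = rng.gamma(shape=np.repeat(r[:, None], n, axis=1), scale=mean[nb] / np.repeat(r[:, None], n, axis=1))
            out[nb] = rng.poisson(lam)
        return out

    control = _draw(population.mean, n_reps)
    treatment = _draw(population.mean * population.theta, n_reps)
    counts = np.hstack([control, treatment])
    lane_ids = np.array(
        [f"control_{j+1}" for j in range(n_reps)] + [f"treatment_{j+1}" for j in range(n_reps)]
    )
    condition = np.array(["control"] * n_reps + ["treatment"] * n_reps)
    return CountMatrix(
        counts=counts,
        transcript_ids=population.transcript_ids.copy(),
        lane_ids=lane_ids,
        condition=condition,
    )


def subsample_depth(counts: CountMatrix, depth_fraction: float, seed=None) -> CountMatrix:
    """Reduce every lane to a fraction of its reads, without replacement.

    Each lane is independently thinned to ``round(depth_fraction * total)``
    reads (round-half-even) by a multivariate hypergeometric draw over its
    transcripts, emulating sequencing the same libraries to lower depth in
    both conditions.  ``depth_fraction = 1`` returns the matrix unchanged.
    """
    if not (0.0 < depth_fraction <= 1.0):
        raise ValueError("depth_fraction must lie in (0, 1]")
    if depth_fraction == 1.0:
        return counts.copy()
    rng = _rng(seed)
    out = counts.counts.copy()
    totals = counts.lane_totals()
    for j in range(counts.n_lanes):
        target = int(np.rint(depth_fraction * totals[j]))
        out[:, j] = _hypergeom_lane(rng, counts.counts[:, j], target)
    return dataclasses.replace(counts, counts=out)
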