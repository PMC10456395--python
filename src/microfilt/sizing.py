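"""Particle-size distribution analytics and the recovery-rate statistic.

A filtration experiment yields three particle populations — the original
suspension, the filtrate (passed) and the retentate (retained).  Separation
performance is summarized by the D-percentiles of the diameter distribution
(D10...D99; D99 approximates the effective size cut-off), a Gaussian or
Gaussian-mixture fit to the diameter histogram, and the recovery rate

    total recovery (%) = (N_filtrate + N_retentate) / N_original * 100,

which quantifies how many particles survive the process (losses are fouling
retained inside the filter, adhesion, or counting error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.mixture import GaussianMixture

__all__ = [
    "ParticlePopulation",
    "SizeDistributionSummary",
    "MixtureComponent",
    "MixtureFit",
    "RecoveryReport",
    "percentile_d",
    "summarize",
    "fit_mixture",
    "recovery",
]

POPULATION_LABELS = ("original", "filtrate", "retentate")


@dataclass(frozen=True)
class ParticlePopulation:
    """A labelled bag of particle diameters (um).

    May be empty as a container (e.g. a filtrate that caught nothing), but
    every statistic requires at least one diameter.
    """

    diameters: np.ndarray
    label: str = "original"
    source: str = ""

    def __post_init__(self) -> None:
        d = np.atleast_1d(np.asarray(self.diameters, dtype=float))
        object.__setattr__(self, "diameters", d)
        if d.size and not (np.all(np.isfinite(d)) and np.all(d > 0)):
            raise ValueError("diameters must be finite and positive")
        if self.label not in POPULATION_LABELS:
            raise ValueError(
                f"label must be one of {POPULATION_LABELS}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return int(self.diameters.size)


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean_um: float
    sd_um: float


@dataclass(frozen=True)
class MixtureFit:
    components: tuple[MixtureComponent, ...]
    converged: bool
    log_likelihood: float
    n_iter: int


@dataclass(frozen=True)
class SizeDistributionSummary:
    """D-percentiles plus Gaussian summary of one population.

    D-values are reported to 0.1 um.  ``multimodal`` flags a diameter
    histogram with more than one well-separated peak, for which the single
    Gaussian is a poor description and a mixture fit should be preferred.
    """

    d10: float
    d50: float
    d90: float
    d95: float
    d99: float
    mean_um: float
    sd_um: float
    n: int
    multimodal: bool = False
    components: tuple[MixtureComponent, ...] | None = None

    def to_dict(self) -> dict:
        out = {
            "D10": self.d10, "D50": self.d50, "D90": self.d90,
            "D95": self.d95, "D99": self.d99,
            "mean_um": self.mean_um, "sd_um": self.sd_um, "n": self.n,
            "multimodal": self.multimodal,
        }
        if self.components is not None:
            out["components"] = [
                {"weight": c.weight, "mean_um": c.mean_um, "sd_um": c.sd_um}
                for c in self.components
            ]
        return out


@dataclass(frozen=True)
class RecoveryReport:
    n_filtrate: int
    n_retentate: int
    n_original: int
    rate_filtrate_pct: float
    rate_retentate_pct: float
    rate_total_pct: float


def percentile_d(pop: ParticlePopulation, q: float) -> float:
    """q-th percentile of the diameters (um) by linear interpolation
    between order statistics (the j-th of n sorted values sits at cumulative
    probability (j - 1)/(n - 1))."""
    if len(pop) == 0:
        raise ValueError("population is empty")
    if not 0 < q < 100:
        raise ValueError(f"q must be in (0, 100), got {q}")
    return float(np.percentile(pop.diameters, q, method="linear"))


def _is_multimodal(d: np.ndarray) -> bool:
    """Histogram dip test: more than one prominent, separated peak."""
    if d.size < 20:
        return False
    counts, _ = np.histogram(d, bins="auto")
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    peaks, _ = signal.find_peaks(smooth, prominence=0.1 * smooth.max(), distance=2)
    return peaks.size >= 2


def summarize(pop: ParticlePopulation, *, check_multimodal: bool = True) -> SizeDistributionSummary:
    """D10/50/90/95/99 (to 0.1 um), plus the maximum-likelihood single
    Gaussian (sample mean and sd)."""
    if len(pop) < 2:
        raise ValueError("need at least 2 diameters to summarize")
    d = pop.diameters
    qs = {q: round(percentile_d(pop, q), 1) for q in (10, 50, 90, 95, 99)}
    multimodal = check_multimodal and _is_multimodal(d)
    if multimodal:
        warnings.warn(
            f"{pop.label}: diameter histogram looks multimodal; the single "
            "Gaussian summary may be misleading — consider fit_mixture",
            stacklevel=2,
        )
    return SizeDistributionSummary(
        d10=qs[10], d50=qs[50], d90=qs[90], d95=qs[95], d99=qs[99],
        mean_um=float(np.mean(d)), sd_um=float(np.std(d)),  # MLE (ddof=0)
        n=len(pop), multimodal=multimodal,
    )


def fit_mixture(pop: ParticlePopulation, n_components: int,
                *, max_iter: int = 500, tol: float = 1e-7) -> MixtureFit:
    """Gaussian-mixture fit to the diameters by expectation-maximization.

    Initialization is deterministic — quantile-spaced component means,
    pooled (sample) sd, equal weights — so repeated fits of the same data
    are identical without any seed.  Non-convergence within ``max_iter``
    returns the best iterate flagged ``converged=False``.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if len(pop) < 10 * n_components:
        raise ValueError(
            f"need at least {10 * n_components} diameters for "
            f"{n_components} components, got {len(pop)}"
        )
    d = pop.diameters
    x = d.reshape(-1, 1)
    probe = (np.arange(n_components) + 0.5) / n_components * 100.0
    means = np.percentile(d, probe).reshape(-1, 1)
    pooled_var = max(float(np.var(d)), 1e-12) / n_components
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        weights_init=np.full(n_components, 1.0 / n_components),
        means_init=means,
        precisions_init=np.full((n_components, 1, 1), 1.0 / pooled_var),
        reg_covar=1e-12,
        max_iter=max_iter,
        tol=tol,
        n_init=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn ConvergenceWarning -> flag
        gm.fit(x)
    order = np.argsort(gm.means_.ravel())
    comps = tuple(
        MixtureComponent(
            weight=float(gm.weights_[i]),
            mean_um=float(gm.means_[i, 0]),
            sd_um=float(np.sqrt(gm.covariances_[i, 0, 0])),
        )
        for i in order
    )
    return MixtureFit(
        components=comps,
        converged=bool(gm.converged_),
        log_likelihood=float(gm.score(x) * len(pop)),
        n_iter=int(gm.n_iter_),
    )


def recovery(n_filtrate: int, n_retentate: int, n_original: int) -> RecoveryReport:
    """Recovery rates (%) from the three particle counts.

    total = (N_filtrate + N_retentate) / N_original * 100; the filtrate and
    retentate rates are the respective counts over N_original.
    """
    for name, n in (("n_filtrate", n_filtrate), ("n_retentate", n_retentate)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0, got {n}")
    if n_original <= 0:
        raise ValueError(f"n_original must be > 0, got {n_original}")
    f = 100.0 * n_filtrate / n_original
    r = 100.0 * n_retentate / n_original
    return RecoveryReport(n_filtrate, n_retentate, n_original, f, r, f + r)
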