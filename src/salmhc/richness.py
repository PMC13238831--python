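"""Allele-number rarefaction, extrapolation and saturation analyses.

The allele-discovery question — how many alleles exist in a population
beyond the ones a finite sample revealed — is addressed by three coupled
pieces:

* a hypergeometric rarefaction curve of the observed sample (expected
  distinct alleles versus subsample size, exact, no resampling noise);
* a hypothetical-population match: the empirical frequency distribution is
  fitted with a Gaussian kernel on log frequencies, hypothetical
  populations with K alleles drawn from it are sampled at the observed
  size, and the K whose mean accumulation curve is L2-closest to the
  observed one is selected;
* plug-in binomial extrapolation under the matched population, giving
  expected alleles at a larger sample size with a percentile interval.

Shannon-Weaver diversity, leave-one-third-out accumulation bootstraps and
Michaelis-Menten saturation fits (D(n) = Dmax * n / (K_half + n)) complete
the toolkit for diversity-versus-sample-size comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import gammaln
from scipy.stats import gaussian_kde

from .popgen import FrequencySpectrum


def shannon_weaver(freqs: np.ndarray, base: float | None = None) -> float:
    """Shannon-Weaver index H' = -sum p ln p (natural log by default)."""
    p = np.asarray(freqs, dtype=float)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / math.log(base) if base else h


def rarefaction_curve(
    counts: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Expected distinct alleles at each subsample size (allele copies) in
    *grid*, by exact hypergeometric rarefaction of copy counts *counts*."""
    Ni = np.asarray(counts, dtype=float)
    g = np.asarray(grid, dtype=float)
    N = Ni.sum()
    if (g > N).any() or (g < 1).any():
        raise ValueError("grid sizes must lie in [1, N]")

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = (N - Ni)[:, None]  # alleles x grid
    with np.errstate(invalid="ignore"):
        term = 1.0 - np.exp(logC(rest, g[None, :]) - logC(N, g[None, :]))
    term[rest < g[None, :]] = 1.0
    return term.sum(axis=0)


# ---------------------------------------------------------------------------
# empirical frequency model and hypothetical-K matching
# ---------------------------------------------------------------------------


class LogFrequencyModel:
    """Gaussian kernel density on log observed allele frequencies.

    Sampled frequency vectors are renormalized to sum to 1, so drawing
    K > N_all alleles yields a population whose extra alleles follow the
    same empirical shape. Degenerate inputs (single allele, or all
    frequencies equal) fall back to resampling the observed values with a
    small lognormal jitter.
    """

    def __init__(self, freqs: np.ndarray, bw_method: str = "silverman"):
        self.logf = np.log(np.asarray(freqs, dtype=float))
        if len(self.logf) >= 2 and np.ptp(self.logf) > 1e-12:
            self._kde = gaussian_kde(self.logf, bw_method=bw_method)
        else:
            self._kde = None

    def sample(self, K: int, rng: np.random.Generator) -> np.ndarray:
        if self._kde is not None:
            draw = self._kde.resample(K, seed=rng)[0]
        else:
            draw = rng.choice(self.logf, size=K) + 0.05 * rng.standard_normal(K)
        q = np.exp(draw)
        return q / q.sum()


@dataclass
class KMatchResult:
    best_K: int
    K_grid: np.ndarray
    discrepancy: np.ndarray  # minimal L2 distance per K
    grid_copies: np.ndarray
    observed_curve: np.ndarray
    model_type: str = "geometric"
    r_hat: float | None = None  # fitted geometric ratio
    fitted_freqs: np.ndarray | None = field(repr=False, default=None)
    kernel: LogFrequencyModel | None = field(repr=False, default=None)


def _copies_grid(N: int, max_points: int = 25) -> np.ndarray:
    sizes = np.arange(2, N + 1, 2)
    if len(sizes) > max_points:
        idx = np.unique(np.linspace(0, len(sizes) - 1, max_points).astype(int))
        sizes = sizes[idx]
    return sizes


def _expected_curve(q: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Expected distinct alleles in a multinomial sample of each size in
    *grid* from population frequencies *q*."""
    return (1.0 - np.power.outer(1.0 - q, grid)).sum(axis=0)


DEFAULT_R_GRID = np.linspace(0.40, 0.99, 60)


def _geometric_curve_bank(
    r_grid: np.ndarray, K_max: int, grid: np.ndarray
) -> np.ndarray:
    """Expected curves for every (r, K) of the geometric rank-frequency
    family; shape (len(r_grid), K_max, len(grid)), entry [ri, K-1]."""
    bank = np.empty((len(r_grid), K_max, len(grid)))
    for ri, r in enumerate(r_grid):
        w = r ** np.arange(K_max)
        cum = np.cumsum(w)
        for K in range(1, K_max + 1):
            q = w[:K] / cum[K - 1]
            bank[ri, K - 1] = _expected_curve(q, grid)
    return bank


def match_hypothetical_K(
    spectrum: FrequencySpectrum,
    K_grid: np.ndarray | None = None,
    reps: int = 200,
    seed: int = 0,
    K_extra: int = 50,
    model: str = "geometric",
    r_grid: np.ndarray = DEFAULT_R_GRID,
) -> KMatchResult:
    """Select the population allele number K best explaining the observed
    allele-accumulation curve.

    The observed sample's exact rarefaction curve is compared by L2
    distance with accumulation curves of hypothetical populations holding
    K alleles, over K from the observed N_all to N_all + *K_extra*; ties
    prefer smaller K.

    With ``model="geometric"`` (default) the hypothetical frequencies
    follow the geometric rank-frequency family p_i proportional to r**i,
    with r fitted jointly on a grid; expected accumulation curves are
    analytic, so the match is deterministic. With ``model="kernel"`` the
    hypothetical frequencies are drawn (renormalized) from a Gaussian
    kernel density on the observed log frequencies and curves are averaged
    over *reps* Monte-Carlo populations sampled at the observed size; this
    variant is only calibrated near saturation, because the kernel cannot
    carry mass below the detection limit of the observed sample.
    """
    N_all, N = spectrum.n_alleles, spectrum.N
    if N_all == 1:
        grid = np.array([2])
        return KMatchResult(1, np.array([1]), np.zeros(1), grid,
                            rarefaction_curve(spectrum.counts, grid),
                            model_type=model, fitted_freqs=np.ones(1))
    if K_grid is None:
        K_grid = np.arange(N_all, N_all + K_extra + 1)
    K_grid = np.asarray(K_grid, dtype=int)
    if K_grid.min() > N_all:
        raise ValueError("K_grid must include the observed allele count")
    grid = _copies_grid(N)
    observed = rarefaction_curve(spectrum.counts, grid)

    if model == "geometric":
        bank = _geometric_curve_bank(r_grid, int(K_grid.max()), grid)
        d = np.sqrt(np.mean((bank[:, K_grid - 1, :] - observed) ** 2, axis=2))
        disc = d.min(axis=0)  # minimized over r, per K
        ki = int(np.argmin(disc))  # first minimum -> smaller K on ties
        best_K = int(K_grid[ki])
        r_hat = float(r_grid[int(np.argmin(d[:, ki]))])
        w = r_hat ** np.arange(best_K)
        return KMatchResult(best_K, K_grid, disc, grid, observed,
                            "geometric", r_hat, w / w.sum())
    if model == "kernel":
        kernel = LogFrequencyModel(spectrum.freqs)
        rng = np.random.default_rng(seed)
        disc = np.empty(len(K_grid))
        for ki, K in enumerate(K_grid):
            curves = np.empty((reps, len(grid)))
            for rep in range(reps):
                q = kernel.sample(K, rng)
                cnt = rng.multinomial(N, q)
                curves[rep] = rarefaction_curve(cnt[cnt > 0], grid)
            disc[ki] = float(np.sqrt(np.mean((curves.mean(axis=0) - observed) ** 2)))
        best_K = int(K_grid[int(np.argmin(disc))])
        return KMatchResult(best_K, K_grid, disc, grid, observed,
                            "kernel", kernel=kernel)
    raise ValueError(f"unknown spectrum model {model!r}")


@dataclass
class ExtrapolationResult:
    expected: float
    lo: float
    hi: float
    best_K: int
    n_observed: int
    n_target: int


def extrapolate_richness(
    spectrum: FrequencySpectrum,
    n_prime: int,
    reps: int = 200,
    seed: int = 0,
    match: KMatchResult | None = None,
) -> ExtrapolationResult:
    """Expected allele count at n' >= n individuals, with a 2.5/97.5%
    interval over matching replicates.

    The matched hypothetical population (``match_hypothetical_K``) supplies
    allele frequencies q; the expected gain over the observed sample is
    A(2n') - A(2n) with A(m) = sum_j 1 - (1 - q_j)^m, added to the
    observed allele count — continuous in n' and exactly N_all at n' = n.
    The interval is a parametric bootstrap: *reps* samples of the observed
    size are redrawn from the matched population, each is re-matched, and
    the refitted gains give the percentile band.
    """
    n = spectrum.N // 2
    if n_prime < n:
        raise ValueError("extrapolation target must be >= observed sample size")
    if match is None:
        match = match_hypothetical_K(spectrum, reps=reps, seed=seed)
    rng = np.random.default_rng([seed, 1])
    N_all, N = spectrum.n_alleles, spectrum.N
    m_now, m_then = 2 * n, 2 * n_prime

    def gain(q: np.ndarray) -> float:
        return float(np.sum((1.0 - q) ** m_now - (1.0 - q) ** m_then))

    if match.model_type == "kernel":
        if match.kernel is None:  # single-allele spectrum
            return ExtrapolationResult(float(N_all), float(N_all), float(N_all),
                                       match.best_K, n, n_prime)
        gains = np.array([gain(match.kernel.sample(match.best_K, rng))
                          for _ in range(reps)])
        values = N_all + gains
        return ExtrapolationResult(float(values.mean()),
                                   float(np.percentile(values, 2.5)),
                                   float(np.percentile(values, 97.5)),
                                   match.best_K, n, n_prime)

    # geometric model: deterministic point estimate, parametric-bootstrap band
    expected = N_all + gain(match.fitted_freqs)
    if match.best_K == 1:
        return ExtrapolationResult(expected, expected, expected,
                                   match.best_K, n, n_prime)
    grid = match.grid_copies
    K_max = int(match.K_grid.max())
    bank = _geometric_curve_bank(DEFAULT_R_GRID, K_max, grid)
    values = np.empty(reps)
    for rep in range(reps):
        cnt = rng.multinomial(N, match.fitted_freqs)
        cnt = cnt[cnt > 0]
        obs_rep = rarefaction_curve(cnt, grid)
        k_lo = len(cnt)
        d = np.sqrt(np.mean((bank[:, k_lo - 1:, :] - obs_rep) ** 2, axis=2))
        disc = d.min(axis=0)
        ki = int(np.argmin(disc))
        K_rep = k_lo + ki
        r_rep = DEFAULT_R_GRID[int(np.argmin(d[:, ki]))]
        w = r_rep ** np.arange(K_rep)
        values[rep] = len(cnt) + gain(w / w.sum())
    return ExtrapolationResult(expected,
                               float(np.percentile(values, 2.5)),
                               float(np.percentile(values, 97.5)),
                               match.best_K, n, n_prime)


# ---------------------------------------------------------------------------
# accumulation bootstraps
# ---------------------------------------------------------------------------


@dataclass
class AccumulationCurve:
    """(sample size, statistic) points aggregated over bootstrap draws."""

    table: pd.DataFrame  # n, mean, sd, q025, q975, reps
    statistic: str
    iters: int
    seed: int
    skipped: int = 0


def _stat_arrays(sub1: np.ndarray, sub2: np.ndarray, statistic: str) -> float:
    pool = np.concatenate([sub1, sub2])
    if statistic == "unique_alleles":
        return float(len(np.unique(pool)))
    if statistic == "shannon":
        _, cnt = np.unique(pool, return_counts=True)
        return shannon_weaver(cnt / cnt.sum())
    raise ValueError(f"unknown statistic {statistic!r}")


def bootstrap_accumulation(
    genotypes: pd.DataFrame,
    locus: str,
    statistic: str = "unique_alleles",
    population: str | None = None,
    frac_out: float = 1 / 3,
    iters: int = 1000,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> AccumulationCurve:
    """Leave-a-third-out bootstrap of a diversity statistic.

    Each iteration removes a uniform random ceil(n * frac_out) individuals
    and recomputes the statistic on the retained set; the full-data point
    is appended. Passing *grid* (individual counts) instead evaluates the
    statistic on nested random subsamples of each listed size, giving a
    smooth curve. Draws on which the statistic is undefined are skipped
    and counted.
    """
    sub = genotypes[genotypes["locus"] == locus]
    if population is not None:
        sub = sub[sub["population"] == population]
    sub = sub.dropna(subset=["allele1", "allele2"])
    n = len(sub)
    if n < 3:
        raise ValueError("bootstrap_accumulation needs >= 3 individuals")
    codes1 = pd.factorize(pd.concat([sub["allele1"], sub["allele2"]]))[0]
    a1, a2 = codes1[:n], codes1[n:]
    rng = np.random.default_rng(seed)
    points: list[tuple[int, float]] = []
    skipped = 0
    if grid is None:
        drop = math.ceil(n * frac_out)
        keep = n - drop
        for _ in range(iters):
            idx = rng.permutation(n)[:keep]
            try:
                points.append((keep, _stat_arrays(a1[idx], a2[idx], statistic)))
            except ValueError:
                skipped += 1
        points.append((n, _stat_arrays(a1, a2, statistic)))
    else:
        grid = np.asarray(grid, dtype=int)
        if (grid < 1).any() or (grid > n).any():
            raise ValueError("grid sizes must lie in [1, n]")
        for _ in range(iters):
            perm = rng.permutation(n)
            for m in grid:
                idx = perm[:m]
                try:
                    points.append((int(m), _stat_arrays(a1[idx], a2[idx], statistic)))
                except ValueError:
                    skipped += 1
    df = pd.DataFrame(points, columns=["n", "value"])
    agg = (
        df.groupby("n")["value"]
        .agg(
            mean="mean",
            sd="std",
            q025=lambda v: v.quantile(0.025),
            q975=lambda v: v.quantile(0.975),
            reps="count",
        )
        .reset_index()
    )
    return AccumulationCurve(agg, statistic, iters, seed, skipped)


# ---------------------------------------------------------------------------
# Michaelis-Menten saturation fit
# ---------------------------------------------------------------------------


@dataclass
class MMFit:
    dmax: float
    k_half: float
    rss: float
    dmax_ci: tuple[float, float] | None = None
    n_boot: int = 0


def _mm(n, dmax, k):
    return dmax * n / (k + n)


def _fit_once(n: np.ndarray, d: np.ndarray, p0: tuple[float, float]):
    popt, _ = curve_fit(
        _mm, n, d, p0=p0, bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=10_000
    )
    rss = float(np.sum((d - _mm(n, *popt)) ** 2))
    return popt, rss


def _starts(n: np.ndarray, d: np.ndarray) -> list[tuple[float, float]]:
    # Lineweaver-Burk linearization: 1/D = 1/Dmax + (K/Dmax) (1/n)
    ok = d > 0
    starts: list[tuple[float, float]] = []
    if ok.sum() >= 2:
        b, a = np.polyfit(1.0 / n[ok], 1.0 / d[ok], 1)
        if a > 0:
            dmax0, k0 = 1.0 / a, max(b / a, 1e-6)
            starts.append((dmax0, k0))
            for f in (0.3, 3.0, 10.0):
                starts.append((dmax0, k0 * f))
    starts.append((float(d.max()) * 1.5, float(np.median(n))))
    return starts


def fit_michaelis_menten(
    n: np.ndarray,
    d: np.ndarray,
    n_boot: int = 0,
    seed: int = 0,
) -> MMFit:
    """Nonlinear least-squares fit of D(n) = Dmax n / (K_half + n).

    Multi-start NLS seeded by the Lineweaver-Burk linearization plus
    perturbed starts; the best residual sum of squares wins. With
    *n_boot* > 0, a leave-half-out bootstrap (refit on random halves of the
    points) yields a 95% percentile interval for Dmax. Raises
    ``RuntimeError`` when no start converges.
    """
    n = np.asarray(n, dtype=float)
    d = np.asarray(d, dtype=float)
    if len(np.unique(n)) < 3:
        raise ValueError("need >= 3 distinct sample sizes")
    best = None
    errors = []
    for p0 in _starts(n, d):
        try:
            popt, rss = _fit_once(n, d, p0)
        except RuntimeError as e:
            errors.append(str(e))
            continue
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError(f"Michaelis-Menten fit failed from all starts: {errors}")
    (dmax, k), rss = best
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        half = len(n) // 2
        if half < 3:
            raise ValueError("leave-half-out bootstrap needs >= 6 points")
        boots = []
        for _ in range(n_boot):
            idx = rng.permutation(len(n))[:half]
            try:
                (bd, _), _ = _fit_once(n[idx], d[idx], (dmax, k))
                boots.append(bd)
            except RuntimeError:
                continue
        if boots:
            ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return MMFit(float(dmax), float(k), rss, ci, n_boot)
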