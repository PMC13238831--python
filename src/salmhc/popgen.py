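"""Per-population diversity statistics on MHC genotype tables.

Observed/expected heterozygosity, hypergeometric rarefied allelic richness,
Nei-style multi-population FST, a Monte-Carlo Hardy-Weinberg test against
heterozygote deficit, and homozygosity rates. All statistics operate on the
long-format genotype table produced by the genotyper or the synthetic
generator (columns: individual, population, group, sex, locus, allele1,
allele2); individuals with a missing call at a locus are excluded from that
locus entirely, so allele-copy totals stay even.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class FrequencySpectrum:
    """Allele copy counts for one locus in one population."""

    locus: str
    population: str
    labels: list[str]
    counts: np.ndarray  # copy count N_i per allele, each >= 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.labels) != len(self.counts):
            raise ValueError("labels/counts length mismatch")
        if (self.counts < 1).any():
            raise ValueError("listed alleles must have copy count >= 1")

    @property
    def N(self) -> int:
        """Total allele copies (2 x called individuals)."""
        return int(self.counts.sum())

    @property
    def n_alleles(self) -> int:
        return len(self.counts)

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.N

    @classmethod
    def from_genotypes(
        cls, genotypes: pd.DataFrame, locus: str, population: str | None = None
    ) -> "FrequencySpectrum":
        sub = _called(genotypes, locus, population)
        if sub.empty:
            raise ValueError(f"no called genotypes for {locus}/{population}")
        copies = pd.concat([sub["allele1"], sub["allele2"]])
        counts = copies.value_counts().sort_index()
        return cls(locus, population or "all", list(counts.index), counts.to_numpy())


def _called(
    genotypes: pd.DataFrame, locus: str, population: str | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    sub = genotypes[genotypes["locus"] == locus]
    if population is not None:
        sub = sub[sub["population"] == population]
    if group is not None:
        sub = sub[sub["group"] == group]
    return sub.dropna(subset=["allele1", "allele2"])


def observed_heterozygosity(
    genotypes: pd.DataFrame, locus: str, population: str | None = None
) -> float:
    """Fraction of called individuals whose two alleles differ; NaN when no
    individual is called."""
    sub = _called(genotypes, locus, population)
    if sub.empty:
        return float("nan")
    return float((sub["allele1"] != sub["allele2"]).mean())


def expected_heterozygosity(spectrum: FrequencySpectrum) -> float:
    """Unbiased gene diversity He = N/(N-1) * (1 - sum p_i^2).

    Equals the probability that two allele copies drawn without replacement
    differ, hence He = 1 for counts (1, 1).
    """
    N = spectrum.N
    if N < 2:
        raise ValueError("expected heterozygosity needs >= 2 allele copies")
    return float(N / (N - 1) * (1.0 - np.sum(spectrum.freqs**2)))


def rarefied_allelic_richness(spectrum: FrequencySpectrum, g: int) -> float:
    """Expected allele count in a random subsample of g allele copies.

    AR(g) = sum_i [1 - C(N - N_i, g) / C(N, g)], evaluated in log space.
    g is in allele copies (diploid rarefaction to n individuals uses
    g = 2n). AR(N) equals the observed allele count exactly.
    """
    N, Ni = spectrum.N, spectrum.counts
    if not 1 <= g <= N:
        raise ValueError(f"rarefaction size g={g} outside [1, {N}]")

    def logC(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = N - Ni
    terms = np.ones(len(Ni))
    ok = rest >= g
    terms[ok] = 1.0 - np.exp(logC(rest[ok], g) - logC(np.array(N), g))
    return float(terms.sum())


@dataclass
class FstResult:
    locus: str
    fst: float
    Hs: float
    Ht: float
    pairwise: pd.DataFrame | None = None


def _nei_fst(spectra: list[FrequencySpectrum]) -> tuple[float, float, float]:
    """Nei/Chesser sample-size-corrected Gst over >= 2 populations.

    Uses unweighted means over populations and the harmonic mean sample
    size; returns (fst, Hs_hat, Ht_hat). NaN when monomorphic overall.
    """
    labels = sorted({l for s in spectra for l in s.labels})
    P = np.zeros((len(spectra), len(labels)))
    for i, s in enumerate(spectra):
        idx = {l: j for j, l in enumerate(labels)}
        for l, c in zip(s.labels, s.counts):
            P[i, idx[l]] = c / s.N
    r = len(spectra)
    n_harm = r / np.sum([2.0 / s.N for s in spectra])  # individuals
    Hs = 1.0 - np.mean(np.sum(P**2, axis=1))
    pbar = P.mean(axis=0)
    Ht = 1.0 - np.sum(pbar**2)
    Hs_hat = (2 * n_harm / (2 * n_harm - 1)) * Hs
    Ht_hat = Ht + Hs_hat / (2 * n_harm * r)
    if Ht_hat <= 0:
        return float("nan"), Hs_hat, Ht_hat
    return float((Ht_hat - Hs_hat) / Ht_hat), float(Hs_hat), float(Ht_hat)


def fst_multi(
    spectra: list[FrequencySpectrum], pairwise: bool = True
) -> FstResult:
    """Global (and optionally pairwise) Nei FST across populations.

    Monomorphic-everywhere input yields NaN (reported, never coerced to 0).
    """
    if len(spectra) < 2:
        raise ValueError("fst_multi needs >= 2 populations")
    if any(s.N < 2 for s in spectra):
        raise ValueError("every population needs >= 2 allele copies")
    locus = spectra[0].locus
    fst, Hs, Ht = _nei_fst(spectra)
    pw = None
    if pairwise:
        names = [s.population for s in spectra]
        mat = pd.DataFrame(np.nan, index=names, columns=names)
        for i in range(len(spectra)):
            for j in range(i + 1, len(spectra)):
                f, _, _ = _nei_fst([spectra[i], spectra[j]])
                mat.iloc[i, j] = mat.iloc[j, i] = f
        pw = mat
    return FstResult(locus, fst, Hs, Ht, pw)


def hwe_test(
    genotypes: pd.DataFrame,
    locus: str,
    population: str | None = None,
    reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo exact test for heterozygote deficit.

    The observed allele copies are randomly re-paired into diploids *reps*
    times; the p-value is the mid-p fraction of pairings with at least as
    many homozygotes as observed (ties counted half, which calibrates the
    discrete statistic to uniformity under the null). One-sided in the
    heterozygote-deficit direction; monomorphic data give p = 1.
    """
    sub = _called(genotypes, locus, population)
    n = len(sub)
    if n < 5:
        raise ValueError("hwe_test needs >= 5 called individuals")
    copies = pd.concat([sub["allele1"], sub["allele2"]]).to_numpy()
    if len(np.unique(copies)) == 1:
        return 1.0
    obs_hom = int((sub["allele1"] == sub["allele2"]).sum())
    codes = pd.factorize(copies)[0].astype(np.int32)
    rng = np.random.default_rng(seed)
    mat = np.tile(codes, (reps, 1))
    mat = rng.permuted(mat, axis=1)
    hom = (mat[:, 0::2] == mat[:, 1::2]).sum(axis=1)
    p = (np.count_nonzero(hom > obs_hom) + 0.5 * np.count_nonzero(hom == obs_hom)) / reps
    return float(p)


def homozygosity_rate(
    genotypes: pd.DataFrame,
    locus: str,
    by: str | None = "population",
) -> pd.Series | float:
    """Fraction of homozygous called individuals, per *by* level (or pooled
    when *by* is None)."""
    sub = _called(genotypes, locus)
    hom = sub["allele1"] == sub["allele2"]
    if by is None:
        return float(hom.mean())
    return hom.groupby(sub[by]).mean()


def summarize_diversity(
    genotypes: pd.DataFrame,
    locus: str,
    rarefaction_individuals: int = 17,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Per-population summary table: N_ind, N_all, Ho, He, AR(2g).

    *rarefaction_individuals* is the standard sample size (in individuals)
    for the rarefied allelic richness column; populations smaller than it
    are rarefied to their own size (AR then equals their allele count).
    """
    pops = populations or sorted(genotypes["population"].unique())
    rows = []
    for pop in pops:
        sub = _called(genotypes, locus, pop)
        if sub.empty:
            continue
        spec = FrequencySpectrum.from_genotypes(genotypes, locus, pop)
        g = 2 * min(rarefaction_individuals, len(sub))
        rows.append(
            {
                "population": pop,
                "locus": locus,
                "N_ind": len(sub),
                "N_all": spec.n_alleles,
                "Ho": observed_heterozygosity(genotypes, locus, pop),
                "He": expected_heterozygosity(spec),
                "AR": rarefied_allelic_richness(spec, g),
            }
        )
    return pd.DataFrame(rows)
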