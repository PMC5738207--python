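"""Generative genotyping-error model for microsatellite observations.

Two error classes act on a true genotype at each replicate PCR:

* **Allelic dropout (E1)** — for a true heterozygote, with probability
  E1 one of the two alleles (chosen uniformly) fails to amplify and the
  call appears homozygous for the other allele.
* **Stochastic miscall (E2)** — each apparent allele copy is then,
  independently, misread with probability E2; the misread value is
  drawn from the locus allele set proportional to population allele
  frequency, excluding the true allele (a uniform choice is available
  via ``miscall_weighting="uniform"``).

The model is deliberately isolated behind this module so an alternative
error structure (e.g. whole-genotype replacement) can be substituted
without touching the pedigree machinery.  Null alleles, contamination
and stutter are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genodata import AlleleFrequencyTable

__all__ = [
    "ErrorRates",
    "LocusStateSpace",
    "observation_distribution",
    "observation_matrix",
    "simulate_observation",
]

DEFAULT_E1 = 0.04
DEFAULT_E2 = 0.022


@dataclass
class ErrorRates:
    """Per-locus, per-source-class dropout (E1) and miscall (E2) rates.

    Unlisted locus/source combinations fall back to the defaults, the
    constants used for the preliminary pedigree fit.
    """

    default_e1: float = DEFAULT_E1
    default_e2: float = DEFAULT_E2
    per_locus: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e1, e2 in [(self.default_e1, self.default_e2), *self.per_locus.values()]:
            if not (0 <= e1 < 1 and 0 <= e2 < 1):
                raise ValueError(f"error rates out of [0,1): E1={e1}, E2={e2}")

    def get(self, locus: str, source_class: str = "SCAT") -> tuple[float, float]:
        return self.per_locus.get((locus, source_class), (self.default_e1, self.default_e2))

    def set(self, locus: str, source_class: str, e1: float, e2: float) -> None:
        if not (0 <= e1 < 1 and 0 <= e2 < 1):
            raise ValueError(f"error rates out of [0,1): E1={e1}, E2={e2}")
        self.per_locus[(locus, source_class)] = (e1, e2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": loc, "source_class": sc, "E1": e1, "E2": e2}
            for (loc, sc), (e1, e2) in sorted(self.per_locus.items())
        ]
        return pd.DataFrame(rows, columns=["locus", "source_class", "E1", "E2"])

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, default_e1: float = DEFAULT_E1, default_e2: float = DEFAULT_E2
    ) -> "ErrorRates":
        rates = cls(default_e1, default_e2)
        for row in df.itertuples(index=False):
            rates.set(str(row.locus), str(row.source_class), float(row.E1), float(row.E2))
        return rates


class LocusStateSpace:
    """Unordered-genotype state space of one locus, with model matrices.

    States are the g = k(k+1)/2 unordered allele pairs of a k-allele
    locus, indexed in lexicographic order.  Provides the Hardy-Weinberg
    prior over states, the observation (error) matrix and the Mendelian
    transmission tensor used by the parentage likelihood.
    """

    def __init__(self, locus_id: str, freqs: Mapping[str, float]):
        self.locus_id = locus_id
        self.alleles: list[str] = sorted(freqs)
        self.p = np.array([freqs[a] for a in self.alleles], float)
        k = len(self.alleles)
        self.k = k
        self.genotypes: list[tuple[int, int]] = [
            (i, j) for i in range(k) for j in range(i, k)
        ]
        self.n_states = len(self.genotypes)
        self._index = {g: s for s, g in enumerate(self.genotypes)}
        # ordered allele pair (u, v) -> unordered state index
        self._pair_state = np.empty((k, k), dtype=np.intp)
        for (i, j), s in self._index.items():
            self._pair_state[i, j] = self._pair_state[j, i] = s
        # collapse matrix: ordered pair (flattened k*k) -> unordered state
        self._collapse = np.zeros((k * k, self.n_states))
        self._collapse[np.arange(k * k), self._pair_state.ravel()] = 1.0
        # Hardy-Weinberg prior over unordered genotypes
        hw = np.empty(self.n_states)
        for s, (i, j) in enumerate(self.genotypes):
            hw[s] = self.p[i] ** 2 if i == j else 2 * self.p[i] * self.p[j]
        self.hw = hw

    def state_of(self, genotype: tuple[str, str]) -> int:
        i = self.alleles.index(genotype[0])
        j = self.alleles.index(genotype[1])
        if i > j:
            i, j = j, i
        return self._index[(i, j)]

    def genotype_of(self, state: int) -> tuple[str, str]:
        i, j = self.genotypes[state]
        return (self.alleles[i], self.alleles[j])

    def _miscall_matrix(self, e2: float, weighting: str) -> np.ndarray:
        """M[true allele, called allele]: per-copy allele read distribution."""
        k = self.k
        m = np.zeros((k, k))
        for t in range(k):
            if k == 1:
                m[t, t] = 1.0
                continue
            if weighting == "frequency":
                w = self.p.copy()
            elif weighting == "uniform":
                w = np.ones(k)
            else:
                raise ValueError(f"unknown miscall weighting {weighting!r}")
            w[t] = 0.0
            w /= w.sum()
            m[t] = e2 * w
            m[t, t] = 1.0 - e2
        return m

    def observation_matrix(
        self, e1: float, e2: float, miscall_weighting: str = "frequency"
    ) -> np.ndarray:
        """O[observed state, true state] = P(observed | true).

        Stage 1 (dropout) maps true genotypes to apparent genotypes;
        stage 2 (miscall) reads each apparent allele copy independently.
        Columns sum to 1.
        """
        g = self.n_states
        # dropout: D[true, apparent]
        d = np.zeros((g, g))
        for s, (i, j) in enumerate(self.genotypes):
            if i == j:
                d[s, s] = 1.0
            else:
                d[s, s] = 1.0 - e1
                d[s, self._index[(i, i)]] += e1 / 2
                d[s, self._index[(j, j)]] += e1 / 2
        # miscall on the two apparent copies (vectorised collapse of the
        # ordered read pair onto unordered observed states)
        m = self._miscall_matrix(e2, miscall_weighting)
        i_idx = np.array([i for i, _ in self.genotypes])
        j_idx = np.array([j for _, j in self.genotypes])
        ordered = np.einsum("su,sv->suv", m[i_idx], m[j_idx]).reshape(g, -1)
        c = ordered @ self._collapse  # C[apparent, observed]
        obs_given_true = d @ c  # [true, observed]
        return obs_given_true.T

    def transmission_tensor(self) -> np.ndarray:
        """T[dam state, sire state, offspring state]: Mendelian segregation."""
        g, k = self.n_states, self.k
        # per-genotype allele transmission distribution
        a = np.zeros((g, k))
        for s, (i, j) in enumerate(self.genotypes):
            a[s, i] += 0.5
            a[s, j] += 0.5
        return self._pair_to_offspring(a, a)

    def _pair_to_offspring(self, a_dam: np.ndarray, a_sire: np.ndarray) -> np.ndarray:
        g, k = self.n_states, self.k
        t = np.zeros((a_dam.shape[0], a_sire.shape[0], g))
        ordered = np.einsum("du,sv->dsuv", a_dam, a_sire)
        for u in range(k):
            for v in range(k):
                s = self._index[(u, v) if u <= v else (v, u)]
                t[:, :, s] += ordered[:, :, u, v]
        return t

    def hw_transmission(self) -> np.ndarray:
        """T[parent state, offspring state] with the other parent unsampled
        (its allele drawn from population frequencies)."""
        g, k = self.n_states, self.k
        a = np.zeros((g, k))
        for s, (i, j) in enumerate(self.genotypes):
            a[s, i] += 0.5
            a[s, j] += 0.5
        return self._pair_to_offspring(a, self.p[None, :])[:, 0, :]


_SPACE_CACHE: dict = {}
_OBS_CACHE: dict = {}


def _space(locus: str, freqs: AlleleFrequencyTable) -> LocusStateSpace:
    key = (locus, tuple(sorted(freqs.locus_freqs(locus).items())))
    space = _SPACE_CACHE.get(key)
    if space is None:
        if len(_SPACE_CACHE) > 4096:
            _SPACE_CACHE.clear()
        space = _SPACE_CACHE[key] = LocusStateSpace(locus, freqs.locus_freqs(locus))
    return space


def _cached_obs_matrix(
    locus: str,
    freqs: AlleleFrequencyTable,
    e1: float,
    e2: float,
    miscall_weighting: str,
) -> tuple[LocusStateSpace, np.ndarray]:
    space = _space(locus, freqs)
    key = (id(space), e1, e2, miscall_weighting)
    obs = _OBS_CACHE.get(key)
    if obs is None:
        if len(_OBS_CACHE) > 4096:
            _OBS_CACHE.clear()
        obs = _OBS_CACHE[key] = space.observation_matrix(e1, e2, miscall_weighting)
    return space, obs


def observation_distribution(
    true_genotype: tuple[str, str],
    locus: str,
    freqs: AlleleFrequencyTable,
    rates: ErrorRates,
    source_class: str = "SCAT",
    miscall_weighting: str = "frequency",
) -> dict[tuple[str, str], float]:
    """Distribution over observed unordered genotypes given the truth.

    Probabilities sum to 1; genotypes with zero probability are omitted.
    """
    e1, e2 = rates.get(locus, source_class)
    space, obs = _cached_obs_matrix(locus, freqs, e1, e2, miscall_weighting)
    for a in true_genotype:
        if a not in space.alleles:
            raise ValueError(f"allele {a!r} unknown at locus {locus}")
    col = obs[:, space.state_of(true_genotype)]
    return {
        space.genotype_of(s): float(p) for s, p in enumerate(col) if p > 0
    }


def observation_matrix(
    locus: str,
    freqs: AlleleFrequencyTable,
    rates: ErrorRates,
    source_class: str = "SCAT",
    miscall_weighting: str = "frequency",
) -> tuple[LocusStateSpace, np.ndarray]:
    """State space and O[observed, true] matrix for one locus."""
    space = _space(locus, freqs)
    e1, e2 = rates.get(locus, source_class)
    return space, space.observation_matrix(e1, e2, miscall_weighting)


def simulate_observation(
    true_genotype: tuple[str, str],
    locus: str,
    freqs: AlleleFrequencyTable,
    rates: ErrorRates,
    rng: np.random.Generator | int,
    source_class: str = "SCAT",
    missing_prob: float = 0.0,
    miscall_weighting: str = "frequency",
) -> tuple[str, str] | None:
    """Draw one replicate observation of a true genotype.

    With probability ``missing_prob`` the replicate fails entirely
    (returns None); otherwise a draw from the observation distribution.
    Deterministic for a fixed seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if missing_prob and rng.random() < missing_prob:
        return None
    dist = observation_distribution(
        true_genotype, locus, freqs, rates, source_class, miscall_weighting
    )
    genos = list(dist)
    probs = np.array([dist[g] for g in genos])
    idx = rng.choice(len(genos), p=probs / probs.sum())
    return genos[idx]
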